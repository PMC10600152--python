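"""Synthetic generators for every input the pipeline consumes.

The clinical tachograms this pipeline was designed around are not publicly
distributable, so the package ships generators for all the stochastic
ingredients the analyses assume: exact fractional Gaussian noise (fGn),
Brownian motion, conservative binomial cascades, and cascade-modulated
RR-interval cohorts with configurable group effects.  All generators are pure
functions of their parameters and seed.

The RR-interval model is a deliberate stand-in, not a fit to patient data:
``RR(i) = clip(mean_rr + sd_rr * w(i) * z(i), 300, 2000)`` where ``z`` is
unit-variance fGn with Hurst exponent ``hurst`` (linear long-range
correlation) and ``w`` is a unit-mean binomial-cascade weight series
(multiplicative amplitude modulation producing multifractal nonlinearity and
non-Gaussianity).  With ``cascade_p = 0.5`` the modulation is identically 1
and the series is a linear Gaussian process.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .series import BeatSeries, InvalidParameterError, UniformSeries

logger = logging.getLogger(__name__)

RR_CLIP_MS = (300.0, 2000.0)  # physiological plausibility bounds


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray, hurst: float, sd: float = 1.0) -> np.ndarray:
    """Autocovariance of fGn: rho(k) = (sd^2/2)(|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sd**2 * (np.abs(k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _check_hurst(hurst: float) -> None:
    if not (0.0 < hurst < 1.0):
        raise InvalidParameterError(f"hurst must lie in (0, 1), got {hurst}")


def _fgn_hosking(hurst: float, length: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Exact O(n^2) fGn via the Durbin–Levinson (Hosking) recursion.

    Fallback path when circulant embedding is not non-negative definite.
    """
    gamma = fgn_autocovariance(np.arange(length), hurst, sd)
    x = np.empty(length)
    phi = np.zeros(length)
    prev = np.zeros(length)
    v = gamma[0]
    x[0] = rng.standard_normal() * np.sqrt(v)
    for i in range(1, length):
        phi[i - 1] = (gamma[i] - phi[: i - 1] @ gamma[i - 1 : 0 : -1]) / v
        phi[: i - 1] = prev[: i - 1] - phi[i - 1] * prev[i - 2 :: -1]
        v *= 1.0 - phi[i - 1] ** 2
        prev[:i] = phi[:i]
        x[i] = phi[:i] @ x[i - 1 :: -1] + rng.standard_normal() * np.sqrt(v)
    return x


def generate_fgn(
    hurst: float,
    length: int,
    sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> UniformSeries:
    """Exact stationary fGn via circulant embedding (Davies–Harte).

    The sample has exactly the fGn autocovariance
    ``rho(k) = (sd^2/2)(|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})`` in distribution
    (not merely asymptotically, as filter-based approximations do).  For fGn
    the circulant embedding is non-negative definite in practice for all
    H in (0, 1); should a numerically negative eigenvalue appear, the
    generator falls back to the exact Hosking recursion and logs it.

    Parameters
    ----------
    hurst : float in (0, 1)
        Hurst exponent; 0.5 gives white noise.
    length : int >= 8
    sd : float
        Marginal standard deviation.
    """
    _check_hurst(hurst)
    if length < 8:
        raise InvalidParameterError("length must be >= 8")
    rng = np.random.default_rng(seed)

    m = 2 * (length - 1)
    gamma = fgn_autocovariance(np.arange(length), hurst, sd)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-9 * lam.max():
        logger.warning(
            "circulant embedding not non-negative definite (min eig %.3g); "
            "falling back to exact Hosking recursion",
            lam.min(),
        )
        return UniformSeries(_fgn_hosking(hurst, length, sd, rng), rate_hz=1.0)
    lam = np.clip(lam, 0.0, None)

    # Davies–Harte: build a Hermitian-symmetric spectral sample so that the
    # inverse transform is real with the prescribed covariance.
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.empty(m, dtype=complex)
    half = m // 2
    w[0] = np.sqrt(lam[0] / m) * z[0].real
    w[half] = np.sqrt(lam[half] / m) * z[half].real
    w[1:half] = np.sqrt(lam[1:half] / (2 * m)) * z[1:half]
    w[half + 1 :] = np.conj(w[half - 1 : 0 : -1])
    x = np.fft.fft(w).real[:length]
    return UniformSeries(x, rate_hz=1.0)


def generate_brownian(length: int, seed: int | np.random.Generator | None = None) -> UniformSeries:
    """Brownian motion: cumulative sum of iid standard-normal increments, x(0)=0."""
    if length < 2:
        raise InvalidParameterError("length must be >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal(length - 1)
    x = np.concatenate(([0.0], np.cumsum(steps)))
    return UniformSeries(x, rate_hz=1.0)


def generate_fbm(
    hurst: float, length: int, seed: int | np.random.Generator | None = None
) -> UniformSeries:
    """Fractional Brownian motion: cumulative sum of exact fGn increments, x(0)=0."""
    incr = generate_fgn(hurst, length - 1 if length > 8 else 8, sd=1.0, seed=seed)
    x = np.concatenate(([0.0], np.cumsum(incr.values)))[:length]
    return UniformSeries(x, rate_hz=1.0)


# ---------------------------------------------------------------------------
# multiplicative cascade
# ---------------------------------------------------------------------------

def generate_binomial_cascade(
    p: float, levels: int, seed: int | np.random.Generator | None = None
) -> UniformSeries:
    """Conservative binomial cascade measure of length ``2**levels``.

    Unit mass is split recursively into halves with weights ``(p, 1-p)``; at
    every node the left/right assignment of the two weights is randomized, so
    the resulting measure is statistically stationary (a fixed assignment
    would create a monotone left-to-right trend trivially visible to DFA).
    Total mass is exactly 1 and the theoretical singularity spectrum is known
    in closed form, which makes this the oracle process for multifractal
    estimation.
    """
    if not (0.5 <= p < 1.0):
        raise InvalidParameterError(f"cascade p must lie in [0.5, 1), got {p}")
    if not (4 <= levels <= 20):
        raise InvalidParameterError(f"levels must lie in [4, 20], got {levels}")
    rng = np.random.default_rng(seed)
    mass = np.array([1.0])
    for lev in range(levels):
        flips = rng.integers(0, 2, size=mass.size).astype(bool)
        left = np.where(flips, p, 1.0 - p)
        children = np.empty(2 * mass.size)
        children[0::2] = mass * left
        children[1::2] = mass * (1.0 - left)
        mass = children
    return UniformSeries(mass, rate_hz=1.0)


def binomial_cascade_alpha(q: np.ndarray | float, p: float) -> np.ndarray:
    """Closed-form singularity strength alpha(q) for the binomial cascade.

    ``alpha(q) = -(p^q ln p + (1-p)^q ln(1-p)) / ((p^q + (1-p)^q) ln 2)``.
    Serves as the analytic oracle for the direct spectrum estimator.
    """
    q = np.asarray(q, dtype=float)
    w = np.array([p, 1.0 - p])
    num = -(w[0] ** q * np.log(w[0]) + w[1] ** q * np.log(w[1]))
    den = (w[0] ** q + w[1] ** q) * np.log(2.0)
    return num / den


def binomial_cascade_delta_alpha(p: float, q_min: float = -5.0, q_max: float = 5.0) -> float:
    """Closed-form spectrum width over a finite q range (alpha is decreasing in q)."""
    return float(binomial_cascade_alpha(q_min, p) - binomial_cascade_alpha(q_max, p))


# ---------------------------------------------------------------------------
# RR-interval cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Generative parameters for one cohort group."""

    label: str
    n_subjects: int
    mean_rr: float = 800.0
    sd_rr: float = 50.0
    hurst: float = 0.75
    cascade_p: float = 0.75
    series_length: int = 2**14

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        _check_hurst(self.hurst)
        if not (0.5 <= self.cascade_p < 1.0):
            raise InvalidParameterError("cascade_p must lie in [0.5, 1)")
        if self.mean_rr <= 0:
            raise InvalidParameterError("mean_rr must be positive")
        if self.sd_rr < 0:
            raise InvalidParameterError("sd_rr must be nonnegative")


@dataclass
class CohortSpec:
    """A multi-group synthetic cohort: groups plus shared contamination/seed."""

    groups: list
    ectopic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ectopic_rate <= 0.2):
            raise InvalidParameterError("ectopic_rate must lie in [0, 0.2]")
        self.groups = [g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups]


def generate_rri_series(
    mean_rr: float = 800.0,
    sd_rr: float = 50.0,
    hurst: float = 0.75,
    cascade_p: float = 0.75,
    length: int = 2**14,
    ectopic_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "",
    group: str = "",
) -> BeatSeries:
    """Cascade-modulated RR-interval series with optional ectopic contamination.

    A fraction ``ectopic_rate`` of beats is labeled "V" and its interval
    halved, mimicking premature beats the cleaner must repair.  Beat times are
    cumulative sums of the (contaminated) intervals.
    """
    if not (0.0 <= ectopic_rate <= 0.2):
        raise InvalidParameterError("ectopic_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    z = generate_fgn(hurst, length, sd=1.0, seed=rng).values
    levels = max(4, int(np.ceil(np.log2(length))))
    w = generate_binomial_cascade(cascade_p, levels, seed=rng).values[:length]
    w = w / w.mean()  # unit-mean modulation
    rr = np.clip(mean_rr + sd_rr * w * z, *RR_CLIP_MS)

    labels = np.full(length, "N", dtype="U1")
    if ectopic_rate > 0:
        ect = rng.random(length) < ectopic_rate
        ect[0] = False  # keep the series anchor a normal beat
        rr = np.where(ect, rr / 2.0, rr)
        labels[ect] = "V"

    time_s = np.cumsum(rr) / 1000.0
    return BeatSeries(time_s=time_s, rr_ms=rr, label=labels,
                      subject_id=subject_id, group=group)


def generate_cohort(spec: CohortSpec) -> list[tuple[str, BeatSeries]]:
    """Generate all subjects of a cohort, deterministically given the seed.

    Per-subject sub-seeds are spawned from the master seed, so cohorts are
    bit-reproducible and individual subjects are statistically independent.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = sum(g.n_subjects for g in spec.groups)
    children = ss.spawn(n_total)
    out: list[tuple[str, BeatSeries]] = []
    i = 0
    for g in spec.groups:
        for j in range(g.n_subjects):
            beats = generate_rri_series(
                mean_rr=g.mean_rr,
                sd_rr=g.sd_rr,
                hurst=g.hurst,
                cascade_p=g.cascade_p,
                length=g.series_length,
                ectopic_rate=spec.ectopic_rate,
                seed=np.random.default_rng(children[i]),
                subject_id=f"{g.label}-{j:03d}",
                group=g.label,
            )
            out.append((g.label, beats))
            i += 1
    return out


def shuffle_series(x, seed: int | np.random.Generator | None = None):
    """Uniformly random permutation of the values; the value multiset is kept.

    Accepts a ``UniformSeries`` (permutes samples), a ``BeatSeries`` (permutes
    intervals and rebuilds beat times), or a plain array.
    """
    rng = np.random.default_rng(seed)
    if isinstance(x, UniformSeries):
        if len(x) < 2:
            raise InvalidParameterError("need at least 2 samples to shuffle")
        return UniformSeries(rng.permutation(x.values), rate_hz=x.rate_hz, t0_s=x.t0_s)
    if isinstance(x, BeatSeries):
        if len(x) < 2:
            raise InvalidParameterError("need at least 2 beats to shuffle")
        perm = rng.permutation(len(x))
        return x.with_intervals(x.rr_ms[perm], label=x.label[perm])
    arr = np.asarray(x)
    if arr.size < 2:
        raise InvalidParameterError("need at least 2 values to shuffle")
    return rng.permutation(arr)
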