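"""Direct (Chhabra–Jensen) estimation of the multifractal singularity spectrum.

The series is treated as a measure: bin proportions P_v(n) over nonoverlapping
bins of size n are raised to a moment order q and normalized into weights
``mu_v(q, n) = P_v^q / sum_j P_j^q``.  The singularity strength alpha(q) and
spectrum value f(q) are then the slopes of ``sum_v mu_v ln P_v`` and
``sum_v mu_v ln mu_v`` against ln n across scales.  A moment order q enters
the spectrum only when both regressions are close to perfect power laws
(|Pearson r| at or above a retention threshold, default 0.9975); the spectrum
width ``delta_alpha = alpha_max - alpha_min`` over the retained q is the
scalar multifractality summary used by the surrogate test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .series import InsufficientDataError, InvalidParameterError, UniformSeries

logger = logging.getLogger(__name__)


@dataclass
class SingularitySpectrum:
    """Estimated singularity spectrum (alpha(q), f(q)) with retention diagnostics."""

    q_grid: np.ndarray
    alpha_q: np.ndarray
    f_q: np.ndarray
    r_alpha: np.ndarray
    r_f: np.ndarray
    retained: np.ndarray
    delta_alpha: float
    scales_n: np.ndarray
    degenerate_reason: str = ""

    @property
    def is_degenerate(self) -> bool:
        return not np.isfinite(self.delta_alpha)


def default_cj_scales(length: int, max_frac: float = 0.125) -> np.ndarray:
    """Dyadic scale progression ``{4, 8, 16, ...}`` strictly below length*max_frac."""
    upper = length * max_frac
    scales = []
    n = 4
    while n < upper:
        scales.append(n)
        n *= 2
    if not scales:
        raise InsufficientDataError(f"series of length {length} admits no scales < {upper:g}")
    return np.asarray(scales, dtype=int)


def default_q_grid(q_min: float = -5.0, q_max: float = 5.0, q_step: float = 0.25) -> np.ndarray:
    return np.arange(q_min, q_max + q_step / 2, q_step)


def _as_positive_measure(values: np.ndarray, eps_frac: float = 1e-3) -> np.ndarray:
    """Shift a signal to a strictly positive measure if needed.

    Signals with nonpositive values (centered series, descriptor series) are
    shifted by ``-min + eps_frac * range`` before binning, and the shift is
    logged; the spectrum of an already-positive series is left untouched.
    """
    if values.min() > 0:
        return values
    rng = values.max() - values.min()
    if rng == 0:
        raise InvalidParameterError("constant nonpositive series has no measure")
    shift = -values.min() + eps_frac * rng
    logger.info("shifting series by %.6g to obtain a positive measure", shift)
    return values + shift


def cj_proportions(x, n: int) -> np.ndarray:
    """Bin proportions P_v(n): bin sums over nonoverlapping size-n bins, renormalized.

    The remainder shorter than one bin is discarded and the proportions are
    renormalized to sum to 1.
    """
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    if np.any(values < 0):
        raise InvalidParameterError("proportions require nonnegative values (shift first)")
    n_bins = values.size // n
    if n_bins < 1:
        raise InsufficientDataError(f"series shorter than one bin of size {n}")
    sums = values[: n_bins * n].reshape(n_bins, n).sum(axis=1)
    total = sums.sum()
    if total <= 0:
        raise InvalidParameterError("nonpositive total mass")
    return sums / total


def singularity_spectrum(
    x,
    q_grid: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    r_min: float = 0.9975,
    eps_frac: float = 1e-3,
) -> SingularitySpectrum:
    """Chhabra–Jensen spectrum of a series, with the r-based retention rule.

    For each scale the q-weighted averages ``A(q,n) = sum_v mu_v ln P_v`` and
    ``F(q,n) = sum_v mu_v ln mu_v`` are computed in log space (stable for
    large |q|); alpha(q) and f(q) are their OLS slopes against ln n.  A q is
    retained only when both regressions have |Pearson r| >= ``r_min``; the
    spectrum is flagged degenerate (``delta_alpha = NaN``) when fewer than 3
    q survive.
    """
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    if values.size < 64:
        raise InsufficientDataError("spectrum estimation needs at least 64 samples")
    values = _as_positive_measure(values, eps_frac=eps_frac)
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if scales is None:
        scales = default_cj_scales(values.size)
    scales = np.asarray(scales, dtype=int)

    A = np.empty((q_grid.size, scales.size))  # sum mu ln P
    F = np.empty((q_grid.size, scales.size))  # sum mu ln mu
    for j, n in enumerate(scales):
        ln_p = np.log(cj_proportions(values, int(n)))
        ql = q_grid[:, None] * ln_p[None, :]
        ln_mu = ql - logsumexp(ql, axis=1, keepdims=True)
        mu = np.exp(ln_mu)
        A[:, j] = mu @ ln_p
        F[:, j] = np.sum(mu * ln_mu, axis=1)

    ln_n = np.log(scales.astype(float))
    alpha_q = np.empty(q_grid.size)
    f_q = np.empty(q_grid.size)
    r_alpha = np.empty(q_grid.size)
    r_f = np.empty(q_grid.size)
    for i in range(q_grid.size):
        alpha_q[i], r_alpha[i] = _slope_and_r(ln_n, A[i])
        f_q[i], r_f[i] = _slope_and_r(ln_n, F[i])

    retained = (np.abs(r_alpha) >= r_min) & (np.abs(r_f) >= r_min)
    if np.sum(retained) < 3:
        return SingularitySpectrum(
            q_grid=q_grid, alpha_q=alpha_q, f_q=f_q, r_alpha=r_alpha, r_f=r_f,
            retained=retained, delta_alpha=float("nan"), scales_n=scales,
            degenerate_reason=(
                f"only {int(np.sum(retained))} q values passed the |r| >= {r_min} rule"
            ),
        )
    delta_alpha = float(alpha_q[retained].max() - alpha_q[retained].min())
    return SingularitySpectrum(
        q_grid=q_grid, alpha_q=alpha_q, f_q=f_q, r_alpha=r_alpha, r_f=r_f,
        retained=retained, delta_alpha=delta_alpha, scales_n=scales,
    )


def _slope_and_r(ln_n: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope of y on ln n plus the Pearson correlation of the fit."""
    slope, _ = np.polyfit(ln_n, y, 1)
    sy = y.std()
    r = 1.0 if sy == 0 else float(np.corrcoef(ln_n, y)[0, 1])
    return float(slope), r
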