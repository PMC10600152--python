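"""Ergodicity-breaking analysis via the Thirumalai–Mountain factor E_B.

A process is ergodic when its long-time averages converge to the ensemble
average.  E_B quantifies this through the time-averaged mean squared
displacement (TA-MSD) at lag Delta: over an ensemble of trajectories of
duration t,

    E_B(t) = ( <d2^2> - <d2>^2 ) / <d2>^2,      d2 = TA-MSD at lag Delta,

i.e. the relative variance of TA-MSD across the ensemble.  For Brownian
motion E_B(t) = (4/3)(Delta/t); for fractional Brownian motion with Hurst
exponent H it decays like Delta/t when H < 3/4 and like (Delta/t)^{4-4H}
when 3/4 < H < 1.  A flat E_B (log-log slope near 0) signals strong
ergodicity breaking; slope near -1 signals Brownian-like ergodic behavior.

For a single recording the ensemble is built from nonoverlapping segments of
the series itself (the time average across epochs within the same
measurement); an overlapping-window variant is available for short epoch
series where few nonoverlapping segments fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .series import InsufficientDataError, InvalidParameterError, UniformSeries
from .synthetic import shuffle_series

logger = logging.getLogger(__name__)


@dataclass
class EBCurve:
    """E_B as a function of trajectory duration t at fixed lag Delta."""

    lag_delta: int
    t_grid: np.ndarray
    eb_values: np.ndarray
    slope_loglog: float
    n_segments: np.ndarray
    series_id: str = ""
    variant: str = "original"  # or "shuffled"


def averages(trajectories: list, t_index: int) -> tuple[float, np.ndarray]:
    """Finite-ensemble average at a fixed time and per-trajectory time averages.

    Returns ``(ensemble_avg, time_avgs)`` where ``ensemble_avg`` is the mean
    across trajectories of the value at ``t_index`` and ``time_avgs`` the
    mean over time of each trajectory.  For an ergodic stationary process the
    two agree as both sizes grow.
    """
    if not trajectories:
        raise InsufficientDataError("empty ensemble")
    arrs = [np.asarray(t, dtype=float) for t in trajectories]
    if any(a.size <= t_index for a in arrs):
        raise InvalidParameterError(f"all trajectories must extend past index {t_index}")
    ensemble_avg = float(np.mean([a[t_index] for a in arrs]))
    time_avgs = np.array([a.mean() for a in arrs])
    return ensemble_avg, time_avgs


def ta_msd(x, lag_delta: int) -> float:
    """Time-averaged mean squared displacement at lag Delta.

    Discrete form: mean over t' of ``(x(t' + Delta) - x(t'))**2``, applied to
    the series values directly.
    """
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    if lag_delta < 1:
        raise InvalidParameterError("lag_delta must be >= 1")
    if values.size <= lag_delta:
        raise InsufficientDataError("series must be longer than the lag")
    d = values[lag_delta:] - values[:-lag_delta]
    return float(np.mean(d**2))


def eb_default_grid(length: int, mode: str = "raw") -> tuple[int, np.ndarray]:
    """Default (lag, t grid) for raw series and for epoch series.

    Raw series: lag Delta = 10, about 20 log-spaced durations from 2*Delta up
    to length/50.  Epoch series: lag Delta = 1, durations from 3 up to
    length/2 (every integer when that is 20 points or fewer).
    """
    if mode == "raw":
        if length < 100:
            raise InsufficientDataError("raw-mode grid needs length >= 100")
        lag = 10
        t_max = length // 50
        t_min = 2 * lag
        if t_max < t_min:
            raise InvalidParameterError("series too short for the T/50 range rule")
        grid = np.unique(np.round(np.geomspace(t_min, t_max, 20)).astype(int))
    elif mode == "epochs":
        if length < 8:
            raise InsufficientDataError("epoch-mode grid needs length >= 8")
        lag = 1
        t_max = length // 2
        candidates = np.arange(3, t_max + 1)
        if candidates.size > 20:
            candidates = np.unique(np.round(np.geomspace(3, t_max, 20)).astype(int))
        grid = candidates
    else:
        raise InvalidParameterError("mode must be 'raw' or 'epochs'")
    if grid.size == 0:
        raise InvalidParameterError("empty duration grid after constraints")
    return lag, grid


def _segment_tamsds(values: np.ndarray, t: int, lag: int, overlapping: bool) -> np.ndarray:
    """TA-MSD of each pseudo-ensemble segment of duration t."""
    if overlapping:
        stride = max(1, t // 4)
        starts = np.arange(0, values.size - t + 1, stride)
        segs = np.stack([values[s : s + t] for s in starts])
    else:
        n_seg = values.size // t
        segs = values[: n_seg * t].reshape(n_seg, t)
    d = segs[:, lag:] - segs[:, :-lag]
    return np.mean(d**2, axis=1)


def eb_curve(
    x,
    lag_delta: int,
    t_grid: np.ndarray | None = None,
    mode: str = "raw",
    overlapping: bool = False,
    series_id: str = "",
    variant: str = "original",
) -> EBCurve:
    """E_B(t) over a grid of trajectory durations, with its log-log decay slope.

    For each duration t the series is cut into segments of length t (the
    pseudo-ensemble); E_B(t) is the relative variance of the per-segment
    TA-MSD at lag ``lag_delta``.  ``slope_loglog`` is the OLS slope of
    ``ln E_B`` on ``ln t``: about -1 for Brownian-like ergodic decay, about 0
    under strong ergodicity breaking.
    """
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    if t_grid is None:
        lag_delta, t_grid = eb_default_grid(values.size, mode=mode)
    t_grid = np.asarray(t_grid, dtype=int)
    if np.any(t_grid <= lag_delta):
        raise InvalidParameterError("every duration must exceed the lag")

    ts, ebs, nsegs = [], [], []
    for t in t_grid:
        if not overlapping and values.size // t < 2:
            logger.warning("duration %d admits < 2 segments, dropped", t)
            continue
        m = _segment_tamsds(values, int(t), lag_delta, overlapping)
        if m.size < 2:
            logger.warning("duration %d admits < 2 segments, dropped", t)
            continue
        mean_m = m.mean()
        if mean_m == 0:
            logger.warning("zero mean TA-MSD at duration %d, dropped", t)
            continue
        eb = float(np.mean(m**2) - mean_m**2) / mean_m**2
        ts.append(int(t))
        ebs.append(eb)
        nsegs.append(m.size)
    if not ts:
        raise InsufficientDataError("no usable durations in the grid")

    ts_arr = np.array(ts)
    ebs_arr = np.array(ebs)
    positive = ebs_arr > 0
    if np.sum(positive) >= 2:
        slope, _ = np.polyfit(np.log(ts_arr[positive]), np.log(ebs_arr[positive]), 1)
    else:
        slope = float("nan")
    return EBCurve(
        lag_delta=lag_delta,
        t_grid=ts_arr,
        eb_values=ebs_arr,
        slope_loglog=float(slope),
        n_segments=np.array(nsegs),
        series_id=series_id,
        variant=variant,
    )


def compare_shuffled(
    x,
    lag_delta: int | None = None,
    t_grid: np.ndarray | None = None,
    mode: str = "raw",
    n_shuffles: int = 1,
    seed: int | None = None,
    overlapping: bool = False,
    series_id: str = "",
) -> tuple[EBCurve, EBCurve, float]:
    """E_B of a series versus its shuffled version.

    Shuffling preserves the value distribution but destroys temporal
    structure, so an ergodic benchmark with identical amplitude statistics is
    obtained.  Returns ``(original, shuffled, slope_gap)`` with
    ``slope_gap = slope(original) - slope(shuffled)``; a positive gap means
    the original decays more slowly (is less ergodic) than its shuffle.  The
    shuffled curve averages E_B over ``n_shuffles`` independent permutations.
    """
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    if lag_delta is None or t_grid is None:
        lag_default, grid_default = eb_default_grid(values.size, mode=mode)
        lag_delta = lag_delta if lag_delta is not None else lag_default
        t_grid = t_grid if t_grid is not None else grid_default

    orig = eb_curve(values, lag_delta, t_grid, overlapping=overlapping,
                    series_id=series_id, variant="original")

    ss = np.random.SeedSequence(seed)
    curves = []
    for child in ss.spawn(n_shuffles):
        shuf = shuffle_series(values, seed=np.random.default_rng(child))
        curves.append(eb_curve(shuf, lag_delta, t_grid, overlapping=overlapping,
                               series_id=series_id, variant="shuffled"))
    # average E_B across shuffles on the common duration grid
    common_t = curves[0].t_grid
    eb_mat = np.stack([c.eb_values for c in curves])
    eb_mean = eb_mat.mean(axis=0)
    positive = eb_mean > 0
    if np.sum(positive) >= 2:
        slope, _ = np.polyfit(np.log(common_t[positive]), np.log(eb_mean[positive]), 1)
    else:
        slope = float("nan")
    shuffled = EBCurve(
        lag_delta=lag_delta,
        t_grid=common_t,
        eb_values=eb_mean,
        slope_loglog=float(slope),
        n_segments=curves[0].n_segments,
        series_id=series_id,
        variant="shuffled",
    )
    gap = float(orig.slope_loglog - shuffled.slope_loglog)
    return orig, shuffled, gap
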