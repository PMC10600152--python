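"""Monofractal detrended fluctuation analysis (DFA).

DFA estimates the Hurst exponent of a noise-like series from the power-law
growth of detrended fluctuations of its integrated profile.  The series is
mean-centered and cumulatively summed, the profile is cut into nonoverlapping
bins of size n, a polynomial trend (linear by default) is removed per bin,
and the pooled RMS residual f(n) is regressed on n in log-log coordinates:
``f(n) ~ n^H``.  For fractional Gaussian noise the slope recovers the Hurst
exponent H directly; an fBm path analyzed the same way yields H + 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .series import InsufficientDataError, InvalidParameterError, UniformSeries

logger = logging.getLogger(__name__)


@dataclass
class FluctuationFunction:
    """DFA fluctuation function and its power-law fit."""

    scales_n: np.ndarray
    f_n: np.ndarray
    hurst: float
    fit_r2: float
    detrend_order: int
    profile_len_T: int


def default_scales(length: int, step: int = 4, max_frac: float = 0.25) -> np.ndarray:
    """Arithmetic scale progression ``{4, 8, 12, ...}`` strictly below length*max_frac."""
    upper = length * max_frac
    scales = np.arange(step, int(np.ceil(upper)), step)
    return scales[scales < upper]


def dfa_profile(x) -> np.ndarray:
    """Integrated, mean-centered profile: ``y(i) = sum_{k<=i} (x(k) - mean(x))``."""
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    if values.size < 16:
        raise InsufficientDataError("profile needs at least 16 samples")
    return np.cumsum(values - values.mean())


def _pooled_rms_residual(profile: np.ndarray, n: int, order: int, both_ends: bool) -> float:
    """RMS residual of per-bin polynomial detrending, pooled over all bins.

    Bins are anchored at the series start; the remainder shorter than n is
    discarded.  With ``both_ends=True`` a second pass anchored at the series
    end is averaged in (useful when the remainder is large).
    """
    n_bins = len(profile) // n
    t = np.arange(n, dtype=float)
    design = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(design)

    def _pass(y: np.ndarray) -> float:
        bins = y[: n_bins * n].reshape(n_bins, n)
        resid = bins - (bins @ q) @ q.T
        return float(np.mean(resid**2))

    ms = _pass(profile)
    if both_ends:
        ms = 0.5 * (ms + _pass(profile[::-1]))
    return float(np.sqrt(ms))


def dfa(
    x,
    scales: np.ndarray | None = None,
    order: int = 1,
    both_ends: bool = False,
) -> FluctuationFunction:
    """Detrended fluctuation analysis of a noise-like series.

    Parameters
    ----------
    x : array-like or UniformSeries
        The series (not its profile); integration happens internally.
    scales : array of int, optional
        Bin sizes; default ``{4, 8, 12, ...} < T/4``.
    order : int
        Detrending polynomial degree per bin (1 = classic DFA).
    both_ends : bool
        If True, average residuals over passes anchored at both series ends.

    Returns
    -------
    FluctuationFunction
        With ``hurst`` the OLS slope of ``log f(n)`` on ``log n`` over all
        retained scales and ``fit_r2`` the squared correlation of that fit.
    """
    values = x.values if isinstance(x, UniformSeries) else np.asarray(x, dtype=float)
    T = values.size
    if T < 32:
        raise InsufficientDataError("DFA needs at least 32 samples")
    if scales is None:
        scales = default_scales(T)
    scales = np.asarray(scales, dtype=int)
    if np.any(np.diff(scales) <= 0) or scales[0] < order + 2:
        raise InvalidParameterError("scales must be increasing and exceed the trend order")
    if np.any(T // scales < 2):
        raise InvalidParameterError("every scale must fit at least 2 bins")

    profile = dfa_profile(values)
    f = np.array([_pooled_rms_residual(profile, int(n), order, both_ends) for n in scales])

    keep = f > 0
    if not np.all(keep):
        logger.warning("dropping %d scales with zero fluctuation", int(np.sum(~keep)))
    if np.sum(keep) < 3:
        raise InsufficientDataError("fewer than 3 scales with positive fluctuation")
    ln_n = np.log(scales[keep].astype(float))
    ln_f = np.log(f[keep])
    slope, intercept = np.polyfit(ln_n, ln_f, 1)
    r = np.corrcoef(ln_n, ln_f)[0, 1]
    return FluctuationFunction(
        scales_n=scales[keep],
        f_n=f[keep],
        hurst=float(slope),
        fit_r2=float(r**2),
        detrend_order=order,
        profile_len_T=T,
    )


def hurst_fgn(x, **kwargs) -> float:
    """Convenience wrapper: the DFA Hurst exponent of a series."""
    return dfa(x, **kwargs).hurst
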