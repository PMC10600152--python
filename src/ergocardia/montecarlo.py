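"""Monte-Carlo group-specificity experiment.

Short segments are repeatedly drawn at random from each subject's long
recording, a descriptor is computed per segment, and a group test is run per
iteration.  The *detection failure rate* — the share of iterations in which
the test misses the group difference at level alpha — measures how badly
descriptor nonergodicity undermines group comparisons based on short
snapshots: for a nonergodic descriptor, a 1000-beat snapshot does not
represent the subject, so even real group differences are missed at high
rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import _LINEAR_FUNCS
from .dfa import dfa
from .preprocess import resample_rri
from .series import (
    BeatSeries,
    InsufficientDataError,
    InvalidParameterError,
    UniformSeries,
)
from .surrogates import tmf

logger = logging.getLogger(__name__)

#: Descriptors whose native domain is the interpolated (sample) series.
SAMPLE_DOMAIN_DESCRIPTORS = ("H_fGn", "t_MF")


@dataclass
class MCResult:
    """Outcome of the Monte-Carlo specificity experiment."""

    descriptor: str
    n_iter: int
    alpha: float
    p_values: np.ndarray  # (n_iter, n_contrasts)
    failure_rate: np.ndarray  # per contrast
    contrasts: list
    test: str
    seed: int | None
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptor": self.descriptor,
                "contrast": self.contrasts,
                "failure_rate": self.failure_rate,
                "alpha": self.alpha,
                "n_iter": self.n_iter,
                "test": self.test,
            }
        )


def sample_segment(
    x, seg_len: int, seed: int | np.random.Generator | None = None
):
    """Contiguous random window of ``seg_len`` beats or samples.

    The start index is uniform over all admissible positions; segments may
    overlap across repeated draws.  Works on a ``BeatSeries`` or a
    ``UniformSeries``; the chosen start index is returned alongside.
    """
    n = len(x)
    if n < seg_len:
        sid = getattr(x, "subject_id", "")
        raise InsufficientDataError(
            f"recording {sid!r} has {n} < {seg_len} required points"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n - seg_len + 1))
    if isinstance(x, BeatSeries):
        return x.slice(start, start + seg_len), start
    if isinstance(x, UniformSeries):
        return (
            UniformSeries(
                values=x.values[start : start + seg_len],
                rate_hz=x.rate_hz,
                t0_s=x.t0_s + start / x.rate_hz,
            ),
            start,
        )
    return np.asarray(x)[start : start + seg_len], start


def _descriptor_value(segment, descriptor: str, rng: np.random.Generator,
                      tmf_n_surr: int = 32) -> float:
    if descriptor in _LINEAR_FUNCS:
        rr = segment.rr_ms if isinstance(segment, BeatSeries) else np.asarray(segment)
        return float(_LINEAR_FUNCS[descriptor](rr))
    if descriptor == "H_fGn":
        return float(dfa(segment).hurst)
    if descriptor == "t_MF":
        seed = int(rng.integers(0, 2**31 - 1))
        return float(tmf(segment, n_surr=tmf_n_surr, seed=seed).t_mf)
    raise InvalidParameterError(f"unknown descriptor {descriptor!r}")


def mc_specificity(
    cohort: list,
    descriptor: str = "M",
    n_iter: int = 1000,
    seg_len: int = 1000,
    test: str = "anova+welch",
    alpha: float = 0.05,
    seed: int | None = None,
    control_group: str | None = None,
    rate_hz: float = 2.0,
    tmf_n_surr: int = 32,
) -> MCResult:
    """Detection-failure rates of a descriptor under repeated short sampling.

    Per iteration, one random ``seg_len``-point segment is drawn per subject
    (beats for linear descriptors, interpolated samples for H_fGn and t_MF),
    the descriptor is computed per subject, and the configured group tests
    are run.  The failure rate per contrast is the share of iterations with
    p >= ``alpha``.

    ``test`` is ``"anova"`` (one-way omnibus only), ``"welch"`` (pairwise
    Welch t of each group against the control only), or ``"anova+welch"``
    (both; the default).  The control group defaults to the first group label
    in cohort order.
    """
    groups = list(dict.fromkeys(g for g, _ in cohort))
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    counts = {g: sum(1 for gg, _ in cohort if gg == g) for g in groups}
    if min(counts.values()) < 3:
        raise InvalidParameterError("need at least 3 subjects per group")
    if test not in ("anova", "welch", "anova+welch"):
        raise InvalidParameterError("test must be 'anova', 'welch' or 'anova+welch'")
    control = control_group or groups[0]
    others = [g for g in groups if g != control]

    # H_fGn / t_MF operate on the evenly sampled series
    if descriptor in SAMPLE_DOMAIN_DESCRIPTORS:
        recordings = [(g, resample_rri(b, rate_hz=rate_hz)) for g, b in cohort]
    else:
        recordings = list(cohort)

    contrasts: list[str] = []
    if test in ("anova", "anova+welch"):
        contrasts.append("anova")
    if test in ("welch", "anova+welch"):
        contrasts.extend(f"{g} vs {control}" for g in others)

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.spawn(n_iter)
    rows = []
    n_dropped = 0
    for it in range(n_iter):
        rng = np.random.default_rng(iter_seeds[it])
        values: dict[str, list[float]] = {g: [] for g in groups}
        try:
            for g, rec in recordings:
                seg, _ = sample_segment(rec, seg_len, seed=rng)
                values[g].append(_descriptor_value(seg, descriptor, rng,
                                                   tmf_n_surr=tmf_n_surr))
        except (InsufficientDataError, InvalidParameterError) as exc:
            n_dropped += 1
            logger.warning("iteration %d dropped: %s", it, exc)
            continue
        ps = []
        if test in ("anova", "anova+welch"):
            ps.append(stats.f_oneway(*(values[g] for g in groups)).pvalue)
        if test in ("welch", "anova+welch"):
            for g in others:
                ps.append(
                    stats.ttest_ind(values[g], values[control], equal_var=False).pvalue
                )
        rows.append(ps)
    if n_dropped > 0.10 * n_iter:
        raise InsufficientDataError(
            f"{n_dropped}/{n_iter} iterations dropped (descriptor failures)"
        )
    p_values = np.asarray(rows)
    failure_rate = np.mean(p_values >= alpha, axis=0)
    return MCResult(
        descriptor=descriptor,
        n_iter=n_iter,
        alpha=alpha,
        p_values=p_values,
        failure_rate=failure_rate,
        contrasts=contrasts,
        test=test,
        seed=seed,
        n_dropped=n_dropped,
    )


def mixed_effects_group_test(epoch_frame: pd.DataFrame) -> pd.DataFrame:
    """Linear mixed-effects group test on pooled epoch descriptor values.

    Fits ``value ~ group`` with a random intercept per subject on a
    long-format epoch table (columns subject_id, group, descriptor, value)
    and returns Wald p-values for the group fixed effects, one frame row per
    descriptor.  This pools all epochs instead of testing one snapshot per
    iteration, which is the appropriate model when the full epoch series is
    available.
    """
    import statsmodels.formula.api as smf

    out = []
    for desc, sub in epoch_frame.dropna(subset=["value"]).groupby("descriptor"):
        if sub["group"].nunique() < 2:
            continue
        model = smf.mixedlm("value ~ C(group)", sub, groups=sub["subject_id"])
        fit = model.fit(reml=True, method="lbfgs")
        for name, p in fit.pvalues.items():
            if name.startswith("C(group)"):
                out.append({"descriptor": desc, "effect": name, "p_value": float(p)})
    return pd.DataFrame(out)
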