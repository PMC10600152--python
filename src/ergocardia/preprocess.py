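"""Tachogram cleaning, 2 Hz resampling, and epoching.

Holter-style preprocessing for 24-hour tachograms: ectopic (S/V-labeled)
intervals are interpolated from their normal neighbors, implausibly large
consecutive-interval jumps are *reported* for review (never silently edited,
because in clinical practice that step is a manual one), and the cleaned
beat-domain series is converted to an evenly sampled signal by cubic-spline
interpolation at 2 Hz (one sample per 500 ms).

Epoching follows a single convention everywhere: 0-based, half-open,
nonoverlapping windows; a trailing remainder shorter than one epoch is
discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .series import (
    BeatSeries,
    InsufficientDataError,
    InvalidParameterError,
    UniformSeries,
)


@dataclass
class CleaningReport:
    """What the cleaner changed and what it flagged for manual review.

    ``flagged_indices`` are 0-based positions ``i`` whose interval changed by
    more than ``rel_diff_threshold`` relative to interval ``i-1``; they are
    reported, not altered.
    """

    n_beats: int
    corrected_indices: list = field(default_factory=list)
    flagged_indices: list = field(default_factory=list)
    rel_diff_threshold: float = 0.20
    ectopic_interpolation: str = "flanking-median"

    @property
    def n_corrected(self) -> int:
        return len(self.corrected_indices)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_indices)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_beats": self.n_beats,
                "n_corrected": self.n_corrected,
                "corrected_indices": list(map(int, self.corrected_indices)),
                "n_flagged": self.n_flagged,
                "flagged_indices": list(map(int, self.flagged_indices)),
                "rel_diff_threshold": self.rel_diff_threshold,
                "ectopic_interpolation": self.ectopic_interpolation,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def clean_rri(
    beats: BeatSeries,
    rel_diff_threshold: float = 0.20,
    interpolation: str = "flanking",
) -> tuple[BeatSeries, CleaningReport]:
    """Interpolate ectopic intervals and flag large consecutive jumps.

    Every interval whose beat label is S or V is replaced by the median of
    the two adjacent N-labeled intervals (equivalently their midpoint); at a
    series boundary the single available neighbor is used.  With
    ``interpolation="following"`` the two *next* N-labeled intervals are used
    instead, for sensitivity analysis.  Intervals whose relative change from
    the previous interval exceeds ``rel_diff_threshold`` are recorded in the
    report but left untouched.  Beat times are recomputed from the corrected
    intervals; corrected beats are relabeled N.

    The pass is idempotent: running it on its own output makes no further
    correction.
    """
    if interpolation not in ("flanking", "following"):
        raise InvalidParameterError("interpolation must be 'flanking' or 'following'")
    rr = beats.rr_ms.copy()
    labels = beats.label.copy()
    ectopic = np.isin(labels, ("S", "V"))
    normal_idx = np.flatnonzero(~ectopic & (labels == "N"))
    if normal_idx.size == 0:
        raise InsufficientDataError("series contains no normal beats to interpolate from")

    corrected = np.flatnonzero(ectopic)
    for i in corrected:
        if interpolation == "flanking":
            prev_n = normal_idx[normal_idx < i]
            next_n = normal_idx[normal_idx > i]
            neighbors = []
            if prev_n.size:
                neighbors.append(rr[prev_n[-1]])
            if next_n.size:
                neighbors.append(rr[next_n[0]])
        else:  # two following normal intervals
            next_n = normal_idx[normal_idx > i][:2]
            neighbors = list(rr[next_n])
            if not neighbors:  # boundary: fall back to preceding neighbors
                prev_n = normal_idx[normal_idx < i][-2:]
                neighbors = list(rr[prev_n])
        rr[i] = float(np.median(neighbors))
        labels[i] = "N"

    out = beats.with_intervals(rr, label=labels)
    rel = np.abs(np.diff(out.rr_ms)) / out.rr_ms[:-1]
    flagged = (np.flatnonzero(rel > rel_diff_threshold) + 1).tolist()
    report = CleaningReport(
        n_beats=len(beats),
        corrected_indices=corrected.tolist(),
        flagged_indices=flagged,
        rel_diff_threshold=rel_diff_threshold,
        ectopic_interpolation=(
            "flanking-median" if interpolation == "flanking" else "following-median"
        ),
    )
    return out, report


def resample_rri(beats: BeatSeries, rate_hz: float = 2.0) -> UniformSeries:
    """Cubic-spline interpolation of the tachogram onto an even grid.

    A natural cubic spline through ``(time_s, rr_ms)`` is evaluated at
    ``t0, t0 + 1/rate_hz, ...`` up to (and including) the last beat time;
    there is no extrapolation beyond the observed range.  The default 2 Hz
    grid spaces samples exactly 500 ms apart.
    """
    if len(beats) < 4:
        raise InsufficientDataError("cubic-spline resampling needs at least 4 beats")
    if rate_hz <= 0:
        raise InvalidParameterError("rate_hz must be positive")
    spline = CubicSpline(beats.time_s, beats.rr_ms, bc_type="natural")
    t0, t_end = beats.time_s[0], beats.time_s[-1]
    n = int(np.floor((t_end - t0) * rate_hz + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate_hz
    return UniformSeries(values=spline(grid), rate_hz=rate_hz, t0_s=t0)


def split_epochs(x, epoch_len: int) -> list:
    """Nonoverlapping epochs ``[k*epoch_len, (k+1)*epoch_len)``, remainder dropped.

    Works on a ``BeatSeries`` (beat-domain epochs), a ``UniformSeries``
    (sample-domain epochs), or a plain array; returns segments of the same
    kind.  A series shorter than one epoch yields an empty list.
    """
    if epoch_len < 2:
        raise InvalidParameterError("epoch_len must be >= 2")
    n = len(x)
    k = n // epoch_len
    if isinstance(x, BeatSeries):
        return [x.slice(i * epoch_len, (i + 1) * epoch_len) for i in range(k)]
    if isinstance(x, UniformSeries):
        return [
            UniformSeries(
                values=x.values[i * epoch_len : (i + 1) * epoch_len],
                rate_hz=x.rate_hz,
                t0_s=x.t0_s + i * epoch_len / x.rate_hz,
            )
            for i in range(k)
        ]
    arr = np.asarray(x)
    return [arr[i * epoch_len : (i + 1) * epoch_len] for i in range(k)]
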