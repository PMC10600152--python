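"""Core containers for beat-indexed and evenly sampled cardiac series.

Two time bases coexist in ambulatory HRV work: the *beat* domain, where the
series is indexed by heartbeat number and carries one RR interval (ms) plus a
morphology label per beat, and the *sample* domain, where the RR-interval
signal has been interpolated onto an even grid.  ``BeatSeries`` and
``UniformSeries`` model the two; ``EpochDescriptorSeries`` holds one
descriptor value per nonoverlapping epoch of either.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Allowed beat morphology labels: normal sinus, supraventricular ectopic,
#: ventricular ectopic, artifact/unclassifiable.
BEAT_LABELS = ("N", "S", "V", "X")

#: Descriptors computable per epoch.
DESCRIPTORS = ("M", "RMS", "RMSSD", "NN50", "pNN50", "H_fGn", "t_MF")


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(ValueError):
    """The input series is too short for the requested operation."""


@dataclass
class BeatSeries:
    """Annotated beat-by-beat record (tachogram).

    Attributes
    ----------
    time_s : ndarray
        Beat occurrence time in seconds, strictly increasing.  Beat ``i``'s
        time is the cumulative sum of intervals up to and including beat
        ``i``, so ``rr_ms[i] == 1000 * (time_s[i] - time_s[i-1])``.
    rr_ms : ndarray
        RR interval in milliseconds, all positive.
    label : ndarray of str
        Per-beat morphology label, one of ``N/S/V/X``.
    """

    time_s: np.ndarray
    rr_ms: np.ndarray
    label: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.label = np.asarray(self.label, dtype="U1")
        if not (len(self.time_s) == len(self.rr_ms) == len(self.label)):
            raise InvalidParameterError("time_s, rr_ms and label must have equal length")
        if len(self.rr_ms) == 0:
            raise InsufficientDataError("empty beat series")
        if np.any(self.rr_ms <= 0):
            raise InvalidParameterError("all RR intervals must be positive")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidParameterError("beat times must be strictly increasing")
        bad = set(np.unique(self.label)) - set(BEAT_LABELS)
        if bad:
            raise InvalidParameterError(f"unknown beat labels: {sorted(bad)}")
        # consistency of times with intervals (1 ms slack for file round-trips)
        if len(self.rr_ms) >= 2:
            dt_ms = 1000.0 * np.diff(self.time_s)
            if np.any(np.abs(dt_ms - self.rr_ms[1:]) > 1.0):
                raise InvalidParameterError(
                    "beat times inconsistent with RR intervals (> 1 ms mismatch)"
                )

    def __len__(self) -> int:
        return len(self.rr_ms)

    def slice(self, start: int, stop: int) -> "BeatSeries":
        """Contiguous sub-series with times rebased onto the same clock."""
        return BeatSeries(
            time_s=self.time_s[start:stop],
            rr_ms=self.rr_ms[start:stop],
            label=self.label[start:stop],
            subject_id=self.subject_id,
            group=self.group,
        )

    def with_intervals(self, rr_ms: np.ndarray, label: np.ndarray | None = None) -> "BeatSeries":
        """New series with intervals replaced and times recomputed cumulatively.

        The first beat keeps the original start time.
        """
        rr_ms = np.asarray(rr_ms, dtype=float)
        t0 = self.time_s[0]
        time_s = t0 + np.concatenate(([0.0], np.cumsum(rr_ms[1:]) / 1000.0))
        return BeatSeries(
            time_s=time_s,
            rr_ms=rr_ms,
            label=self.label if label is None else label,
            subject_id=self.subject_id,
            group=self.group,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "rr_ms": self.rr_ms, "label": self.label}
        )


@dataclass
class UniformSeries:
    """Evenly sampled series: interpolated RR signal or any simulated x(t)."""

    values: np.ndarray
    rate_hz: float = 2.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise InvalidParameterError("rate_hz must be positive")
        if self.values.size < 1:
            raise InsufficientDataError("UniformSeries needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz


@dataclass
class EpochDescriptorSeries:
    """One descriptor value per nonoverlapping epoch.

    ``values`` may contain NaN only where an epoch failed; the reason is kept
    in ``failures`` keyed by epoch index.
    """

    descriptor: str
    values: np.ndarray
    epoch_len: int
    epoch_domain: str  # "beats" or "samples"
    subject_id: str = ""
    group: str = ""
    failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.descriptor not in DESCRIPTORS:
            raise InvalidParameterError(f"unknown descriptor {self.descriptor!r}")
        if self.epoch_domain not in ("beats", "samples"):
            raise InvalidParameterError("epoch_domain must be 'beats' or 'samples'")
        self.values = np.asarray(self.values, dtype=float)
        nan_idx = set(np.flatnonzero(~np.isfinite(self.values)).tolist())
        if not nan_idx <= set(self.failures):
            raise InvalidParameterError(
                "non-finite epoch values require a logged failure reason"
            )

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject_id, group, descriptor, epoch_index, value."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "descriptor": self.descriptor,
                "epoch_index": np.arange(len(self.values)),
                "value": self.values,
            }
        )


def write_tachogram(beats: BeatSeries, path: str | Path) -> None:
    """Write a tachogram CSV with columns ``time_s, rr_ms, label``."""
    beats.to_frame().to_csv(path, index=False)


def read_tachogram(path: str | Path, subject_id: str = "", group: str = "") -> BeatSeries:
    """Read a tachogram CSV written by :func:`write_tachogram`."""
    df = pd.read_csv(path)
    missing = {"time_s", "rr_ms", "label"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"tachogram file lacks columns: {sorted(missing)}")
    return BeatSeries(
        time_s=df["time_s"].to_numpy(float),
        rr_ms=df["rr_ms"].to_numpy(float),
        label=df["label"].to_numpy(str),
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def epoch_series_frame(series: Iterable[EpochDescriptorSeries]) -> pd.DataFrame:
    """Concatenate epoch descriptor series into one long-format table."""
    frames = [s.to_frame() for s in series]
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "group", "descriptor", "epoch_index", "value"]
        )
    return pd.concat(frames, ignore_index=True)
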