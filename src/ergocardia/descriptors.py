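"""Conventional linear HRV descriptors, computed per epoch.

M (mean RR), RMS, RMSSD, NN50 and pNN50 summarize an RR-interval segment in
the time domain.  Two RMS variants are provided because both readings are in
circulation: ``rms`` is the root mean square of the interval values
themselves, ``rmssd`` the root mean square of successive differences.  The
pipeline default is ``rms``; either can be selected.
"""

from __future__ import annotations

import numpy as np

from .preprocess import split_epochs
from .series import (
    BeatSeries,
    EpochDescriptorSeries,
    InsufficientDataError,
    InvalidParameterError,
)


def mean_rr(segment: np.ndarray) -> float:
    """Arithmetic mean of the RR intervals (descriptor M), in ms."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise InsufficientDataError("empty segment")
    return float(segment.mean())


def rms(segment: np.ndarray) -> float:
    """Root mean square of the interval values: sqrt(mean(x^2)), in ms.

    Note this is computed on the values themselves, not on successive
    differences (see :func:`rmssd`), so for RR intervals it satisfies
    ``rms**2 == mean**2 + population variance``.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise InsufficientDataError("empty segment")
    return float(np.sqrt(np.mean(segment**2)))


def rmssd(segment: np.ndarray) -> float:
    """Root mean square of successive RR-interval differences, in ms."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise InsufficientDataError("RMSSD needs at least 2 intervals")
    return float(np.sqrt(np.mean(np.diff(segment) ** 2)))


def nn_counts(segment: np.ndarray, threshold_ms: float = 50.0) -> tuple[int, float]:
    """NN50 and pNN50 of a segment.

    NN50 counts successive interval pairs differing by strictly more than
    ``threshold_ms``; pNN50 is that count as a percentage of the
    ``len(segment) - 1`` pairs.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise InsufficientDataError("NN50 needs at least 2 intervals")
    nn50 = int(np.sum(np.abs(np.diff(segment)) > threshold_ms))
    pnn50 = 100.0 * nn50 / (segment.size - 1)
    return nn50, pnn50


_LINEAR_FUNCS = {
    "M": mean_rr,
    "RMS": rms,
    "RMSSD": rmssd,
    "NN50": lambda s: float(nn_counts(s)[0]),
    "pNN50": lambda s: nn_counts(s)[1],
}


def descriptor_epoch_series(
    beats: BeatSeries, descriptor: str, epoch_len: int = 500
) -> EpochDescriptorSeries:
    """One linear descriptor value per nonoverlapping ``epoch_len``-beat epoch.

    The default epoch length is 500 beats.  At least 2 full epochs are
    required, since the downstream ergodicity analysis needs a series of
    epoch values, not a single number.
    """
    if descriptor not in _LINEAR_FUNCS:
        raise InvalidParameterError(
            f"descriptor must be one of {sorted(_LINEAR_FUNCS)}, got {descriptor!r}"
        )
    epochs = split_epochs(beats, epoch_len)
    if len(epochs) < 2:
        raise InsufficientDataError(
            f"need at least 2 full epochs of {epoch_len} beats, got {len(epochs)}"
        )
    func = _LINEAR_FUNCS[descriptor]
    values = np.array([func(e.rr_ms) for e in epochs])
    return EpochDescriptorSeries(
        descriptor=descriptor,
        values=values,
        epoch_len=epoch_len,
        epoch_domain="beats",
        subject_id=beats.subject_id,
        group=beats.group,
    )
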