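"""Inter-recording lag estimation and communication-window segmentation.

Independently started mobile recorders are offset by up to a few seconds.
The offsets are estimated by cross-correlating each subject's audio envelope
against a reference subject's, communication-event timestamps are shifted
onto each subject's recording clock, and the corresponding EEG sample
windows are cut for TI analysis. Windows shorter than one 1-second epoch
cannot contribute a coherence estimate and are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .preprocess import EEGRecording

__all__ = [
    "CommunicationEvent",
    "LagEstimate",
    "SegmentWindow",
    "estimate_lag",
    "lag_table",
    "apply_lags",
    "segment_eeg",
]


class AlignmentError(ValueError):
    """Raised on invalid alignment inputs."""


#: Normalized cross-correlation peaks below this are flagged unreliable.
MIN_PEAK_CORR = 0.2
#: Default search range for lags, seconds (recorders start within seconds).
DEFAULT_MAX_LAG = 5.0


@dataclass(frozen=True)
class CommunicationEvent:
    """A verbal interaction between two subjects, on the reference clock."""

    id: str
    sender: str
    receiver: str
    start_unix: float
    end_unix: float

    def __post_init__(self) -> None:
        if self.end_unix <= self.start_unix:
            raise AlignmentError(f"event {self.id}: end not after start")
        if self.sender == self.receiver:
            raise AlignmentError(f"event {self.id}: sender equals receiver")

    @property
    def duration(self) -> float:
        return self.end_unix - self.start_unix


@dataclass(frozen=True)
class LagEstimate:
    """Lag of one subject's recording relative to the reference, milliseconds.

    Positive lag: the subject's content starts later than the reference's.
    """

    lag_ms: float
    peak_corr: float
    reliable: bool


def estimate_lag(
    env_ref: np.ndarray,
    env_other: np.ndarray,
    fs_audio: float,
    max_lag: float = DEFAULT_MAX_LAG,
    min_duration: float = 10.0,
) -> LagEstimate:
    """Lag between two audio envelopes via normalized cross-correlation.

    The lag is the argmax of the normalized cross-correlation within
    ``+-max_lag`` seconds. The estimate is antisymmetric in its arguments
    (within one audio sample). A peak correlation below 0.2 yields
    ``reliable=False``.
    """
    a = np.asarray(env_ref, dtype=float)
    b = np.asarray(env_other, dtype=float)
    if min(len(a), len(b)) < min_duration * fs_audio:
        raise AlignmentError(f"envelopes must cover at least {min_duration} s")
    if a.std() == 0 or b.std() == 0:
        raise AlignmentError("zero-variance envelope")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()

    max_shift = int(round(max_lag * fs_audio))
    corr = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(len(b), len(a), mode="full")
    keep = np.abs(lags) <= max_shift
    corr, lags = corr[keep], lags[keep]
    # normalize by the overlap length so partial overlaps are comparable
    overlap = np.minimum(len(a), len(b)) - np.abs(lags)
    corr = corr / overlap
    best = int(np.argmax(corr))
    lag_samples = int(lags[best])
    peak = float(corr[best])
    return LagEstimate(
        lag_ms=1000.0 * lag_samples / fs_audio,
        peak_corr=peak,
        reliable=peak >= MIN_PEAK_CORR,
    )


def lag_table(
    envelopes: Mapping[str, np.ndarray],
    fs_audio: float,
    reference: str | None = None,
    max_lag: float = DEFAULT_MAX_LAG,
) -> dict[str, LagEstimate]:
    """Per-subject lags relative to a reference subject (first by default).

    The reference's own lag is exactly 0 ms.
    """
    subjects = list(envelopes)
    reference = reference or subjects[0]
    if reference not in envelopes:
        raise AlignmentError(f"reference subject {reference!r} has no envelope")
    out: dict[str, LagEstimate] = {}
    for sid in subjects:
        if sid == reference:
            out[sid] = LagEstimate(lag_ms=0.0, peak_corr=1.0, reliable=True)
        else:
            out[sid] = estimate_lag(
                envelopes[reference], envelopes[sid], fs_audio, max_lag
            )
    return out


def apply_lags(
    events: Sequence[CommunicationEvent],
    lags_ms: Mapping[str, float],
    subjects: Sequence[str] | None = None,
) -> dict[str, list[CommunicationEvent]]:
    """Shift event windows onto each subject's recording clock.

    A subject whose content starts ``L`` ms late sees the interaction at
    reference time ``t`` at its own timestamp ``t + L``; each subject's event
    list is therefore shifted by that subject's lag. Event ordering is
    preserved (a common shift cannot reorder events).
    """
    subjects = list(subjects) if subjects is not None else list(lags_ms)
    missing = [s for ev in events for s in (ev.sender, ev.receiver) if s not in lags_ms]
    if missing:
        raise AlignmentError(f"no lag for subject(s) {sorted(set(missing))}")
    out: dict[str, list[CommunicationEvent]] = {}
    for sid in subjects:
        shift = lags_ms[sid] / 1000.0
        out[sid] = [
            replace(ev, start_unix=ev.start_unix + shift, end_unix=ev.end_unix + shift)
            for ev in events
        ]
    return out


@dataclass(frozen=True)
class SegmentWindow:
    """0-based half-open sample window of an event within a recording."""

    start: int
    stop: int
    valid: bool
    reason: str = ""

    @property
    def n_samples(self) -> int:
        return max(self.stop - self.start, 0)


def segment_eeg(
    rec: EEGRecording,
    event: CommunicationEvent,
    min_seconds: float = 1.0,
) -> SegmentWindow:
    """Sample window of an event: ``[ceil((start-t0)*fs), floor((end-t0)*fs))``.

    Clipped to the recording; windows shorter than ``min_seconds`` (one epoch
    by default, the coherence floor) are reported invalid rather than raising.
    """
    start = int(np.ceil((event.start_unix - rec.t0_unix) * rec.fs))
    stop = int(np.floor((event.end_unix - rec.t0_unix) * rec.fs))
    clipped_start = max(start, 0)
    clipped_stop = min(stop, rec.n_times)
    if clipped_stop <= clipped_start:
        return SegmentWindow(clipped_start, clipped_start, False, "outside recording")
    if clipped_stop - clipped_start < min_seconds * rec.fs:
        return SegmentWindow(
            clipped_start, clipped_stop, False, "shorter than one epoch"
        )
    return SegmentWindow(clipped_start, clipped_stop, True)
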