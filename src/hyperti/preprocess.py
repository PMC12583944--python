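"""Reading, filtering, rereferencing, region reduction and artifact epoching of EEG.

The preprocessing chain mirrors a mobile-EEG hyperscanning workflow:
15-channel 10-20 recordings digitized at 125 Hz, referenced to CPz at
acquisition, are band-pass filtered to 1-40 Hz with a zero-phase filter,
rereferenced to the scalp average, reduced to three lobe-level regions
(anterior / central / posterior), cut into contiguous 1-second epochs, and
screened with an amplitude rule: an epoch is rejected when any sample on any
channel exceeds a multiple (default 6) of that channel's "golden SD" -- a
robust, artifact-resistant per-channel scale estimate (1.4826 x median
absolute deviation of the filtered signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

#: 10-20 montage used throughout: 15 passive electrodes.
MONTAGE_15: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "C3", "Cz", "C4",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Standard lobe partition of the montage into three analysis regions.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "anterior": ("Fp1", "Fp2", "F3", "Fz", "F4"),
    "central": ("C3", "Cz", "C4"),
    "posterior": ("P7", "P3", "Pz", "P4", "P8", "O1", "O2"),
}

REGION_NAMES: tuple[str, ...] = ("anterior", "central", "posterior")

DEFAULT_FS: float = 125.0
#: Band-pass edges, Hz.
FILTER_LO: float = 1.0
FILTER_HI: float = 40.0
#: Golden-SD multiplier for the amplitude rejection rule.
DEFAULT_GOLDEN_MULT: float = 6.0
#: Epoch length, seconds (fixed by the 1-Hz spectral resolution of the method).
EPOCH_SECONDS: float = 1.0


class PreprocessError(ValueError):
    """Raised on invalid recordings or preprocessing parameters."""


@dataclass
class EEGRecording:
    """One subject's continuous multichannel EEG.

    Parameters
    ----------
    subject : str
        Subject / profession identifier.
    channel_labels : sequence of str
        Unique 10-20 channel names, one per column of ``samples``.
    fs : float
        Sampling rate in Hz (125 by default for the supported devices).
    samples : ndarray, shape (n_times, n_channels)
        Signal in microvolts.
    t0_unix : float
        Unix timestamp (seconds) of the first sample.
    reference : str
        One of ``"CPz"``, ``"average"`` or ``"raw"``.
    """

    subject: str
    channel_labels: tuple[str, ...]
    fs: float
    samples: np.ndarray
    t0_unix: float = 0.0
    reference: str = "CPz"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise PreprocessError("samples must be a (time x channel) matrix")
        if self.samples.shape[1] != len(self.channel_labels):
            raise PreprocessError(
                f"{self.samples.shape[1]} columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise PreprocessError("channel labels must be unique")
        if self.fs <= 0:
            raise PreprocessError("sampling rate must be positive")

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.fs

    @property
    def times_unix(self) -> np.ndarray:
        return self.t0_unix + np.arange(self.n_times) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise PreprocessError(f"channel {label!r} not present") from None
        return self.samples[:, idx]


@dataclass(frozen=True)
class RegionMap:
    """Assignment of channels to disjoint scalp regions."""

    regions: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, chans in self.regions.items():
            if not chans:
                raise PreprocessError(f"region {name!r} is empty")
            overlap = seen.intersection(chans)
            if overlap:
                raise PreprocessError(f"channels {sorted(overlap)} in two regions")
            seen.update(chans)

    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)


@dataclass(frozen=True)
class GoldenSD:
    """Robust per-channel scale estimates (microvolts) from clean EEG."""

    values: Mapping[str, float]
    description: str = "1.4826 x MAD of the filtered recording"

    def __post_init__(self) -> None:
        for ch, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise PreprocessError(f"golden SD for channel {ch!r} is not positive")

    def as_array(self, channel_labels: Sequence[str]) -> np.ndarray:
        return np.array([self.values[ch] for ch in channel_labels])


@dataclass
class EpochSet:
    """Contiguous non-overlapping 1-s epochs with per-epoch clean flags."""

    fs: float
    n_epochs: int
    clean: np.ndarray  # bool, shape (n_epochs,)

    def __post_init__(self) -> None:
        self.clean = np.asarray(self.clean, dtype=bool)
        if self.clean.shape != (self.n_epochs,):
            raise PreprocessError("clean flags must have one entry per epoch")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.fs * EPOCH_SECONDS))

    def boundaries(self) -> np.ndarray:
        """0-based half-open sample windows, shape (n_epochs, 2)."""
        n = self.epoch_samples
        starts = np.arange(self.n_epochs) * n
        return np.stack([starts, starts + n], axis=1)

    def clean_indices(self) -> np.ndarray:
        return np.flatnonzero(self.clean)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as ``unix_time,<channels>`` CSV (microvolts)."""
    df = pd.DataFrame(rec.samples, columns=list(rec.channel_labels))
    df.insert(0, "unix_time", rec.times_unix)
    df.to_csv(path, index=False, float_format="%.6f")


def read_eeg_csv(
    path: str | Path,
    subject: str | None = None,
    expected_labels: Sequence[str] = MONTAGE_15,
    reference: str = "CPz",
    dt_tol: float = 0.01,
) -> EEGRecording:
    """Read a ``unix_time,<channels>`` CSV into an :class:`EEGRecording`.

    Validates that every expected channel is present and that sampling is
    uniform: consecutive timestamp differences may deviate from the median
    interval by at most ``dt_tol`` (fractional).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "unix_time" not in df.columns:
        raise PreprocessError(f"{path}: missing 'unix_time' column")
    missing = [ch for ch in expected_labels if ch not in df.columns]
    if missing:
        raise PreprocessError(f"{path}: missing channel(s) {missing}")
    t = df["unix_time"].to_numpy(float)
    if len(t) < 2:
        raise PreprocessError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise PreprocessError(f"{path}: timestamps not strictly increasing")
    bad = np.flatnonzero(np.abs(dt - med) > dt_tol * med)
    if bad.size:
        i = int(bad[0])
        raise PreprocessError(
            f"{path}: non-uniform sampling at row {i + 1} "
            f"(dt={dt[i]:.6f}s vs median {med:.6f}s)"
        )
    if subject is None:
        subject = path.stem.replace("_eeg", "")
    # span-based rate estimate: robust to per-timestamp rounding jitter
    fs = (len(t) - 1) / (t[-1] - t[0])
    return EEGRecording(
        subject=subject,
        channel_labels=tuple(expected_labels),
        fs=fs,
        samples=df[list(expected_labels)].to_numpy(float),
        t0_unix=float(t[0]),
        reference=reference,
    )


# ---------------------------------------------------------------------------
# Filtering and rereferencing
# ---------------------------------------------------------------------------

def bandpass(
    rec: EEGRecording,
    lo: float = FILTER_LO,
    hi: float = FILTER_HI,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (default 1-40 Hz, order 4).

    Applied forward-backward (``sosfiltfilt``) so cross-spectral phase is
    preserved, which matters for coherence estimation downstream.
    """
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise PreprocessError(f"invalid band edges ({lo}, {hi})")
    if hi >= nyq:
        raise PreprocessError(
            f"upper edge {hi} Hz at or above Nyquist frequency of {nyq} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=0)
    return replace(rec, samples=filtered)


def nyquist(fs: float = DEFAULT_FS) -> float:
    """Highest analyzable frequency for a sampling rate (fs/2; 62.5 Hz at 125)."""
    return fs / 2.0


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Rereference to the instantaneous mean across channels.

    After this the per-sample mean over channels is zero. Applying it to an
    already average-referenced recording is a no-op (with a warning).
    """
    if rec.n_channels < 2:
        raise PreprocessError("average reference needs at least 2 channels")
    if rec.reference == "average":
        warnings.warn("recording already average-referenced; no-op", stacklevel=2)
        return replace(rec, samples=rec.samples.copy())
    demeaned = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    return replace(rec, samples=demeaned, reference="average")


def region_signals(
    rec: EEGRecording, region_map: RegionMap | None = None
) -> dict[str, np.ndarray]:
    """Collapse each region to a single series: the mean of its channels."""
    region_map = region_map or RegionMap()
    out: dict[str, np.ndarray] = {}
    for name, chans in region_map.regions.items():
        missing = [ch for ch in chans if ch not in rec.channel_labels]
        if missing:
            raise PreprocessError(f"region {name!r}: channels {missing} absent")
        idx = [rec.channel_labels.index(ch) for ch in chans]
        out[name] = rec.samples[:, idx].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Golden SD and epoch screening
# ---------------------------------------------------------------------------

#: Consistency factor making the MAD unbiased for a Gaussian SD.
MAD_SCALE = 1.4826


def golden_sd(rec: EEGRecording, min_duration: float = 30.0) -> GoldenSD:
    """Per-channel robust SD: ``1.4826 x median(|x - median(x)|)``.

    The median absolute deviation is insensitive to the sparse large-amplitude
    artifacts the 6x rule is meant to catch, so the threshold itself is not
    inflated by the artifacts it screens.
    """
    if rec.duration < min_duration:
        raise PreprocessError(
            f"need >= {min_duration} s of signal to estimate golden SDs "
            f"(got {rec.duration:.1f} s)"
        )
    med = np.median(rec.samples, axis=0)
    mad = np.median(np.abs(rec.samples - med), axis=0)
    values = MAD_SCALE * mad
    flat = [ch for ch, v in zip(rec.channel_labels, values) if v <= 0]
    if flat:
        raise PreprocessError(f"flat channel(s) {flat}: golden SD undefined")
    return GoldenSD(values=dict(zip(rec.channel_labels, values)))


def epoch_and_flag(
    rec: EEGRecording,
    gsd: GoldenSD,
    mult: float = DEFAULT_GOLDEN_MULT,
) -> EpochSet:
    """Cut into 1-s epochs; flag an epoch unclean when any sample on any
    channel exceeds ``mult`` times that channel's golden SD in magnitude.

    A trailing partial epoch is dropped.
    """
    n = int(round(rec.fs * EPOCH_SECONDS))
    n_epochs = rec.n_times // n
    thresh = mult * gsd.as_array(rec.channel_labels)  # (n_channels,)
    x = rec.samples[: n_epochs * n].reshape(n_epochs, n, rec.n_channels)
    exceed = np.abs(x) > thresh[None, None, :]
    clean = ~exceed.any(axis=(1, 2))
    return EpochSet(fs=rec.fs, n_epochs=int(n_epochs), clean=clean)


def common_clean(epochs_a: EpochSet, epochs_b: EpochSet) -> np.ndarray:
    """Indices of epochs clean for both subjects (the only epochs analyzed)."""
    if epochs_a.n_epochs != epochs_b.n_epochs or epochs_a.fs != epochs_b.fs:
        raise PreprocessError("epoch grids do not match")
    return np.flatnonzero(epochs_a.clean & epochs_b.clean)
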