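"""Synthetic hyperscanning sessions with known ground truth.

The original study's raw recordings are not deposited, so every downstream
stage is exercised on simulated sessions that emulate the study design: six
subjects (one per simulated profession), 15 channels on the 10-20 montage,
125 Hz sampling, a communication-event schedule, per-subject audio envelopes
with known inter-recording lags, planted large-amplitude artifacts, and
two-rater TeamSTEPPS scores drawn from a two-way random-effects model with a
controllable monotone link between a session's injected inter-brain
coherence and its latent group score.

Coherence injection
-------------------
Within a target band, the subjects' spectral coefficients are drawn through
a Cholesky factor of the target *coherency* matrix G (G_ij = sqrt of the
target magnitude-squared coherence), on a pink (1/f power) amplitude
profile, so the generated pairwise magnitude-squared coherence equals the
requested target. For a single pair this is exactly the two-signal mixing
rule ``channel = w * shared + (1 - w) * independent`` with the weight knob

    coherency(w) = w^2 / (w^2 + (1 - w)^2),

exposed as :func:`coherence_for_weight` / :func:`weight_for_coherence`.
Each channel additionally carries a small independent pink component
(channel-noise fraction ``eps``); the injected coherency is pre-compensated
for the attenuation this causes at the region-mean level.

Artifacts are 1-5-sample spikes plus occasional 0.5-s square drifts at a
fixed multiple of the channel's robust SD, placed wholly inside single
1-second epochs (with a small guard margin so zero-phase filter ringing
cannot leak past the epoch boundary), and their epoch indices are recorded
as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    DEFAULT_FS,
    DEFAULT_REGIONS,
    MONTAGE_15,
    EEGRecording,
    write_eeg_csv,
)
from .scores import DEFAULT_RANGES, OVERALL, PROFESSIONS, TOPICS

__all__ = [
    "SessionSpec",
    "ScoreModel",
    "StudySpec",
    "GroundTruth",
    "SessionData",
    "StudyData",
    "coherence_for_weight",
    "weight_for_coherence",
    "generate_eeg_session",
    "generate_audio_envelopes",
    "generate_rater_scores",
    "generate_session",
    "generate_study",
    "write_study",
    "subject_ids",
    "default_roster",
]


class SyntheticError(ValueError):
    """Raised on invalid generator specifications."""


#: Injection frequency ranges by band name, Hz (inclusive analysis bins).
BAND_FREQS: dict[str, tuple[float, float]] = {"all": (1.0, 20.0), "alpha": (8.0, 12.0)}
#: Widen the injected band by the Hann main-lobe half-width (1 bin at 1-s
#: epochs) so the analysis bins at the band edges see fully coherent content.
BAND_GUARD_HZ = 1.0
#: Fraction of channel variance that is channel-specific pink noise.
CHANNEL_NOISE_FRACTION = 0.3
#: Baseline channel amplitude, microvolts (SD).
CHANNEL_SD_UV = 10.0


def subject_ids(n: int = 6) -> tuple[str, ...]:
    return tuple(f"sub-{k}" for k in range(1, n + 1))


def default_roster(n: int = 6) -> dict[str, str]:
    """Map subject ids to the simulated professions, in fixed order."""
    return dict(zip(subject_ids(n), PROFESSIONS[:n]))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SessionSpec:
    """Parameters of one simulated session.

    ``band_coherence`` maps band name -> region -> target magnitude-squared
    coherence, either one value for every subject pair or a mapping from
    pair tuples (0-based subject indices) to values.
    """

    n_subjects: int = 6
    channel_labels: tuple[str, ...] = MONTAGE_15
    fs: float = DEFAULT_FS
    duration: float = 120.0
    band_coherence: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    artifact_rate: float = 0.2  # expected artifacts / minute / channel
    artifact_amplitude: float = 12.0  # multiple of baseline (robust) SD, > 6
    comm_schedule: Sequence[tuple[int, int, float, float]] | None = None
    audio_lags_ms: Mapping[str, float] | None = None  # subject id -> ms
    t0_unix: float = 1.7e9
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise SyntheticError("fs must be positive")
        if self.duration < 1.0:
            raise SyntheticError("duration shorter than one epoch")
        if self.n_subjects < 2:
            raise SyntheticError("need at least 2 subjects")
        if self.artifact_rate < 0:
            raise SyntheticError("artifact_rate must be nonnegative")
        if self.artifact_amplitude <= 6:
            raise SyntheticError("artifact_amplitude must exceed the 6x rule")
        for band, regions in self.band_coherence.items():
            if band not in BAND_FREQS:
                raise SyntheticError(f"unknown band {band!r}")
            for region, target in regions.items():
                if region not in DEFAULT_REGIONS:
                    raise SyntheticError(f"unknown region {region!r}")
                vals = (
                    target.values() if isinstance(target, Mapping) else [target]
                )
                for v in vals:
                    if not 0 <= v < 1:
                        raise SyntheticError(
                            f"coherence target {v} outside [0, 1) for "
                            f"{band}/{region}"
                        )
        for sender, receiver, start, end in self.comm_schedule or ():
            if sender == receiver:
                raise SyntheticError("communication sender equals receiver")
            if not (0 <= sender < self.n_subjects and 0 <= receiver < self.n_subjects):
                raise SyntheticError("communication subject index out of range")
            if not (0 <= start < end <= self.duration):
                raise SyntheticError(
                    f"communication window [{start}, {end}] outside "
                    f"[0, {self.duration}]"
                )


@dataclass
class ScoreModel:
    """Variance components of the two-way random-effects score generator.

    The defaults imply a single-rater absolute-agreement ICC of about 0.74,
    the "good" interrater agreement regime reported for trained raters.
    """

    var_subject: float = 0.7
    var_rater: float = 0.05
    var_error: float = 0.2

    def validate(self) -> None:
        if min(self.var_subject, self.var_rater, self.var_error) < 0:
            raise SyntheticError("variance components must be nonnegative")

    def implied_icc(self) -> float:
        """Single-rater absolute-agreement ICC implied by the components."""
        tot = self.var_subject + self.var_rater + self.var_error
        return self.var_subject / tot if tot > 0 else 0.0


@dataclass
class StudySpec:
    """A multi-session study with a planted score-synchrony link.

    Each session's coherence target for (``link_band``, ``link_region``) is
    drawn uniformly from ``coherence_range``; the session's latent group
    score is ``link_slope`` times the target's position within the range
    (plus noise), so ``sign(link_slope)`` is the planted sign of the
    score-synchrony correlation across sessions and its magnitude is in
    latent score units per full coherence span.

    The default coherence range is deliberately weak (magnitude-squared
    coherence up to 0.08): it keeps the resulting normalized TI on the order
    observed in real inter-brain data (|z| of a few at most) rather than the
    tens that strong coherence would produce.
    """

    n_sessions: int = 20
    session: SessionSpec = field(default_factory=SessionSpec)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    link_slope: float = 0.0
    link_noise_sd: float = 0.1
    link_band: str = "alpha"
    link_region: str = "anterior"
    coherence_range: tuple[float, float] = (0.0, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sessions < 2:
            raise SyntheticError("need at least 2 sessions")
        self.score_model.validate()
        lo, hi = self.coherence_range
        if not (0 <= lo <= hi < 1):
            raise SyntheticError("coherence_range must lie within [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for oracle-style checks downstream."""

    coherence_targets: dict = field(default_factory=dict)
    artifact_epochs: dict[str, list[int]] = field(default_factory=dict)
    audio_lags_ms: dict[str, float] = field(default_factory=dict)
    audio_lag_samples: dict[str, int] = field(default_factory=dict)
    latent_group_scores: dict[str, float] = field(default_factory=dict)
    session_coherence: dict[str, float] = field(default_factory=dict)
    link_sign: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=str)


@dataclass
class SessionData:
    """One in-memory session: recordings, events, envelopes, scores, truth."""

    session_id: str
    recordings: dict[str, EEGRecording]
    events: list  # of alignment.CommunicationEvent
    envelopes: dict[str, np.ndarray]
    fs_audio: float
    scores: pd.DataFrame
    truth: GroundTruth


@dataclass
class StudyData:
    sessions: list[SessionData]
    scores: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Coherence weight knob
# ---------------------------------------------------------------------------

def coherence_for_weight(w: float) -> float:
    """|Coherency| produced by mixing ``w*shared + (1-w)*independent`` of
    equal per-bin power: ``w^2 / (w^2 + (1-w)^2)``. Monotone in w on [0, 1]."""
    if not 0 <= w <= 1:
        raise SyntheticError("mixing weight must lie in [0, 1]")
    return w**2 / (w**2 + (1 - w) ** 2)


def weight_for_coherence(msc: float) -> float:
    """Mixing weight whose generated magnitude-squared coherence is ``msc``.

    MSC is the squared coherency, so the weight solves
    ``coherence_for_weight(w) = sqrt(msc)``.
    """
    if not 0 <= msc < 1:
        raise SyntheticError("coherence target must lie in [0, 1)")
    r = np.sqrt(msc)
    if r == 0:
        return 0.0
    u = np.sqrt(r / (1 - r))
    return float(u / (1 + u))


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _pink_amplitude(freqs: np.ndarray) -> np.ndarray:
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    amp[freqs == 0] = 0.0
    return amp


def _complex_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)


def _coherency_matrix(
    n_subjects: int, target: Any, attenuation: float
) -> np.ndarray:
    """Target coherency matrix, pre-compensated for channel-noise attenuation."""
    g = np.eye(n_subjects)
    if isinstance(target, Mapping):
        items = [(tuple(sorted(p)), v) for p, v in target.items()]
    else:
        items = [
            ((i, j), target)
            for i in range(n_subjects)
            for j in range(i + 1, n_subjects)
        ]
    for (i, j), msc in items:
        if i == j:
            raise SyntheticError("coherence target for a subject with itself")
        coherency = min(np.sqrt(msc) / attenuation, 0.999)
        g[i, j] = g[j, i] = coherency
    return g


def _coherency_factor(g: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = G (eigen-based, robust to semidefiniteness)."""
    vals, vecs = np.linalg.eigh(g)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)[None, :]


def _region_attenuation(n_channels: int, eps: float = CHANNEL_NOISE_FRACTION) -> float:
    """Coherency shrinkage of the region mean caused by per-channel noise."""
    return (1 - eps**2) / ((1 - eps**2) + eps**2 / n_channels)


def generate_eeg_session(
    spec: SessionSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, EEGRecording], GroundTruth]:
    """Simulate the six subjects' raw (unfiltered, CPz-referenced) recordings.

    Returns the recordings keyed by subject id plus the planted ground truth
    (coherence targets, artifact epoch indices, audio lags). Recording
    content is delayed per subject by its audio lag, so that timestamps must
    be lag-compensated before cross-subject windows align -- as with real
    independently started mobile recorders.
    """
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sids = subject_ids(spec.n_subjects)

    lags_ms = dict(spec.audio_lags_ms or {s: 0.0 for s in sids})
    for s in sids:
        lags_ms.setdefault(s, 0.0)
    shifts = {s: int(round(lags_ms[s] / 1000.0 * spec.fs)) for s in sids}
    pad = max((abs(v) for v in shifts.values()), default=0)

    n = int(round(spec.duration * spec.fs))
    n_full = n + 2 * pad
    freqs = np.fft.rfftfreq(n_full, d=1.0 / spec.fs)
    pink = _pink_amplitude(freqs)

    # per-bin band assignment: narrower bands override wider ones
    bands = sorted(
        spec.band_coherence.items(),
        key=lambda kv: BAND_FREQS[kv[0]][1] - BAND_FREQS[kv[0]][0],
        reverse=True,
    )

    region_base: dict[str, np.ndarray] = {}
    for region, chans in DEFAULT_REGIONS.items():
        coeff = _complex_normal(rng, (spec.n_subjects, len(freqs)))
        atten = _region_attenuation(len(chans))
        for band, regions in bands:
            if region not in regions:
                continue
            lo, hi = BAND_FREQS[band]
            mask = (freqs >= lo - BAND_GUARD_HZ) & (freqs <= hi + BAND_GUARD_HZ)
            g = _coherency_matrix(spec.n_subjects, regions[region], atten)
            coeff[:, mask] = _coherency_factor(g) @ coeff[:, mask]
        coeff *= pink[None, :]
        base = np.fft.irfft(coeff, n_full, axis=1)
        base /= base.std(axis=1, keepdims=True)
        region_base[region] = base

    eps = CHANNEL_NOISE_FRACTION
    recordings: dict[str, EEGRecording] = {}
    artifact_epochs: dict[str, list[int]] = {s: [] for s in sids}
    epoch_len = int(round(spec.fs))
    n_epochs = n // epoch_len
    margin = 5  # samples; keeps filter ringing inside the artifact's epoch

    for si, sid in enumerate(sids):
        chans = np.empty((n_full, len(spec.channel_labels)))
        for ci, ch in enumerate(spec.channel_labels):
            region = next(r for r, cs in DEFAULT_REGIONS.items() if ch in cs)
            noise_coeff = _complex_normal(rng, (len(freqs),)) * pink
            noise = np.fft.irfft(noise_coeff, n_full)
            noise /= noise.std()
            chans[:, ci] = np.sqrt(1 - eps**2) * region_base[region][si] + eps * noise
        chans *= CHANNEL_SD_UV

        # content delayed by the subject's lag: sample j holds the signal of
        # true time j/fs - lag, i.e. master index j - shift
        shift = shifts[sid]
        samples = chans[pad - shift : pad - shift + n, :]
        samples = np.array(samples)

        # planted artifacts: spikes and square drifts confined to one epoch
        if spec.artifact_rate > 0 and n_epochs > 0:
            expected = spec.artifact_rate * spec.duration / 60.0
            hit_epochs: set[int] = set()
            for ci in range(samples.shape[1]):
                n_art = rng.poisson(expected)
                if n_art == 0:
                    continue
                sd = 1.4826 * np.median(
                    np.abs(samples[:, ci] - np.median(samples[:, ci]))
                )
                for _ in range(n_art):
                    epoch = int(rng.integers(n_epochs))
                    if rng.random() < 0.8:
                        # >= 2 samples so the 1-40 Hz band-pass keeps the
                        # peak well above the 6x rule it must trip
                        width = int(rng.integers(2, 6))
                        guard = margin
                    else:
                        # 0.5-s square drift: the 1-Hz high-pass settles
                        # slowly around its edges, so keep it mid-epoch
                        width = int(round(0.5 * spec.fs))
                        guard = max((epoch_len - width) // 2 - 3, margin)
                    offset = int(
                        rng.integers(guard, epoch_len - width - guard + 1)
                    )
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    start = epoch * epoch_len + offset
                    samples[start : start + width, ci] += (
                        sign * spec.artifact_amplitude * sd
                    )
                    hit_epochs.add(epoch)
            artifact_epochs[sid] = sorted(hit_epochs)

        recordings[sid] = EEGRecording(
            subject=sid,
            channel_labels=spec.channel_labels,
            fs=spec.fs,
            samples=samples,
            t0_unix=spec.t0_unix,
            reference="CPz",
        )

    truth = GroundTruth(
        coherence_targets={
            band: {region: _jsonable(v) for region, v in regions.items()}
            for band, regions in spec.band_coherence.items()
        },
        artifact_epochs=artifact_epochs,
        audio_lags_ms=lags_ms,
        audio_lag_samples=shifts,
        seed=spec.seed,
    )
    return recordings, truth


def _jsonable(v: Any) -> Any:
    if isinstance(v, Mapping):
        return {f"{i}-{j}": float(x) for (i, j), x in v.items()}
    return float(v)


def generate_audio_envelopes(
    spec: SessionSpec,
    rng: np.random.Generator | None = None,
    fs_audio: float | None = None,
    noise_sd: float = 0.05,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Per-subject audio envelopes: one shared broadband envelope delayed by
    each subject's true lag, plus small independent noise.

    Returns the envelopes and the planted integer-sample shifts on the audio
    grid (positive shift = that subject's content starts later).
    """
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    fs_audio = fs_audio or spec.fs
    sids = subject_ids(spec.n_subjects)
    lags_ms = dict(spec.audio_lags_ms or {s: 0.0 for s in sids})
    for s in sids:
        lags_ms.setdefault(s, 0.0)
    shifts = {s: int(round(lags_ms[s] / 1000.0 * fs_audio)) for s in sids}
    pad = max(abs(v) for v in shifts.values()) if shifts else 0

    n = int(round(spec.duration * fs_audio))
    from scipy import signal as sp_signal

    master = np.abs(rng.standard_normal(n + 2 * pad))
    sos = sp_signal.butter(2, 8.0, btype="lowpass", fs=fs_audio, output="sos")
    master = sp_signal.sosfiltfilt(sos, master)
    master = (master - master.mean()) / master.std()

    envelopes = {}
    for sid in sids:
        shift = shifts[sid]
        env = master[pad - shift : pad - shift + n].copy()
        env += noise_sd * rng.standard_normal(n)
        envelopes[sid] = env
    return envelopes, shifts


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def generate_rater_scores(
    study: StudySpec,
    rng: np.random.Generator | None = None,
    latent_shifts: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-rater TeamSTEPPS topic scores for every session and profession.

    Scores follow the two-way random-effects model the ICC assumes:
    ``score = mid + scale * (u_subject + v_rater + e)`` with independent
    normal components of the spec's variances, clipped to the topic's
    declared range (``scale`` maps +-4 latent units onto the range, so
    clipping is rare). ``latent_shifts`` adds a per-session offset to every
    subject latent -- the hook through which the planted coherence-score
    link enters.
    """
    study.validate()
    rng = rng if rng is not None else np.random.default_rng(study.seed + 2)
    model = study.score_model
    sd_s, sd_r, sd_e = (
        np.sqrt(model.var_subject),
        np.sqrt(model.var_rater),
        np.sqrt(model.var_error),
    )
    sessions = [f"ses-{i + 1}" for i in range(study.n_sessions)]
    latent_shifts = latent_shifts or {s: 0.0 for s in sessions}

    rows = []
    latents: dict[str, float] = {}
    for session in sessions:
        shift = latent_shifts.get(session, 0.0)
        latents[session] = shift
        for profession in PROFESSIONS:
            # per-(topic, rater) rater effects: raters are profession-specific
            rater_eff = {r: sd_r * rng.standard_normal() for r in (1, 2)}
            for topic in TOPICS:
                u = shift + sd_s * rng.standard_normal()
                lo, hi = DEFAULT_RANGES[profession][topic]
                mid, scale = (lo + hi) / 2.0, (hi - lo) / 8.0
                for rater in (1, 2):
                    e = sd_e * rng.standard_normal()
                    raw = mid + scale * (u + rater_eff[rater] + e)
                    rows.append(
                        {
                            "session": session,
                            "profession": profession,
                            "rater": rater,
                            "topic": topic,
                            "score": float(np.clip(raw, lo, hi)),
                        }
                    )
    table = pd.DataFrame(rows)
    truth = GroundTruth(latent_group_scores=latents, seed=study.seed)
    return table, truth


# ---------------------------------------------------------------------------
# Sessions and studies
# ---------------------------------------------------------------------------

def _auto_schedule(
    spec: SessionSpec, rng: np.random.Generator, comm_seconds: float = 32.0
) -> list[tuple[int, int, float, float]]:
    """Default communication schedule: back-to-back windows covering most of
    the session, each attributed to a random sender/receiver pair."""
    start = 2.0
    schedule = []
    while start + comm_seconds <= spec.duration - 2.0:
        i, j = rng.choice(spec.n_subjects, size=2, replace=False)
        schedule.append((int(i), int(j), start, start + comm_seconds))
        start += comm_seconds + 2.0
    if not schedule:
        raise SyntheticError("duration too short for one communication window")
    return schedule


def generate_session(
    spec: SessionSpec,
    session_id: str = "ses-1",
    rng: np.random.Generator | None = None,
    scores: pd.DataFrame | None = None,
) -> SessionData:
    """One full in-memory session: EEG, events, envelopes and (optionally)
    externally generated scores."""
    from .alignment import CommunicationEvent

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.audio_lags_ms is None:
        sids = subject_ids(spec.n_subjects)
        lags = {sids[0]: 0.0}
        for s in sids[1:]:
            lags[s] = float(rng.uniform(-500.0, 500.0))
        spec = _with_lags(spec, lags)
    recordings, truth = generate_eeg_session(spec, rng)
    envelopes, audio_shifts = generate_audio_envelopes(spec, rng)
    truth.audio_lag_samples = audio_shifts

    schedule = list(spec.comm_schedule) if spec.comm_schedule else _auto_schedule(
        spec, rng
    )
    sids = subject_ids(spec.n_subjects)
    events = [
        CommunicationEvent(
            id=f"{session_id}-comm-{k + 1}",
            sender=sids[i],
            receiver=sids[j],
            start_unix=spec.t0_unix + start,
            end_unix=spec.t0_unix + end,
        )
        for k, (i, j, start, end) in enumerate(schedule)
    ]
    if scores is None:
        scores = pd.DataFrame(
            columns=["session", "profession", "rater", "topic", "score"]
        )
    return SessionData(
        session_id=session_id,
        recordings=recordings,
        events=events,
        envelopes=envelopes,
        fs_audio=spec.fs,
        scores=scores,
        truth=truth,
    )


def _with_lags(spec: SessionSpec, lags: Mapping[str, float]) -> SessionSpec:
    from dataclasses import replace

    return replace(spec, audio_lags_ms=dict(lags))


def generate_study(
    study: StudySpec, out_dir: str | Path | None = None
) -> StudyData:
    """Generate ``n_sessions`` sessions with a planted score-synchrony link.

    Per session s: a coherence target c_s ~ U(coherence_range) is injected
    for (link_band, link_region) in all subject pairs, and the session's
    latent group score is ``link_slope * c_s + N(0, link_noise_sd^2)``,
    entering every subject's score latent. With ``link_slope`` strongly
    negative and low noise the realized score-synchrony correlation across
    sessions is strongly negative; with ``link_slope = 0`` there is none.

    If ``out_dir`` is given, the study is also written to disk in the
    standard session-folder layout (see :func:`write_study`).
    """
    study.validate()
    master = np.random.default_rng(study.seed)
    session_ids = [f"ses-{i + 1}" for i in range(study.n_sessions)]

    lo, hi = study.coherence_range
    span = max(hi - lo, 1e-12)
    session_coh = {
        s: float(master.uniform(lo, hi)) for s in session_ids
    }
    latent_shifts = {
        s: study.link_slope * (session_coh[s] - lo) / span
        + study.link_noise_sd * master.standard_normal()
        for s in session_ids
    }
    score_table, score_truth = generate_rater_scores(
        study, np.random.default_rng([study.seed, 10_007]), latent_shifts
    )

    sessions = []
    for i, sid in enumerate(session_ids):
        from dataclasses import replace

        bc = {b: dict(r) for b, r in study.session.band_coherence.items()}
        bc.setdefault(study.link_band, {})[study.link_region] = session_coh[sid]
        spec = replace(study.session, band_coherence=bc, seed=study.seed + i)
        rng = np.random.default_rng([study.seed, 1_000 + i])
        data = generate_session(
            spec, sid, rng, scores=score_table[score_table["session"] == sid]
        )
        data.truth.session_coherence = {sid: session_coh[sid]}
        data.truth.latent_group_scores = {sid: latent_shifts[sid]}
        sessions.append(data)

    truth = GroundTruth(
        session_coherence=session_coh,
        latent_group_scores=latent_shifts,
        link_sign=int(np.sign(study.link_slope)),
        seed=study.seed,
    )
    data = StudyData(sessions=sessions, scores=score_table, truth=truth)
    if out_dir is not None:
        write_study(data, out_dir)
    return data


def write_study(data: StudyData, out_dir: str | Path) -> None:
    """Write a study in the on-disk layout:

    ``<out>/<session>/sub-<k>_eeg.csv`` (``unix_time,<channels>``, microvolts),
    ``events.json``, ``audio_sub-<k>.csv``, ``scores.csv`` and a per-session
    ``ground_truth.json``; the master ground truth goes to
    ``<out>/ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ses in data.sessions:
        d = out / ses.session_id
        d.mkdir(exist_ok=True)
        for sid, rec in ses.recordings.items():
            write_eeg_csv(rec, d / f"{sid}_eeg.csv")
        for sid, env in ses.envelopes.items():
            pd.DataFrame({"envelope": env}).to_csv(
                d / f"audio_{sid}.csv", index=False, float_format="%.6f"
            )
        events = [
            {
                "id": ev.id,
                "sender": ev.sender,
                "receiver": ev.receiver,
                "start_unix": ev.start_unix,
                "end_unix": ev.end_unix,
            }
            for ev in ses.events
        ]
        (d / "events.json").write_text(json.dumps(events, indent=1))
        ses.scores.to_csv(d / "scores.csv", index=False)
        (d / "ground_truth.json").write_text(ses.truth.to_json())
    (out / "ground_truth.json").write_text(data.truth.to_json())
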