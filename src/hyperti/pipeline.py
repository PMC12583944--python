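"""End-to-end orchestration: simulate -> preprocess -> align -> TI ->
aggregate -> scores -> inference, with deterministic seeding and a manifest.

The stages are pure functions of their inputs plus the configuration;
rerunning with the same inputs and master seed reproduces every numeric
output bit-for-bit. Per-communication permutation seeds are derived
deterministically from (master seed, session index, communication index,
pair), so results do not depend on execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import alignment, preprocess, scores as scores_mod, stats, synthetic, ti

__all__ = ["PipelineConfig", "StudyResults", "analyze_study", "read_study",
           "run_all", "validate_inputs", "planted_replicate"]

log = logging.getLogger("hyperti")


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with the study's defaults."""

    bands: tuple[str, ...] = ("all", "alpha")
    golden_mult: float = 6.0
    k_min: int = 10
    n_perm: int = 1000
    mcd_support: float = 0.75
    mcd_alpha: float = 0.001
    bh_alpha: float = 0.05
    max_lag: float = 5.0
    filter_lo: float = 1.0
    filter_hi: float = 40.0
    seed: int = 0

    def band_specs(self) -> tuple[ti.BandSpec, ...]:
        known = {b.name: b for b in ti.DEFAULT_BANDS}
        return tuple(known[name] for name in self.bands)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.bands, list):
            cfg.bands = tuple(cfg.bands)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResults:
    """All tables the pipeline produces for one study."""

    pair_table: pd.DataFrame
    student_table: pd.DataFrame
    group_table: pd.DataFrame
    scaled_scores: pd.DataFrame
    group_scores: pd.DataFrame
    icc_report: pd.DataFrame
    grids: dict[str, pd.DataFrame] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    lag_table: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Per-session TI
# ---------------------------------------------------------------------------

def _session_pair_table(
    data: synthetic.SessionData,
    session_index: int,
    config: PipelineConfig,
    region_map: preprocess.RegionMap,
) -> pd.DataFrame:
    subjects = sorted(data.recordings)
    bands = config.band_specs()

    # preprocess every subject: band-pass, average reference, golden SDs
    filtered: dict[str, preprocess.EEGRecording] = {}
    gsds: dict[str, preprocess.GoldenSD] = {}
    for sid, rec in data.recordings.items():
        f = preprocess.bandpass(rec, config.filter_lo, config.filter_hi)
        f = preprocess.rereference_average(f)
        filtered[sid] = f
        gsds[sid] = preprocess.golden_sd(f)

    # lag estimation and event compensation
    lags = alignment.lag_table(
        data.envelopes, data.fs_audio, reference=subjects[0], max_lag=config.max_lag
    )
    lags_ms = {s: est.lag_ms for s, est in lags.items()}
    lag_rows = [
        {"session": data.session_id, "subject": s, "lag_ms": est.lag_ms,
         "peak_corr": est.peak_corr, "reliable": est.reliable}
        for s, est in lags.items()
    ]
    shifted = alignment.apply_lags(data.events, lags_ms, subjects)

    rows = []
    n_invalid = 0
    for ci, event in enumerate(data.events):
        # per-subject epoch spectra and clean flags for this communication
        spectra: dict[str, dict[str, np.ndarray]] = {}
        clean: dict[str, np.ndarray] = {}
        n_ep_per_subject = []
        windows = {}
        for sid in subjects:
            rec = filtered[sid]
            win = alignment.segment_eeg(rec, shifted[sid][ci])
            windows[sid] = win
            if not win.valid:
                continue
            n_ep_per_subject.append(win.n_samples // int(round(rec.fs)))
        if len(n_ep_per_subject) < len(subjects) or not n_ep_per_subject:
            n_invalid += 1
            continue
        n_ep = min(n_ep_per_subject)
        if n_ep < 2:
            n_invalid += 1
            continue

        freqs = None
        for sid in subjects:
            rec = filtered[sid]
            win = windows[sid]
            epoch_len = int(round(rec.fs))
            seg = rec.samples[win.start : win.start + n_ep * epoch_len]
            seg_rec = preprocess.EEGRecording(
                subject=sid,
                channel_labels=rec.channel_labels,
                fs=rec.fs,
                samples=seg,
                t0_unix=rec.t0_unix + win.start / rec.fs,
                reference=rec.reference,
            )
            flags = preprocess.epoch_and_flag(seg_rec, gsds[sid], config.golden_mult)
            clean[sid] = flags.clean
            regions = preprocess.region_signals(seg_rec, region_map)
            spectra[sid] = {}
            for rname, series in regions.items():
                epochs = series[: n_ep * epoch_len].reshape(n_ep, epoch_len)
                spectra[sid][rname] = ti.epoch_spectra(epochs, rec.fs)
            if freqs is None:
                freqs = np.fft.rfftfreq(epoch_len, d=1.0 / rec.fs)

        for ai in range(len(subjects)):
            for bi in range(ai + 1, len(subjects)):
                a, b = subjects[ai], subjects[bi]
                common = np.flatnonzero(clean[a] & clean[b])
                K = len(common)
                for rname in region_map.names():
                    base_row = {
                        "session": data.session_id,
                        "comm_id": event.id,
                        "subject_a": a,
                        "subject_b": b,
                        "region": rname,
                        "K": K,
                        "n_perm": config.n_perm,
                    }
                    if K < max(config.k_min, 2):
                        for band in bands:
                            rows.append(
                                {**base_row, "band": band.name, "raw_ti": np.nan,
                                 "z": np.nan, "ks_flag": False}
                            )
                        continue
                    rng = np.random.default_rng(
                        [config.seed, session_index, ci, ai, bi]
                    )
                    results = ti.normalized_ti_from_spectra(
                        spectra[a][rname][common],
                        spectra[b][rname][common],
                        freqs,
                        bands,
                        config.n_perm,
                        rng,
                    )
                    for band in bands:
                        res = results[band.name]
                        rows.append(
                            {**base_row, "band": band.name, "raw_ti": res.raw_ti,
                             "z": res.z, "ks_flag": res.ks_flag}
                        )
    if n_invalid:
        log.info("%s: %d communication(s) invalid", data.session_id, n_invalid)
    cols = ["session", "comm_id", "subject_a", "subject_b", "region", "band",
            "K", "raw_ti", "z", "ks_flag", "n_perm"]
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(lag_rows)


# ---------------------------------------------------------------------------
# Study-level analysis
# ---------------------------------------------------------------------------

def _group_topic_scores(scaled: pd.DataFrame, roster_size: int = 6) -> pd.DataFrame:
    """Session-level scores: per-topic means over the professions plus the
    group (scaled-overall mean) score; defined only for complete sessions."""
    rows = []
    score_cols = [c for c in scaled.columns if c.startswith("scaled_")]
    for session, sub in scaled.groupby("session"):
        rec: dict[str, object] = {"session": session}
        complete = len(sub) == roster_size and sub[score_cols].notna().all().all()
        for col in score_cols:
            rec[col] = float(sub[col].mean()) if complete else np.nan
        rec["complete"] = complete
        rows.append(rec)
    return pd.DataFrame(rows)


def analyze_study(
    study: synthetic.StudyData,
    config: PipelineConfig | None = None,
    region_map: preprocess.RegionMap | None = None,
    roster: Mapping[str, str] | None = None,
) -> StudyResults:
    """Run the full analysis on an in-memory study.

    ``roster`` maps subject ids to professions (the default six-profession
    assignment); TI aggregates are keyed by profession before being merged
    with the score tables.
    """
    config = config or PipelineConfig()
    region_map = region_map or preprocess.RegionMap()
    roster = dict(roster or synthetic.default_roster())

    pair_tables, lag_tables = [], []
    for i, ses in enumerate(study.sessions):
        log.info("session %s: TI analysis", ses.session_id)
        pairs, lags = _session_pair_table(ses, i, config, region_map)
        pair_tables.append(pairs)
        lag_tables.append(lags)
    pair_table = pd.concat(pair_tables, ignore_index=True) if pair_tables else (
        pd.DataFrame()
    )
    lag_table = pd.concat(lag_tables, ignore_index=True) if lag_tables else (
        pd.DataFrame()
    )

    subjects = sorted(roster)
    student = agg.student_table(pair_table, subjects, k_min=config.k_min)
    group = agg.group_table(student, subjects)
    student["profession"] = student["subject"].map(roster)

    scaled = scores_mod.scale_scores(study.scores)
    group_scores = scores_mod.group_score(scaled)
    group_topic = _group_topic_scores(scaled)
    icc = scores_mod.icc_report(study.scores)

    grids = {}
    grids["group"] = stats.correlation_grid(
        group.dropna(subset=["group_ti"]),
        group_topic[group_topic["complete"]],
        level="group",
        mcd_support=config.mcd_support,
        mcd_alpha=config.mcd_alpha,
        bh_alpha=config.bh_alpha,
        seed=config.seed,
    )
    grids["individual"] = stats.correlation_grid(
        student,
        scaled,
        level="individual",
        mcd_support=config.mcd_support,
        mcd_alpha=config.mcd_alpha,
        bh_alpha=config.bh_alpha,
        seed=config.seed,
    )

    counts = {
        "sessions": len(study.sessions),
        "pair_rows": int(len(pair_table)),
        "invalid_pair_rows": int(pair_table["z"].isna().sum()) if len(pair_table) else 0,
        "complete_group_sessions": int(group["complete"].sum()) if len(group) else 0,
    }
    return StudyResults(
        pair_table=pair_table,
        student_table=student,
        group_table=group,
        scaled_scores=scaled,
        group_scores=group_scores,
        icc_report=icc,
        grids=grids,
        counts=counts,
        lag_table=lag_table,
    )


def planted_replicate(
    seed: int,
    link_slope: float,
    n_sessions: int = 20,
    duration: float = 106.0,
    n_perm: int = 120,
    link_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """One end-to-end recovery/calibration replicate: simulate a study with a
    planted anterior-alpha score-synchrony link of the given slope (0 for a
    null study), run the full analysis, and return the group-level grid.

    Used for sign-recovery power checks and type-I calibration; ``duration``
    defaults to three 32-second communications per session and a reduced
    permutation count to keep many-replicate experiments tractable.
    """
    spec = synthetic.StudySpec(
        n_sessions=n_sessions,
        session=synthetic.SessionSpec(duration=duration, artifact_rate=0.2),
        link_slope=link_slope,
        link_noise_sd=link_noise_sd,
        seed=seed,
    )
    study = synthetic.generate_study(spec)
    config = PipelineConfig(n_perm=n_perm, seed=seed)
    return analyze_study(study, config).grids["group"]


# ---------------------------------------------------------------------------
# Disk front ends
# ---------------------------------------------------------------------------

def read_study(study_dir: str | Path) -> synthetic.StudyData:
    """Load a study from the on-disk session-folder layout."""
    study_dir = Path(study_dir)
    session_dirs = sorted(
        (d for d in study_dir.iterdir() if d.is_dir() and (d / "events.json").exists()),
        key=lambda d: (len(d.name), d.name),
    )
    if not session_dirs:
        raise FileNotFoundError(f"no session folders under {study_dir}")
    sessions = []
    score_frames = []
    for d in session_dirs:
        recordings = {}
        for f in sorted(d.glob("sub-*_eeg.csv")):
            rec = preprocess.read_eeg_csv(f)
            recordings[rec.subject] = rec
        envelopes = {}
        for f in sorted(d.glob("audio_sub-*.csv")):
            sid = f.stem.replace("audio_", "")
            envelopes[sid] = pd.read_csv(f)["envelope"].to_numpy(float)
        events = [
            alignment.CommunicationEvent(**ev)
            for ev in json.loads((d / "events.json").read_text())
        ]
        scores = pd.read_csv(d / "scores.csv") if (d / "scores.csv").exists() else (
            pd.DataFrame(columns=["session", "profession", "rater", "topic", "score"])
        )
        score_frames.append(scores)
        fs_audio = next(iter(recordings.values())).fs if recordings else 125.0
        sessions.append(
            synthetic.SessionData(
                session_id=d.name,
                recordings=recordings,
                events=events,
                envelopes=envelopes,
                fs_audio=fs_audio,
                scores=scores,
                truth=synthetic.GroundTruth(),
            )
        )
    all_scores = pd.concat(score_frames, ignore_index=True)
    return synthetic.StudyData(
        sessions=sessions, scores=all_scores, truth=synthetic.GroundTruth()
    )


def run_all(
    study_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> StudyResults:
    """Disk-to-disk pipeline: read a study, analyze it, write every table
    plus a run manifest (config, hash, seed, library versions)."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = read_study(study_dir)
    results = analyze_study(study, config)

    results.pair_table.to_csv(out / "ti_pairs.csv", index=False)
    results.student_table.to_csv(out / "ti_students.csv", index=False)
    results.group_table.to_csv(out / "ti_groups.csv", index=False)
    results.scaled_scores.to_csv(out / "scores_scaled.csv", index=False)
    results.group_scores.to_csv(out / "scores_group.csv", index=False)
    results.icc_report.to_csv(out / "icc_report.csv", index=False)
    results.lag_table.to_csv(out / "lags.csv", index=False)
    for level, grid in results.grids.items():
        grid.to_csv(out / f"correlations_{level}.csv", index=False)

    import scipy
    import sklearn
    import statsmodels

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": results.counts,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results


def validate_inputs(study_dir: str | Path) -> pd.DataFrame:
    """Sanity report over a study directory: per-file pass/fail with reasons
    (sampling uniformity, channel set, event-window sanity, rater
    completeness). Never raises; problems become report rows."""
    study_dir = Path(study_dir)
    rows = []

    def add(path, check, ok, reason=""):
        rows.append({"path": str(path), "check": check, "ok": ok, "reason": reason})

    for d in sorted(p for p in study_dir.iterdir() if p.is_dir()):
        for f in sorted(d.glob("sub-*_eeg.csv")):
            try:
                preprocess.read_eeg_csv(f)
                add(f, "eeg", True)
            except Exception as exc:  # noqa: BLE001 - report, don't raise
                add(f, "eeg", False, str(exc))
        ev_path = d / "events.json"
        if ev_path.exists():
            try:
                raw = json.loads(ev_path.read_text())
                for ev in raw:
                    alignment.CommunicationEvent(**ev)
                add(ev_path, "events", True)
            except Exception as exc:  # noqa: BLE001
                add(ev_path, "events", False, str(exc))
        else:
            add(ev_path, "events", False, "missing")
        sc_path = d / "scores.csv"
        if sc_path.exists():
            try:
                sc = pd.read_csv(sc_path)
                counts = sc.groupby(["profession", "topic"])["rater"].nunique()
                if (counts != 2).any():
                    bad = counts[counts != 2].index.tolist()
                    add(sc_path, "scores", False, f"missing rater for {bad}")
                else:
                    add(sc_path, "scores", True)
            except Exception as exc:  # noqa: BLE001
                add(sc_path, "scores", False, str(exc))
    return pd.DataFrame(rows, columns=["path", "check", "ok", "reason"])
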