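"""The synthetic-session generator: coherence control, artifacts, lags,
rater scores and study-level determinism."""

import json

import numpy as np
import pytest

from hyperti import preprocess as pp
from hyperti import synthetic, ti


def measured_band_coherence(recs, a, b, region, band, fs=125.0):
    """Reference measurement: band-mean epoch coherence of region means of
    the band-passed (not rereferenced) recordings."""
    fa = pp.bandpass(recs[a])
    fb = pp.bandpass(recs[b])
    xa = pp.region_signals(fa)[region]
    xb = pp.region_signals(fb)[region]
    n = int(fs)
    K = len(xa) // n
    c = ti.coherence_epochs(xa[: K * n].reshape(K, n), xb[: K * n].reshape(K, n), fs)
    return float(c.band_values(band).mean())


class TestCoherenceInjection:
    def test_zero_target_sits_at_bias_level(self, quiet_recordings):
        recs, _ = quiet_recordings  # 60 s -> K = 60 epochs
        c = measured_band_coherence(recs, "sub-1", "sub-2", "anterior", ti.ALPHA_BAND)
        assert c <= 0.15

    def test_pair_target_hit_within_tolerance(self):
        spec = synthetic.SessionSpec(
            duration=120.0,
            band_coherence={"alpha": {"anterior": {(0, 1): 0.8}}},
            artifact_rate=0.0,
            audio_lags_ms={s: 0.0 for s in synthetic.subject_ids()},
            seed=3,
        )
        recs, _ = synthetic.generate_eeg_session(spec)
        c = measured_band_coherence(recs, "sub-1", "sub-2", "anterior", ti.ALPHA_BAND)
        assert 0.7 <= c <= 0.9
        # untargeted pair stays at the bias level
        c_other = measured_band_coherence(
            recs, "sub-1", "sub-3", "anterior", ti.ALPHA_BAND
        )
        assert c_other <= 0.15

    def test_measured_coherence_monotone_in_weight(self):
        """Three mixing weights -> strictly increasing measured coherence."""
        targets = [synthetic.coherence_for_weight(w) ** 2 for w in (0.2, 0.45, 0.7)]
        measured = []
        for k, t in enumerate(targets):
            spec = synthetic.SessionSpec(
                duration=90.0,
                band_coherence={"alpha": {"anterior": t}},
                artifact_rate=0.0,
                audio_lags_ms={s: 0.0 for s in synthetic.subject_ids()},
                seed=17,
            )
            recs, _ = synthetic.generate_eeg_session(spec)
            measured.append(
                measured_band_coherence(recs, "sub-1", "sub-2", "anterior", ti.ALPHA_BAND)
            )
        assert measured[0] < measured[1] < measured[2]

    def test_weight_knob_round_trip(self):
        for msc in (0.0, 0.2, 0.5, 0.9):
            w = synthetic.weight_for_coherence(msc)
            assert synthetic.coherence_for_weight(w) ** 2 == pytest.approx(msc)

    def test_coherence_target_of_one_rejected(self):
        spec = synthetic.SessionSpec(
            band_coherence={"alpha": {"anterior": 1.0}}, seed=0
        )
        with pytest.raises(synthetic.SyntheticError):
            spec.validate()

    def test_subsecond_duration_rejected(self):
        with pytest.raises(synthetic.SyntheticError, match="epoch"):
            synthetic.SessionSpec(duration=0.5).validate()


class TestArtifacts:
    def test_zero_rate_gives_empty_ground_truth(self, quiet_recordings):
        _, truth = quiet_recordings
        assert all(len(v) == 0 for v in truth.artifact_epochs.values())

    def test_planted_epochs_trip_the_golden_sd_rule(self):
        """Sensitivity 1.0 on planted epochs; planted-free epochs stay clean."""
        spec = synthetic.SessionSpec(
            duration=60.0,
            artifact_rate=1.0,
            audio_lags_ms={s: 0.0 for s in synthetic.subject_ids()},
            seed=23,
        )
        recs, truth = synthetic.generate_eeg_session(spec)
        planted_total = sum(len(v) for v in truth.artifact_epochs.values())
        assert planted_total > 0
        n_false = n_clean = 0
        for sid, rec in recs.items():
            filt = pp.rereference_average(pp.bandpass(rec))
            flags = pp.epoch_and_flag(filt, pp.golden_sd(filt), mult=6.0)
            planted = set(truth.artifact_epochs[sid])
            flagged = set(np.flatnonzero(~flags.clean).tolist())
            assert planted <= flagged  # every planted epoch caught
            n_false += len(flagged - planted)
            n_clean += flags.n_epochs - len(planted)
        assert n_false <= 0.01 * n_clean  # false-flag rate on clean epochs


class TestAudioEnvelopes:
    def test_zero_lags_give_aligned_envelopes(self, zero_lag_spec):
        envs, shifts = synthetic.generate_audio_envelopes(zero_lag_spec)
        assert set(shifts.values()) == {0}
        a, b = envs["sub-1"], envs["sub-2"]
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.9

    def test_planted_shift_is_recorded_on_sample_grid(self):
        spec = synthetic.SessionSpec(
            duration=30.0,
            audio_lags_ms={"sub-1": 0.0, "sub-2": 250.0, "sub-3": -80.0},
            seed=5,
        )
        _, shifts = synthetic.generate_audio_envelopes(spec)
        assert shifts["sub-2"] == round(0.250 * 125)  # 31 samples
        assert shifts["sub-3"] == round(-0.080 * 125)
        assert shifts["sub-3"] < 0

    def test_planted_shift_matches_brute_force_argmax(self):
        spec = synthetic.SessionSpec(
            duration=30.0,
            audio_lags_ms={"sub-1": 0.0, "sub-2": 250.0},
            seed=5,
        )
        envs, shifts = synthetic.generate_audio_envelopes(spec)
        a = envs["sub-1"] - envs["sub-1"].mean()
        b = envs["sub-2"] - envs["sub-2"].mean()
        best, best_lag = -np.inf, None
        for lag in range(-60, 61):  # brute-force shift search
            if lag >= 0:
                v = np.dot(a[: len(a) - lag], b[lag:])
            else:
                v = np.dot(a[-lag:], b[: len(b) + lag])
            if v > best:
                best, best_lag = v, lag
        assert abs(best_lag - shifts["sub-2"]) <= 1


class TestRaterScores:
    def test_no_noise_components_give_identical_raters(self):
        study = synthetic.StudySpec(
            n_sessions=10,
            score_model=synthetic.ScoreModel(
                var_subject=1.0, var_rater=0.0, var_error=0.0
            ),
            seed=1,
        )
        table, _ = synthetic.generate_rater_scores(study)
        pivot = table.pivot_table(
            index=["session", "profession", "topic"], columns="rater", values="score"
        )
        assert np.allclose(pivot[1], pivot[2])

    def test_realized_icc_matches_variance_components(self):
        """sigma_s = sigma_e = 1, sigma_r = 0  =>  ICC(2,1) ~ 0.5."""
        from hyperti import scores as sc

        study = synthetic.StudySpec(
            n_sessions=500,
            score_model=synthetic.ScoreModel(
                var_subject=1.0, var_rater=0.0, var_error=1.0
            ),
            seed=7,
        )
        table, _ = synthetic.generate_rater_scores(study)
        sub = table[
            (table.profession == "medical doctor") & (table.topic == "leadership")
        ]
        m = sub.pivot_table(index="session", columns="rater", values="score")
        icc = sc.icc_2way_random_single_absolute(m.to_numpy())
        assert icc == pytest.approx(0.5, abs=0.05)

    def test_scores_respect_declared_ranges(self):
        study = synthetic.StudySpec(
            n_sessions=50,
            score_model=synthetic.ScoreModel(
                var_subject=2.0, var_rater=1.0, var_error=2.0
            ),
            seed=9,
        )
        table, _ = synthetic.generate_rater_scores(study)
        rt = table[
            (table.profession == "radiological technologist")
            & (table.topic == "team structure")
        ]["score"]
        assert rt.between(2, 10).all()  # declared range 2-10

    def test_negative_variance_rejected(self):
        with pytest.raises(synthetic.SyntheticError):
            synthetic.ScoreModel(var_subject=-1.0).validate()


class TestStudyGeneration:
    def test_null_link_gives_weak_correlation(self):
        study = synthetic.generate_study(
            synthetic.StudySpec(
                n_sessions=20,
                session=synthetic.SessionSpec(duration=40.0, artifact_rate=0.0),
                link_slope=0.0,
                seed=31,
            )
        )
        c = np.array(list(study.truth.session_coherence.values()))
        g = np.array(list(study.truth.latent_group_scores.values()))
        assert abs(np.corrcoef(c, g)[0, 1]) <= 0.3

    def test_strong_negative_link_recovered_in_latents(self):
        study = synthetic.generate_study(
            synthetic.StudySpec(
                n_sessions=20,
                session=synthetic.SessionSpec(duration=40.0, artifact_rate=0.0),
                link_slope=-5.0,
                link_noise_sd=0.01,
                seed=32,
            )
        )
        c = np.array(list(study.truth.session_coherence.values()))
        g = np.array(list(study.truth.latent_group_scores.values()))
        assert np.corrcoef(c, g)[0, 1] <= -0.9

    def test_same_seed_writes_identical_study(self, tmp_path):
        spec = synthetic.StudySpec(
            n_sessions=2,
            session=synthetic.SessionSpec(duration=8.0, comm_schedule=[(0, 1, 1.0, 7.0)]),
            seed=13,
        )
        synthetic.generate_study(spec, out_dir=tmp_path / "a")
        synthetic.generate_study(spec, out_dir=tmp_path / "b")
        files_a = sorted((tmp_path / "a").rglob("*.*"))
        files_b = sorted((tmp_path / "b").rglob("*.*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_session_layout_on_disk(self, tmp_path):
        spec = synthetic.StudySpec(
            n_sessions=2,
            session=synthetic.SessionSpec(
                duration=8.0, comm_schedule=[(0, 1, 1.0, 7.0)]
            ),
            seed=2,
        )
        synthetic.generate_study(spec, out_dir=tmp_path)
        ses = tmp_path / "ses-1"
        assert (ses / "sub-1_eeg.csv").exists()
        assert (ses / "audio_sub-6.csv").exists()
        assert (ses / "scores.csv").exists()
        events = json.loads((ses / "events.json").read_text())
        assert {"id", "sender", "receiver", "start_unix", "end_unix"} <= set(events[0])
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert "session_coherence" in truth
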