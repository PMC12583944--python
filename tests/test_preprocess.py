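"""Filtering, rereferencing, region reduction, golden SDs and epoch flags."""

import numpy as np
import pytest

from hyperti import preprocess as pp


def _rec(samples, fs=125.0, labels=None, **kw):
    labels = labels or pp.MONTAGE_15[: samples.shape[1]]
    return pp.EEGRecording(
        subject="sub-1", channel_labels=labels, fs=fs, samples=samples, **kw
    )


@pytest.fixture()
def noise_rec(rng):
    return _rec(rng.standard_normal((125 * 40, 15)) * 10.0)


# ---------------------------------------------------------------------- I/O

class TestCsvRoundTrip:
    def test_round_trip_preserves_samples_and_metadata(self, rng, tmp_path):
        rec = _rec(rng.standard_normal((1250, 15)), t0_unix=1.7e9)
        path = tmp_path / "sub-1_eeg.csv"
        pp.write_eeg_csv(rec, path)
        back = pp.read_eeg_csv(path)
        assert back.channel_labels == rec.channel_labels
        assert back.fs == pytest.approx(rec.fs, rel=1e-6)
        assert back.t0_unix == pytest.approx(rec.t0_unix)
        assert np.allclose(back.samples, rec.samples, atol=1e-6)

    def test_missing_channel_is_named(self, rng, tmp_path):
        rec = _rec(rng.standard_normal((300, 15)))
        path = tmp_path / "x.csv"
        pp.write_eeg_csv(rec, path)
        text = path.read_text().replace("O2", "XX")
        path.write_text(text)
        with pytest.raises(pp.PreprocessError, match="O2"):
            pp.read_eeg_csv(path)

    def test_timestamp_gap_rejected_with_location(self, rng, tmp_path):
        rec = _rec(rng.standard_normal((300, 15)))
        path = tmp_path / "x.csv"
        pp.write_eeg_csv(rec, path)
        lines = path.read_text().splitlines()
        parts = lines[150].split(",")
        parts[0] = str(float(parts[0]) + 1.0)  # 1-s gap
        lines[150] = ",".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(pp.PreprocessError, match="non-uniform"):
            pp.read_eeg_csv(path)


# ------------------------------------------------------------------- filter

class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(125 * 20) / 125.0
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = _rec(np.tile(x[:, None], (1, 15)))
        out = pp.bandpass(rec)
        mid = out.samples[500:-500, 0]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.12)

    def test_slow_drift_suppressed(self):
        t = np.arange(125 * 30) / 125.0
        x = np.sin(2 * np.pi * 0.2 * t)
        rec = _rec(np.tile(x[:, None], (1, 15)))
        out = pp.bandpass(rec)
        assert np.abs(out.samples[500:-500, 0]).max() <= 0.10

    def test_edge_above_nyquist_rejected(self):
        rec = _rec(np.zeros((1250, 15)))
        with pytest.raises(pp.PreprocessError, match="62.5"):
            pp.bandpass(rec, 1.0, 70.0)

    def test_filter_and_rereference_commute(self, noise_rec):
        a = pp.rereference_average(pp.bandpass(noise_rec))
        b = pp.bandpass(pp.rereference_average(noise_rec))
        assert np.allclose(a.samples, b.samples, atol=1e-6)


# ---------------------------------------------------------------- reference

class TestAverageReference:
    def test_column_mean_is_zero(self, noise_rec):
        out = pp.rereference_average(noise_rec)
        assert np.abs(out.samples.mean(axis=1)).max() < 1e-9
        assert out.reference == "average"

    def test_constant_across_channels_becomes_zero(self):
        rec = _rec(np.full((250, 15), 5.0))
        out = pp.rereference_average(rec)
        assert np.allclose(out.samples, 0.0)

    def test_already_average_is_noop_with_warning(self, noise_rec):
        once = pp.rereference_average(noise_rec)
        with pytest.warns(UserWarning):
            twice = pp.rereference_average(once)
        assert np.array_equal(once.samples, twice.samples)

    def test_single_channel_rejected(self, rng):
        rec = _rec(rng.standard_normal((250, 1)), labels=("Cz",))
        with pytest.raises(pp.PreprocessError):
            pp.rereference_average(rec)


# ------------------------------------------------------------------ regions

class TestRegionSignals:
    def test_single_channel_region_identity(self, noise_rec):
        rmap = pp.RegionMap({"solo": ("Cz",)})
        out = pp.region_signals(noise_rec, rmap)
        assert np.array_equal(out["solo"], noise_rec.channel("Cz"))

    def test_opposite_channels_cancel(self, rng):
        x = rng.standard_normal(500)
        rec = _rec(np.stack([x, -x], axis=1), labels=("C3", "C4"))
        out = pp.region_signals(rec, pp.RegionMap({"pair": ("C3", "C4")}))
        assert np.allclose(out["pair"], 0.0)

    def test_default_map_means_anterior_channels(self, noise_rec):
        out = pp.region_signals(noise_rec)
        idx = [noise_rec.channel_labels.index(c)
               for c in ("Fp1", "Fp2", "F3", "Fz", "F4")]
        assert np.allclose(out["anterior"], noise_rec.samples[:, idx].mean(axis=1))

    def test_regions_must_be_disjoint(self):
        with pytest.raises(pp.PreprocessError):
            pp.RegionMap({"a": ("Cz",), "b": ("Cz", "C3")})


# ---------------------------------------------------------------- golden SD

class TestGoldenSD:
    def test_consistent_for_gaussian_noise(self, rng):
        rec = _rec(rng.standard_normal((125 * 120, 15)))
        gsd = pp.golden_sd(rec)
        vals = gsd.as_array(rec.channel_labels)
        assert (vals > 0.9).all() and (vals < 1.1).all()

    def test_scales_homogeneously(self, noise_rec):
        g1 = pp.golden_sd(noise_rec)
        g3 = pp.golden_sd(_rec(noise_rec.samples * 3.0))
        a1 = g1.as_array(noise_rec.channel_labels)
        a3 = g3.as_array(noise_rec.channel_labels)
        assert np.allclose(a3, 3.0 * a1)

    def test_robust_to_sparse_artifacts(self, rng):
        clean = rng.standard_normal((125 * 60, 15))
        dirty = clean.copy()
        n_bad = int(0.01 * dirty.shape[0])
        bad = rng.choice(dirty.shape[0], size=n_bad, replace=False)
        dirty[bad, :] += 50.0
        g_clean = pp.golden_sd(_rec(clean)).as_array(pp.MONTAGE_15)
        g_dirty = pp.golden_sd(_rec(dirty)).as_array(pp.MONTAGE_15)
        assert np.allclose(g_dirty, g_clean, rtol=0.02)

    def test_flat_channel_named(self, rng):
        samples = rng.standard_normal((125 * 40, 15))
        samples[:, 3] = 7.0
        with pytest.raises(pp.PreprocessError, match="Fz"):
            pp.golden_sd(_rec(samples))

    def test_short_recording_rejected(self, rng):
        with pytest.raises(pp.PreprocessError, match="30"):
            pp.golden_sd(_rec(rng.standard_normal((125 * 10, 15))))


# ------------------------------------------------------------------- epochs

class TestEpochFlagging:
    def _gsd(self, rec):
        return pp.golden_sd(rec)

    def test_bounded_signal_all_clean(self):
        t = np.arange(125 * 40) / 125.0
        x = np.sin(2 * np.pi * 7.0 * t)
        rec = _rec(np.tile(x[:, None], (1, 15)))
        gsd = pp.GoldenSD({ch: 1.0 for ch in rec.channel_labels})
        flags = pp.epoch_and_flag(rec, gsd, mult=2.0)
        assert flags.clean.all()

    def test_planted_spike_flags_exactly_its_epoch(self, rng):
        samples = rng.standard_normal((125 * 40, 15))
        rec = _rec(samples)
        gsd = self._gsd(rec)
        spiked = samples.copy()
        spiked[7 * 125 + 60, 4] = 10.0 * gsd.values["F4"]
        flags = pp.epoch_and_flag(_rec(spiked), gsd, mult=6.0)
        assert not flags.clean[7]
        assert flags.clean[np.arange(40) != 7].all()

    def test_zero_multiplier_flags_everything(self, noise_rec):
        flags = pp.epoch_and_flag(noise_rec, self._gsd(noise_rec), mult=0.0)
        assert not flags.clean.any()

    def test_grid_is_half_open_and_exhaustive(self, noise_rec):
        flags = pp.epoch_and_flag(noise_rec, self._gsd(noise_rec))
        bounds = flags.boundaries()
        assert bounds[0, 0] == 0
        assert (bounds[:, 1] - bounds[:, 0] == 125).all()
        assert (bounds[1:, 0] == bounds[:-1, 1]).all()
        # clean + flagged partitions the epochs
        assert flags.clean.sum() + (~flags.clean).sum() == flags.n_epochs

    def test_trailing_partial_epoch_dropped(self, rng):
        rec = _rec(rng.standard_normal((125 * 31 + 60, 15)))
        flags = pp.epoch_and_flag(rec, self._gsd(rec))
        assert flags.n_epochs == 31


class TestCommonClean:
    def test_intersection(self):
        a = pp.EpochSet(fs=125, n_epochs=5, clean=[False, True, True, True, False])
        b = pp.EpochSet(fs=125, n_epochs=5, clean=[False, False, True, True, True])
        assert pp.common_clean(a, b).tolist() == [2, 3]

    def test_disjoint_sets_give_empty(self):
        a = pp.EpochSet(fs=125, n_epochs=4, clean=[True, True, False, False])
        b = pp.EpochSet(fs=125, n_epochs=4, clean=[False, False, True, True])
        assert pp.common_clean(a, b).size == 0

    def test_mismatched_grids_rejected(self):
        a = pp.EpochSet(fs=125, n_epochs=4, clean=[True] * 4)
        b = pp.EpochSet(fs=125, n_epochs=5, clean=[True] * 5)
        with pytest.raises(pp.PreprocessError):
            pp.common_clean(a, b)
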