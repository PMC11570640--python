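"""Fixture generator: layout counts, planted signal, determinism, I/O."""

import numpy as np
import pytest
from scipy import stats

import moodgraph as mg
from moodgraph import synthetic
from moodgraph.acoustic import AudioRecording


SMALL = dict(n_mdd_subjects=4, n_hc_subjects=5, segments_per_subject=3,
             n_eeg_channels=16, n_audio_slices=8)


class TestMontageGeneration:
    def test_mirror_symmetry(self):
        m = mg.generate_montage(128)
        coords = {(round(x, 9), round(y, 9)) for x, y in m.coords}
        for x, y in m.coords:
            assert (round(-x, 9), round(y, 9)) in coords

    def test_hemisphere_counts_balanced(self):
        m = mg.generate_montage(128)
        counts = {h: m.hemisphere.count(h) for h in ("left", "right", "midline")}
        assert counts["left"] == counts["right"]
        assert sum(counts.values()) == 128

    def test_deterministic(self):
        a, b = mg.generate_montage(64), mg.generate_montage(64)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.labels == b.labels

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            mg.generate_montage(1)


class TestGenerateDataset:
    def test_default_sample_counts(self, default_fixture):
        samples = default_fixture["samples"]
        assert sum(1 for s in samples if s.label == "MDD") == 638
        assert sum(1 for s in samples if s.label == "HC") == 841
        assert len(samples) == 1479

    def test_paired_shapes_and_manifest(self, default_fixture):
        s = default_fixture["samples"][0]
        man = default_fixture["manifest"]
        assert s.eeg.shape == (128, 16)
        assert s.audio.shape == (32, sum(synthetic.COMPACT_AUDIO_LAYOUT.values()))
        assert man["n_samples"] == 1479
        assert man["seed"] == 17
        assert len(man["signal_channels"]) > 0

    def test_seeded_determinism(self):
        cfg = mg.FixtureConfig(seed=5, **SMALL)
        s1, m1 = mg.generate_dataset(cfg)
        s2, m2 = mg.generate_dataset(cfg)
        assert m1 == m2
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.eeg, b.eeg)
            np.testing.assert_array_equal(a.audio, b.audio)

    def test_zero_effect_size_removes_class_signal(self):
        # compare subject-level means (segments of one subject share a
        # random effect, so they are not independent replicates)
        cfg = mg.FixtureConfig(seed=11, effect_size=0.0, n_mdd_subjects=12,
                               n_hc_subjects=12, segments_per_subject=3,
                               n_eeg_channels=16, n_audio_slices=8)
        samples, _ = mg.generate_dataset(cfg)
        arr = mg.as_arrays(samples)
        pooled = arr["eeg"].mean(axis=1)  # (N, m_e) channel means
        subjects = arr["subjects"]
        uniq = np.unique(subjects)
        subj_mean = np.stack([pooled[subjects == s].mean(axis=0)
                              for s in uniq])
        subj_y = np.array([arr["y"][subjects == s][0] for s in uniq])
        pvals = [stats.ttest_ind(subj_mean[subj_y == 1, j],
                                 subj_mean[subj_y == 0, j]).pvalue
                 for j in range(subj_mean.shape[1])]
        assert np.mean(np.array(pvals) > 0.01) >= 0.9

    def test_subject_random_effect_induces_correlation(self, default_fixture):
        arr = default_fixture["data"]
        man = default_fixture["manifest"]
        sig = np.array(man["signal_channels"])
        # intraclass correlation of the pooled signal-channel mean:
        # between-subject variance must be a positive share of the total
        value = arr["eeg"][:, sig, :].mean(axis=(1, 2))
        subject_means = {}
        for v, s in zip(value, arr["subjects"]):
            subject_means.setdefault(s, []).append(v)
        within = np.mean([np.var(v) for v in subject_means.values()])
        between = np.var([np.mean(v) for v in subject_means.values()])
        assert between / (between + within) > 0.1

    def test_linear_probe_separability(self, default_fixture):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        arr = default_fixture["data"]
        pooled = arr["eeg"].mean(axis=1)
        acc = cross_val_score(LogisticRegression(max_iter=2000), pooled,
                              arr["y"], cv=5).mean()
        assert acc >= 0.85

    def test_waveform_mode_produces_recordings(self):
        cfg = mg.FixtureConfig(seed=2, audio_mode="waveform", **SMALL)
        samples, _ = mg.generate_dataset(cfg)
        rec = samples[0].audio
        assert isinstance(rec, AudioRecording)
        assert len(rec) == cfg.n_audio_slices * cfg.audio_samples_per_slice
        # the waveform path feeds the standard feature extractor
        fm = mg.build_audio_feature_matrix(rec, cfg.n_audio_slices)
        assert fm.values.shape[0] == cfg.n_audio_slices

    def test_waveform_pitch_is_lower_for_mdd(self):
        cfg = mg.FixtureConfig(seed=2, audio_mode="waveform", **SMALL)
        samples, _ = mg.generate_dataset(cfg)
        from moodgraph.acoustic import FeatureConfig, compute_slice_features

        fc = FeatureConfig(frame_length=1024, hop_length=256)
        span = fc.family_slices()["pitch"]

        def mean_pitch(label):
            recs = [s.audio for s in samples if s.label == label][:3]
            return np.mean([compute_slice_features(r, fc)[span][0]
                            for r in recs])

        assert mean_pitch("MDD") < mean_pitch("HC")


class TestFixtureIO:
    def test_roundtrip_bitwise(self, tmp_path):
        cfg = mg.FixtureConfig(seed=7, **SMALL)
        samples, manifest = mg.generate_dataset(cfg)
        mg.write_fixture(samples, manifest, tmp_path / "fix")
        back, man2 = mg.read_fixture(tmp_path / "fix")
        assert man2 == manifest
        assert len(back) == len(samples)
        key = lambda s: (s.subject_id, s.segment_id)
        for a, b in zip(sorted(samples, key=key), sorted(back, key=key)):
            assert a.label == b.label
            np.testing.assert_array_equal(a.eeg, b.eeg)
            np.testing.assert_array_equal(a.audio, b.audio)

    def test_missing_manifest_is_integrity_error(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="manifest"):
            mg.read_fixture(tmp_path / "empty")

    def test_sample_count_mismatch_detected(self, tmp_path):
        cfg = mg.FixtureConfig(seed=7, **SMALL)
        samples, manifest = mg.generate_dataset(cfg)
        mg.write_fixture(samples, manifest, tmp_path / "fix")
        victim = next((tmp_path / "fix" / samples[0].subject_id).glob("*.npz"))
        victim.unlink()
        with pytest.raises(ValueError, match="integrity"):
            mg.read_fixture(tmp_path / "fix")


def test_default_eeg_adjacency_is_valid(default_fixture):
    from moodgraph.graphs import validate_adjacency

    a = default_fixture["data"]["eeg_adjacency"]
    validate_adjacency(a)
    assert a.shape == (128, 128)
    assert a.sum() > 0
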