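"""Feature extraction, LDA, nested CV and the binomial significance test."""

from __future__ import annotations

import math

import numpy as np
import pytest

import erdsbci as eb
from erdsbci.classify import laplacian_features


class TestExtractFeatures:
    def test_segment_tiling_and_reference(self, alpha_session):
        _, _, _, epochs = alpha_session
        f = eb.extract_features(epochs)
        assert f.values.shape == (45, 9, 5, 12)
        np.testing.assert_allclose(f.segment_mids, np.arange(12) + 0.5)
        assert f.reference_segment == 1  # the 1-2 s period
        assert f.activity_segments.tolist() == list(range(2, 12))

    def test_all_values_finite(self, alpha_features):
        assert np.all(np.isfinite(alpha_features.values))

    def test_stationary_signal_reference_equals_activity(self, null_features):
        """No modulation → reference and activity features share one mean."""
        bi = null_features.band_names.index("alpha")
        ref = null_features.values[:, :, bi, null_features.reference_segment]
        act = null_features.values[:, :, bi, 5]
        assert abs(ref.mean() - act.mean()) < 0.15

    def test_implanted_erd_shifts_log_power_by_log_ratio(self, alpha_session):
        """Amplitude factor 0.5 quarters the rhythm's power, so the
        post-cue log α power drops by ln((0.25·P + N)/(P + N)), where N is
        the 1/f background's share of the band (read off a rhythm-free
        channel)."""
        _, _, _, epochs = alpha_session
        f = eb.extract_features(epochs)  # raw channels: Cz carries the rhythm
        ci = f.channel_labels.index("Cz")
        bi = f.band_names.index("alpha")
        ref = f.values[:, ci, bi, f.reference_segment].mean()
        act = f.values[:, ci, bi, 4:].mean()
        noise = float(np.exp(f.values[:, f.channel_labels.index("C1"), bi, :]).mean())
        total = float(np.exp(f.values[:, ci, bi, f.reference_segment]).mean())
        rhythm = total - noise
        expected = math.log((0.25 * rhythm + noise) / (rhythm + noise))
        assert act - ref == pytest.approx(expected, abs=0.15)
        assert act - ref < math.log(0.4)  # still a deep, detectable drop

    def test_causality_of_features(self, alpha_session):
        """Features at a segment midpoint ignore all later samples."""
        _, _, _, epochs = alpha_session
        f1 = eb.extract_features(epochs)
        tampered = epochs.data.copy()
        fs = int(epochs.fs)
        tampered[:, :, 6 * fs :] = 0.0  # wipe everything after t = 6 s
        e2 = eb.EpochSet(
            data=tampered, fs=epochs.fs, channel_labels=epochs.channel_labels,
            labels=epochs.labels, runs=epochs.runs,
        )
        f2 = eb.extract_features(e2)
        np.testing.assert_array_equal(f1.values[..., :5], f2.values[..., :5])

    def test_csv_export(self, alpha_features, tmp_path):
        import pandas as pd

        alpha_features.to_csv(tmp_path / "f.csv")
        df = pd.read_csv(tmp_path / "f.csv")
        assert len(df) == alpha_features.values.size
        assert set(df.columns) == {"trial", "block", "channel", "band", "segment", "value"}


class TestTrainLda:
    def test_symmetric_classes_boundary_at_midpoint(self, rng):
        x0 = rng.normal(0.0, 1.0, (2000, 1))
        x1 = rng.normal(2.0, 1.0, (2000, 1))
        model = eb.train_lda(x0, x1)
        assert model.w[0] > 0
        boundary = -model.b / model.w[0]
        assert boundary == pytest.approx(1.0, abs=0.1)

    def test_class_swap_antisymmetry(self, rng):
        x0 = rng.normal(0.0, 1.0, (200, 2))
        x1 = rng.normal(1.0, 1.0, (200, 2))
        m = eb.train_lda(x0, x1)
        m_swapped = eb.train_lda(x1, x0)
        np.testing.assert_allclose(m_swapped.w, -m.w, rtol=1e-9)
        assert m_swapped.b == pytest.approx(-m.b)
        x = rng.normal(0.5, 1.0, (50, 2))
        np.testing.assert_array_equal(m.predict(x), 1 - m_swapped.predict(x))

    def test_weight_parallel_to_closed_form(self, rng):
        """Oracle: w ∝ Σ⁻¹Δμ for known Σ and means, n = 10⁴."""
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        delta = np.array([2.0, 1.0])
        chol = np.linalg.cholesky(cov)
        n = 10_000
        x0 = rng.standard_normal((n, 2)) @ chol.T
        x1 = rng.standard_normal((n, 2)) @ chol.T + delta
        model = eb.train_lda(x0, x1)
        w_true = np.linalg.solve(cov, delta)
        cosine = model.w @ w_true / (np.linalg.norm(model.w) * np.linalg.norm(w_true))
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) <= 1.0

    def test_agrees_with_sklearn_direction(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x0 = rng.normal(0.0, 1.0, (300, 3))
        x1 = rng.normal(0.4, 1.0, (300, 3))
        model = eb.train_lda(x0, x1)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(
            np.vstack([x0, x1]), np.r_[np.zeros(300), np.ones(300)]
        )
        w_sk = sk.coef_.ravel()
        cosine = model.w @ w_sk / (np.linalg.norm(model.w) * np.linalg.norm(w_sk))
        assert cosine > 0.999

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            eb.train_lda(np.zeros((0, 2)), np.ones((5, 2)))

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            eb.train_lda(np.ones((5, 2)), np.ones((5, 2)))


def _separable_features(n_trials=30, n_blocks=3, seed=0):
    """Toy FeatureSet where one (channel, band, segment) separates
    perfectly: activity values 5 log-units below reference at Cz/alpha."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 0.5, (n_trials, 2, 2, 6))
    values[:, 0, 1, 3:] -= 5.0  # Cz, alpha, post-cue segments
    return eb.FeatureSet(
        values=values,
        channel_labels=["Cz", "C1"],
        band_names=["theta", "alpha"],
        segment_mids=np.arange(6) + 0.5,
        reference_segment=1,
        labels=["sport"] * n_trials,
        blocks=np.repeat(np.arange(n_blocks), n_trials // n_blocks),
        cue_onset=2.0,
    )


class TestNestedBlockwiseCV:
    def test_perfectly_separable_reaches_full_accuracy(self):
        f = _separable_features()
        res = eb.nested_blockwise_cv(f, seed=0)
        assert res.accuracy == 100.0
        assert res.p_value < 0.01
        assert res.channel == "Cz" and res.band == "alpha"

    def test_micro_average_identity(self, alpha_features):
        res = eb.nested_blockwise_cv(alpha_features, seed=0)
        c = res.confusion
        assert c.sum() == 2 * alpha_features.n_trials
        assert res.accuracy == pytest.approx(100.0 * (c[0, 0] + c[1, 1]) / c.sum())

    def test_selects_implanted_channel_and_band(self, alpha_features):
        res = eb.nested_blockwise_cv(alpha_features, seed=0)
        assert res.band == "alpha"
        assert res.channel in ("Cz", "FCz", "CPz", "C1", "C2")
        assert res.accuracy >= 70.0

    def test_null_label_flips_give_chance_accuracy(self, null_features):
        rng = np.random.default_rng(7)
        accs = [
            eb.nested_blockwise_cv(
                null_features, seed=0, flip_mask=rng.random(null_features.n_trials) < 0.5
            ).accuracy
            for _ in range(8)
        ]
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_outer_selection_ignores_test_block_labels(self, alpha_features):
        """Permutation audit: flipping class roles inside the held-out
        block must not change what the inner loop selects for that fold."""
        res = eb.nested_blockwise_cv(alpha_features, seed=3)
        flip = alpha_features.blocks == 0  # corrupt block 0 only
        res_flipped = eb.nested_blockwise_cv(alpha_features, seed=3, flip_mask=flip)
        assert res.per_fold_selected[0] == res_flipped.per_fold_selected[0]

    def test_deterministic_under_seed(self, alpha_features):
        r1 = eb.nested_blockwise_cv(alpha_features, seed=5)
        r2 = eb.nested_blockwise_cv(alpha_features, seed=5)
        assert r1.accuracy == r2.accuracy
        assert (r1.channel, r1.band, r1.segment) == (r2.channel, r2.band, r2.segment)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_single_block_rejected(self):
        f = _separable_features(n_blocks=1)
        with pytest.raises(ValueError, match="2 blocks"):
            eb.nested_blockwise_cv(f)


class TestLotoCV:
    def test_one_outer_evaluation_per_trial(self, alpha_features):
        res = eb.loto_cv(alpha_features, seed=0)
        assert res.confusion.sum() == 2 * alpha_features.n_trials
        assert res.scheme == "loto"

    def test_consistent_with_nested_on_separable_data(self, alpha_features):
        nested = eb.nested_blockwise_cv(alpha_features, seed=0)
        loto = eb.loto_cv(alpha_features, seed=0)
        assert abs(nested.accuracy - loto.accuracy) <= 10.0

    def test_too_few_trials_rejected(self):
        f = _separable_features(n_trials=9, n_blocks=3)
        with pytest.raises(ValueError, match="10 trials"):
            eb.loto_cv(f)


class TestMonotonicity:
    def test_deeper_erd_never_reduces_mean_accuracy(self, montage9):
        """Smaller amplitude factor (deeper ERD) → easier detection."""
        from conftest import make_alpha_config

        mean_acc = {}
        for factor in (0.8, 0.5):
            accs = []
            for seed in (20, 21):
                rec, ev, _ = eb.generate_session(make_alpha_config(seed=seed, factor=factor))
                f = laplacian_features(eb.epoch(rec, ev), montage9)
                accs.append(eb.nested_blockwise_cv(f, seed=0).accuracy)
            mean_acc[factor] = np.mean(accs)
        assert mean_acc[0.5] >= mean_acc[0.8]


class TestAccuracySignificance:
    def test_chance_level_not_significant(self):
        """Oracle: exact binomial tail via math.comb, 45 of 90 correct."""
        p_oracle = sum(math.comb(90, k) for k in range(45, 91)) / 2**90
        confusion = np.array([[23, 22], [23, 22]])  # 45 correct of 90
        assert eb.accuracy_significance(confusion) == pytest.approx(p_oracle, rel=1e-10)
        assert eb.accuracy_significance(confusion) > 0.5

    def test_perfect_classification(self):
        confusion = np.array([[45, 0], [0, 45]])
        assert eb.accuracy_significance(confusion) == pytest.approx(2.0**-90, rel=1e-9)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            eb.accuracy_significance(np.zeros((2, 2)))

    def test_significance_level_tags(self):
        res_ns = eb.SessionResult(
            channel="Cz", band="alpha", segment=5, segment_time=5.5,
            confusion=np.array([[23, 22], [23, 22]]), accuracy=50.0,
            p_value=0.54, scheme="nested_blockwise",
        )
        assert res_ns.significance_level == "n.s."
        res_01 = eb.SessionResult(
            channel="Cz", band="alpha", segment=5, segment_time=5.5,
            confusion=np.array([[45, 0], [0, 45]]), accuracy=100.0,
            p_value=1e-20, scheme="nested_blockwise",
        )
        assert res_01.significance_level == "0.01"
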