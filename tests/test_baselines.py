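"""Baselines: peak-feature SVC, Rosenstein MaxLE, Youden-J, entropy score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitbarrier.baselines import (
    delay_embed,
    entropy_segment_scores,
    extract_features,
    maxle_loso,
    pool_magnitudes,
    rosenstein_maxle,
    svc_loso,
    train_rbf_svm,
    window_maxle,
    youden_threshold,
)
from gaitbarrier.preprocess import CHANNEL_NAMES, GaitWindow


def _window_with_svm(values):
    samples = np.zeros((8, len(values)))
    samples[CHANNEL_NAMES.index("SVM_Acc")] = values
    return GaitWindow(0, 0, 0, 0.0, samples, 100.0)


class TestFeatures:
    @pytest.mark.parametrize(
        "values, expected", [([9.8, 10.1, 12.3, 9.9], 12.3), ([9.8, 9.8], 9.8)]
    )
    def test_peak(self, values, expected):
        assert extract_features(_window_with_svm(values))["peak"] == expected

    def test_extended_set(self):
        feats = extract_features(_window_with_svm([9.8, 10.2]), ("peak", "mean", "std"))
        assert feats["mean"] == pytest.approx(10.0)
        assert feats["std"] == pytest.approx(0.2)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_window_with_svm([1.0]), ("kurtosis",))


class TestRbfSvc:
    def test_separable_classes_fit_perfectly(self, rng):
        x = np.concatenate([rng.normal(5, 0.1, 40), rng.normal(15, 0.1, 40)])[:, None]
        y = np.repeat([0, 1], 40)
        clf = train_rbf_svm(x, y)
        assert (clf.predict(x) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_rbf_svm(np.zeros((5, 1)), np.ones(5))

    def test_decision_values_match_kernel_expansion(self, rng):
        """Decision function equals the dual-coefficient RBF kernel sum."""
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = train_rbf_svm(x, y, C=10.0, gamma=0.01)
        svc = clf.named_steps["svc"]
        xs = clf.named_steps["scale"].transform(x)
        sv = svc.support_vectors_
        k = np.exp(-0.01 * ((xs[:, None, :] - sv[None, :, :]) ** 2).sum(-1))
        manual = k @ svc.dual_coef_.ravel() + svc.intercept_[0]
        np.testing.assert_allclose(clf.decision_function(x), manual, atol=1e-6)


class TestRosensteinMaxle:
    def test_delay_embedding_shape_and_content(self):
        X = delay_embed(np.arange(20.0), m=3, tau=4)
        assert X.shape == (12, 3)
        np.testing.assert_array_equal(X[0], [0, 4, 8])

    @pytest.mark.parametrize("freq", [0.5, 1.0, 2.0, 3.0])
    def test_periodic_signal_zero_exponent(self, freq):
        """Noise-free sinusoids sit in the zero-divergence band."""
        t = np.arange(2000) / 100.0
        est = rosenstein_maxle(np.sin(2 * np.pi * freq * t), fs=100.0)
        assert abs(est.lam) <= 0.05

    def test_white_noise_diverges_immediately(self):
        noise = np.random.default_rng(0).standard_normal(2000)
        assert rosenstein_maxle(noise, fs=100.0).lam > 1.0

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            rosenstein_maxle(np.zeros(30), fs=100.0, m=6, tau=5)

    def test_lorenz_against_benettin_oracle(self, lorenz_x, benettin_lambda):
        """Rosenstein on the Lorenz x-series lands within +/-20% of the
        independent Benettin two-trajectory estimate. The fit window spans
        ~1.5 Lyapunov times (the initial linear scaling region); the
        Theiler window is one mean orbital period."""
        est = rosenstein_maxle(lorenz_x, fs=100.0, m=6, tau=5, theiler=100, fit_window=150)
        assert est.lam == pytest.approx(benettin_lambda, rel=0.20)

    def test_window_scorer_separates_perturbed_windows(self, small_dataset):
        lam = window_maxle(small_dataset)
        assert np.all(np.isfinite(lam)) and len(lam) == len(small_dataset.included)


class TestYoudenThreshold:
    def test_perfect_separation_midpoint(self):
        thr = youden_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.5)

    def test_identical_distributions_zero_j(self):
        scores = np.array([0.3, 0.7, 0.3, 0.7])
        labels = np.array([0, 0, 1, 1])
        thr = youden_threshold(scores, labels)
        pred = scores > thr
        j = (pred & (labels == 1)).sum() / 2 + (~pred & (labels == 0)).sum() / 2 - 1
        assert j == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_exhaustive_search(self, seed):
        """Equals brute force over all candidate midpoints (500 instances)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]

        def j_of(thr):
            pred = scores > thr
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            return sens + spec - 1

        uniq = np.unique(scores)
        if len(uniq) == 1:
            assert youden_threshold(scores, labels) == uniq[0]
            return
        cands = (uniq[:-1] + uniq[1:]) / 2
        js = np.array([j_of(c) for c in cands])
        best = cands[js >= js.max() - 1e-12].min()
        got = youden_threshold(scores, labels)
        assert j_of(got) == pytest.approx(js.max())
        assert got == pytest.approx(best)


class TestEntropyScores:
    def test_uniform_histogram_max_entropy(self, rng):
        # one sample per bin centre -> uniform counts over 40 bins
        centres = (np.arange(40) + 0.5) / 40
        prof = entropy_segment_scores([centres, np.full(10, 0.5)])
        assert prof.h_bits[0] == pytest.approx(np.log2(40), abs=1e-3)

    def test_single_bin_near_zero_entropy(self):
        prof = entropy_segment_scores([np.full(100, 0.31), np.linspace(0, 1, 50)])
        assert prof.h_bits[0] == pytest.approx(0.0, abs=1e-2)

    def test_normalisation_extremes(self):
        prof = entropy_segment_scores(
            [np.linspace(0, 1, 200), np.full(50, 0.5), np.array([0.1, 0.9])]
        )
        assert prof.normalized.max() == 1.0 and prof.normalized.min() == 0.0

    def test_empty_segment_flagged_not_fatal(self):
        prof = entropy_segment_scores([np.array([]), np.linspace(0, 1, 20), np.full(5, 0.2)])
        assert np.isnan(prof.h_bits[0]) and np.isfinite(prof.h_bits[1])

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy_segment_scores([np.array([]), np.array([])])

    def test_permutation_and_duplication_invariance(self, rng):
        x = rng.random(200)
        a = entropy_segment_scores([x, x[::-1]], epsilon=0.0)
        b = entropy_segment_scores([rng.permutation(x), np.tile(x, 3)], epsilon=0.0)
        np.testing.assert_allclose(a.h_bits, b.h_bits, atol=1e-12)

    def test_pooling_per_participant_normalisation(self):
        edges = np.array([0.0, 5.0, 10.0])
        per_subject = {
            0: [(np.array([1.0, 6.0]), np.array([10.0, 20.0]))],
            1: [(np.array([2.0, 7.0]), np.array([100.0, 300.0]))],
        }
        pooled = pool_magnitudes(per_subject, edges)
        np.testing.assert_allclose(pooled[0], [0.0, 0.0])  # per-subject minima
        np.testing.assert_allclose(pooled[1], [1.0, 1.0])  # per-subject maxima


class TestBaselineLoso:
    def test_svc_loso_covers_all_windows_once(self, small_dataset):
        preds = svc_loso(small_dataset)
        assert len(preds) == len(small_dataset.included)
        assert preds.duplicated(["subject", "trial", "window_id"]).sum() == 0
        assert set(preds["pred_label"]) <= {0, 1}

    def test_maxle_loso_learns_threshold_per_fold(self, small_dataset):
        preds = maxle_loso(small_dataset)
        assert len(preds) == len(small_dataset.included)
        assert preds["fold_id"].nunique() == len(small_dataset.subjects)
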