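"""Decoder contracts: balancing, the LDA solver against scikit-learn,
AUC against a brute-force pairwise oracle, fold hygiene, activation maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from dualdecode.decoding import (TimeResolvedDecoder, activation_map,
                                 auc_from_scores, balance_between_class,
                                 balance_within_class, crossval_decode,
                                 make_fold_plan, train_lda)
from dualdecode.simulate import SimulationConfig, default_channel_split, \
    generate_dataset


def brute_force_auc(scores, labels):
    """O(n^2) concordant-pair oracle; ties count one half."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def make_trials(h_counts):
    """Trials table with given (h_class, v_class) -> count mapping."""
    rows = []
    for (h, v), n in h_counts.items():
        rows += [{"h_class": h, "v_class": v}] * n
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
class TestWithinClassBalance:
    def test_undersamples_to_minimum(self, rng):
        trials = make_trials({("left", "top"): 30, ("left", "bottom"): 26,
                              ("right", "top"): 28, ("right", "bottom"): 28})
        keep = balance_within_class(trials, "horizontal", rng)
        sub = trials.iloc[keep]
        counts = sub.groupby(["h_class", "v_class"]).size()
        assert counts[("left", "top")] == 26
        assert counts[("left", "bottom")] == 26
        assert counts[("right", "top")] == 28

    def test_already_balanced_unchanged(self, rng):
        trials = make_trials({("left", "top"): 32, ("left", "bottom"): 32,
                              ("right", "top"): 32, ("right", "bottom"): 32})
        keep = balance_within_class(trials, "horizontal", rng)
        assert len(keep) == 128

    def test_empty_cell_raises(self, rng):
        trials = make_trials({("right", "top"): 10, ("left", "top"): 5,
                              ("left", "bottom"): 5})
        with pytest.raises(ValueError):
            balance_within_class(trials, "horizontal", rng)


class TestBetweenClassBalance:
    def test_count_rule_40_vs_60(self, rng):
        X = rng.standard_normal((100, 5))
        y = np.r_[np.ones(40, bool), np.zeros(60, bool)]
        Xa, ya = balance_between_class(X, y, rng)
        assert len(Xa) == 120 and ya.sum() == 60

    def test_balanced_input_untouched(self, rng):
        X = rng.standard_normal((100, 5))
        y = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        Xa, ya = balance_between_class(X, y, rng)
        assert Xa is X and ya is y

    def test_synthetic_samples_in_minority_envelope(self, rng):
        X = rng.uniform(2.0, 9.0, size=(80, 7))
        y = np.r_[np.ones(20, bool), np.zeros(60, bool)]
        Xa, ya = balance_between_class(X, y, rng)
        synth = Xa[80:]
        lo, hi = X[:20].min(axis=0), X[:20].max(axis=0)
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_singleton_minority_duplicates_with_warning(self, rng):
        X = rng.standard_normal((5, 3))
        y = np.array([True, False, False, False, False])
        with pytest.warns(UserWarning):
            Xa, ya = balance_between_class(X, y, rng)
        assert ya.sum() == 4
        assert np.allclose(Xa[5:], X[0])


# ----------------------------------------------------------------------
class TestLda:
    def test_matches_sklearn_ledoit_wolf(self, rng):
        X = rng.standard_normal((90, 10)) * rng.uniform(0.5, 2.0, 10)
        y = rng.random(90) < 0.5
        w, b = train_lda(X, y, "auto")
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                        priors=[0.5, 0.5]).fit(X, y)
        assert np.allclose(w, sk.coef_[0], rtol=1e-5)
        assert np.isclose(b, sk.intercept_[0], rtol=1e-5)

    def test_matches_sklearn_fixed_shrinkage(self, rng):
        X = rng.standard_normal((60, 8))
        y = rng.random(60) < 0.5
        w, b = train_lda(X, y, 0.3)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.3,
                                        priors=[0.5, 0.5]).fit(X, y)
        assert np.allclose(w, sk.coef_[0], rtol=1e-6)

    def test_separable_clouds_perfect_training_auc(self, rng):
        X = np.r_[rng.standard_normal((40, 2)) + 8.0,
                  rng.standard_normal((40, 2)) - 8.0]
        y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        w, b = train_lda(X, y)
        assert auc_from_scores(X @ w + b, y) == 1.0

    def test_full_shrinkage_weights_proportional_to_mean_difference(self, rng):
        # shrinkage 1 -> spherical covariance -> w parallel to mu1 - mu0
        X = rng.standard_normal((200, 6))
        y = rng.random(200) < 0.5
        w, _ = train_lda(X, y, 1.0)
        diff = X[y].mean(axis=0) - X[~y].mean(axis=0)
        cos = w @ diff / (np.linalg.norm(w) * np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0], [2.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            train_lda(X, np.array([True, True, False, False]))


class TestAuc:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
        ([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.75),
    ])
    def test_stated_examples(self, scores, labels, expected):
        got = auc_from_scores(np.array(scores), np.array(labels, bool))
        assert got == expected

    def test_matches_pairwise_oracle_exactly(self, rng):
        for n in (5, 17, 63, 200):
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            assert auc_from_scores(scores, labels) == \
                brute_force_auc(scores, labels)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_from_scores(np.array([1.0, 2.0]), np.array([True, True]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(-5.0, 5.0, allow_nan=False).map(
            lambda x: round(x, 1)), st.booleans()),
        min_size=4, max_size=60))
    def test_pairwise_oracle_property(self, pairs):
        scores = np.array([p[0] for p in pairs])
        labels = np.array([p[1] for p in pairs])
        assume(labels.any() and not labels.all())
        assert auc_from_scores(scores, labels) == \
            brute_force_auc(scores, labels)


# ----------------------------------------------------------------------
class TestFoldPlan:
    def test_partition_and_near_equal_sizes(self, rng):
        fold = make_fold_plan(97, 10, rng)
        sizes = np.bincount(fold, minlength=10)
        assert sizes.sum() == 97
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_trials_than_folds_raises(self, rng):
        with pytest.raises(ValueError):
            make_fold_plan(5, 10, rng)


class TestTimeResolvedDecoder:
    def test_sklearn_protocol(self):
        dec = TimeResolvedDecoder(n_folds=5, random_state=3)
        assert dec.get_params()["n_folds"] == 5
        dec2 = clone(dec).set_params(n_folds=4)
        assert dec2.get_params()["n_folds"] == 4

    def test_shuffled_labels_give_chance_auc(self, rng):
        X = rng.standard_normal((80, 8, 20))
        y = rng.random(80) < 0.5
        dec = TimeResolvedDecoder(n_folds=5, random_state=0).fit(X, y)
        assert 0.4 < dec.auc_.mean() < 0.6

    def test_confidence_complete_and_from_test_fold_only(self, rng):
        X = rng.standard_normal((40, 4, 6))
        y = np.arange(40) % 2 == 0
        dec = TimeResolvedDecoder(n_folds=5, random_state=1).fit(X, y)
        assert np.all(np.isfinite(dec.confidence_))
        assert dec.fold_.shape == (40,)
        assert np.bincount(dec.fold_).tolist() == [8] * 5

    def test_determinism(self, neg_epochs):
        a = crossval_decode(neg_epochs, "horizontal", seed=5,
                            window_ms=(300.0, 400.0))
        b = crossval_decode(neg_epochs, "horizontal", seed=5,
                            window_ms=(300.0, 400.0))
        assert np.array_equal(a.auc, b.auc)
        assert np.array_equal(a.confidence, b.confidence)
        c = crossval_decode(neg_epochs, "horizontal", seed=6,
                            window_ms=(300.0, 400.0))
        assert not np.array_equal(a.auc, c.auc)


class TestActivationMaps:
    def test_identity_covariance_returns_weights(self, rng):
        X = rng.standard_normal((40000, 2))
        pattern = activation_map(np.array([1.0, 1.0]), X)
        assert np.allclose(pattern, [1.0, 1.0], atol=0.05)

    def test_diagonal_covariance_scales_weights(self, rng):
        X = rng.standard_normal((80000, 2)) * np.array([np.sqrt(2.0), 1.0])
        pattern = activation_map(np.array([1.0, 1.0]), X)
        assert np.allclose(pattern, [2.0, 1.0], atol=0.05)

    def test_recovers_injected_channel_template(self, neg_pair):
        res_h, _ = neg_pair
        split = default_channel_split()
        template = split.pattern("horizontal", 64)
        peak = int(np.argmax(res_h.auc))
        a = res_h.activation[peak]
        corr = np.corrcoef(a, template)[0, 1]
        assert corr > 0.9


# ----------------------------------------------------------------------
class TestEndToEndDecoding:
    def test_high_snr_peak_auc_above_reliability_band(self, neg_pair):
        res_h, res_v = neg_pair
        # negative mode: each dimension carries signal on half the trials,
        # so BOTH decoders perform above chance
        assert res_h.auc.max() >= 0.6
        assert res_v.auc.max() >= 0.6

    def test_noise_only_dataset_decodes_at_chance(self):
        ep = generate_dataset(SimulationConfig(
            n_trials=96, amplitude=0.0, noise_amplitude=0.25, seed=31))
        res = crossval_decode(ep, "horizontal", seed=7,
                              window_ms=(150.0, 700.0))
        assert abs(res.auc.mean() - 0.5) < 0.03

    def test_too_few_trials_raise(self):
        ep = generate_dataset(SimulationConfig(n_trials=8, seed=1))
        with pytest.raises(ValueError):
            crossval_decode(ep, "horizontal", folds=10, seed=0,
                            window_ms=(300.0, 320.0))
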