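"""Classifier protocol: balancing, optimization, LORO folds, transforms."""

import numpy as np
import pandas as pd
import pytest

from contextval import decoding as C


class TestBalanceUpsample:
    def _toy(self):
        return pd.DataFrame({
            "label": ["a"] * 5 + ["b"] * 3,
            "block": [1, 1, 2, 2, 3, 1, 1, 1],
            "x": range(8),
        })

    def test_under_represented_cell_filled(self):
        up = C.balance_upsample(self._toy(), ["label"], seed=0)
        counts = up["label"].value_counts()
        assert counts["a"] == 5 and counts["b"] == 5

    def test_balanced_set_unchanged(self):
        df = self._toy().iloc[[0, 1, 5, 6]]
        up = C.balance_upsample(df, ["label"], seed=0)
        pd.testing.assert_frame_equal(up, df)

    def test_duplicates_are_exact_copies(self):
        df = self._toy()
        up = C.balance_upsample(df, ["label"], seed=1)
        added = up.iloc[len(df):]
        for _, row in added.iterrows():
            assert ((df["label"] == row["label"]) & (df["x"] == row["x"])).any()

    def test_duplicates_prefer_scarce_blocks(self):
        # cell "b" has blocks 1,1,1 and 2: the first duplicates must come
        # from block 2 until blocks balance
        df = pd.DataFrame({
            "label": ["a"] * 6 + ["b"] * 4,
            "block": [1, 1, 2, 2, 3, 3, 1, 1, 1, 2],
            "x": range(10),
        })
        up = C.balance_upsample(df, ["label"], seed=2)
        added = up.iloc[len(df):]
        assert (added["block"] == 2).iloc[0]

    def test_empty_cell_detected(self):
        df = pd.DataFrame({"ev": [30, 30, 50], "ctx": ["c", "m", "c"],
                           "block": [1, 1, 1]})
        with pytest.raises(ValueError, match="empty balancing cell"):
            C.check_cells_nonempty(df, ["ev", "ctx"])


class TestFitMultinomial:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1], [20, 0], [20, 1]])
        y = np.array([0, 0, 1, 1, 2, 2])
        clf = C.fit_multinomial(X, y)
        assert (clf.predict(X) == y).all()

    def test_penalized_objective_not_worse_than_zero_weights(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 3, 60)
        clf = C.fit_multinomial(X, y)
        n_classes = 3

        def objective(W, b):
            z = X @ W.T + b
            z -= z.max(axis=1, keepdims=True)
            log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            nll = -log_p[np.arange(len(y)), y].sum()
            return nll + 0.5 * (W ** 2).sum()

        at_fit = objective(clf.coef_, clf.intercept_)
        at_zero = objective(np.zeros_like(clf.coef_), np.zeros(n_classes))
        assert at_fit <= at_zero

    def test_gradient_norm_small_against_finite_differences(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = rng.integers(0, 2, 40)
        clf = C.fit_multinomial(X, y, tol=1e-12)

        # independent oracle: finite-difference gradient of the penalized
        # binomial objective sklearn minimizes (sum NLL + w^2 / (2C))
        w = np.concatenate([clf.coef_.ravel(), clf.intercept_])

        def obj(wvec):
            coef, b = wvec[:-1], wvec[-1]
            z = X @ coef + b
            nll = np.logaddexp(0, -z[y == 1]).sum() + np.logaddexp(0, z[y == 0]).sum()
            return nll + 0.5 * coef @ coef

        eps = 1e-6
        grad = np.array([
            (obj(w + eps * e) - obj(w - eps * e)) / (2 * eps)
            for e in np.eye(len(w))
        ])
        assert np.linalg.norm(grad) < 1e-4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            C.fit_multinomial(np.zeros((5, 2)), np.zeros(5))


class TestLoroDecode:
    def test_each_trial_predicted_exactly_once(self, strong_patterns):
        out = C.loro_decode(strong_patterns, "value", seed=0)
        assert len(out) == 432
        assert out["trial"].is_unique
        assert (out.groupby("fold").size() == 108).all()

    def test_probabilities_clipped_and_normalized(self, strong_value_probs):
        probs = strong_value_probs[["p_30", "p_50", "p_70"]].to_numpy()
        assert probs.min() >= C.PROB_CLIP[0]
        assert probs.max() <= C.PROB_CLIP[1]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=6e-5)

    def test_signal_patterns_beat_chance(self, strong_value_probs):
        acc = C.balanced_accuracy(strong_value_probs, "EV", "p_").iloc[0, 0]
        assert acc > 0.4

    def test_noise_patterns_at_chance(self, null_patterns):
        val = C.loro_decode(null_patterns, "value", seed=1)
        ctx = C.loro_decode(null_patterns, "context", seed=2)
        acc_v = C.balanced_accuracy(val, "EV", "p_").iloc[0, 0]
        acc_c = C.balanced_accuracy(ctx, "context", "p_").iloc[0, 0]
        # binomial CI around chance for ~400 trials
        assert abs(acc_v - 1 / 3) < 0.08
        assert abs(acc_c - 1 / 2) < 0.08

    def test_context_decodable_with_context_code(self, strong_patterns):
        ctx = C.loro_decode(strong_patterns, "context", seed=3)
        assert C.balanced_accuracy(ctx, "context", "p_").iloc[0, 0] > 0.6

    def test_unknown_target_rejected(self, strong_patterns):
        with pytest.raises(ValueError):
            C.loro_decode(strong_patterns, "evback")

    def test_value_probability_profile_graded(self, strong_value_probs):
        """Graded codes: mean P(class) falls with |EV - class| (Fig.-4c style)."""
        df = strong_value_probs[(strong_value_probs["dim"] == "1D")
                                & (strong_value_probs["accuracy"] == 1)]
        by_dist = {0: [], 20: [], 40: []}
        for c in C.VALUE_CLASSES:
            for ev in C.VALUE_CLASSES:
                by_dist[abs(ev - c)].extend(df[df["EV"] == ev][f"p_{c}"])
        means = {k: np.mean(v) for k, v in by_dist.items()}
        assert means[0] > means[20] > means[40]


class TestOvrEvback:
    def test_renormalized_probabilities_sum_to_one(self, strong_patterns):
        out = C.ovr_evback_decode(strong_patterns, seed=0)
        assert np.allclose(out["raw_sum"], 1.0, atol=1e-10)
        assert len(out) == 288  # 2D trials only

    def test_ovr_weights_balance_positive_and_negative(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        w = np.where(y == 1, 0.5 / y.sum(), 0.5 / (len(y) - y.sum())) * len(y)
        assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())

    def test_signal_beats_permutation_null(self, strong_patterns):
        out = C.ovr_evback_decode(strong_patterns, seed=1)
        correct = np.zeros(len(out))
        for i, (_, row) in enumerate(out.iterrows()):
            correct[i] = row[f"pback_{int(row['EV_back'])}"]
        rng = np.random.default_rng(2)
        null_means = []
        levels = out["EV_back"].to_numpy()
        for _ in range(200):
            perm = rng.permutation(levels)
            null_means.append(np.mean([
                out.iloc[i][f"pback_{int(perm[i])}"] for i in range(len(out))]))
        assert correct.mean() > np.mean(null_means)


class TestTransforms:
    def test_uniform_distribution_maps_to_zero(self):
        assert np.allclose(C.mlogit(np.array([1 / 3, 1 / 3, 1 / 3])), 0.0)

    def test_printed_example(self):
        ml = C.mlogit(np.array([0.5, 0.25, 0.25]))
        assert ml[0] == pytest.approx(np.log(2))

    def test_logit_half_is_zero(self):
        assert C.logit(0.5) == 0.0

    def test_transform_probs_adds_columns(self, strong_value_probs):
        out = C.transform_probs(strong_value_probs)
        assert {"mlogit_p_30", "mlogit_p_50", "mlogit_p_70"} <= set(out.columns)
        row = out.iloc[0]
        manual = C.mlogit(row[["p_30", "p_50", "p_70"]].to_numpy(dtype=float))
        assert row["mlogit_p_30"] == pytest.approx(manual[0])


class TestBalancedAccuracy:
    def test_all_correct_scores_one(self):
        df = pd.DataFrame({"fold": [1, 1, 2, 2], "y": ["a", "b", "a", "b"],
                           "p_a": [0.9, 0.1, 0.8, 0.2],
                           "p_b": [0.1, 0.9, 0.2, 0.8]})
        assert C.balanced_accuracy(df, "y", "p_").iloc[0, 0] == 1.0

    def test_majority_predictor_on_imbalanced_set(self):
        # 2:1 imbalance, predictor always says the majority class: balanced
        # accuracy must be 1 / n_classes, not the raw 2/3
        df = pd.DataFrame({"fold": [1] * 6, "y": ["a", "a", "a", "a", "b", "b"],
                           "p_a": [0.9] * 6, "p_b": [0.1] * 6})
        assert C.balanced_accuracy(df, "y", "p_").iloc[0, 0] == 0.5

    def test_argmax_tie_counts_incorrect(self):
        df = pd.DataFrame({"fold": [1], "y": ["a"],
                           "p_a": [0.5], "p_b": [0.5]})
        assert C.balanced_accuracy(df, "y", "p_").iloc[0, 0] == 0.0


class TestAggregate:
    def test_full_design_gives_36_cells(self, strong_value_probs):
        agg = C.aggregate_combinations(
            strong_value_probs[strong_value_probs["accuracy"] == 1])
        assert len(agg) == 36

    def test_averaging_preserves_sum_to_one(self, strong_value_probs):
        agg = C.aggregate_combinations(
            strong_value_probs[strong_value_probs["accuracy"] == 1])
        total = agg[["p_30", "p_50", "p_70"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=2e-4)

    def test_single_trial_cell_equals_trial_value(self):
        df = pd.DataFrame({
            "dim": ["2D"], "choice_side": ["left"], "irr_left": [70.0],
            "irr_right": [10.0], "EV": [50], "p_30": [0.2], "p_50": [0.5],
            "p_70": [0.3]})
        agg = C.aggregate_combinations(df)
        assert agg.iloc[0]["p_50"] == 0.5
        assert agg.iloc[0]["EV_back"] == 70
        assert agg.iloc[0]["congruency"] == "congruent"
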