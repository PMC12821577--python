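"""PLS-LDA model, repeated double cross-validation, permutation test,
variable selection and sample stability."""

import numpy as np
import pytest

from urinmr.plslda import (
    PLSLDA,
    RdCVConfig,
    fit_pls,
    fit_plslda,
    permutation_test,
    rdcv,
    sample_stability,
    select_variables,
)


def _separable(rng, n_per=30, p=20, delta=4.0):
    X = rng.normal(size=(2 * n_per, p))
    X[:n_per, :3] += delta
    y = np.repeat([1, 0], n_per)
    return X - X.mean(axis=0), y


class TestFitPls:
    def test_first_weight_is_normalized_xty(self):
        """One NIPALS step on a hand-sized fixture: w1 = X'y / ||X'y||."""
        X = np.array(
            [
                [1.0, 0.5, -0.2],
                [-0.8, 0.1, 0.3],
                [0.2, -0.7, 0.5],
                [0.4, 0.6, -0.9],
                [-0.8, -0.5, 0.3],
            ]
        )
        X = X - X.mean(axis=0)
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        W, P, T, q = fit_pls(X, y, 2)
        yc = y - y.mean()
        expected = X.T @ yc
        expected /= np.linalg.norm(expected)
        assert np.allclose(W[:, 0], expected, atol=1e-12)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(40, 15))
        X -= X.mean(axis=0)
        y = (rng.random(40) > 0.5).astype(float)
        W, P, T, q = fit_pls(X, y, 5)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_scores_equal_x_times_rotation(self, rng):
        X = rng.normal(size=(30, 10))
        X -= X.mean(axis=0)
        y = (rng.random(30) > 0.5).astype(float)
        W, P, T, q = fit_pls(X, y, 4)
        R = W @ np.linalg.inv(P.T @ W)
        assert np.allclose(T, X @ R, atol=1e-8)

    def test_single_informative_column(self):
        y = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        X = np.zeros((6, 3))
        X[:, 1] = np.where(y == 1, 1.0, -1.0)
        X -= X.mean(axis=0)
        W, *_ = fit_pls(X, y, 1)
        assert abs(W[1, 0]) == pytest.approx(1.0)
        assert np.allclose(W[[0, 2], 0], 0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(np.zeros((5, 3)), np.array([1.0, 0, 1, 0, 1]), 1)


class TestFitPlslda:
    def test_separable_classes_perfect_training_accuracy(self, rng):
        X, y = _separable(rng)
        res = fit_plslda(X, y, 2)
        assert res.training_accuracy() == 1.0

    def test_label_flip_flips_all_cv1_weights(self, rng):
        X, y = _separable(rng, delta=1.5)
        a = PLSLDA(X, y, positive_class=1).fit(3)
        b = PLSLDA(X, 1 - y, positive_class=1).fit(3)
        assert np.allclose(a.cv1_weights, -b.cv1_weights, atol=1e-8)

    def test_null_variable_weight_below_planted(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 10))
            y = np.repeat([1, 0], 30)
            X[:30, 0] += 2.0  # planted; columns 1..9 null
            res = PLSLDA(X, y, positive_class=1).fit(2)
            w = np.abs(res.cv1_weights)
            if w[0] > w[1:].max():
                hits += 1
        assert hits >= 90

    def test_predict_on_new_data(self, rng):
        X, y = _separable(rng)
        res = PLSLDA(X, y, positive_class=1).fit(2)
        # training X was globally centered, so its classes sit at ±delta/2
        Xnew = rng.normal(size=(10, X.shape[1]))
        Xnew[:5, :3] += 2.0
        Xnew[5:, :3] -= 2.0
        pred = res.predict(Xnew)
        assert (pred[:5] == 1).all() and (pred[5:] == 0).all()

    def test_summary_mentions_key_facts(self, rng):
        X, y = _separable(rng)
        text = PLSLDA(X, y, positive_class=1).fit(2).summary()
        assert "training accuracy" in text and "components" in text

    def test_two_class_requirement(self, rng):
        with pytest.raises(ValueError):
            PLSLDA(rng.normal(size=(6, 3)), np.zeros(6))


class TestRdcv:
    def test_null_data_accuracy_near_chance(self):
        """Honest outer loop: pure-noise metrics center at 50% regardless of
        the component search space."""
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 40))
            y = np.repeat([1, 0], 30)
            cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=3,
                             max_components=8, seed=seed)
            accs.append(rdcv(X, y, cfg).metric_means["accuracy"])
        assert np.mean(accs) == pytest.approx(50.0, abs=5.0)

    def test_separable_data_all_metrics_100(self, rng):
        X, y = _separable(rng)
        cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=3, seed=0)
        res = rdcv(X, y, cfg)
        assert (res.metrics.to_numpy() == 100.0).all()

    def test_every_sample_predicted_once_per_repetition(self, rng):
        X, y = _separable(rng, delta=0.5)
        cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=4, seed=1)
        res = rdcv(X, y, cfg)
        assert res.predictions.shape == (4, 60)

    def test_seed_contract(self, rng):
        X, y = _separable(rng, delta=0.5)
        cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=3, seed=42)
        a, b = rdcv(X, y, cfg), rdcv(X, y, cfg)
        assert a.metrics.equals(b.metrics)
        assert np.array_equal(a.fold_weights, b.fold_weights)

    def test_metric_definitions(self, rng):
        """Sensitivity counts the positive class, specificity the negative;
        accuracy is their mean, CCR the raw fraction correct."""
        X, y = _separable(rng, n_per=20)
        # unbalanced by dropping some negatives
        keep = np.r_[np.arange(20), np.arange(20, 34)]
        cfg = RdCVConfig(n_outer_folds=4, n_inner_folds=3, n_repetitions=2, seed=3)
        res = rdcv(X[keep], y[keep], cfg)
        m = res.metrics.iloc[0]
        assert m["accuracy"] == pytest.approx((m["sensitivity"] + m["specificity"]) / 2)
        n1, n0 = 20, 14
        expected_ccr = (m["sensitivity"] / 100 * n1 + m["specificity"] / 100 * n0) / (n1 + n0)
        assert m["ccr"] == pytest.approx(100 * expected_ccr, abs=1e-9)

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.array([1] * 3 + [0] * 7)
        with pytest.raises(ValueError):
            rdcv(X, y, RdCVConfig(n_outer_folds=5, seed=0))

    def test_summary_reports_metrics(self, rng):
        X, y = _separable(rng)
        cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=2, seed=0)
        text = rdcv(X, y, cfg).summary()
        assert "accuracy" in text and "sample stability" in text


class TestPermutationTest:
    def test_planted_effect_significant(self, rng):
        X, y = _separable(rng, n_per=25, delta=2.0)
        cfg = RdCVConfig(n_outer_folds=4, n_inner_folds=3, n_repetitions=2,
                         n_permutations=49, permutation_repetitions=1, seed=5)
        pt = permutation_test(X, y, cfg)
        assert all(p <= 0.05 for p in pt.p_values.values())

    def test_p_values_in_unit_interval(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.repeat([1, 0], 15)
        cfg = RdCVConfig(n_outer_folds=3, n_inner_folds=2, n_repetitions=1,
                         n_permutations=19, permutation_repetitions=1, seed=2)
        pt = permutation_test(X, y, cfg)
        assert all(0 < p <= 1 for p in pt.p_values.values())
        assert pt.null_distribution.shape == (19, 4)


class TestSelectVariables:
    def test_planted_variables_recovered_with_sign(self, rng):
        X = rng.normal(size=(80, 30))
        y = np.repeat([1, 0], 40)
        X[:40, 0] += 2.0   # up in positive class
        X[40:, 1] += 2.0   # up in negative class
        cfg = RdCVConfig(n_outer_folds=2, n_inner_folds=3, n_repetitions=10, seed=0)
        res = rdcv(X, y, cfg)
        sel = select_variables(res)
        frame = sel.frame
        assert frame["significant"].iloc[0] and frame["mean_weight"].iloc[0] > 0
        assert frame["significant"].iloc[1] and frame["mean_weight"].iloc[1] < 0

    def test_sign_unstable_variable_never_significant(self, rng):
        from urinmr.plslda.rdcv import RdCVResults
        import pandas as pd

        reps, p = 10, 4
        W = rng.normal(size=(reps, p))
        W[:, 0] = [1, -1] * 5  # alternating signs
        W[:, 1] = 2.0          # perfectly stable
        res = RdCVResults(
            metrics=pd.DataFrame(np.full((reps, 4), 50.0),
                                 columns=["accuracy", "sensitivity", "specificity", "ccr"]),
            weights=W, fold_weights=W[:, None, :], predictions=np.zeros((reps, 6), dtype=np.uint8),
            components=np.ones((reps, 1), dtype=int), y01=np.repeat([1, 0], 3),
            config=RdCVConfig(seed=0),
        )
        sel = select_variables(res)
        assert not sel.frame["significant"].iloc[0]
        assert sel.frame["significant"].iloc[1]
        assert sel.frame["ci_lo"].iloc[1] == sel.frame["ci_hi"].iloc[1] == 2.0

    def test_significant_implies_sign_stable_and_ci_excludes_zero(self, rng):
        X = rng.normal(size=(40, 20))
        y = np.repeat([1, 0], 20)
        cfg = RdCVConfig(n_outer_folds=2, n_inner_folds=2, n_repetitions=8, seed=1)
        sel = select_variables(rdcv(X, y, cfg))
        sig = sel.frame[sel.frame["significant"]]
        assert (sig["sign_stable"]).all()
        assert ((sig["ci_lo"] > 0) | (sig["ci_hi"] < 0)).all()


class TestSampleStability:
    def test_separable_data_all_always_correct(self, rng):
        X, y = _separable(rng)
        cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=3, seed=0)
        stab = sample_stability(rdcv(X, y, cfg))
        assert (stab == "always-correct").all()

    def test_mislabeled_sample_always_wrong(self, rng):
        X, y = _separable(rng, n_per=25)
        y = y.copy()
        y[0] = 0  # strongly class-1 profile labelled 0
        cfg = RdCVConfig(n_outer_folds=5, n_inner_folds=4, n_repetitions=5, seed=0)
        stab = sample_stability(rdcv(X, y, cfg))
        assert stab.iloc[0] == "always-wrong"

    def test_categories_partition_cohort(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.repeat([1, 0], 15)
        cfg = RdCVConfig(n_outer_folds=3, n_inner_folds=2, n_repetitions=5, seed=0)
        stab = sample_stability(rdcv(X, y, cfg))
        assert set(stab.unique()) <= {"always-correct", "always-wrong", "unstable"}
        assert len(stab) == 30


class TestColumnScalingEquivariance:
    def test_autoscaled_results_invariant_to_column_scaling(self, rng):
        """Positive per-column rescaling upstream of auto-scaling leaves every
        rdCV output unchanged."""
        from urinmr.datatypes import BinnedMatrix
        from urinmr.preprocess import log_autoscale

        raw = np.abs(rng.normal(size=(30, 12))) + 0.5
        edges = np.column_stack([np.arange(12, 0, -1.0), np.arange(11, -1, -1.0)])
        y = np.repeat([1, 0], 15)
        cfg = RdCVConfig(n_outer_folds=3, n_inner_folds=2, n_repetitions=2, seed=9)
        scales = rng.uniform(0.5, 5.0, 12)
        out = []
        for values in (raw, raw * scales):
            m = BinnedMatrix(values, edges, [f"s{i}" for i in range(30)])
            # offset=0: a nonzero log offset is deliberately NOT scale
            # equivariant (log(c x + o) is not log x + const)
            X = log_autoscale(m, offset=0.0).values
            out.append(rdcv(X, y, cfg))
        assert out[0].metrics.equals(out[1].metrics)
        assert np.allclose(out[0].fold_weights, out[1].fold_weights, atol=1e-8)
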