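"""Hardness estimators: OLS + Cook's filter, ANFIS, snapping, benchmark."""

import numpy as np
import pandas as pd
import pytest

from pwvlab._nnet import TinyNet, coral_head
from pwvlab.anfis import (AnfisModel, anfis_forward, anfis_init, anfis_predict,
                          anfis_train)
from pwvlab.stiffness import (classification_metrics, cooks_filter,
                              fit_regression, predict_regression,
                              run_benchmark, snap_to_class)

# reference coefficients of the published hardness regression
EQ2 = {"intercept": 42.5, "ST": -24.8, "PP": 1.1, "SV": -1.8,
       "HR": -0.1, "W": -7.9}


def _design(n=80, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "ST": rng.uniform(0.2, 0.6, n), "PP": rng.uniform(5, 30, n),
        "SV": rng.choice([10.0, 20.0], n), "HR": rng.choice([30.0, 60.0, 80.0], n),
        "W": rng.choice([1.0, 1.5, 2.0], n)})


def _affine(X, coefs):
    return (coefs["intercept"] + coefs["ST"] * X["ST"] + coefs["PP"] * X["PP"]
            + coefs["SV"] * X["SV"] + coefs["HR"] * X["HR"]
            + coefs["W"] * X["W"]).to_numpy()


class TestCooksFilter:
    def test_clean_linear_data_unflagged(self):
        X = _design()
        y = _affine(X, EQ2)
        assert not cooks_filter(X, y).any()

    def test_gross_outlier_flagged(self):
        X = _design()
        y = _affine(X, EQ2) + np.random.default_rng(1).normal(0, 1, len(X))
        y[17] += 10 * np.std(y)
        mask = cooks_filter(X, y)
        assert mask[17]

    def test_agrees_with_leave_one_out_oracle(self):
        # brute-force Cook's D by refitting without each observation
        rng = np.random.default_rng(2)
        X = _design(25, seed=2)
        y = _affine(X, EQ2) + rng.normal(0, 2, 25)
        import statsmodels.api as sm
        Xc = sm.add_constant(X.to_numpy())
        full = sm.OLS(y, Xc).fit()
        p = Xc.shape[1]
        s2 = full.ssr / (len(y) - p)
        d_oracle = []
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            sub = sm.OLS(y[keep], Xc[keep]).fit()
            diff = full.predict(Xc) - sub.predict(Xc)
            d_oracle.append(float(diff @ diff) / (p * s2))
        d_pkg = sm.OLS(y, Xc).fit().get_influence().cooks_distance[0]
        assert np.allclose(d_pkg, d_oracle, rtol=1e-8)
        # and the package threshold reproduces the same flags
        assert np.array_equal(cooks_filter(X, y), np.array(d_oracle) > 4 / len(y))

    def test_too_few_observations(self):
        X = _design(6)
        with pytest.raises(ValueError):
            cooks_filter(X, np.zeros(6))


class TestFitRegression:
    def test_recovers_reference_coefficients_exactly(self):
        X = _design()
        model = fit_regression(X, _affine(X, EQ2))
        for k, v in EQ2.items():
            assert model.coefficients[k] == pytest.approx(v, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_constant_target(self):
        X = _design()
        model = fit_regression(X, np.full(len(X), 30.0))
        for k in ("ST", "PP", "SV", "HR", "W"):
            assert model.coefficients[k] == pytest.approx(0.0, abs=1e-8)
        assert model.coefficients["intercept"] == pytest.approx(30.0)
        assert model.r_squared == 0.0

    def test_standard_errors_match_bootstrap(self):
        rng = np.random.default_rng(3)
        X = _design(83, seed=3)
        y = _affine(X, EQ2) + rng.normal(0, 3, 83)
        model = fit_regression(X, y)
        boots = []
        Xa = X.to_numpy()
        for _ in range(400):
            idx = rng.integers(0, 83, 83)
            import statsmodels.api as sm
            b = sm.OLS(y[idx], sm.add_constant(Xa[idx])).fit().params
            boots.append(b)
        boot_se = np.std(boots, axis=0, ddof=1)
        analytic = [model.standard_errors[k] for k in
                    ("intercept", "ST", "PP", "SV", "HR", "W")]
        assert np.allclose(boot_se, analytic, rtol=0.35)

    def test_rank_deficiency_reported(self):
        X = _design()
        X["W"] = X["ST"] * 2.0  # collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_regression(X, _affine(X, EQ2))


class TestPredictRegression:
    def test_intercept_at_origin(self):
        assert predict_regression(EQ2, 0, 0, 0, 0, 0) == pytest.approx(42.5)

    def test_hand_evaluation(self):
        # 42.5 - 24.8 + 11 - 18 - 6 - 7.9 = -3.2
        assert predict_regression(EQ2, 1, 10, 10, 60, 1) == pytest.approx(-3.2)

    def test_zero_coefficients(self):
        zero = {k: 0.0 for k in EQ2}
        assert predict_regression(zero, 1, 2, 3, 4, 5) == 0.0


class TestAnfisStructure:
    def test_grid_partition_counts(self):
        X = np.random.default_rng(0).normal(size=(90, 6))
        m = anfis_init(X, mfs_per_input=2)
        assert m.n_rules == 64
        assert m.n_consequent_params == 448
        assert m.n_premise_params == 24

    def test_constant_column_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 6))
        X[:, 3] = 1.0
        with pytest.raises(ValueError, match="constant"):
            anfis_init(X)

    def test_json_roundtrip(self):
        X = np.random.default_rng(0).normal(size=(40, 6))
        m = anfis_init(X)
        m2 = AnfisModel.from_json(m.to_json())
        assert np.allclose(m.centers, m2.centers)
        assert np.array_equal(m.rules, m2.rules)


class TestAnfisForward:
    def _toy(self):
        # 2 inputs, 2 MFs each: hand-checkable four-rule model
        m = anfis_init(np.array([[-1.0, -1.0], [1.0, 1.0], [0.0, 0.0],
                                 [-1.0, 1.0]]), mfs_per_input=2)
        return m

    def test_single_rule_constant_consequent(self):
        m = self._toy()
        m.rules = m.rules[:1]
        m.consequents = np.array([[0.0, 0.0, 3.25]])
        for x in ([-5.0, 2.0], [0.0, 0.0], [9.0, -9.0]):
            z = (np.array(x) - m.x_mean) / m.x_scale
            assert anfis_forward(m, z) == pytest.approx(3.25)

    def test_two_symmetric_rules_average_at_midpoint(self):
        m = self._toy()
        m.rules = np.array([[0, 0], [1, 1]])
        m.consequents = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 8.0]])
        mid = m.centers.mean(axis=1)  # equidistant from both MFs per input
        assert anfis_forward(m, mid) == pytest.approx(5.0)

    def test_matches_layerwise_hand_computation(self):
        m = self._toy()
        rng = np.random.default_rng(5)
        m.centers = rng.normal(size=m.centers.shape)
        m.sigmas = np.abs(rng.normal(1, 0.2, size=m.sigmas.shape))
        m.consequents = rng.normal(size=m.consequents.shape)
        z = np.array([0.3, -0.7])
        # independent five-layer evaluation
        mu = np.exp(-(z[:, None] - m.centers) ** 2 / (2 * m.sigmas**2))
        w = np.array([mu[0, r0] * mu[1, r1] for r0, r1 in m.rules])
        wn = w / w.sum()
        f = np.array([c[0] * z[0] + c[1] * z[1] + c[2] for c in m.consequents])
        expected = float(np.sum(wn * f))
        assert anfis_forward(m, z) == pytest.approx(expected, abs=1e-12)

    def test_output_is_convex_combination_of_rule_outputs(self):
        m = self._toy()
        rng = np.random.default_rng(6)
        m.consequents = rng.normal(size=m.consequents.shape)
        for _ in range(20):
            z = rng.normal(scale=2.0, size=2)
            f = m.consequents[:, :2] @ z + m.consequents[:, 2]
            y = anfis_forward(m, z)
            assert f.min() - 1e-9 <= y <= f.max() + 1e-9


class TestAnfisTraining:
    def test_linear_target_solved_by_first_lse_step(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0, 0.0, 1.5]) + 0.7
        _, hist = anfis_train(anfis_init(X), X, y, epochs=1, holdout=0.0, seed=1)
        assert hist.train_rmse[0] < 1e-6

    def test_single_rule_reduces_to_ols(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(70, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.5, 70)
        m = anfis_init(X)
        m.rules = m.rules[:1]
        m.consequents = m.consequents[:1]
        m, _ = anfis_train(m, X, y, epochs=1, holdout=0.0, seed=1)
        import statsmodels.api as sm
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        pred = anfis_predict(m, X)
        assert np.allclose(pred, ols.predict(sm.add_constant(X)), atol=1e-8)

    def test_lse_step_never_increases_sse(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 6))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2 + rng.normal(0, 0.2, 80)
        _, hist = anfis_train(anfis_init(X), X, y, epochs=15, holdout=0.0, seed=2)
        for before, after in zip(hist.sse_before_lse, hist.sse_after_lse):
            assert after <= before + 1e-9

    def test_same_seed_identical_parameters(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 6))
        y = rng.normal(size=60)
        a, _ = anfis_train(anfis_init(X), X, y, epochs=5, seed=3)
        b, _ = anfis_train(anfis_init(X), X, y, epochs=5, seed=3)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.consequents, b.consequents)

    def test_misaligned_inputs_rejected(self):
        X = np.zeros((10, 6))
        with pytest.raises(ValueError):
            anfis_train(anfis_init(np.random.default_rng(0).normal(size=(10, 6))),
                        X, np.zeros(9))


class TestSnapToClass:
    def test_nearest(self):
        assert snap_to_class(23.4) == 20.0

    def test_midpoint_rounds_up(self):
        assert snap_to_class(25.0) == 30.0

    def test_clamps_to_endpoints(self):
        assert snap_to_class(57.0) == 50.0
        assert snap_to_class(-3.0) == 10.0

    def test_idempotent(self):
        vals = np.array([11.0, 24.9, 25.0, 49.0, 99.0])
        once = snap_to_class(vals)
        assert np.array_equal(snap_to_class(once), once)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            snap_to_class(10.0, grid=[])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.repeat([10.0, 20.0, 30.0], 5)
        f1, sens, spec, mae, rmse = classification_metrics(y, y, [10, 20, 30])
        assert (f1, sens, spec, mae, rmse) == (1.0, 1.0, 1.0, 0.0, 0.0)

    def test_constant_predictor_on_balanced_classes(self):
        # brute-force confusion counting gives sens 1/3, spec 2/3
        y = np.repeat([10.0, 20.0, 30.0], 6)
        pred = np.full(18, 10.0)
        _, sens, spec, _, _ = classification_metrics(y, pred, [10, 20, 30])
        assert sens == pytest.approx(1 / 3)
        assert spec == pytest.approx(2 / 3)

    def test_single_sample_errors(self):
        f1, _, _, mae, rmse = classification_metrics([10.0], [20.0], [10, 20])
        assert mae == 10.0 and rmse == 10.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classification_metrics([10.0], [15.0], [10, 20])


class TestCoralHead:
    def test_strongly_negative_scores_give_lowest_class(self):
        _, cls = coral_head(np.array([-50.0]), np.array([0.0, 0.0]))
        assert cls[0] == 1

    def test_strongly_positive_scores_give_highest_class(self):
        _, cls = coral_head(np.array([50.0]), np.array([0.0, 0.0]))
        assert cls[0] == 3

    def test_hand_set_biases_give_middle_class(self):
        probs, cls = coral_head(np.array([0.0]), np.array([2.0, -2.0]))
        assert cls[0] == 2
        assert probs[0, 0] == pytest.approx(1 / (1 + np.exp(-2)))
        assert np.all(np.diff(probs[0]) <= 0)  # monotone non-increasing


class TestBenchmark:
    @staticmethod
    def _separable_table(seed=0):
        rng = np.random.default_rng(seed)
        sha = np.repeat([10.0, 20.0, 30.0], 18)
        return pd.DataFrame({
            "sha": sha,
            "x1": sha + rng.normal(0, 0.1, len(sha)),
            "x2": rng.normal(size=len(sha)),
        })

    def test_separable_classes_solved_by_tree_ensembles(self):
        res = run_benchmark(self._separable_table(), "LOW_10_30", seed=1)
        by_name = {r.model_name: r for r in res}
        assert by_name["ML_RF"].f1_macro == 1.0
        assert by_name["ML_HistGB"].f1_macro == 1.0

    def test_mae_never_exceeds_rmse(self, noisy_features):
        res = run_benchmark(noisy_features, "FULL_10_50", seed=0)
        assert len(res) == 14
        for r in res:
            assert r.mae_sha <= r.rmse_sha + 1e-12

    def test_deterministic_for_fixed_seed(self):
        t = self._separable_table()
        a = run_benchmark(t, "LOW_10_30", seed=5)
        b = run_benchmark(t, "LOW_10_30", seed=5)
        for ra, rb in zip(a, b):
            assert (ra.f1_macro, ra.mae_sha) == (rb.f1_macro, rb.mae_sha)

    def test_undersized_class_rejected(self):
        t = self._separable_table().iloc[:40]  # class 30 has only 4 members
        with pytest.raises(ValueError, match="stratified"):
            run_benchmark(t, "LOW_10_30", seed=0)
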