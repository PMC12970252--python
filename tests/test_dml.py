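"""Summary-level DML: cross-fitting mechanics and causal recovery."""

import numpy as np
import pandas as pd
import pytest

from mrdml import (DMLConfig, SimulationConfig, SummaryDML,
                   build_feature_matrix, cross_fit_nuisance, dml_theta,
                   harmonize, ivw, run_dml, simulate_pair)

from conftest import make_hset


def _feature_sim(n_snp=500, theta=0.3, seed=1234, feature_effect=0.1):
    cfg = SimulationConfig(
        n_snp=n_snp, n_instruments=n_snp, theta=theta,
        pleiotropy_mode="feature", n_features=20, n_active_features=5,
        feature_effect=feature_effect, frac_palindromic=0.0,
        mhc_fraction=0.0, seed=seed)
    exposure, outcome, truth = simulate_pair(cfg)
    return harmonize(exposure, outcome), truth


class TestFeatureMatrix:
    def test_shape_and_alignment(self):
        h, truth = _feature_sim(n_snp=100)
        Z = build_feature_matrix(h, truth.features)
        assert Z.shape == (100, 20)

    def test_standardized_columns(self):
        h, truth = _feature_sim(n_snp=100)
        Z = build_feature_matrix(h, truth.features, standardize=True)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-8)

    def test_constant_column_dropped_with_warning(self, caplog):
        h, truth = _feature_sim(n_snp=50)
        feats = truth.features.copy()
        feats["flat"] = 1.0
        with caplog.at_level("WARNING"):
            Z = build_feature_matrix(h, feats)
        assert Z.shape[1] == 20
        assert "flat" in caplog.text

    def test_all_constant_fatal(self):
        h, _ = _feature_sim(n_snp=50)
        feats = pd.DataFrame({"a": np.ones(50), "b": np.zeros(50)})
        with pytest.raises(ValueError, match="constant"):
            build_feature_matrix(h, feats)

    def test_default_features_available(self):
        h, _ = _feature_sim(n_snp=50)
        Z = build_feature_matrix(h, None)
        assert Z.shape[0] == 50 and Z.shape[1] >= 3

    def test_driver_column_improves_recovery(self):
        # withholding the true pleiotropy drivers degrades theta recovery
        h, truth = _feature_sim(n_snp=500, feature_effect=0.2)
        active = np.flatnonzero(truth.feature_weights != 0.0)
        names = [f"z{k}" for k in active]
        with_drivers = run_dml(h, truth.features, DMLConfig(seed=1234))
        without = run_dml(
            h, truth.features.drop(columns=names), DMLConfig(seed=1234))
        assert (abs(with_drivers.theta - truth.theta_true)
                < abs(without.theta - truth.theta_true))


class TestCrossFit:
    def test_constant_target_predicted_exactly(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((60, 4))
        preds, folds, _ = cross_fit_nuisance(
            Z, np.full(60, 2.5), DMLConfig(seed=1))
        np.testing.assert_allclose(preds, 2.5, atol=1e-8)
        # balanced partition: fold sizes differ by at most one
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1

    def test_linear_signal_recovered_out_of_fold(self):
        rng = np.random.default_rng(1234)
        Z = rng.standard_normal((500, 20))
        w = np.zeros(20)
        w[:5] = [0.5, -0.4, 0.3, 0.2, -0.6]
        target = Z @ w + 0.05 * rng.standard_normal(500)
        preds, _, fold_r2 = cross_fit_nuisance(
            Z, target, DMLConfig(learner="l1_linear", seed=1234))
        ss_res = np.sum((target - preds) ** 2)
        ss_tot = np.sum((target - target.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9

    def test_leave_one_out_boundary(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((12, 3))
        target = Z[:, 0] + rng.standard_normal(12)
        preds, folds, _ = cross_fit_nuisance(
            Z, target, DMLConfig(k_folds=12, seed=2))
        assert np.all(np.isfinite(preds))
        assert len(np.unique(folds)) == 12

    def test_fewer_rows_than_folds_fatal(self):
        Z = np.ones((3, 2)) + np.arange(3)[:, None]
        with pytest.raises(ValueError, match="fewer rows"):
            cross_fit_nuisance(Z, np.arange(3.0), DMLConfig(k_folds=5))


class TestThetaStage:
    def test_exact_proportionality(self):
        bx = np.array([0.1, 0.2, 0.3])
        theta, _, _ = dml_theta(bx, 2 * bx, np.zeros(3), np.zeros(3))
        assert theta == pytest.approx(2.0)

    def test_matches_ols_through_origin_oracle(self):
        bx_t = np.array([1.0, 2.0, 3.0])
        by_t = np.array([1.1, 1.9, 3.2])
        theta, _, _ = dml_theta(bx_t, by_t, np.zeros(3), np.zeros(3))
        oracle = np.sum(bx_t * by_t) / np.sum(bx_t ** 2)
        assert theta == pytest.approx(oracle, abs=1e-10)

    def test_zero_nuisance_equals_unweighted_ivw(self):
        rng = np.random.default_rng(3)
        bx = rng.normal(0.2, 0.1, 20)
        by = rng.normal(0.06, 0.05, 20)
        theta, _, _ = dml_theta(bx, by, np.zeros(20), np.zeros(20))
        assert theta == pytest.approx(np.sum(bx * by) / np.sum(bx ** 2))

    def test_zero_residual_variance_fatal(self):
        bx = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            dml_theta(bx, bx, bx, np.zeros(2))


class TestRunDML:
    def test_recovers_theta_under_sparse_feature_pleiotropy(self):
        h, truth = _feature_sim()
        est = run_dml(h, truth.features, DMLConfig(seed=1234))
        assert 0.2 <= est.theta <= 0.4

    def test_null_effect_recovery(self):
        # single-replicate z-scores are slightly overdispersed (the
        # influence-function SE ignores leftover nuisance structure), so
        # judge the null property over replicates: most estimates sit
        # within 3 SE and the replicate mean is consistent with zero
        thetas, inside = [], 0
        for rep in range(10):
            h, truth = _feature_sim(theta=0.0, n_snp=300, seed=1234 + rep)
            est = run_dml(h, truth.features, DMLConfig(seed=1234))
            thetas.append(est.theta)
            inside += abs(est.theta) < 3 * est.se
        assert inside >= 8
        sem = np.std(thetas, ddof=1) / np.sqrt(len(thetas))
        assert abs(np.mean(thetas)) < 3 * sem

    def test_deterministic_for_lasso(self):
        h, truth = _feature_sim(n_snp=200)
        a = run_dml(h, truth.features, DMLConfig(seed=1234))
        b = run_dml(h, truth.features, DMLConfig(seed=1234))
        assert a.theta == b.theta
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_learners_agree_within_pooled_se(self):
        h, truth = _feature_sim()
        lasso = run_dml(h, truth.features, DMLConfig(seed=1234))
        forest = run_dml(h, truth.features,
                         DMLConfig(learner="tree_ensemble", seed=1234))
        pooled = np.hypot(lasso.se, forest.se)
        assert np.sign(lasso.theta) == np.sign(forest.theta)
        assert abs(lasso.theta - forest.theta) < 2 * pooled

    def test_too_few_snps_fatal(self):
        h, truth = _feature_sim(n_snp=30)
        with pytest.raises(ValueError):
            run_dml(h.subset(np.arange(8)), None, DMLConfig(k_folds=5))


def test_orthogonality_damps_nuisance_perturbation():
    """First-order insensitivity: a 1% perturbation of m_hat moves the
    orthogonal estimate far less than a non-orthogonal plug-in."""
    h, truth = _feature_sim(n_snp=400)
    Z = build_feature_matrix(h, truth.features)
    config = DMLConfig(seed=1234)
    m_hat, folds, _ = cross_fit_nuisance(Z, h.beta_x, config)
    r_hat, _, _ = cross_fit_nuisance(Z, h.beta_y, config,
                                     fold_assignment=folds)
    theta0, _, _ = dml_theta(h.beta_x, h.beta_y, m_hat, r_hat)

    def plug_in(m):
        # non-orthogonal: uses the nuisance fit itself as the instrument
        return float(np.sum(m * h.beta_y) / np.sum(m * h.beta_x))

    rng = np.random.default_rng(99)
    delta = rng.standard_normal(h.n_snp)
    delta *= 0.01 * np.linalg.norm(m_hat) / np.linalg.norm(delta)
    theta1, _, _ = dml_theta(h.beta_x, h.beta_y, m_hat + delta, r_hat)
    change_orth = abs(theta1 - theta0)
    change_naive = abs(plug_in(m_hat + delta) - plug_in(m_hat))
    assert change_orth < 10 * change_naive
    assert change_orth / abs(theta0) < 0.01


def test_summary_dml_results_surface():
    h, truth = _feature_sim(n_snp=120)
    results = SummaryDML(h, truth.features).fit()
    table = results.summary()
    assert {"theta", "se", "pval", "learner"} <= set(table.columns)
    lo, hi = results.conf_int()
    assert lo < results.theta < hi
    scatter = results.scatter_data()
    assert len(scatter) == 120
    np.testing.assert_allclose(scatter["fitted"],
                               results.theta * scatter["beta_x"])
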