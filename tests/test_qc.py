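"""Heterogeneity, pleiotropy and influence diagnostics."""

import numpy as np
import pytest
from scipy import stats

from mrdml import (SimulationConfig, cochran_q, egger_intercept_test, ivw,
                   leave_one_out, mhc_sensitivity_rerun, presso_global,
                   remove_radial_outliers, run_qc, simulate_pair, harmonize)

from conftest import make_hset, simulate_instrument_set


class TestCochranQ:
    def test_homogeneous_ratios_give_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, 0.4 * bx, se_y=0.01)
        q, q_df, p, per_snp = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_two_snp_hand_computation(self, two_snp_set):
        # weights 400 and 100 around theta 0.6: Q = 400*0.01 + 100*0.16
        q, q_df, p, per_snp = cochran_q(two_snp_set)
        assert q == pytest.approx(20.0)
        assert q_df == 1
        assert p == pytest.approx(7.744e-6, rel=1e-3)
        np.testing.assert_allclose(per_snp, [4.0, 16.0])

    def test_additivity(self, sim_instruments):
        h, _ = simulate_instrument_set(SimulationConfig(theta=0.2, seed=21))
        q, _, _, per_snp = cochran_q(h)
        assert q == pytest.approx(per_snp.sum(), abs=1e-8)

    def test_null_q_over_df_near_one(self, sim_instruments):
        ratios = []
        for rep in range(200):
            h, _ = simulate_instrument_set(SimulationConfig(
                n_snp=100, n_instruments=100, theta=0.0,
                seed=80_000 + rep))
            q, q_df, _, _ = cochran_q(h)
            ratios.append(q / q_df)
        assert 0.85 <= np.mean(ratios) <= 1.15

    def test_single_snp_fatal(self):
        with pytest.raises(ValueError):
            cochran_q(make_hset([0.1], [0.05], se_y=0.01))


class TestRadialOutliers:
    def test_homogeneous_set_untouched(self):
        bx = np.linspace(0.1, 0.4, 8)
        h = make_hset(bx, 0.3 * bx, se_y=0.05)
        pruned, removed = remove_radial_outliers(h)
        assert removed == []
        assert pruned.n_snp == 8

    def test_planted_outlier_removed(self, sim_instruments):
        h, _ = simulate_instrument_set(
            SimulationConfig(n_snp=50, n_instruments=50, theta=0.3,
                             seed=22))
        h.beta_y[7] = h.beta_x[7] * 0.3 + 10 * h.se_y[7] * 5  # far-off ratio
        pruned, removed = remove_radial_outliers(h)
        assert h.snp_ids[7] in removed

    def test_alpha_zero_removes_nothing(self, sim_instruments):
        h, _ = simulate_instrument_set(SimulationConfig(theta=0.3, seed=23))
        pruned, removed = remove_radial_outliers(h, alpha=0.0)
        assert removed == []

    def test_idempotent(self, sim_instruments):
        h, _ = simulate_instrument_set(SimulationConfig(
            n_snp=100, n_instruments=100, theta=0.3,
            pleiotropy_mode="balanced", sigma_alpha=0.01, seed=24))
        pruned, _ = remove_radial_outliers(h)
        again, removed2 = remove_radial_outliers(pruned)
        assert removed2 == []

    def test_degenerate_stops_with_warning(self, caplog):
        # three wildly heterogeneous SNPs: pruning would drop below 3
        h = make_hset([0.1, 0.1, 0.1], [0.5, -0.5, 0.0], se_y=0.001)
        with caplog.at_level("WARNING"):
            pruned, removed = remove_radial_outliers(h)
        assert pruned.n_snp >= 3


class TestPresso:
    def test_null_data_not_flagged_at_fixed_seed(self):
        exposure, outcome, _ = simulate_pair(SimulationConfig(
            n_snp=100, n_instruments=100, theta=0.3,
            frac_palindromic=0.0, seed=1234))
        h = harmonize(exposure, outcome)
        _, p = presso_global(h, n_sim=1000, seed=1234)
        assert p > 0.05

    def test_planted_pleiotropy_flagged(self):
        exposure, outcome, _ = simulate_pair(SimulationConfig(
            n_snp=100, n_instruments=100, theta=0.3,
            pleiotropy_mode="directional", mu_alpha=0.1,
            frac_pleiotropic=0.2, frac_palindromic=0.0, seed=1234))
        h = harmonize(exposure, outcome)
        _, p = presso_global(h, n_sim=1000, seed=1234)
        assert p < 0.05

    def test_nsim_zero_fatal(self, two_snp_set):
        h = make_hset([0.1, 0.2, 0.3, 0.4], [0.05, 0.1, 0.15, 0.2],
                      se_y=0.01)
        with pytest.raises(ValueError):
            presso_global(h, n_sim=0)

    def test_too_few_snps_fatal(self, two_snp_set):
        with pytest.raises(ValueError):
            presso_global(two_snp_set)


class TestEggerIntercept:
    def test_balanced_pleiotropy_not_directional(self, sim_instruments):
        h, _ = simulate_instrument_set(SimulationConfig(
            n_snp=200, n_instruments=200, theta=0.3,
            pleiotropy_mode="balanced", sigma_alpha=0.05,
            frac_palindromic=0.0, seed=1234))
        intercept, se, _ = egger_intercept_test(h)
        assert abs(intercept) < 2 * se

    def test_directional_pleiotropy_detected(self, sim_instruments):
        h, _ = simulate_instrument_set(SimulationConfig(
            n_snp=200, n_instruments=200, theta=0.3,
            pleiotropy_mode="directional", mu_alpha=0.05,
            frac_palindromic=0.0, seed=1234))
        _, _, p = egger_intercept_test(h)
        assert p < 0.05

    def test_exact_linear_data_zero_intercept(self):
        bx = np.linspace(0.1, 0.3, 5)
        h = make_hset(bx, 0.3 * bx, se_y=0.01)
        intercept, _, _ = egger_intercept_test(h)
        assert intercept == pytest.approx(0.0, abs=1e-12)


class TestLeaveOneOut:
    def test_cardinality(self, sim_instruments):
        h, _ = simulate_instrument_set(
            SimulationConfig(n_snp=30, n_instruments=30, theta=0.3, seed=26))
        loo = leave_one_out(h)
        assert len(loo) == h.n_snp
        assert list(loo["snp_id"]) == list(h.snp_ids)

    def test_two_snp_set_fatal(self, two_snp_set):
        with pytest.raises(ValueError):
            leave_one_out(two_snp_set)

    def test_planted_outlier_has_largest_influence(self, sim_instruments):
        h, _ = simulate_instrument_set(
            SimulationConfig(n_snp=40, n_instruments=40, theta=0.3, seed=27))
        h.beta_y[5] = h.beta_x[5] * 2.0  # ratio far from theta
        full = ivw(h).beta
        loo = leave_one_out(h)
        shifts = np.abs(loo["beta"].to_numpy() - full)
        assert np.argmax(shifts) == 5


class TestMHCSensitivity:
    def _dominant_mhc_set(self):
        # the chr6 SNP carries almost all the weight; without it the
        # estimate loses significance
        return make_hset(
            beta_x=[0.3, 0.1, 0.1], beta_y=[0.09, 0.0, 0.0],
            se_y=[0.01, 0.5, 0.5],
            chrom=[6, 1, 2],
            pos=[29_626_949, 1_000_000, 1_000_000],
        )

    def test_no_mhc_snps_returns_none(self):
        h = make_hset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], se_y=0.01)
        assert mhc_sensitivity_rerun(h) is None

    def test_dominant_mhc_snp_flips_significance(self):
        report = mhc_sensitivity_rerun(self._dominant_mhc_set(),
                                       sig_threshold=0.0167)
        assert report is not None
        assert report["before"]["pval"] < 0.0167 < report["after"]["pval"]
        assert report["significance_flipped"]

    def test_negligible_mhc_snp_changes_little(self):
        h = make_hset(
            beta_x=[0.1, 0.3, 0.25], beta_y=[0.03, 0.09, 0.075],
            se_y=[0.5, 0.01, 0.01],
            chrom=[6, 1, 2], pos=[29_626_949, 1_000_000, 1_000_000])
        report = mhc_sensitivity_rerun(h)
        assert not report["significance_flipped"]
        after_se = ivw(h.subset(np.array([1, 2]))).se
        assert abs(report["before"]["beta"]
                   - report["after"]["beta"]) < after_se


def test_presso_null_pvalues_uniform():
    pvals = []
    for rep in range(100):
        exposure, outcome, _ = simulate_pair(SimulationConfig(
            n_snp=100, n_instruments=100, theta=0.3,
            frac_palindromic=0.0, seed=90_000 + rep))
        h = harmonize(exposure, outcome)
        pvals.append(presso_global(h, n_sim=500, seed=90_000 + rep)[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_run_qc_report_assembles(sim_instruments):
    h, _ = simulate_instrument_set(
        SimulationConfig(n_snp=40, n_instruments=40, theta=0.3,
                         mhc_fraction=0.1, seed=28))
    report = run_qc(h, presso_nsim=200, seed=1)
    assert report.q_df == h.n_snp - 1
    assert report.q_stat == pytest.approx(report.per_snp_q.sum(), abs=1e-8)
    assert len(report.loo_estimates) == h.n_snp
    payload = report.to_dict()
    assert payload["presso_nsim"] == 200
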