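"""Heterogeneity, pleiotropy and influence diagnostics.

Covers Cochran's Q on the IVW fit with radial-style iterative outlier
removal, a PRESSO-style simulation-based global pleiotropy test, the Egger
intercept test, leave-one-out influence estimates, and the MHC
remove-and-rerun sensitivity comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import cochran_q_components, ivw, mr_egger, wald_ratio
from .gwasio import HarmonizedInstrumentSet
from .instruments import MHC_REGION_GRCH37

logger = logging.getLogger(__name__)


def cochran_q(hset: HarmonizedInstrumentSet):
    """Cochran's Q on the fixed-effect IVW fit.

    Returns (q_stat, q_df, q_pval, per_snp_q); Q is the sum of the per-SNP
    contributions w_j (r_j - theta_ivw)^2 on n_snp - 1 degrees of freedom.
    """
    if hset.n_snp < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    per_snp_q, _ = cochran_q_components(hset)
    q = float(np.sum(per_snp_q))
    q_df = hset.n_snp - 1
    return q, q_df, float(stats.chi2.sf(q, q_df)), per_snp_q


def remove_radial_outliers(hset: HarmonizedInstrumentSet,
                           alpha: float = 0.05):
    """Iteratively drop SNPs whose Q contribution is significant.

    Each round refits IVW, converts per-SNP Q contributions to chi-square
    (1 df) p-values and removes every SNP with p < alpha, until no SNP is
    removed or fewer than 3 SNPs would remain (then stops with a warning).
    Returns (pruned set, removed id list).
    """
    if hset.n_snp < 3:
        raise ValueError("radial outlier removal requires at least 3 SNPs")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    current = hset
    removed: list[str] = []
    while True:
        per_snp_q, _ = cochran_q_components(current)
        pvals = stats.chi2.sf(per_snp_q, 1)
        out = pvals < alpha
        if not out.any():
            break
        if current.n_snp - int(out.sum()) < 3:
            logger.warning(
                "radial pruning would leave fewer than 3 SNPs; stopping "
                "with %d SNPs retained", current.n_snp)
            break
        removed.extend(current.snp_ids[out].tolist())
        current = current.subset(~out)
    return current, removed


def presso_global(hset: HarmonizedInstrumentSet, n_sim: int = 1000,
                  seed: int = 1234):
    """PRESSO-style global pleiotropy test.

    The observed statistic is the weighted leave-one-out residual sum of
    squares RSS = sum_j w_j (beta_y_j - theta_{-j} beta_x_j)^2 with
    w_j = 1/se_y_j^2 and theta_{-j} the IVW estimate excluding SNP j. Its
    null distribution comes from ``n_sim`` parametric replicates that
    resample both sides, beta_x* ~ N(beta_x, se_x) and
    beta_y* ~ N(theta_hat beta_x, se_y), and recompute the leave-one-out
    RSS on each replicate; resampling the exposure side as well is what
    keeps the test calibrated in the two-sample setting, where exposure
    estimation noise propagates into the observed residuals. The global
    p-value is the fraction of simulated RSS >= observed.
    """
    if hset.n_snp < 4:
        raise ValueError("PRESSO global test requires at least 4 SNPs")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    bx, by, sx, sy = hset.beta_x, hset.beta_y, hset.se_x, hset.se_y
    w = 1.0 / sy ** 2

    def loo_rss(bx_mat: np.ndarray, by_mat: np.ndarray) -> np.ndarray:
        # rows are replicates; vectorized leave-one-out IVW per SNP j
        a_mat = bx_mat * by_mat * w
        b_mat = bx_mat * bx_mat * w
        theta_loo = ((a_mat.sum(axis=1, keepdims=True) - a_mat)
                     / (b_mat.sum(axis=1, keepdims=True) - b_mat))
        resid = by_mat - theta_loo * bx_mat
        return (w * resid ** 2).sum(axis=1)

    theta_full = float(np.sum(bx * by * w) / np.sum(bx * bx * w))
    rss_obs = float(loo_rss(bx[None, :], by[None, :])[0])
    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, hset.n_snp))
    by_sim = rng.normal(theta_full * bx, sy, size=(n_sim, hset.n_snp))
    rss_sim = loo_rss(bx_sim, by_sim)
    pval = float(np.mean(rss_sim >= rss_obs))
    return rss_obs, pval


def egger_intercept_test(hset: HarmonizedInstrumentSet):
    """Directional-pleiotropy test: (intercept, se, two-sided p)."""
    _, intercept = mr_egger(hset)
    return intercept.beta, intercept.se, intercept.pval


def leave_one_out(hset: HarmonizedInstrumentSet) -> pd.DataFrame:
    """IVW estimates each excluding one SNP; row j omits SNP j."""
    if hset.n_snp < 3:
        raise ValueError("leave-one-out requires at least 3 SNPs "
                         "(each subfit needs >= 2)")
    rows = []
    for j in range(hset.n_snp):
        mask = np.ones(hset.n_snp, dtype=bool)
        mask[j] = False
        est = ivw(hset.subset(mask))
        rows.append({"snp_id": hset.snp_ids[j], "beta": est.beta,
                     "se": est.se, "pval": est.pval})
    return pd.DataFrame(rows)


def mhc_sensitivity_rerun(hset: HarmonizedInstrumentSet,
                          mhc_region: tuple[int, int, int] = MHC_REGION_GRCH37,
                          sig_threshold: float = 0.05) -> dict | None:
    """Remove flagged MHC SNPs, refit, and compare.

    Returns None (with a warning) when no SNP is flagged or removal would
    leave fewer than 2 SNPs; otherwise a dict with before/after (beta,
    pval), the removed ids and a flag saying whether significance at
    ``sig_threshold`` flipped.
    """
    chrom, start, stop = mhc_region
    in_mhc = ((np.asarray(hset.chrom).astype(str) == str(chrom))
              & (hset.pos >= start) & (hset.pos <= stop))
    if not in_mhc.any():
        logger.warning("no MHC-flagged SNPs; sensitivity rerun skipped")
        return None
    if hset.n_snp - int(in_mhc.sum()) < 2:
        logger.warning("MHC removal would leave fewer than 2 SNPs; "
                       "sensitivity rerun skipped")
        return None

    def _fit(s):
        return ivw(s) if s.n_snp >= 2 else wald_ratio(s)

    before = _fit(hset)
    after = _fit(hset.subset(~in_mhc))
    flip = ((before.pval < sig_threshold) != (after.pval < sig_threshold))
    return {"removed": hset.snp_ids[in_mhc].tolist(),
            "before": {"beta": before.beta, "pval": before.pval},
            "after": {"beta": after.beta, "pval": after.pval},
            "sig_threshold": sig_threshold,
            "significance_flipped": bool(flip)}


@dataclass
class QCReport:
    """Collected instrument diagnostics for one exposure/outcome pair."""

    q_stat: float
    q_df: int
    q_pval: float
    per_snp_q: np.ndarray
    outliers_removed: list[str]
    presso_rss: float | None
    presso_global_pval: float | None
    presso_nsim: int
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    loo_estimates: pd.DataFrame | None
    mhc_before_after: dict | None

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat, "q_df": self.q_df, "q_pval": self.q_pval,
            "per_snp_q": np.asarray(self.per_snp_q).tolist(),
            "outliers_removed": self.outliers_removed,
            "presso_rss": self.presso_rss,
            "presso_global_pval": self.presso_global_pval,
            "presso_nsim": self.presso_nsim,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "loo_estimates": (None if self.loo_estimates is None
                              else self.loo_estimates.to_dict("records")),
            "mhc_before_after": self.mhc_before_after,
        }


def run_qc(hset: HarmonizedInstrumentSet, qc_alpha: float = 0.05,
           presso_nsim: int = 1000, seed: int = 1234,
           mhc_region: tuple[int, int, int] = MHC_REGION_GRCH37,
           sig_threshold: float = 0.05,
           outliers_removed: list[str] | None = None) -> QCReport:
    """Assemble the full diagnostic battery on an (already pruned) set."""
    q, q_df, q_pval, per_snp_q = cochran_q(hset)
    presso_rss = presso_p = None
    if hset.n_snp >= 4 and presso_nsim > 0:
        presso_rss, presso_p = presso_global(hset, presso_nsim, seed)
    intercept = intercept_se = intercept_p = None
    loo = None
    if hset.n_snp >= 3:
        intercept, intercept_se, intercept_p = egger_intercept_test(hset)
        loo = leave_one_out(hset)
    mhc = mhc_sensitivity_rerun(hset, mhc_region, sig_threshold) \
        if hset.n_snp >= 2 else None
    return QCReport(
        q_stat=q, q_df=q_df, q_pval=q_pval, per_snp_q=per_snp_q,
        outliers_removed=outliers_removed or [],
        presso_rss=presso_rss, presso_global_pval=presso_p,
        presso_nsim=presso_nsim,
        egger_intercept=intercept, egger_intercept_se=intercept_se,
        egger_intercept_pval=intercept_p,
        loo_estimates=loo, mhc_before_after=mhc,
    )
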