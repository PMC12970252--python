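"""Summary-level double machine learning for the SNP-level partially
linear model

    beta_Y,j = theta * beta_X,j + h(Z_j) + eps_j,

where rows are harmonized SNP instruments, Z_j is a vector of observable
SNP-level features and h an arbitrary nuisance function standing in for
horizontal pleiotropy shared across instruments. The causal parameter
theta is estimated by Neyman-orthogonal residual-on-residual regression
with K-fold cross-fitting (K = 5 by default):

1. partition the SNPs into K folds;
2. on the complement of each fold train two learners,
   m(Z) ~ E[beta_X | Z] and r(Z) ~ E[beta_Y | Z], and predict the held-out
   fold, so every prediction is out-of-sample;
3. form residuals bx_tilde = beta_X - m_hat, by_tilde = beta_Y - r_hat and
   pool theta = sum(bx_tilde * by_tilde) / sum(bx_tilde^2) across folds;
4. the SE comes from the influence-function variance
   mean(psi^2) / (n * J^2), psi = bx_tilde (by_tilde - theta bx_tilde),
   J = mean(bx_tilde^2), with a two-sided normal p-value.

Orthogonality makes theta first-order insensitive to nuisance-model error,
so Lasso and tree-ensemble learners can be swapped without moving the
estimate beyond its sampling noise.

What to put in Z for summary data is genuinely open: the default feature
set (allele frequency, per-chromosome indicators, distance to the MHC
block, |beta_x| rank) encodes the axes along which pleiotropy plausibly
clusters, and callers should supply richer annotations when they have
them. The synthetic generator's "feature" pleiotropy mode produces data in
which Z contains the true drivers of h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .gwasio import HarmonizedInstrumentSet
from .instruments import MHC_REGION_GRCH37

logger = logging.getLogger(__name__)

LEARNERS = ("l1_linear", "tree_ensemble", "gradient_boosting")


@dataclass
class DMLConfig:
    k_folds: int = 5
    learner: str = "l1_linear"
    standardize: bool = True
    seed: int = 1234
    feature_spec: list[str] | None = None

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")


@dataclass
class DMLEstimate:
    theta: float
    se: float
    pval: float
    fold_assignment: np.ndarray
    nuisance_fit_r2: list[tuple[float, float]]
    learner: str
    n_snp: int

    def to_dict(self) -> dict:
        return {"theta": self.theta, "se": self.se, "pval": self.pval,
                "learner": self.learner, "n_snp": self.n_snp,
                "fold_assignment": self.fold_assignment.tolist(),
                "nuisance_fit_r2": [list(p) for p in self.nuisance_fit_r2]}


def default_features(hset: HarmonizedInstrumentSet) -> pd.DataFrame:
    """SNP-level feature columns derivable from any harmonized set."""
    chrom = np.asarray(hset.chrom).astype(str)
    mhc_chrom, mhc_start, mhc_stop = MHC_REGION_GRCH37
    centre = 0.5 * (mhc_start + mhc_stop)
    dist = np.where(chrom == str(mhc_chrom),
                    np.abs(hset.pos - centre) / 1e6, 300.0)
    features = {"eaf": np.where(np.isfinite(hset.eaf), hset.eaf, 0.5),
                "mhc_distance_mb": dist,
                "abs_bx_rank": stats.rankdata(np.abs(hset.beta_x))}
    for c in sorted(set(chrom)):
        features[f"chr_{c}"] = (chrom == c).astype(float)
    return pd.DataFrame(features, index=pd.RangeIndex(hset.n_snp))


def build_feature_matrix(hset: HarmonizedInstrumentSet,
                         features: pd.DataFrame | None = None,
                         standardize: bool = True,
                         feature_spec: list[str] | None = None) -> np.ndarray:
    """Assemble the numeric Z matrix, one row per SNP.

    ``features`` may carry a ``SNP`` column (aligned by id) or simply be
    row-aligned. Columns are restricted to ``feature_spec`` when given,
    z-score standardized when configured, and constant columns are dropped
    with a warning (an all-constant matrix is an error).
    """
    if features is None:
        features = default_features(hset)
    else:
        features = features.copy()
        if "SNP" in features.columns:
            features = (features.set_index("SNP")
                        .loc[hset.snp_ids].reset_index(drop=True))
    if len(features) != hset.n_snp:
        raise ValueError("feature rows must align with the harmonized set")
    if feature_spec:
        missing = set(feature_spec) - set(features.columns)
        if missing:
            raise ValueError(f"feature_spec names not present: {sorted(missing)}")
        features = features[list(feature_spec)]
    Z = features.to_numpy(dtype=float)
    sd = Z.std(axis=0)
    constant = sd == 0.0
    if constant.all():
        raise ValueError("all feature columns are constant")
    if constant.any():
        dropped = [c for c, flag in zip(features.columns, constant) if flag]
        logger.warning("dropping constant feature column(s): %s", dropped)
        Z = Z[:, ~constant]
        sd = sd[~constant]
    if standardize:
        Z = (Z - Z.mean(axis=0)) / sd
    return Z


def _make_learner(name: str, seed: int):
    if name == "l1_linear":
        return LassoCV(cv=5, random_state=seed, max_iter=5000)
    if name == "tree_ensemble":
        # leaf-size regularization keeps out-of-fold prediction noise from
        # attenuating the residual regression on small SNP panels
        return RandomForestRegressor(n_estimators=500, min_samples_leaf=5,
                                     random_state=seed, n_jobs=1)
    if name == "gradient_boosting":
        return GradientBoostingRegressor(n_estimators=500, learning_rate=0.05,
                                         max_depth=2, random_state=seed)
    raise ValueError(f"unknown learner {name!r}")


def cross_fit_nuisance(Z: np.ndarray, targets: np.ndarray,
                       config: DMLConfig,
                       fold_assignment: np.ndarray | None = None):
    """Out-of-fold predictions of ``targets`` from ``Z``.

    Returns (predictions, fold_assignment, per-fold out-of-sample R^2).
    With ``k_folds`` equal to the number of rows this degenerates to
    leave-one-out (per-fold R^2 is then undefined and reported as NaN).
    """
    config.validate()
    Z = np.asarray(Z, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = Z.shape[0]
    if targets.shape[0] != n:
        raise ValueError("Z and targets must have the same number of rows")
    if n < config.k_folds:
        raise ValueError("fewer rows than folds")
    if fold_assignment is None:
        splitter = KFold(n_splits=config.k_folds, shuffle=True,
                         random_state=config.seed)
        fold_assignment = np.empty(n, dtype=int)
        for k, (_, test_idx) in enumerate(splitter.split(Z)):
            fold_assignment[test_idx] = k
    predictions = np.empty(n)
    fold_r2: list[float] = []
    for k in range(config.k_folds):
        test = fold_assignment == k
        train = ~test
        model = _make_learner(config.learner, config.seed)
        model.fit(Z[train], targets[train])
        predictions[test] = model.predict(Z[test])
        ss_res = float(np.sum((targets[test] - predictions[test]) ** 2))
        ss_tot = float(np.sum((targets[test] - targets[test].mean()) ** 2))
        fold_r2.append(1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"))
    return predictions, fold_assignment, fold_r2


def dml_theta(beta_x, beta_y, m_hat, r_hat):
    """Residual-on-residual estimate of theta with influence-function SE."""
    bx = np.asarray(beta_x, dtype=float) - np.asarray(m_hat, dtype=float)
    by = np.asarray(beta_y, dtype=float) - np.asarray(r_hat, dtype=float)
    denom = float(np.sum(bx ** 2))
    if denom <= 0.0:
        raise ValueError("zero residual variance in beta_x residuals")
    theta = float(np.sum(bx * by) / denom)
    n = bx.size
    J = float(np.mean(bx ** 2))
    psi = bx * (by - theta * bx)
    var = float(np.mean(psi ** 2)) / (n * J ** 2)
    se = float(np.sqrt(var))
    pval = 2.0 * stats.norm.sf(abs(theta / se)) if se > 0 else 0.0
    return theta, se, pval


def run_dml(hset: HarmonizedInstrumentSet,
            features: pd.DataFrame | None = None,
            config: DMLConfig | None = None) -> DMLEstimate:
    """Full cross-fitted pipeline; deterministic given the config seed."""
    config = config or DMLConfig()
    config.validate()
    if hset.n_snp < 2 * config.k_folds:
        raise ValueError("need at least 2 * k_folds SNPs for cross-fitting")
    Z = build_feature_matrix(hset, features, config.standardize,
                             config.feature_spec)
    m_hat, folds, r2_m = cross_fit_nuisance(Z, hset.beta_x, config)
    r_hat, _, r2_r = cross_fit_nuisance(Z, hset.beta_y, config,
                                        fold_assignment=folds)
    theta, se, pval = dml_theta(hset.beta_x, hset.beta_y, m_hat, r_hat)
    return DMLEstimate(theta=theta, se=se, pval=pval,
                       fold_assignment=folds,
                       nuisance_fit_r2=list(zip(r2_m, r2_r)),
                       learner=config.learner, n_snp=hset.n_snp)


class DMLResults:
    """Fitted summary-DML estimate with scatter data for plotting."""

    def __init__(self, estimate: DMLEstimate, hset: HarmonizedInstrumentSet):
        self.estimate = estimate
        self.hset = hset
        self.theta = estimate.theta
        self.se = estimate.se
        self.pval = estimate.pval

    def conf_int(self) -> tuple[float, float]:
        z = float(stats.norm.ppf(0.975))
        return (self.theta - z * self.se, self.theta + z * self.se)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.conf_int()
        return pd.DataFrame([{
            "learner": self.estimate.learner, "n_snp": self.estimate.n_snp,
            "theta": self.theta, "se": self.se, "ci_low": lo, "ci_high": hi,
            "pval": self.pval,
            "mean_nuisance_r2_x": float(np.nanmean(
                [a for a, _ in self.estimate.nuisance_fit_r2])),
            "mean_nuisance_r2_y": float(np.nanmean(
                [b for _, b in self.estimate.nuisance_fit_r2])),
        }])

    def scatter_data(self) -> pd.DataFrame:
        """Per-SNP (beta_x, beta_y) with the fitted through-origin slope,
        the layout of the standard DML-vs-MR validation scatter plot."""
        return pd.DataFrame({
            "SNP": self.hset.snp_ids,
            "beta_x": self.hset.beta_x, "beta_y": self.hset.beta_y,
            "fitted": self.theta * self.hset.beta_x,
        })

    def __repr__(self):
        lo, hi = self.conf_int()
        return (f"<DMLResults theta={self.theta:.4g} "
                f"(95% CI {lo:.4g}, {hi:.4g}), p={self.pval:.3g}, "
                f"learner={self.estimate.learner}>")


class SummaryDML:
    """Model object for the summary-level DML estimator.

    ``SummaryDML(hset, features).fit()`` returns a :class:`DMLResults`.
    """

    def __init__(self, hset: HarmonizedInstrumentSet,
                 features: pd.DataFrame | None = None,
                 config: DMLConfig | None = None):
        self.hset = hset
        self.features = features
        self.config = config or DMLConfig()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "SummaryDML":
        return cls(HarmonizedInstrumentSet.from_frame(df), **kwargs)

    def fit(self, learner: str | None = None) -> DMLResults:
        config = self.config
        if learner is not None:
            config = DMLConfig(k_folds=config.k_folds, learner=learner,
                               standardize=config.standardize,
                               seed=config.seed,
                               feature_spec=config.feature_spec)
        return DMLResults(run_dml(self.hset, self.features, config),
                          self.hset)
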