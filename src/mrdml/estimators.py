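"""Two-sample MR estimators on harmonized summary statistics.

All estimators consume a :class:`~mrdml.gwasio.HarmonizedInstrumentSet`
(aligned beta_x, se_x, beta_y, se_y vectors) and return an
:class:`MREstimate`. The inverse-variance-weighted (IVW) estimate is the
weighted least-squares slope of beta_y on beta_x through the origin with
weights 1/se_y^2; its multiplicative random-effects variant (the default)
inflates the fixed-effect SE by sqrt(max(1, Q/(n-1))), where Q is Cochran's
heterogeneity statistic. MR-Egger adds an intercept (after orienting every
pair so beta_x >= 0) whose deviation from zero measures directional
pleiotropy; the weighted median takes the 50% crossing point of the
weighted empirical distribution of per-SNP Wald ratios and is consistent
while at least half the weight comes from valid instruments.

The :class:`MRModel` / :class:`MRResults` pair wraps these functions in the
fit/results idiom: ``MRModel(hset).fit("ivw")`` or ``.fit_all()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwasio import HarmonizedInstrumentSet

Z95 = float(stats.norm.ppf(0.975))

MIN_SNPS_IVW = 2
MIN_SNPS_EGGER = 3
MIN_SNPS_WMEDIAN = 3


@dataclass
class MREstimate:
    """One method's causal-effect estimate on the beta (log-OR) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) for binary outcomes."""
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))

    def to_dict(self) -> dict:
        or_, lo, hi = self.or_scale
        return {"method": self.method, "n_snp": self.n_snp,
                "beta": self.beta, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "pval": self.pval, "or": or_, "or_ci_low": lo,
                "or_ci_high": hi}


def _require(hset: HarmonizedInstrumentSet, n_min: int, method: str) -> None:
    if hset.n_snp < n_min:
        raise ValueError(
            f"{method} requires at least {n_min} SNPs, got {hset.n_snp}; "
            "bidirectional MR needs at least 2 SNPs available as IVs "
            "(single-SNP sets fall back to the Wald ratio)")


def wald_ratio(hset: HarmonizedInstrumentSet) -> MREstimate:
    """Single-SNP causal estimate beta_y/beta_x (first-order delta SE)."""
    if hset.n_snp != 1:
        raise ValueError("wald_ratio is defined for exactly one SNP")
    bx = float(hset.beta_x[0])
    if bx == 0.0:
        raise ValueError("Wald ratio undefined for beta_x = 0")
    beta = float(hset.beta_y[0]) / bx
    se = abs(float(hset.se_y[0]) / bx)
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate("wald_ratio", beta, se, pval, 1)


def cochran_q_components(hset: HarmonizedInstrumentSet,
                         beta_ref: float | None = None):
    """Per-SNP contributions w_j (r_j - theta)^2 to Cochran's Q.

    Weights are the inverse Wald-ratio variances w_j = beta_x_j^2/se_y_j^2;
    ``beta_ref`` defaults to the fixed-effect IVW estimate.
    """
    w = hset.beta_x ** 2 / hset.se_y ** 2
    ratios = hset.beta_y / hset.beta_x
    if beta_ref is None:
        beta_ref = float(np.sum(w * ratios) / np.sum(w))
    return w * (ratios - beta_ref) ** 2, beta_ref


def ivw(hset: HarmonizedInstrumentSet, mode: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    mode "fixed" uses the fixed-effect SE 1/sqrt(sum w); "mre"
    (multiplicative random effects, the default) scales it by
    sqrt(max(1, Q/(n-1))) so between-SNP dispersion widens the interval.
    """
    _require(hset, MIN_SNPS_IVW, "ivw")
    if mode not in ("fixed", "mre"):
        raise ValueError("mode must be 'fixed' or 'mre'")
    w = hset.beta_x ** 2 / hset.se_y ** 2
    beta = float(np.sum(hset.beta_x * hset.beta_y / hset.se_y ** 2)
                 / np.sum(hset.beta_x ** 2 / hset.se_y ** 2))
    se = float(1.0 / np.sqrt(np.sum(w)))
    per_snp_q, _ = cochran_q_components(hset, beta)
    q = float(np.sum(per_snp_q))
    q_df = hset.n_snp - 1
    q_pval = float(stats.chi2.sf(q, q_df))
    dispersion = 1.0
    if mode == "mre":
        dispersion = max(1.0, q / q_df)
        se *= float(np.sqrt(dispersion))
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    method = "ivw_fixed" if mode == "fixed" else "ivw_mre"
    return MREstimate(method, beta, se, pval, hset.n_snp,
                      diagnostics={"q_stat": q, "q_df": q_df,
                                   "q_pval": q_pval,
                                   "dispersion": dispersion})


def mr_egger(hset: HarmonizedInstrumentSet) -> tuple[MREstimate, MREstimate]:
    """Egger regression: weighted fit of beta_y on beta_x with intercept.

    Pairs are sign-oriented so every beta_x >= 0 before fitting (the
    intercept's sign is only meaningful under a fixed orientation). SEs use
    the weighted residual variance floored at 1; p-values come from the t
    distribution on n-2 df. Returns (slope, intercept) estimates.
    """
    _require(hset, MIN_SNPS_EGGER, "mr_egger")
    sign = np.where(hset.beta_x < 0, -1.0, 1.0)
    x = hset.beta_x * sign
    y = hset.beta_y * sign
    w = 1.0 / hset.se_y ** 2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    n = hset.n_snp
    sigma2 = float(np.sum(w * resid ** 2) / (n - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    slope = MREstimate("egger_slope", float(coef[1]), float(se[1]),
                       float(pvals[1]), n,
                       diagnostics={"residual_dispersion": sigma2})
    intercept = MREstimate("egger_intercept", float(coef[0]), float(se[0]),
                           float(pvals[0]), n)
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # midpoint cumulative weights: symmetric, reduces to the plain median
    # for equal weights
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] < 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="left"))
    if s[k] == 0.5:
        return float(r[k])
    lo, hi = k - 1, k
    t = (0.5 - s[lo]) / (s[hi] - s[lo])
    return float(r[lo] + t * (r[hi] - r[lo]))


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000,
                    seed: int = 1234) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and the estimate is the ratio at which
    the weighted empirical CDF (inverse-variance weights, midpoint
    convention) crosses 0.5, linearly interpolated between the straddling
    order statistics. The SE resamples beta_x and beta_y from their
    reported SEs ``n_boot`` times under a fixed seed.
    """
    _require(hset, MIN_SNPS_WMEDIAN, "weighted_median")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    weights = hset.beta_x ** 2 / hset.se_y ** 2
    beta = _weighted_median_point(hset.beta_y / hset.beta_x, weights)
    rng = np.random.default_rng(seed)
    n = hset.n_snp
    bx = rng.normal(hset.beta_x, hset.se_x, size=(n_boot, n))
    by = rng.normal(hset.beta_y, hset.se_y, size=(n_boot, n))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        wb = bx[b] ** 2 / hset.se_y ** 2
        boot[b] = _weighted_median_point(by[b] / bx[b], wb)
    se = float(np.std(boot, ddof=1))
    pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else float(beta == 0.0)
    return MREstimate("weighted_median", beta, se, pval, n,
                      diagnostics={"n_boot": n_boot, "seed": seed})


class MRResults:
    """Fitted MR estimates with a statsmodels-flavoured summary table."""

    def __init__(self, estimates: list[MREstimate],
                 binary_outcome: bool = True):
        if not estimates:
            raise ValueError("no estimates")
        self.estimates = estimates
        self.binary_outcome = binary_outcome
        primary = estimates[0]
        self.method = primary.method
        self.beta = primary.beta
        self.se = primary.se
        self.pval = primary.pval
        self.n_snp = primary.n_snp
        self.diagnostics = primary.diagnostics

    def conf_int(self) -> tuple[float, float]:
        return (self.estimates[0].ci_low, self.estimates[0].ci_high)

    def summary(self) -> pd.DataFrame:
        rows = [e.to_dict() for e in self.estimates]
        df = pd.DataFrame(rows)
        if not self.binary_outcome:
            df = df.drop(columns=["or", "or_ci_low", "or_ci_high"])
        return df

    def __repr__(self):
        lo, hi = self.conf_int()
        return (f"<MRResults {self.method}: beta={self.beta:.4g} "
                f"(95% CI {lo:.4g}, {hi:.4g}), p={self.pval:.3g}, "
                f"n_snp={self.n_snp}>")


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    Parameters
    ----------
    hset
        Harmonized exposure/outcome effects.
    binary_outcome
        Whether to report the exp(beta) odds-ratio scale in summaries
        (forward analyses with disease outcomes) or plain beta (reverse
        analyses with continuous outcomes).
    """

    _METHODS = ("ivw", "ivw_fixed", "egger", "weighted_median", "wald_ratio")

    def __init__(self, hset: HarmonizedInstrumentSet,
                 binary_outcome: bool = True):
        self.hset = hset
        self.binary_outcome = binary_outcome

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "MRModel":
        return cls(HarmonizedInstrumentSet.from_frame(df), **kwargs)

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        if method == "ivw":
            estimates = [ivw(self.hset, mode="mre")]
        elif method == "ivw_fixed":
            estimates = [ivw(self.hset, mode="fixed")]
        elif method == "egger":
            estimates = list(mr_egger(self.hset))
        elif method == "weighted_median":
            estimates = [weighted_median(self.hset, **kwargs)]
        elif method == "wald_ratio":
            estimates = [wald_ratio(self.hset)]
        else:
            raise ValueError(f"unknown method {method!r}; "
                             f"choose from {self._METHODS}")
        return MRResults(estimates, self.binary_outcome)

    def fit_all(self, n_boot: int = 1000, seed: int = 1234) -> MRResults:
        """IVW (primary) plus Egger and weighted median where the SNP count
        allows; a single-SNP set yields the Wald ratio alone."""
        if self.hset.n_snp == 1:
            return MRResults([wald_ratio(self.hset)], self.binary_outcome)
        estimates = [ivw(self.hset)]
        if self.hset.n_snp >= MIN_SNPS_EGGER:
            estimates.extend(mr_egger(self.hset))
            estimates.append(weighted_median(self.hset, n_boot=n_boot,
                                             seed=seed))
        return MRResults(estimates, self.binary_outcome)
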