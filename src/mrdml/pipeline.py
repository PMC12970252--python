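"""Bidirectional analysis orchestration and decision rules.

A forward analysis treats the continuous imaging phenotype as exposure and
the binary disease as outcome (effects reported as odds ratios); the
reverse direction swaps the roles and reports plain betas. Per family of
tests, significance is judged against the Bonferroni threshold
alpha / n_tests, and a significant finding is classified as
hypothesis-confirming only when its statistical power is adequate
(>= 80%); otherwise it is exploratory. Power uses the normal
approximation

    power = Phi(|ln OR| * sqrt(n * VE) - z_{1 - alpha/2}),

with n the outcome case count and VE the variance in the exposure
explained by the instruments (5% by convention).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import instruments as ivsel
from .dml import DMLConfig, run_dml
from .estimators import MRModel
from .gwasio import PALINDROME_WINDOW, HarmonizedInstrumentSet, harmonize
from .qc import remove_radial_outliers, run_qc


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional alternative adjuster)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def power_normal_approx(odds_ratio: float, n_cases: float,
                        variance_explained: float = 0.05,
                        alpha: float = 0.05, literal: bool = False,
                        z_beta: float | None = None) -> float:
    """Statistical power for detecting a causal odds ratio.

    The default is the standard normal approximation
    Phi(|ln OR| sqrt(n VE) - z_{1-alpha/2}), clamped to [0, 1]. With
    ``literal=True`` the printed-form expression
    Phi(OR * n * VE - z_{alpha/2} - z_beta) is evaluated instead (z_beta
    defaults to the 80%-power quantile); it is exposed for comparison only,
    as it is not a self-consistent power function.
    """
    if not (np.isfinite(odds_ratio) and odds_ratio > 0):
        raise ValueError("odds_ratio must be positive")
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 < variance_explained < 1.0:
        raise ValueError("variance_explained must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    if literal:
        if z_beta is None:
            z_beta = float(stats.norm.ppf(0.8))
        arg = odds_ratio * n_cases * variance_explained - z_crit - z_beta
    else:
        arg = abs(np.log(odds_ratio)) * np.sqrt(n_cases * variance_explained) \
            - z_crit
    return float(np.clip(stats.norm.cdf(arg), 0.0, 1.0))


@dataclass
class AnalysisDecision:
    """Decision-rule outcome for one exposure/outcome pair."""

    direction: str
    n_tests: int
    bonferroni: float
    ivw_pval: float
    significant: bool
    power: float
    power_adequate: bool
    classification: str
    conforming: bool = True  # false when the >= 2 SNP rule was not met

    def to_dict(self) -> dict:
        return asdict(self)


def decide(ivw_pval: float, n_tests: int, power: float,
           direction: str = "forward", family_alpha: float = 0.05,
           power_adequate: float = 0.8,
           conforming: bool = True) -> AnalysisDecision:
    """Pure decision function: Bonferroni significance x power adequacy.

    Significant and adequately powered findings are hypothesis-confirming;
    significant but underpowered ones are exploratory; the rest are null.
    """
    threshold = bonferroni_threshold(n_tests, family_alpha)
    significant = bool(ivw_pval < threshold)
    adequate = bool(power >= power_adequate)
    if significant and adequate:
        classification = "hypothesis_confirming"
    elif significant:
        classification = "exploratory"
    else:
        classification = "null"
    return AnalysisDecision(direction=direction, n_tests=n_tests,
                            bonferroni=threshold, ivw_pval=float(ivw_pval),
                            significant=significant, power=float(power),
                            power_adequate=adequate,
                            classification=classification,
                            conforming=conforming)


@dataclass
class PipelineConfig:
    """Thresholds and seeds for one bidirectional run."""

    p_instrument: float = ivsel.GENOME_WIDE_P
    clump_r2: float = ivsel.CLUMP_R2
    clump_window_kb: float = ivsel.CLUMP_WINDOW_KB
    palindrome_window: tuple[float, float] = PALINDROME_WINDOW
    qc_alpha: float = 0.05
    family_alpha: float = 0.05
    power_adequate: float = 0.8
    variance_explained: float = 0.05
    presso_nsim: int = 1000
    mhc_region: tuple[int, int, int] = ivsel.MHC_REGION_GRCH37
    radial_pruning: bool = True
    run_dml: bool = False
    dml: DMLConfig = field(default_factory=DMLConfig)
    seed: int = 1234

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        dml_map = mapping.pop("dml", None)
        config = cls(**mapping)
        if dml_map:
            config.dml = DMLConfig(**dml_map)
        return config


@dataclass
class PairReport:
    """Machine-readable result for one exposure/outcome pair."""

    direction: str
    n_candidates: int
    n_instruments: int
    estimates: pd.DataFrame
    qc: dict | None
    dml: dict | None
    decision: AnalysisDecision
    instrument_report: pd.DataFrame
    aggregate_strength: dict

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "n_candidates": self.n_candidates,
            "n_instruments": self.n_instruments,
            "estimates": self.estimates.to_dict("records"),
            "qc": self.qc,
            "dml": self.dml,
            "decision": self.decision.to_dict(),
            "instrument_report": self.instrument_report.to_dict("records"),
            "aggregate_strength": self.aggregate_strength,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_pair(exposure: pd.DataFrame, outcome: pd.DataFrame,
             direction: str = "forward", ld: pd.DataFrame | None = None,
             features: pd.DataFrame | None = None,
             config: PipelineConfig | None = None,
             n_tests: int = 1, n_cases: float | None = None) -> PairReport:
    """Single-pair analysis: select instruments, harmonize, QC, estimate,
    and classify. ``n_tests`` is the size of the Bonferroni family this
    pair belongs to; ``n_cases`` (outcome case count) feeds the power
    calculation and defaults to the outcome table's median N.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    config = config or PipelineConfig()
    selected, iv_report, aggregate = ivsel.grade_instruments(
        exposure, ld, config.p_instrument, config.clump_r2,
        config.clump_window_kb, config.mhc_region)
    if selected.empty:
        raise ValueError("no instruments pass the significance threshold")
    hset = harmonize(selected, outcome, config.palindrome_window)

    removed: list[str] = []
    if config.radial_pruning and hset.n_snp >= 3:
        hset, removed = remove_radial_outliers(hset, config.qc_alpha)

    binary_outcome = direction == "forward"
    model = MRModel(hset, binary_outcome=binary_outcome)
    conforming = hset.n_snp >= 2
    results = model.fit_all(seed=config.seed)
    estimates = results.summary()

    qc_dict = None
    if hset.n_snp >= 2:
        qc_dict = run_qc(hset, config.qc_alpha, config.presso_nsim,
                         config.seed, config.mhc_region,
                         bonferroni_threshold(n_tests, config.family_alpha),
                         outliers_removed=removed).to_dict()

    dml_dict = None
    if config.run_dml and hset.n_snp >= 2 * config.dml.k_folds:
        dml_dict = run_dml(hset, features, config.dml).to_dict()

    primary = results.estimates[0]
    if n_cases is None:
        n_cases = float(np.median(hset.n_y))
    power = power_normal_approx(float(np.exp(primary.beta)), n_cases,
                                config.variance_explained,
                                config.family_alpha)
    decision = decide(primary.pval, n_tests, power, direction,
                      config.family_alpha, config.power_adequate,
                      conforming=conforming)
    return PairReport(direction=direction, n_candidates=len(exposure),
                      n_instruments=hset.n_snp, estimates=estimates,
                      qc=qc_dict, dml=dml_dict, decision=decision,
                      instrument_report=iv_report,
                      aggregate_strength=aggregate)


def run_bidirectional(exposure: pd.DataFrame, outcome: pd.DataFrame,
                      ld: pd.DataFrame | None = None,
                      features: pd.DataFrame | None = None,
                      config: PipelineConfig | None = None,
                      n_tests_forward: int = 1, n_tests_reverse: int = 1,
                      n_cases: float | None = None) -> dict:
    """Run both directions for one trait pair.

    Forward: ``exposure -> outcome`` (OR scale); reverse:
    ``outcome -> exposure`` (beta scale). Instrument counts and scale
    conventions are the only direction-dependent elements.
    """
    forward = run_pair(exposure, outcome, "forward", ld, features, config,
                       n_tests_forward, n_cases)
    reverse = run_pair(outcome, exposure, "reverse", ld, features, config,
                       n_tests_reverse, None)
    return {"forward": forward, "reverse": reverse}


def top_k_by_pvalue(forward_results: pd.DataFrame, k: int = 5,
                    screen_alpha: float = 0.05) -> pd.DataFrame:
    """Per outcome, the k nominally positive exposures with smallest IVW p.

    Only rows with p < ``screen_alpha`` qualify; ties on p break by |beta|
    descending, then exposure identifier. Expects columns
    (outcome, exposure, pval, beta); may return fewer than k per outcome.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = forward_results.loc[
        forward_results["pval"] < screen_alpha].copy()
    candidates["_abs_beta"] = candidates["beta"].abs()
    ordered = candidates.sort_values(
        ["outcome", "pval", "_abs_beta", "exposure"],
        ascending=[True, True, False, True], kind="mergesort")
    top = ordered.groupby("outcome", sort=True).head(k)
    return top.drop(columns="_abs_beta").reset_index(drop=True)


def decision_from_dict(payload: dict) -> AnalysisDecision:
    return AnalysisDecision(**payload)
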