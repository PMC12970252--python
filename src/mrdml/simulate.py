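"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator produces a paired exposure/outcome summary-statistics table
under the partially linear instrumental-variable model

    beta_Y,j = theta * gamma_j + alpha_j + eps_Y,j,
    beta_X,j = gamma_j + eps_X,j,

where ``gamma_j`` is SNP j's true per-allele effect on the continuous
exposure (in SD units), ``theta`` the causal effect of the exposure on the
outcome (log-odds per SD for a binary outcome), and ``alpha_j`` a horizontal
pleiotropy term. Estimation noise has SD ``1/sqrt(n)`` per study, the scale
implied by a standardized genotype and trait, so that the per-SNP variance
explained beta^2/(beta^2 + se^2 * n) is internally consistent.

Pleiotropy modes
----------------
``none``
    alpha identically zero.
``balanced``
    alpha ~ N(0, sigma_alpha): zero-mean, InSIDE holds.
``directional``
    alpha = sign(gamma) * N(mu_alpha, sigma_alpha): a systematic outcome
    effect aligned with the exposure-increasing allele, the mechanism the
    Egger intercept is designed to detect.
``correlated``
    alpha = rho_corr * gamma + N(0, sigma_alpha): instrument strength and
    direct effect are correlated, violating the InSIDE assumption.
``feature``
    alpha = Z @ w with a sparse weight vector over simulated SNP-level
    features Z; the drivers of pleiotropy are observable columns, the
    setting the summary-level DML estimator is built for.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwasio import CANONICAL_COLUMNS

MHC_REGION_GRCH37 = (6, 28_477_797, 33_448_354)

_PLEIOTROPY_MODES = ("none", "balanced", "directional", "correlated", "feature")

# non-complementary allele pairs: strand-resolvable
_STANDARD_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generating parameters for one exposure/outcome GWAS pair.

    Defaults mirror the study design the package targets: a brain-imaging
    exposure GWAS of 8,428 individuals supplying strong instruments
    (per-SNP F = gamma^2 * n of order 10^2-10^3, comfortably clearing the
    genome-wide threshold), and a disease outcome GWAS of ~10^5 samples.
    """

    n_snp: int = 200
    n_exposure: int = 8428
    n_outcome: int = 100_000
    theta: float = 0.0
    n_instruments: int = 150
    sigma_gamma: float = 0.3
    pleiotropy_mode: str = "none"
    mu_alpha: float = 0.05
    sigma_alpha: float = 0.05
    frac_pleiotropic: float = 1.0
    rho_corr: float = 0.5
    frac_palindromic: float = 0.05
    ld_block_size: int = 1
    ld_rho: float = 0.0
    mhc_fraction: float = 0.05
    n_features: int = 0
    n_active_features: int = 5
    feature_effect: float = 0.1
    seed: int = 1234

    def validate(self) -> None:
        fractions = {
            "frac_palindromic": self.frac_palindromic,
            "mhc_fraction": self.mhc_fraction,
            "frac_pleiotropic": self.frac_pleiotropic,
        }
        for name, value in fractions.items():
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.n_snp < 1:
            raise ValueError("n_snp must be positive")
        if not 0 <= self.n_instruments <= self.n_snp:
            raise ValueError("n_instruments must lie in [0, n_snp]")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be at least 2")
        for name in ("sigma_gamma", "sigma_alpha"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}"
            )
        if self.pleiotropy_mode == "feature":
            if self.n_features < 1:
                raise ValueError("feature-mode pleiotropy needs n_features >= 1")
            if self.n_active_features > self.n_features:
                raise ValueError("n_active_features cannot exceed n_features")


@dataclass
class SimulationTruth:
    """Generating values retained for parameter-recovery tests."""

    theta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    instrument_indices: np.ndarray
    seed: int
    features: pd.DataFrame | None = None
    feature_weights: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_true": self.theta_true,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "instrument_indices": self.instrument_indices.tolist(),
            "seed": self.seed,
        }
        if self.feature_weights is not None:
            payload["feature_weights"] = self.feature_weights.tolist()
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_alleles(rng: np.random.Generator, n_snp: int, frac_palindromic: float):
    n_pal = int(round(frac_palindromic * n_snp))
    is_pal = np.zeros(n_snp, dtype=bool)
    if n_pal:
        is_pal[rng.choice(n_snp, size=n_pal, replace=False)] = True
    ea = np.empty(n_snp, dtype=object)
    oa = np.empty(n_snp, dtype=object)
    eaf = np.empty(n_snp)
    std_idx = rng.integers(0, len(_STANDARD_PAIRS), size=n_snp)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n_snp)
    eaf_std = rng.uniform(0.05, 0.95, size=n_snp)
    # palindromic SNPs get intermediate frequencies so the ambiguity filter
    # is exercised by construction
    eaf_pal = rng.uniform(0.45, 0.55, size=n_snp)
    for j in range(n_snp):
        if is_pal[j]:
            ea[j], oa[j] = _PALINDROMIC_PAIRS[pal_idx[j]]
            eaf[j] = eaf_pal[j]
        else:
            ea[j], oa[j] = _STANDARD_PAIRS[std_idx[j]]
            eaf[j] = eaf_std[j]
    return ea, oa, eaf, is_pal


def _draw_positions(rng: np.random.Generator, n_snp: int, mhc_fraction: float):
    chrom = rng.integers(1, 23, size=n_snp)
    pos = rng.integers(1, 240_000_000, size=n_snp)
    n_mhc = int(round(mhc_fraction * n_snp))
    if n_mhc:
        idx = rng.choice(n_snp, size=n_mhc, replace=False)
        chrom[idx] = MHC_REGION_GRCH37[0]
        pos[idx] = rng.integers(
            MHC_REGION_GRCH37[1], MHC_REGION_GRCH37[2] + 1, size=n_mhc
        )
    return chrom, pos


def _draw_pleiotropy(rng: np.random.Generator, config: SimulationConfig,
                     gamma: np.ndarray, instruments: np.ndarray,
                     features: np.ndarray | None):
    n = config.n_snp
    alpha = np.zeros(n)
    weights = None
    mode = config.pleiotropy_mode
    if mode == "none":
        return alpha, weights
    if mode == "feature":
        weights = np.zeros(config.n_features)
        active = rng.choice(config.n_features, size=config.n_active_features,
                            replace=False)
        weights[active] = config.feature_effect * rng.choice([-1.0, 1.0],
                                                             size=active.size)
        alpha = features @ weights
        return alpha, weights
    # remaining modes act on a fraction of the instruments
    n_pleio = int(round(config.frac_pleiotropic * instruments.size))
    target = rng.choice(instruments, size=n_pleio, replace=False)
    if mode == "balanced":
        alpha[target] = rng.normal(0.0, config.sigma_alpha, size=n_pleio)
    elif mode == "directional":
        raw = rng.normal(config.mu_alpha, config.sigma_alpha, size=n_pleio)
        alpha[target] = np.sign(gamma[target]) * raw
    elif mode == "correlated":
        alpha[target] = (config.rho_corr * gamma[target]
                         + rng.normal(0.0, config.sigma_alpha, size=n_pleio))
    return alpha, weights


def simulate_pair(config: SimulationConfig):
    """Generate one exposure/outcome summary-statistic pair plus the truth.

    Returns
    -------
    (exposure, outcome, truth)
        Two DataFrames in the canonical column layout
        (SNP, CHR, BP, EA, OA, EAF, BETA, SE, P, N) and a
        :class:`SimulationTruth`. Identical configs yield byte-identical
        tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snp

    gamma = np.zeros(n)
    instruments = np.sort(rng.choice(n, size=config.n_instruments,
                                     replace=False))
    gamma[instruments] = rng.normal(0.0, config.sigma_gamma,
                                    size=config.n_instruments)

    features = None
    feature_frame = None
    if config.n_features > 0:
        features = rng.standard_normal((n, config.n_features))

    alpha, weights = _draw_pleiotropy(rng, config, gamma, instruments, features)

    se_x = np.full(n, 1.0 / np.sqrt(config.n_exposure))
    se_y = np.full(n, 1.0 / np.sqrt(config.n_outcome))
    beta_x = gamma + rng.normal(0.0, 1.0, size=n) * se_x
    beta_y = config.theta * gamma + alpha + rng.normal(0.0, 1.0, size=n) * se_y

    ea, oa, eaf, _ = _draw_alleles(rng, n, config.frac_palindromic)
    chrom, pos = _draw_positions(rng, n, config.mhc_fraction)
    snp_ids = np.array([f"rs{j:06d}" for j in range(1, n + 1)], dtype=object)

    def table(beta, se, n_samples):
        z = beta / se
        pval = 2.0 * stats.norm.sf(np.abs(z))
        # exact-zero p-values are outside the valid domain of downstream code
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        return pd.DataFrame({
            "SNP": snp_ids, "CHR": chrom, "BP": pos, "EA": ea, "OA": oa,
            "EAF": eaf, "BETA": beta, "SE": se, "P": pval,
            "N": np.full(n, n_samples, dtype=int),
        })

    exposure = table(beta_x, se_x, config.n_exposure)
    outcome = table(beta_y, se_y, config.n_outcome)

    if features is not None:
        feature_frame = pd.DataFrame(
            features, columns=[f"z{k}" for k in range(config.n_features)]
        )
        feature_frame.insert(0, "SNP", snp_ids)

    truth = SimulationTruth(
        theta_true=config.theta, gamma=gamma, alpha=alpha,
        instrument_indices=instruments, seed=config.seed,
        features=feature_frame, feature_weights=weights,
    )
    return exposure, outcome, truth


def inject_ld_blocks(table: pd.DataFrame, block_size: int, rho: float,
                     seed: int = 1234):
    """Impose block-equicorrelated LD on a summary table.

    Consecutive runs of ``block_size`` SNPs are moved onto a shared
    chromosome with adjacent positions (1 kb apart) and their z-scores mixed
    with a shared block component so that every within-block pair has
    correlation ``rho`` (hence r^2 = rho^2); across blocks r^2 = 0. Returns
    the modified copy and the pairwise LD matrix (signed r, SNP id on both
    axes).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    out = table.copy(deep=True)
    n = len(out)
    ids = out["SNP"].to_numpy()
    ld = np.eye(n)
    if rho > 0.0 and block_size > 1:
        z = (out["BETA"] / out["SE"]).to_numpy(dtype=float)
        chrom = out["CHR"].to_numpy().copy()
        pos = out["BP"].to_numpy().copy()
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            members = np.arange(start, stop)
            if members.size < 2:
                continue
            shared = rng.standard_normal()
            z[members] = (np.sqrt(rho) * shared
                          + np.sqrt(1.0 - rho) * z[members])
            chrom[members] = chrom[members[0]]
            pos[members] = pos[members[0]] + 1000 * (members - members[0])
            ld[np.ix_(members, members)] = rho
            ld[members, members] = 1.0
        out["CHR"] = chrom
        out["BP"] = pos
        out["BETA"] = z * out["SE"].to_numpy()
        pval = 2.0 * stats.norm.sf(np.abs(z))
        out["P"] = np.clip(pval, np.finfo(float).tiny, 1.0)
    ld_frame = pd.DataFrame(ld, index=ids, columns=ids)
    return out, ld_frame


def write_simulation(prefix: str | Path, exposure: pd.DataFrame,
                     outcome: pd.DataFrame, truth: SimulationTruth,
                     ld: pd.DataFrame | None = None) -> None:
    """Write exposure/outcome TSVs, the truth JSON and an optional LD TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    exposure[CANONICAL_COLUMNS].to_csv(f"{prefix}.exposure.tsv", sep="\t",
                                       index=False)
    outcome[CANONICAL_COLUMNS].to_csv(f"{prefix}.outcome.tsv", sep="\t",
                                      index=False)
    truth.to_json(f"{prefix}.truth.json")
    if ld is not None:
        ld.to_csv(f"{prefix}.ld.tsv", sep="\t")
    if truth.features is not None:
        truth.features.to_csv(f"{prefix}.features.tsv", sep="\t", index=False)


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a config from a YAML-style mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    extra = set(mapping) - known
    if extra:
        raise ValueError(f"unknown simulation keys: {sorted(extra)}")
    return SimulationConfig(**mapping)
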