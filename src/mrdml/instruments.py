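"""Instrument selection and grading.

Selection follows the conventional two-sample MR recipe: keep exposure
associations below genome-wide significance (P < 5e-8, strict), prune to
approximate linkage equilibrium by greedy p-value clumping (r^2 = 0.001
within a 10,000 kb window by default), then grade each retained SNP by its
variance explained R^2 = beta^2 / (beta^2 + se^2 N) and F-statistic
F = R^2 (N - k - 1) / (k (1 - R^2)), with F > 10 (strict) marking a strong
instrument. Variants inside the extended MHC region
(chr6:28,477,797-33,448,354, GRCh37) are flagged for sensitivity reruns
rather than silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_KB = 10_000.0
F_STRONG_THRESHOLD = 10.0
MHC_REGION_GRCH37 = (6, 28_477_797, 33_448_354)


def select_genome_wide_significant(records: pd.DataFrame,
                                   p_threshold: float = GENOME_WIDE_P
                                   ) -> pd.DataFrame:
    """Strict filter P < p_threshold on the exposure association."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    return records.loc[records["P"] < p_threshold].reset_index(drop=True)


def _validate_ld(ld: pd.DataFrame) -> None:
    values = ld.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("LD matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    if np.nanmax(np.abs(values)) > 1.0 + 1e-8:
        raise ValueError("LD entries must be correlations in [-1, 1]")


def ld_clump(records: pd.DataFrame, ld: pd.DataFrame | None = None,
             r2_threshold: float = CLUMP_R2,
             window_kb: float = CLUMP_WINDOW_KB) -> pd.DataFrame:
    """Greedy p-value clumping against a caller-supplied LD matrix.

    SNPs are visited in ascending p-value order (ties broken by SNP id) and
    accepted unless an already-accepted SNP on the same chromosome lies
    within ``window_kb`` and is correlated at r^2 > ``r2_threshold``. Pairs
    absent from ``ld`` (or ``ld=None``) are treated as uncorrelated, so the
    result does not depend on input row order. The matrix stores signed r;
    it is squared here.
    """
    if ld is not None:
        _validate_ld(ld)
    order = records.sort_values(["P", "SNP"], kind="mergesort")
    accepted: list[int] = []
    acc_chr: list = []
    acc_pos: list[float] = []
    acc_id: list[str] = []
    window_bp = window_kb * 1000.0
    for row in order.itertuples():
        keep = True
        for c, p, other in zip(acc_chr, acc_pos, acc_id):
            if c != row.CHR or abs(row.BP - p) > window_bp:
                continue
            r = 0.0
            if ld is not None and row.SNP in ld.index and other in ld.columns:
                r = float(ld.at[row.SNP, other])
            if r * r > r2_threshold:
                keep = False
                break
        if keep:
            accepted.append(row.Index)
            acc_chr.append(row.CHR)
            acc_pos.append(row.BP)
            acc_id.append(row.SNP)
    return order.loc[accepted].reset_index(drop=True)


def variance_explained(beta, se, n):
    """Per-SNP variance explained, beta^2 / (beta^2 + se^2 N)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))
            and np.all(np.isfinite(n))):
        raise ValueError("inputs must be finite")
    if np.any(se <= 0) or np.any(n <= 0):
        raise ValueError("se and n must be positive")
    b2 = beta ** 2
    return b2 / (b2 + se ** 2 * n)


def f_statistic(r2, n, k=1):
    """Instrument-strength F = R^2 (N - k - 1) / (k (1 - R^2))."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(r2 < 0) or np.any(r2 >= 1):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(n <= k + 1):
        raise ValueError("need n > k + 1")
    return r2 * (n - k - 1) / (k * (1.0 - r2))


def strong_instrument(f) -> np.ndarray | bool:
    """Conventional weak-instrument rule: strong iff F > 10 (strict)."""
    return np.asarray(f, dtype=float) > F_STRONG_THRESHOLD


def filter_mhc(records: pd.DataFrame,
               build_region: tuple[int, int, int] = MHC_REGION_GRCH37
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a table into (outside-MHC, inside-MHC); interval is closed."""
    chrom, start, stop = build_region
    in_mhc = ((records["CHR"].astype(str) == str(chrom))
              & (records["BP"] >= start) & (records["BP"] <= stop))
    return (records.loc[~in_mhc].reset_index(drop=True),
            records.loc[in_mhc].reset_index(drop=True))


def grade_instruments(records: pd.DataFrame,
                      ld: pd.DataFrame | None = None,
                      p_threshold: float = GENOME_WIDE_P,
                      r2_threshold: float = CLUMP_R2,
                      window_kb: float = CLUMP_WINDOW_KB,
                      mhc_region: tuple[int, int, int] = MHC_REGION_GRCH37,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full selection ladder and emit a per-SNP report.

    Returns ``(selected, report, aggregate)`` where ``report`` has one row
    per input SNP (r2, f_stat, in_mhc, retained, drop_reason) and
    ``aggregate`` carries both instrument-strength conventions: the mean of
    per-SNP F (k = 1) and the aggregate F computed from the summed R^2 with
    k equal to the number of instruments.
    """
    sig = select_genome_wide_significant(records, p_threshold)
    clumped = ld_clump(sig, ld, r2_threshold, window_kb)
    retained_ids = set(clumped["SNP"])
    sig_ids = set(sig["SNP"])

    r2 = variance_explained(records["BETA"], records["SE"], records["N"])
    f = f_statistic(r2, records["N"].to_numpy(dtype=float), 1)
    chrom, start, stop = mhc_region
    in_mhc = ((records["CHR"].astype(str) == str(chrom))
              & (records["BP"] >= start) & (records["BP"] <= stop))
    retained = records["SNP"].isin(retained_ids)
    drop_reason = np.where(retained, "none",
                           np.where(records["SNP"].isin(sig_ids), "clumped",
                                    "pval"))
    report = pd.DataFrame({
        "snp_id": records["SNP"], "r2": r2, "f_stat": f,
        "in_mhc": in_mhc.to_numpy(), "retained": retained.to_numpy(),
        "drop_reason": drop_reason,
    })
    sel = report.loc[report["retained"]]
    k = len(sel)
    aggregate = {"n_instruments": k,
                 "mean_f": float(sel["f_stat"].mean()) if k else float("nan"),
                 "total_r2": float(sel["r2"].sum()) if k else float("nan")}
    if k and sel["r2"].sum() < 1.0:
        n_bar = float(records.loc[retained, "N"].mean())
        if n_bar > k + 1:
            aggregate["aggregate_f"] = float(
                f_statistic(sel["r2"].sum(), n_bar, k))
    return clumped, report, aggregate
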