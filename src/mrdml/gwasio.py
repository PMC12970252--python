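"""Reading, writing and harmonizing GWAS summary statistics.

Tables use the canonical column layout ``SNP, CHR, BP, EA, OA, EAF, BETA,
SE, P, N`` (tab-separated on disk); arbitrary source headers are mapped via
``column_map``. Harmonization aligns an exposure/outcome pair onto the
exposure's effect allele, flipping outcome effect signs where the alleles
are reported the other way round (directly or on the opposite strand) and
dropping palindromic A/T and C/G variants whose allele frequency is too
close to 0.5 for the strand to be resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: default ambiguity window for palindromic variants; the conventional
#: two-sample MR choice for "allele frequency close to 0.5"
PALINDROME_WINDOW = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None
    pval: float
    n: int


def read_summary_stats(path: str | Path, column_map: dict[str, str] | None = None,
                       strict: bool = False) -> pd.DataFrame:
    """Read a summary-statistics TSV into the canonical layout.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Mapping from canonical name to the source header, e.g.
        ``{"SNP": "rsid", "BETA": "b"}``. Unmapped canonical names are
        looked up verbatim.
    strict
        If true, any malformed row raises; otherwise malformed rows are
        logged with their line number and skipped.

    Raises
    ------
    ValueError
        If a mandatory column cannot be resolved, or (strict mode) a row is
        malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    column_map = column_map or {}
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            if canonical in ("EAF",):  # optional
                continue
            raise ValueError(f"missing mandatory column {canonical!r} "
                             f"(looked for {source!r}) in {path}")
        rename[source] = canonical
    df = raw.rename(columns=rename)
    if "EAF" not in df.columns:
        df["EAF"] = np.nan
    df = df[CANONICAL_COLUMNS]

    numeric = df[["BETA", "SE", "P", "EAF", "N", "BP"]].apply(
        pd.to_numeric, errors="coerce")
    bad = (
        numeric["BETA"].isna() | ~np.isfinite(numeric["BETA"])
        | numeric["SE"].isna() | (numeric["SE"] <= 0)
        | numeric["P"].isna() | (numeric["P"] <= 0) | (numeric["P"] > 1)
        | (df["EA"].astype(str) == df["OA"].astype(str))
    )
    eaf_bad = numeric["EAF"].notna() & ((numeric["EAF"] < 0) | (numeric["EAF"] > 1))
    bad |= eaf_bad
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        msg = f"{path}: {int(bad.sum())} malformed row(s) at line(s) {lines}"
        if strict:
            raise ValueError(msg)
        logger.warning("%s -- skipped", msg)
    df = df.loc[~bad].copy()
    for col in ("BETA", "SE", "P", "EAF"):
        df[col] = pd.to_numeric(df[col])
    df["BP"] = pd.to_numeric(df["BP"]).astype(int)
    df["N"] = pd.to_numeric(df["N"]).astype(int)
    return df.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effects aligned to the exposure's effect allele."""

    snp_ids: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    pval_x: np.ndarray
    pval_y: np.ndarray
    n_x: np.ndarray
    n_y: np.ndarray
    n_dropped_palindromic: int = 0
    n_dropped_irreconcilable: int = 0
    n_flipped: int = 0

    def __post_init__(self):
        arrays = [self.snp_ids, self.beta_x, self.se_x, self.beta_y,
                  self.se_y, self.eaf, self.chrom, self.pos,
                  self.pval_x, self.pval_y, self.n_x, self.n_y]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("harmonized vectors must share one length")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, index) -> "HarmonizedInstrumentSet":
        """Positional subset (bool mask or integer index), counters reset."""
        index = np.asarray(index)
        return HarmonizedInstrumentSet(
            snp_ids=self.snp_ids[index], beta_x=self.beta_x[index],
            se_x=self.se_x[index], beta_y=self.beta_y[index],
            se_y=self.se_y[index], eaf=self.eaf[index],
            chrom=self.chrom[index], pos=self.pos[index],
            pval_x=self.pval_x[index], pval_y=self.pval_y[index],
            n_x=self.n_x[index], n_y=self.n_y[index],
        )

    def drop_ids(self, ids) -> "HarmonizedInstrumentSet":
        mask = ~np.isin(self.snp_ids, np.asarray(list(ids)))
        return self.subset(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SNP": self.snp_ids, "CHR": self.chrom, "BP": self.pos,
            "EAF": self.eaf, "beta_x": self.beta_x, "se_x": self.se_x,
            "beta_y": self.beta_y, "se_y": self.se_y,
            "pval_x": self.pval_x, "pval_y": self.pval_y,
            "n_x": self.n_x, "n_y": self.n_y,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizedInstrumentSet":
        return cls(
            snp_ids=df["SNP"].to_numpy(dtype=object),
            beta_x=df["beta_x"].to_numpy(dtype=float),
            se_x=df["se_x"].to_numpy(dtype=float),
            beta_y=df["beta_y"].to_numpy(dtype=float),
            se_y=df["se_y"].to_numpy(dtype=float),
            eaf=df["EAF"].to_numpy(dtype=float),
            chrom=df["CHR"].to_numpy(),
            pos=df["BP"].to_numpy(dtype=int),
            pval_x=df["pval_x"].to_numpy(dtype=float),
            pval_y=df["pval_y"].to_numpy(dtype=float),
            n_x=df["n_x"].to_numpy(dtype=int),
            n_y=df["n_y"].to_numpy(dtype=int),
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_window: tuple[float, float] = PALINDROME_WINDOW,
              ) -> HarmonizedInstrumentSet:
    """Align an exposure/outcome pair onto the exposure's effect allele.

    SNPs are intersected on identifier (exposure order preserved). For each
    SNP the outcome alleles are matched to the exposure alleles directly or
    via strand complement; a reversed match negates the outcome beta and
    reflects its allele frequency. Palindromic variants whose exposure or
    outcome allele frequency lies inside ``palindrome_window`` (or is
    missing) are dropped as strand-ambiguous; allele sets that cannot be
    reconciled are dropped and counted.
    """
    if exposure.empty or outcome.empty:
        raise ValueError("exposure and outcome tables must be nonempty")
    merged = exposure.merge(outcome, on="SNP", suffixes=("_x", "_y"),
                            how="inner")
    if merged.empty:
        raise ValueError("no overlapping SNP identifiers between exposure "
                         "and outcome tables")
    lo, hi = palindrome_window
    keep_rows: list[int] = []
    flip = np.zeros(len(merged), dtype=bool)
    n_pal = 0
    n_bad = 0
    ea_x = merged["EA_x"].to_numpy(dtype=object)
    oa_x = merged["OA_x"].to_numpy(dtype=object)
    ea_y = merged["EA_y"].to_numpy(dtype=object)
    oa_y = merged["OA_y"].to_numpy(dtype=object)
    eaf_x = merged["EAF_x"].to_numpy(dtype=float)
    eaf_y = merged["EAF_y"].to_numpy(dtype=float)
    for i in range(len(merged)):
        ea, oa = ea_x[i], oa_x[i]
        if _is_palindromic(ea, oa):
            freqs = [f for f in (eaf_x[i], eaf_y[i]) if np.isfinite(f)]
            if not freqs or any(lo <= f <= hi for f in freqs):
                n_pal += 1
                continue
        pair = (ea_y[i], oa_y[i])
        comp = (_COMPLEMENT.get(ea_y[i]), _COMPLEMENT.get(oa_y[i]))
        if pair == (ea, oa) or comp == (ea, oa):
            keep_rows.append(i)
        elif pair == (oa, ea) or comp == (oa, ea):
            keep_rows.append(i)
            flip[i] = True
        else:
            n_bad += 1
    idx = np.array(keep_rows, dtype=int)
    if idx.size == 0:
        raise ValueError("harmonization dropped every overlapping SNP")
    sub = merged.iloc[idx]
    sign = np.where(flip[idx], -1.0, 1.0)
    beta_y = sub["BETA_y"].to_numpy(dtype=float) * sign
    eaf_out = sub["EAF_y"].to_numpy(dtype=float)
    eaf_out = np.where(flip[idx], 1.0 - eaf_out, eaf_out)
    eaf = sub["EAF_x"].to_numpy(dtype=float)
    eaf = np.where(np.isfinite(eaf), eaf, eaf_out)
    return HarmonizedInstrumentSet(
        snp_ids=sub["SNP"].to_numpy(dtype=object),
        beta_x=sub["BETA_x"].to_numpy(dtype=float),
        se_x=sub["SE_x"].to_numpy(dtype=float),
        beta_y=beta_y,
        se_y=sub["SE_y"].to_numpy(dtype=float),
        eaf=eaf,
        chrom=sub["CHR_x"].to_numpy(),
        pos=sub["BP_x"].to_numpy(dtype=int),
        pval_x=sub["P_x"].to_numpy(dtype=float),
        pval_y=sub["P_y"].to_numpy(dtype=float),
        n_x=sub["N_x"].to_numpy(dtype=int),
        n_y=sub["N_y"].to_numpy(dtype=int),
        n_dropped_palindromic=n_pal,
        n_dropped_irreconcilable=n_bad,
        n_flipped=int(flip[idx].sum()),
    )


def harmonized_to_tables(hset: HarmonizedInstrumentSet,
                         exposure: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-express a harmonized set as two canonical tables (both on the
    exposure's effect allele), e.g. for writing or re-harmonizing."""
    exp = exposure.set_index("SNP").loc[hset.snp_ids].reset_index()
    out = exp.copy()
    out["BETA"] = hset.beta_y
    out["SE"] = hset.se_y
    out["P"] = hset.pval_y
    out["N"] = hset.n_y
    return exp, out
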