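"""Reading, filtering and annotating GWAS summary statistics.

All genomic coordinates are 1-based inclusive (Ensembl convention).  The
module covers the harmonization steps applied before gene scoring: the
MAF >= 1% filter, inflation correction by the LD-score intercept, the
shared-SNP intersection across studies, exclusion of the extended MHC
region, and strand-aware SNP-to-gene assignment with the 35 kb upstream /
10 kb downstream regulatory window ("upstream" means 5' of the
transcription start, so the padding flips on the minus strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpRecord",
    "GeneModel",
    "GenomicRegion",
    "MHC_REGION",
    "read_summary_stats",
    "read_gene_table",
    "filter_maf",
    "correct_inflation",
    "intersect_studies",
    "exclude_region",
    "map_snps_to_genes",
]


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int       # 1-based
    p: float       # in (0, 1]
    maf: float     # in (0, 0.5]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int     # 1-based inclusive
    end: int
    strand: str    # '+' or '-'


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int


# extended major histocompatibility complex, conventionally excluded
MHC_REGION = GenomicRegion("6", 25652464, 33771788)

_DEFAULT_COLUMNS = {"snp_id": "snp_id", "chrom": "chrom", "pos": "pos", "p": "p", "maf": "maf"}


def read_summary_stats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV into a validated DataFrame.

    ``column_map`` maps canonical names (snp_id, chrom, pos, p, maf) to the
    file's column names.  Malformed rows raise with their 1-based data line
    number.  Extra columns are ignored.
    """
    cmap = {**_DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype={cmap["chrom"]: str})
    missing = [v for k, v in cmap.items() if v not in df.columns and k != "maf"]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    keep = [c for c in ("snp_id", "chrom", "pos", "p", "maf") if c in df.columns]
    df = df[keep].copy()
    df["pos"] = df["pos"].astype(int)
    df["p"] = df["p"].astype(float)
    bad = df.index[(df["p"] <= 0) | (df["p"] > 1)]
    if len(bad):
        raise ValueError(f"p-value outside (0, 1] at data row(s) {[i + 1 for i in bad.tolist()]}")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1]
        raise ValueError(f"position < 1 at data row(s) {[i + 1 for i in bad.tolist()]}")
    if "maf" in df.columns:
        df["maf"] = df["maf"].astype(float)
        bad = df.index[(df["maf"] <= 0) | (df["maf"] > 0.5)]
        if len(bad):
            raise ValueError(f"MAF outside (0, 0.5] at data row(s) {[i + 1 for i in bad.tolist()]}")
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Read a BED-like gene TSV (gene_id, chrom, start, end, strand);
    coordinates are 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("gene with start > end")
    return df


def filter_maf(snps: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep SNPs with MAF >= threshold (boundary inclusive); order preserved."""
    if not (0 < threshold <= 0.5):
        raise ValueError("threshold must be in (0, 0.5]")
    return snps[snps["maf"] >= threshold].reset_index(drop=True)


def correct_inflation(snps: pd.DataFrame, intercept: float) -> pd.DataFrame:
    """Rescale p-values by the LD-score intercept.

    Each p is converted to a 1-df chi-square statistic, divided by the
    intercept, and converted back; monotone in p.  Intercepts below 1 are
    clamped to 1 with a warning (no deflation is applied).
    """
    if intercept <= 0:
        raise ValueError("intercept must be positive")
    if intercept < 1:
        warnings.warn(f"intercept {intercept} < 1: clamped to 1 (no correction)")
        intercept = 1.0
    out = snps.copy()
    chi2 = stats.chi2.isf(out["p"].to_numpy(float), 1)
    out["p"] = np.clip(stats.chi2.sf(chi2 / intercept, 1), np.finfo(float).tiny, 1.0)
    return out


def intersect_studies(studies: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict every study to the SNP ids present in all studies."""
    if len(studies) < 2:
        raise ValueError("need at least 2 studies")
    shared = set(studies[0]["snp_id"])
    for s in studies[1:]:
        shared &= set(s["snp_id"])
    if not shared:
        warnings.warn("no SNPs shared among studies")
    return [s[s["snp_id"].isin(shared)].reset_index(drop=True) for s in studies]


def _padded_interval(start: int, end: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Strand-aware window: upstream pads the 5' side (start on '+',
    end on '-')."""
    if strand == "-":
        return start - down, end + up
    return start - up, end + down


def exclude_region(
    genes: pd.DataFrame,
    region: GenomicRegion,
    window_up: int = 35000,
    window_down: int = 10000,
) -> pd.DataFrame:
    """Remove genes whose strand-aware padded body intersects the region
    (default padding matches the gene-analysis 35/10 kb window)."""
    keep = []
    for row in genes.itertuples(index=False):
        if row.chrom != region.chrom:
            keep.append(True)
            continue
        lo, hi = _padded_interval(row.start, row.end, row.strand, window_up, window_down)
        keep.append(not (lo <= region.end and region.start <= hi))
    return genes[np.array(keep, dtype=bool)].reset_index(drop=True)


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_up: int = 35000,
    window_down: int = 10000,
) -> pd.DataFrame:
    """Assign each SNP to every gene whose strand-aware window contains it.

    A SNP may map to multiple genes.  Returns a (snp_id, gene_id) table.
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("windows must be >= 0")
    rows = []
    for chrom, gsub in genes.groupby("chrom"):
        ssub = snps[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy(int)
        ids = ssub["snp_id"].to_numpy()
        for g in gsub.itertuples(index=False):
            lo, hi = _padded_interval(g.start, g.end, g.strand, window_up, window_down)
            mask = (pos >= lo) & (pos <= hi)
            rows.extend((sid, g.gene_id) for sid in ids[mask])
    return pd.DataFrame(rows, columns=["snp_id", "gene_id"])
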