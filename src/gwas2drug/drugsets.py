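"""Drug gene-sets, ATC therapeutic classes and druggable-genome tiers.

A drug is represented by the set of genes encoding its known protein
targets, built by merging interaction evidence from a DGIdb-style table
(curated drug-gene pairs) and a Ki-database-style table (binding affinities,
kept below a configurable Ki cut-off, default 10 uM).  Gene symbols are
mapped to stable gene identifiers; drugs are grouped into ATC classes
(3-character level by default, e.g. N05A for antipsychotics at level 4 or
N05 at level 3), and only classes with at least 10 drugs are scanned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DrugGeneSet",
    "AtcClass",
    "build_drug_sets",
    "build_atc_classes",
    "select_significant_druggable",
]


@dataclass
class DrugGeneSet:
    drug_id: str
    genes: set[str]
    atc_codes: list[str] = field(default_factory=list)


@dataclass
class AtcClass:
    code: str
    drugs: list[str]


def build_drug_sets(
    interactions: pd.DataFrame,
    symbol_map: dict[str, str],
    ki_max_nM: float = 10000.0,
) -> tuple[list[DrugGeneSet], dict]:
    """Merge interaction tables into one gene-set per drug.

    ``interactions`` needs columns drug_id, gene_symbol, source (dgidb-like
    or kidb-like) and, for kidb-like rows, affinity (Ki in nM).  Affinity
    rows above ``ki_max_nM`` are discarded; per-drug sets are the union over
    sources.  Unmappable symbols and drugs left empty are dropped and
    counted in the returned report.  Output order is independent of input
    row order (drugs sorted by id, genes as sets).
    """
    df = interactions.copy()
    is_ki = df["source"].astype(str).str.startswith("kidb")
    if "affinity" in df.columns:
        aff = pd.to_numeric(df["affinity"], errors="coerce")
        drop_aff = is_ki & (aff.isna() | (aff > ki_max_nM))
    else:
        drop_aff = is_ki  # affinity required for kidb-like evidence
    df = df[~drop_aff]
    report = {"n_affinity_filtered": int(drop_aff.sum()), "unmapped_symbols": set(),
              "dropped_drugs": []}
    sets: dict[str, set[str]] = {}
    for drug, sub in df.groupby("drug_id"):
        genes = set()
        for sym in sub["gene_symbol"]:
            gid = symbol_map.get(sym)
            if gid is None:
                report["unmapped_symbols"].add(sym)
            else:
                genes.add(gid)
        if genes:
            sets[str(drug)] = genes
        else:
            report["dropped_drugs"].append(str(drug))
    out = [DrugGeneSet(d, sets[d]) for d in sorted(sets)]
    report["dropped_drugs"].sort()
    return out, report


def build_atc_classes(
    drug_sets: list[DrugGeneSet],
    atc_map: pd.DataFrame,
    min_class_size: int = 10,
    level: int = 4,
) -> list[AtcClass]:
    """Group drugs into ATC classes at a given code-prefix length.

    ``atc_map`` has columns drug_id, code; a drug with several codes joins
    every matching class.  Classes with fewer than ``min_class_size`` drugs
    are excluded.  The default level of 4 characters matches classes like
    N05A (antipsychotics).
    """
    have = {d.drug_id for d in drug_sets}
    by_drug: dict[str, list[str]] = {}
    classes: dict[str, set[str]] = {}
    for drug, code in atc_map[["drug_id", "code"]].itertuples(index=False):
        drug = str(drug)
        if drug not in have:
            continue
        prefix = str(code)[:level]
        classes.setdefault(prefix, set()).add(drug)
        by_drug.setdefault(drug, []).append(prefix)
    for d in drug_sets:
        d.atc_codes = sorted(set(by_drug.get(d.drug_id, [])))
    return [
        AtcClass(code, sorted(drugs))
        for code, drugs in sorted(classes.items())
        if len(drugs) >= min_class_size
    ]


def select_significant_druggable(
    gene_results: pd.DataFrame,
    tiers: dict[str, str],
    t_druggable: float,
    t_genomewide: float,
    mhc_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Partition significant druggable genes by tier and threshold.

    Keeps druggable genes (present in ``tiers``) outside the MHC with
    ``p_combined <= t_druggable``; each is labeled
    ``below_protein_coding_threshold`` when it also passes the stricter
    genome-wide cut-off, else ``below_druggable_threshold_only``.  The two
    labels partition the selection exhaustively and disjointly.
    """
    df = gene_results.copy()
    df = df[df["gene_id"].isin(tiers)]
    if mhc_genes:
        df = df[~df["gene_id"].isin(mhc_genes)]
    df = df[df["p_combined"] <= t_druggable].copy()
    df["tier"] = df["gene_id"].map(tiers)
    df["category"] = np.where(
        df["p_combined"] <= t_genomewide,
        "below_protein_coding_threshold",
        "below_druggable_threshold_only",
    )
    return df.sort_values("p_combined").reset_index(drop=True)
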