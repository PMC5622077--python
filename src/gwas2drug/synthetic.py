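"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the shape of the real study inputs without any
external downloads: GWAS summary statistics whose per-gene SNP Z-scores are
multivariate normal with exchangeable (compound-symmetry) LD and a mean
shift on SNPs in planted causal genes; a drug library in which one
therapeutic class preferentially samples its target genes from the causal
set; pathway collections with planted Tanimoto cluster structure; and
random STRING-style weighted interaction graphs.  Everything is byte-
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .formats import write_gmt

__all__ = [
    "SyntheticConfig",
    "gen_gwas",
    "gen_drug_library",
    "gen_pathway_collection",
    "gen_ppi",
    "write_bundle",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale version of the real inputs: hundreds of
    genes over several chromosomes, ~10 SNPs per gene with moderate
    exchangeable LD, a few percent of genes carrying signal, and a drug
    library with one enriched therapeutic class.
    """

    seed: int = 0
    n_genes: int = 400
    snps_per_gene: int = 10
    ld_rho: float = 0.3
    causal_gene_fraction: float = 0.05
    effect_delta: float = 2.0
    n_drugs: int = 120
    set_size_range: tuple[int, int] = (5, 30)
    n_classes: int = 6
    planted_class: str = "N05A"
    planted_bias: float = 0.9
    n_pathways: int = 40
    n_pathway_clusters: int = 4
    pathway_size: int = 25
    pathway_swap_fraction: float = 0.1
    min_class_size: int = 10
    n_chromosomes: int = 4
    gene_length_range: tuple[int, int] = (5_000, 60_000)
    gene_spacing: int = 200_000  # slot pitch; gaps exceed the 35/10 kb windows

    def validate(self) -> None:
        positive = {
            "n_genes": self.n_genes,
            "snps_per_gene": self.snps_per_gene,
            "n_drugs": self.n_drugs,
            "n_classes": self.n_classes,
            "n_pathways": self.n_pathways,
            "n_pathway_clusters": self.n_pathway_clusters,
            "n_chromosomes": self.n_chromosomes,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 <= self.planted_bias <= 1):
            raise ValueError("planted_bias must be in [0, 1]")
        if not (0 <= self.causal_gene_fraction <= 1):
            raise ValueError("causal_gene_fraction must be in [0, 1]")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid set_size_range")
        if hi > self.n_genes:
            raise ValueError("set_size_range max exceeds n_genes")
        if self.n_chromosomes < 2:
            raise ValueError("need genes on at least 2 chromosomes")


def gen_gwas(config: SyntheticConfig):
    """Synthetic GWAS summary statistics with per-gene exchangeable LD.

    Returns ``(snp_table, gene_table, causal_genes, ld_matrices)``.  Genes
    are laid out non-overlapping on ``n_chromosomes`` chromosomes; each
    gene's SNP Z-scores are MVN with correlation ``ld_rho`` between every
    pair, shifted by ``effect_delta`` in causal genes.  Two-sided p-values
    are emitted and MAFs are drawn uniform on [0.005, 0.5] so that the 1%
    MAF filter always removes some SNPs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_causal = int(round(config.causal_gene_fraction * config.n_genes))
    causal_idx = rng.choice(config.n_genes, size=n_causal, replace=False)
    causal = np.zeros(config.n_genes, dtype=bool)
    causal[causal_idx] = True

    rho, m = config.ld_rho, config.snps_per_gene
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)

    gene_rows, snp_rows = [], []
    ld_matrices: dict[str, np.ndarray] = {}
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    for gi in range(config.n_genes):
        gene_id = f"G{gi:05d}"
        chrom = str(gi // per_chrom + 1)
        slot = gi % per_chrom
        length = int(rng.integers(*config.gene_length_range))
        start = 1_000_000 + slot * config.gene_spacing
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((gene_id, chrom, start, end, strand))
        # exchangeable draw: sqrt(rho)*shared + sqrt(1-rho)*independent
        shared = rng.standard_normal()
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(m)
        if causal[gi]:
            z = z + config.effect_delta
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        maf = rng.uniform(0.005, 0.5, size=m)
        pos = np.linspace(start, end, m).astype(int)
        for j in range(m):
            snp_rows.append((f"rs{gi:05d}_{j:02d}", chrom, int(pos[j]), float(p[j]),
                             float(maf[j]), float(z[j])))
        ld_matrices[gene_id] = R.copy()

    snp_table = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "p", "maf", "z"])
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    causal_genes = {f"G{gi:05d}" for gi in np.flatnonzero(causal)}
    return snp_table, gene_table, causal_genes, ld_matrices


def gen_drug_library(config: SyntheticConfig, causal_genes: set[str], gene_table: pd.DataFrame):
    """Drug gene-sets with one planted enriched class.

    Every class receives at least ``min_class_size`` drugs by construction.
    Drugs in ``planted_class`` draw each member gene from the causal set
    with probability ``planted_bias`` and uniformly otherwise; all other
    drugs sample genes uniformly.  Returns ``(drug_sets, atc_map)``.
    """
    config.validate()
    all_genes = gene_table["gene_id"].tolist()
    if not set(causal_genes) <= set(all_genes):
        raise ValueError("causal_genes must be a subset of gene_table")
    causal_list = sorted(causal_genes)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_per = max(config.min_class_size, config.n_drugs // config.n_classes)
    codes = [config.planted_class] + [f"C{c:02d}" for c in range(1, config.n_classes)]
    drug_sets: dict[str, set[str]] = {}
    atc_rows = []
    lo, hi = config.set_size_range
    di = 0
    for code in codes:
        for _ in range(n_per):
            drug_id = f"D{di:04d}"
            di += 1
            size = int(rng.integers(lo, hi + 1))
            genes: set[str] = set()
            planted = code == config.planted_class and len(causal_list) > 0
            while len(genes) < size:
                if planted and rng.random() < config.planted_bias:
                    genes.add(causal_list[rng.integers(len(causal_list))])
                else:
                    genes.add(all_genes[rng.integers(len(all_genes))])
            drug_sets[drug_id] = genes
            atc_rows.append((drug_id, code))
    atc_map = pd.DataFrame(atc_rows, columns=["drug_id", "code"])
    return drug_sets, atc_map


def gen_pathway_collection(config: SyntheticConfig, gene_table: pd.DataFrame) -> dict[str, set[str]]:
    """Pathway collection with planted cluster structure.

    Each cluster is generated by perturbing a random template set: a
    ``pathway_swap_fraction`` of member genes is swapped for random genes,
    so within-cluster Tanimoto similarity exceeds between-cluster similarity
    in expectation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = gene_table["gene_id"].tolist()
    size = min(config.pathway_size, len(genes))
    per_cluster = int(np.ceil(config.n_pathways / config.n_pathway_clusters))
    collection: dict[str, set[str]] = {}
    pi = 0
    for c in range(config.n_pathway_clusters):
        template = set(rng.choice(len(genes), size=size, replace=False))
        for _ in range(per_cluster):
            if pi >= config.n_pathways:
                break
            members = set(template)
            n_swap = int(round(config.pathway_swap_fraction * size))
            if n_swap:
                out = rng.choice(sorted(members), size=n_swap, replace=False)
                members -= set(out.tolist())
                pool = [i for i in range(len(genes)) if i not in members]
                members |= set(rng.choice(pool, size=n_swap, replace=False).tolist())
            collection[f"PW{c:02d}_{pi:04d}"] = {genes[i] for i in members}
            pi += 1
    return collection


def gen_ppi(
    gene_table: pd.DataFrame,
    config: SyntheticConfig,
    density: float = 0.05,
    hub_gene: str | None = None,
    hub_prob: float = 0.8,
) -> pd.DataFrame:
    """Random STRING-style undirected weighted edge table.

    Edges appear independently with probability ``density``; scores are
    uniform on [0, 1000]; no self-loops.  If ``hub_gene`` is given it is
    additionally connected to every other gene with probability
    ``hub_prob``, producing a degree hub.
    """
    genes = gene_table["gene_id"].tolist()
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            p_edge = density
            if hub_gene is not None and hub_gene in (genes[i], genes[j]):
                p_edge = max(density, hub_prob)
            if rng.random() < p_edge:
                rows.append((genes[i], genes[j], float(rng.uniform(0, 1000))))
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def write_bundle(config: SyntheticConfig, out_dir) -> dict[str, str]:
    """Generate the full synthetic bundle and write every artifact as text.

    Writes summary-stats TSV, gene BED-like TSV, drug-set GMT, ATC map TSV,
    pathway GMT, STRING-style edge TSV, and the causal-gene list.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snp_table, gene_table, causal, _ = gen_gwas(config)
    drug_sets, atc_map = gen_drug_library(config, causal, gene_table)
    pathways = gen_pathway_collection(config, gene_table)
    edges = gen_ppi(gene_table, config)
    paths = {
        "summary_stats": str(out / "summary_stats.tsv"),
        "genes": str(out / "genes.tsv"),
        "drug_sets": str(out / "drug_sets.gmt"),
        "atc_map": str(out / "atc_map.tsv"),
        "pathways": str(out / "pathways.gmt"),
        "ppi_edges": str(out / "ppi_edges.tsv"),
        "causal_genes": str(out / "causal_genes.txt"),
    }
    snp_table.to_csv(paths["summary_stats"], sep="\t", index=False)
    gene_table.to_csv(paths["genes"], sep="\t", index=False)
    write_gmt(drug_sets, paths["drug_sets"])
    atc_map.to_csv(paths["atc_map"], sep="\t", index=False)
    write_gmt(pathways, paths["pathways"])
    edges.to_csv(paths["ppi_edges"], sep="\t", index=False)
    Path(paths["causal_genes"]).write_text("\n".join(sorted(causal)) + "\n")
    return paths
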