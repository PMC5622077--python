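"""End-to-end orchestration: synthetic inputs (or files) -> SNP prep ->
gene scoring -> competitive drug/pathway scan -> class enrichment -> maps ->
networks, under one config with a run report.

Every stage is reproducible from the config and its seeds; the report
records the counts surviving each filter (SNPs kept, genes scored, sets
tested, classes scanned, significant results under Bonferroni/BH/BY).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import drugsets as ds
from . import enrichment as en
from . import gene_scoring as gs
from . import gwas_io as io
from . import networks as nw
from . import pathway_maps as pm
from . import synthetic as syn

logger = logging.getLogger("gwas2drug")

__all__ = ["RunConfig", "run", "score_genes", "scan_sets"]


@dataclass
class RunConfig:
    """Single structured configuration for a pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    # input paths; when None the synthetic stage must be enabled
    summary_stats: str | None = None
    genes: str | None = None
    drug_sets_gmt: str | None = None
    atc_map: str | None = None
    pathways_gmt: str | None = None
    ppi_edges: str | None = None
    # thresholds
    maf: float = 0.01
    intercept: float = 1.0
    alpha: float = 0.05
    min_class_size: int = 10
    top_n: int = 50
    variance_fraction: float = 0.995
    mc_draws: int = 1000
    exclude_mhc: bool = False
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "synth": True, "prep": True, "genescore": True, "setscan": True,
        "enrich": True, "maps": True, "networks": True,
    })
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k == "stages":
                cfg.stages.update(v)
            else:
                setattr(cfg, k, v)
        return cfg


def snp_z(snp_table: pd.DataFrame) -> np.ndarray:
    """Per-SNP |Z| from two-sided p when no signed z column is present."""
    if "z" in snp_table.columns:
        return snp_table["z"].to_numpy(float)
    return stats.norm.isf(snp_table["p"].to_numpy(float) / 2.0)


def score_genes(
    snp_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    assignment: pd.DataFrame,
    ld_matrices: dict[str, np.ndarray] | None = None,
    mc_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level p-values and Z for every gene with assigned SNPs.

    Genes lacking an LD matrix are scored under an identity (independent
    SNP) model.  Adds the covariate columns used by the competitive test
    (gene size, n_snps, mean MAF).
    """
    snp_idx = snp_table.set_index("snp_id")
    results = []
    meta = gene_table.set_index("gene_id")
    for gene_id, sub in assignment.groupby("gene_id"):
        snps = snp_idx.loc[snp_idx.index.intersection(sub["snp_id"])]
        if snps.empty:
            continue
        n = len(snps)
        R = None if ld_matrices is None else ld_matrices.get(gene_id)
        if R is None or np.asarray(R).shape[0] != n:
            R = np.eye(n)
        zs = snp_z(snps.reset_index())
        res = gs.score_gene(gene_id, snps["p"].to_numpy(float), zs, R,
                            mc_draws=mc_draws, seed=seed)
        row = meta.loc[gene_id]
        results.append(
            (gene_id, res.n_snps, res.p_top, res.p_mean, res.p_combined, res.z,
             int(row["end"] - row["start"] + 1),
             float(snps["maf"].mean()) if "maf" in snps else np.nan)
        )
    return pd.DataFrame(
        results,
        columns=["gene_id", "n_snps", "p_top", "p_mean", "p_combined", "z",
                 "size", "mean_maf"],
    )


def scan_sets(
    gene_results: pd.DataFrame,
    collections: dict[str, set[str]],
    min_set_genes: int = 1,
) -> pd.DataFrame:
    """Competitive test for every gene-set against the scored gene universe."""
    universe = gene_results["gene_id"].tolist()
    uni_idx = {g: i for i, g in enumerate(universe)}
    z = gene_results["z"].to_numpy(float)
    cov_table = gene_results.rename(columns={"size": "length"})
    cov_table = pd.DataFrame({
        "start": 1, "end": gene_results["size"], "n_snps": gene_results["n_snps"],
        "mean_maf": gene_results["mean_maf"],
    })
    C = gs.default_covariates(cov_table)
    # constant covariates (e.g. uniform SNP counts) carry no information and
    # would be collinear with the intercept
    keep = C.std(axis=0) > 1e-12
    C = C[:, keep] if keep.any() else None
    results = []
    for set_id, genes in collections.items():
        member = np.zeros(len(universe))
        idx = [uni_idx[g] for g in genes if g in uni_idx]
        if len(idx) < min_set_genes or len(idx) == 0 or len(idx) == len(universe):
            continue
        member[idx] = 1.0
        results.append(gs.competitive_set_test(z, member, C, set_id=set_id))
    return gs.annotate_set_results(results)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": [], "counts": {}}
    st = config.stages

    def enabled(name: str) -> bool:
        return bool(st.get(name, False))

    def require(name: str, stage: str) -> None:
        if not enabled(name):
            raise RuntimeError(f"stage {stage!r} requires stage {name!r} to be enabled")

    ld_matrices = None
    causal = None
    if enabled("synth"):
        scfg = syn.SyntheticConfig(seed=config.seed, **config.synthetic)
        snp_table, gene_table, causal, ld_matrices = syn.gen_gwas(scfg)
        drug_gmt, atc_map = syn.gen_drug_library(scfg, causal, gene_table)
        pathways = syn.gen_pathway_collection(scfg, gene_table)
        edges = syn.gen_ppi(gene_table, scfg)
        report["stages"].append("synth")
        report["counts"]["causal_genes"] = len(causal)
    else:
        for key in ("summary_stats", "genes"):
            if getattr(config, key) is None:
                raise RuntimeError(f"stage 'prep' requires input {key!r} or the synth stage")
        snp_table = io.read_summary_stats(config.summary_stats)
        gene_table = io.read_gene_table(config.genes)
        drug_gmt = en_pathways = None
        from .formats import read_gmt
        drug_gmt = read_gmt(config.drug_sets_gmt) if config.drug_sets_gmt else {}
        atc_map = pd.read_csv(config.atc_map, sep="\t") if config.atc_map else pd.DataFrame(columns=["drug_id", "code"])
        pathways = read_gmt(config.pathways_gmt) if config.pathways_gmt else {}
        edges = pd.read_csv(config.ppi_edges, sep="\t") if config.ppi_edges else None

    report["counts"]["snps_input"] = len(snp_table)
    report["counts"]["genes_input"] = len(gene_table)

    if enabled("prep"):
        snp_table = io.filter_maf(snp_table, config.maf)
        report["counts"]["snps_after_maf"] = len(snp_table)
        if config.intercept != 1.0:
            snp_table = io.correct_inflation(snp_table, config.intercept)
        if config.exclude_mhc:
            gene_table = io.exclude_region(gene_table, io.MHC_REGION)
        assignment = io.map_snps_to_genes(snp_table, gene_table)
        report["counts"]["snp_gene_assignments"] = len(assignment)
        report["stages"].append("prep")
        snp_table.to_csv(out / "snps_prepared.tsv", sep="\t", index=False)

    gene_results = None
    if enabled("genescore"):
        require("prep", "genescore")
        gene_results = score_genes(snp_table, gene_table, assignment,
                                   ld_matrices, config.mc_draws, config.seed)
        report["counts"]["genes_scored"] = len(gene_results)
        gene_results.to_csv(out / "gene_results.tsv", sep="\t", index=False)
        report["stages"].append("genescore")

    set_results = None
    if enabled("setscan"):
        require("genescore", "setscan")
        collections = dict(drug_gmt)
        collections.update(pathways)
        set_results = scan_sets(gene_results, collections)
        report["counts"]["sets_tested"] = len(set_results)
        for col, key in (("p_bonf", "sets_bonferroni"), ("q_bh", "sets_bh"), ("q_by", "sets_by")):
            report["counts"][key] = int((set_results[col] <= config.alpha).sum())
        set_results.to_csv(out / "set_results.tsv", sep="\t", index=False)
        report["stages"].append("setscan")

    if enabled("enrich"):
        require("setscan", "enrich")
        drug_results = set_results[set_results["set_id"].isin(drug_gmt)]
        drug_objs = [ds.DrugGeneSet(d, drug_gmt[d]) for d in drug_results["set_id"]]
        classes = ds.build_atc_classes(drug_objs, atc_map, config.min_class_size)
        class_map = {c.code: c.drugs for c in classes}
        enr = en.class_enrichment_scan(
            drug_results.rename(columns={"p_competitive": "p_competitive"}),
            class_map, config.alpha,
        ) if class_map else []
        enr_df = en.results_table(enr)
        report["counts"]["classes_scanned"] = len(enr)
        report["counts"]["classes_significant"] = int(enr_df["significant"].sum()) if len(enr) else 0
        enr_df.to_csv(out / "class_enrichment.tsv", sep="\t", index=False)
        report["stages"].append("enrich")

    if enabled("maps"):
        require("setscan", "maps")
        top = pm.select_top_sets(set_results, config.top_n)
        collections = dict(drug_gmt)
        collections.update(pathways)
        top_sets = {sid: collections[sid] for sid in top["set_id"] if sid in collections}
        if len(top_sets) >= 4:
            ids, M = pm.membership_matrix(top_sets)
            K = pm.tanimoto_matrix(M)
            model = pm.kgtm_fit(K, seed=config.seed)
            pmap = {r.set_id: -np.log10(max(r.p_competitive, 1e-300))
                    for r in top.itertuples(index=False)}
            proj = pm.project(model, ids, [pmap[i] for i in ids])
            proj.to_frame().to_csv(out / "map_projection.tsv", sep="\t", index=False)
            report["counts"]["sets_mapped"] = len(ids)
        report["stages"].append("maps")

    if enabled("networks") and edges is not None and len(edges):
        G = nw.read_string_edges_df(edges)
        metrics = nw.node_metrics(G)
        nw.metrics_table(metrics).to_csv(out / "node_metrics.tsv", sep="\t", index=False)
        report["counts"]["ppi_nodes"] = G.number_of_nodes()
        report["counts"]["ppi_edges"] = G.number_of_edges()
        report["stages"].append("networks")

    (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
    return report
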