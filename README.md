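# gwas2drug

Drug-repurposing analysis of GWAS summary statistics.

Genome-wide association studies assign a p-value to each SNP; drug
databases assign a set of protein targets to each drug. This package
connects the two: if the targets of an existing therapeutic class are
enriched among the genes most associated with a disorder, the genetics
corroborates (or suggests) that class for the disorder. The library
implements the full chain for anyone working with summary statistics and
drug-target tables — statistical geneticists, cheminformaticians, and
translational researchers:

1. **SNP preparation** (`gwas_io`) — MAF ≥ 1% filtering, p-value rescaling
   by the LD-score intercept (chi-square on 1 df divided by the intercept),
   shared-SNP intersection across studies, exclusion of the extended MHC
   region (chr6:25652464–33771788), and strand-aware SNP-to-gene assignment
   with a 35 kb upstream / 10 kb downstream regulatory window.
2. **Gene scoring** (`gene_scoring`) — per-gene p-values from a combined
   top-SNP + mean-chi-square model adjusted for LD, converted to
   Z = Φ⁻¹(1 − p); a **competitive gene-set test**, the GLS regression
   Z = β₀ + β·1{gene ∈ set} + Γ·covariates, one-sided in β > 0, with gene
   size, SNP density and minor-allele-count covariates; BH, BY, Bonferroni
   and effective-test (Meff) Bonferroni corrections.
3. **Drug sets** (`drugsets`) — merge DGIdb-style and Ki-database-style
   interaction tables (Ki ≤ 10 µM) into one gene-set per drug, group drugs
   into ATC classes (≥ 10 drugs), and partition significant druggable genes
   by tier against the two Bonferroni cut-offs 0.05/4298 = 1.163×10⁻⁵
   (druggable genome) and 0.05/19870 = 2.516×10⁻⁶ (protein-coding genome).
4. **Class enrichment** (`enrichment`) — rank all scored gene-sets by
   −log₁₀(p), draw the enrichment curve for a class, and compute its
   trapezoidal **AUC**, identical to the normalized Wilcoxon–Mann–Whitney
   statistic: AUC = 100·U/(n₁n₂), 50% random, 100% perfect; significance
   by the one-sided WMW test, Bonferroni over the classes scanned.
5. **Pathway maps** (`pathway_maps`) — Tanimoto (Jaccard) kernel over
   gene-set contents, kernel-PCA embedding at the dimension capturing 99.5%
   of variance, a generative topographic map (k = √N grid, m = √k RBFs,
   l = 1, w = 1) fitted by EM, posterior-mean 2D projection, and an
   ordinary-kriging color surface in −log₁₀(p).
6. **Networks** (`networks`) — normalized degree (100·deg/(n−1)) and
   betweenness (100·2B/((n−1)(n−2))) for hub prioritization, drug-class
   target subgraphs (≥ 2 drugs per protein), pathway-core subgraphs
   (≥ 10 pathways per gene), and classification of significant genes
   against GWAS loci (35/10 kb overlap, 500/500 kb LD window, independent).
7. **Synthetic data** (`synthetic`) — seeded generators reproducing the
   statistical structure of all inputs (block-LD Z-scores, planted causal
   genes, a planted enriched ATC class, clustered pathway collections,
   random weighted PPI graphs), so the whole pipeline is testable offline.

## Worked example

Run the full pipeline on a synthetic study (400 genes, 10 SNPs/gene with
exchangeable LD ρ = 0.3, 5% causal genes shifted by Δ = 2, 120 drugs in 6
ATC classes with class N05A biased toward causal genes):

```python
from gwas2drug.pipeline import RunConfig, run
report = run(RunConfig(out_dir="demo_out", seed=42))
```

The report counts what survives each stage:

```
counts:
  causal_genes: 20
  snps_input: 4000
  snps_after_maf: 3962
  genes_scored: 400
  sets_tested: 160
  sets_bonferroni: 19
  classes_scanned: 6
  classes_significant: 1
```

and `demo_out/class_enrichment.tsv` holds the drug-class scan:

```
class  n_drugs   auc            p       p_bonf  significant
 N05A       20 99.70 1.316715e-12 7.900288e-12         True
  C02       20 52.90 3.427745e-01 1.000000e+00        False
  C01       20 41.45 8.864122e-01 1.000000e+00        False
  ...
```

The planted class N05A is recovered with AUC ≈ 99.7% (its drugs' gene-sets
rank almost entirely above the rest) and a WMW p far below the realized
Bonferroni threshold 0.05/6; the unplanted classes scatter around the
random expectation of 50%. The same run writes per-gene results
(`gene_results.tsv`), per-set competitive statistics with q-values
(`set_results.tsv`), 2D map coordinates for the top 50 sets
(`map_projection.tsv`) and PPI node metrics (`node_metrics.tsv`).

The same workflow is scriptable from the shell:

```sh
gwas2drug synth --seed 42 --out bundle/
gwas2drug prep --stats bundle/summary_stats.tsv --genes bundle/genes.tsv --out prep/
gwas2drug run --config config.yaml
```

## Documentation

The model, its assumptions, every tunable parameter, and known limitations
are described in [docs/methods.md](docs/methods.md).
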