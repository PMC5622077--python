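# Methods

## Scope and model overview

The package estimates whether groups of drugs (therapeutic classes) are
preferentially supported by GWAS signal, via three statistical layers: a
gene model that aggregates SNP associations into per-gene p-values, a
competitive gene-set regression that scores each drug's target set against
the gene universe, and an enrichment-curve AUC statistic over the ranked
sets that scores whole classes. Two descriptive layers — kernel-GTM maps
and PPI metrics — organize the results for interpretation.

## SNP preparation

Coordinates are 1-based inclusive everywhere. SNPs with MAF < 1% are
removed (boundary inclusive: MAF = 0.01 is kept). Inflation correction
converts each p to a 1-df chi-square quantile, divides by the LD-score
intercept, and converts back; intercepts below 1 are clamped to 1 with a
warning, since deflating test statistics would manufacture signal. SNPs are
assigned to every gene whose window contains them; the 35 kb/10 kb window
is strand-aware — "upstream" pads the 5′ side, which on the minus strand is
the high-coordinate side — because the window exists to capture regulatory
regions, which are defined relative to transcription, not to the reference
orientation. The extended MHC region is excluded with the same 35/10 kb
padding applied to genes, so that a gene just outside the region boundary
cannot be scored from MHC SNPs.

## Gene model

MAGMA-style gene analysis is approximated with a self-contained,
oracle-checkable model (bit-exact MAGMA replication is a non-goal):

* **Top component.** `p_top = 1 − (1 − min p)^Meff`, a Šidák correction at
  the effective number of independent SNPs. Meff is the smallest count of
  leading eigenvalues of the gene's LD correlation matrix R whose sum
  reaches 99.5% of the trace — the same rule used for the feature dimension
  of the maps and for effective-test Bonferroni corrections, so one
  definition serves all three uses.
* **Mean component.** `T = Σ z_i²` has null distribution `Σ λ_j χ²₁` with
  λ the eigenvalues of R. The tail is evaluated by Satterthwaite moment
  matching: a scaled chi-square with scale `Σλ²/Σλ` and
  `(Σλ)²/Σλ²` degrees of freedom. This is exact when the λ are equal
  (independent SNPs, or perfect LD where it collapses to a single SNP) and
  a two-moment approximation otherwise.
* **Combination.** The two probit scores `Φ⁻¹(1−p)` are combined Stouffer
  style, `z = (z_top + z_mean)/√(2+2ρ)`, where ρ is the null correlation of
  the two scores under `Z ~ MVN(0, R)`, estimated once per distinct R by
  1000 seeded Monte-Carlo draws (cached, so a study whose genes share an LD
  structure pays the cost once). Probit scores saturate at |z| ≤ 37 to
  avoid infinities at machine-precision p-values.

The gene Z used downstream is `Φ⁻¹(1 − p_combined)`.

## Competitive gene-set test

GLS regression of gene Z on set membership plus covariates, with error
covariance given by an inter-gene correlation matrix (identity by default,
i.e. OLS; estimating gene-gene correlation from an LD reference panel is
out of scope). Covariates are gene size, SNP density, the logs of both,
and a log minor-allele-count proxy (n_snps × mean MAF); covariate columns
with zero variance (as arises when a design fixes SNP counts) are dropped
rather than declared collinear. The alternative is one-sided (β > 0,
enrichment only). A response with zero residual variance returns p = 1
with a warning rather than failing, so degenerate simulated universes do
not abort a scan. Significance reporting includes BH and BY q-values,
Bonferroni, and Bonferroni at a supplied effective test count.

## Enrichment AUC for drug classes

All scored sets are ranked by −log₁₀(p_competitive). For a class, the
enrichment curve plots the fraction of member sets ("hits") recovered
against the fraction of non-members passed (ROC convention — this choice
makes the trapezoidal area equal the normalized Wilcoxon–Mann–Whitney U
exactly, the identity the method relies on). Tied scores are processed as
blocks contributing diagonal segments, crediting ties 0.5 per pair. The
trapezoid is accumulated in integer arithmetic over tie blocks, so boundary
values (100% at perfect separation) are exact rather than
floating-point-approximate. Significance uses the one-sided WMW test
(exact enumeration for pooled n ≤ 20 without ties; otherwise the normal
approximation with tie and continuity corrections, via scipy), Bonferroni
over the number of classes actually scanned rather than any fixed count.

## Kernel-GTM pathway maps

Gene-sets are binary gene-content vectors compared by Tanimoto similarity
K_ij = |A∩B|/|A∪B|. The kernel is double-centered and eigendecomposed;
the feature dimension D is the number of nonnegative-eigenvalue components
reaching 99.5% of the variance, and the data are embedded at those
kernel-PCA coordinates (the embedding reproduces kernel-induced distances
at full D). A generative topographic map is then fitted: a k×k latent grid
on [−1,1]² with k = round(√N), an m×m RBF basis with m = round(√k) (both
floored at 2 — the square-root rules leave rounding unspecified, and a 1×1
grid would be degenerate), RBF width w × the center spacing, regularization
l = 1. Initialization maps the latent grid through the first two principal
axes of the embedding, making the fit deterministic; β is initialized to
the reciprocal of the mean squared distance between the initial projected
nodes and the data.

EM maximizes the penalized log-likelihood — the log-likelihood minus
(l/2)‖W‖² (bias row unpenalized), the MAP objective for a Gaussian prior
on the mapping weights. With l > 0 it is the penalized objective, not the
raw likelihood, that EM is guaranteed never to decrease; the model traces
both, converges on a relative penalized-objective change below 1e-6 (or
500 iterations), and treats a decrease beyond 1e-9 relative tolerance as
an internal error. Each set projects to the posterior mean of its
responsibilities over the grid — a convex combination of nodes, hence
inside [−1,1]². The map has no intrinsic orientation: only distances
between projections are meaningful, and all tests and downstream uses
respect that.

The color surface uses ordinary kriging with an exponential variogram
(nugget, sill, range) fitted by weighted least squares to the binned
empirical semivariogram, weights proportional to pair counts; duplicated
projection locations are averaged first, a constant color field
short-circuits to a constant surface, and a failed variogram fit falls
back to inverse-distance weighting, flagged in the output metadata. The
public surface function requires ≥ 3 distinct points; the low-level solver
accepts any n and is the one used to verify the two-point closed form.

## PPI metrics

Degree is normalized to the percentage of possible neighbors,
100·deg/(n−1); betweenness to the percentage of maximum pair coverage,
100·2B/((n−1)(n−2)), computed on unweighted topology (interaction scores
only gate edge inclusion, since there is no principled way to treat STRING
scores as path lengths). Hub flags default to >5% (degree) and >2.5%
(betweenness) and are configuration, not constants. Graphs with fewer than
three nodes report betweenness 0 with a warning. Locus classification is
exclusive and exhaustive: overlap (strand-aware 35/10 kb pad) takes
precedence over LD-window (symmetric 500 kb pad), which takes precedence
over independent.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all tests. Within a gene,
SNP Z-scores are multivariate normal with exchangeable correlation ρ
(default 0.3) — the simplest structure that exercises the Meff and
weighted-chi-square logic; genes are independent of each other. Defaults:
400 genes over 4 chromosomes with non-overlapping bodies of 5–60 kb,
10 SNPs per gene, 5% causal genes whose SNP means shift by Δ = 2, MAF
uniform on [0.005, 0.5] so the 1% filter always bites, 120 drugs of 5–30
genes in 6 ATC classes of ≥ 10 drugs, with the planted class drawing each
member gene from the causal set with probability 0.9, pathway collections
of 40 sets in 4 clusters built by swapping 10% of a template's genes, and
Erdős–Rényi PPI graphs with uniform scores on [0, 1000].

Not emulated: realistic human LD (long-range structure, varying block
sizes), real MAF spectra, gene-gene LD leakage across neighboring genes,
drug-target promiscuity structure, or STRING's score distribution. Tests
passing on this generator therefore demonstrate the statistical machinery
is correct and calibrated under its stated assumptions — not that the
pipeline reproduces any particular real-data finding. There is no
established null model for drug libraries; the comparison implied by
"unplanted classes" (uniformly sampled, size-matched sets) is this
package's choice of baseline.

## Numerical choices and tie-breaking

* p-values are clipped to [tiny, 1]; probit saturates at |z| = 37.
* Top-set selection breaks p-value ties by lexicographic set id, so runs
  are reproducible across hash orders.
* The competitive test names collinear design columns in its error; near-
  constant covariates are dropped silently only in the pipeline wrapper.
* All generators route randomness through `numpy` `SeedSequence`s derived
  from a single config seed; rerunning any stage with the same config is
  byte-identical.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen to exercise
every code path with stable statistics: 500 replicates of 1000 sets for
AUC calibration, 1000-replicate null simulations for the competitive and
WMW tests, 200 EM fits for the map-convergence property, and 20 pipeline
replicates for planted-class recovery. These sizes are the package's
standing definition of its own regression checks.

## Known limitations

* The gene model approximates the combined top/mean approach; it is not a
  reimplementation of MAGMA and will not match its p-values numerically.
* The Satterthwaite tail is a two-moment approximation; extreme tails of
  highly unequal eigenvalue spectra are less accurate than exact methods.
* The default identity inter-gene correlation understates dependence
  between physically close genes; a band correlation matrix can be
  supplied where that matters.
* Kernel-GTM equivalence with other k-GTM formulations is not claimed; the
  realization here is standard GTM on a kernel-PCA embedding.
* The Ki ≤ 10 µM activity cut-off and the ATC grouping level are
  conventions exposed as configuration, not assertions about any external
  database's curation rules.
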