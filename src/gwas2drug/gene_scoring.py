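"""Gene-level association scoring and the competitive gene-set test.

Gene p-values are computed from per-SNP summary statistics with a
self-contained gene model combining a top-SNP component and a mean-chi-square
component, both adjusted for linkage disequilibrium within the gene:

* top:      Sidak-style ``p = 1 - (1 - min p)^Meff``, where Meff is the
            effective number of independent SNPs (eigenvalue count capturing
            a fixed fraction of the LD matrix trace);
* mean:     ``T = sum z_i^2`` whose null is a weighted chi-square mixture
            with weights the eigenvalues of the LD matrix, evaluated by
            Satterthwaite moment matching;
* combined: Stouffer combination of the two probit scores with their null
            correlation estimated by seeded Monte-Carlo simulation.

Gene p-values are converted to Z via the probit and used as the response of
a competitive generalized-least-squares regression that asks whether genes
in a set are more associated than genes outside it, correcting for gene
size, SNP density and a minor-allele-count proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneResult",
    "SetResult",
    "meff",
    "gene_p_top",
    "gene_p_mean",
    "gene_p_combined",
    "score_gene",
    "probit_z",
    "competitive_set_test",
    "adjust_pvalues",
    "druggable_thresholds",
]

# probit(1-p) saturates here to avoid infinities at machine-precision p
_Z_CAP = 37.0


@dataclass
class GeneResult:
    gene_id: str
    n_snps: int
    p_top: float
    p_mean: float
    p_combined: float
    z: float


@dataclass
class SetResult:
    set_id: str
    n_genes_in_universe: int
    n_genes_in_set: int
    beta: float
    se: float
    p_competitive: float
    q_bh: float = np.nan
    q_by: float = np.nan
    p_bonf: float = np.nan


def probit_z(p: float) -> float:
    """Probit score ``Phi^-1(1 - p)``, capped at |z| <= 37."""
    z = stats.norm.isf(p)
    return float(np.clip(z, -_Z_CAP, _Z_CAP))


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    return R


def meff(R: np.ndarray, variance_fraction: float = 0.995) -> int:
    """Effective number of independent tests for a correlation matrix.

    The smallest number of leading eigenvalues whose cumulative sum reaches
    ``variance_fraction`` of the trace.  Identity gives the full dimension;
    perfect correlation gives 1.
    """
    R = _check_corr(R)
    lam = np.sort(np.linalg.eigvalsh(R))[::-1]
    lam = np.clip(lam, 0.0, None)
    target = variance_fraction * np.trace(R)
    csum = np.cumsum(lam)
    k = int(np.searchsorted(csum, target - 1e-12) + 1)
    return max(1, min(k, R.shape[0]))


def gene_p_top(snp_ps, R: np.ndarray) -> float:
    """Top-SNP gene p-value with a Sidak correction for Meff tests."""
    snp_ps = np.asarray(snp_ps, dtype=float)
    if snp_ps.size == 0:
        raise ValueError("gene has no SNPs")
    m = meff(R)
    pmin = snp_ps.min()
    # log1p formulation keeps precision for tiny pmin
    p = -np.expm1(m * np.log1p(-min(pmin, 1.0 - 1e-16)))
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def gene_p_mean(snp_zs, R: np.ndarray) -> float:
    """Mean-chi-square gene p-value under the LD-weighted chi-square null.

    T = sum z_i^2 has null distribution sum_j lambda_j chi2_1 with lambda the
    eigenvalues of R; the tail is evaluated by Satterthwaite moment matching
    (scaled chi-square with g = (sum lam)^2 / sum lam^2 degrees of freedom).
    """
    snp_zs = np.asarray(snp_zs, dtype=float)
    if snp_zs.size == 0:
        raise ValueError("gene has no SNPs")
    R = _check_corr(R)
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    s1, s2 = lam.sum(), (lam**2).sum()
    scale = s2 / s1
    g = s1**2 / s2
    T = float((snp_zs**2).sum())
    p = stats.chi2.sf(T / scale, g)
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


_rho_cache: dict[bytes, float] = {}


def _null_probit_correlation(R: np.ndarray, mc_draws: int, seed: int) -> float:
    """Null correlation between the top and mean probit scores, by simulation."""
    key = R.tobytes() + mc_draws.to_bytes(4, "little") + seed.to_bytes(4, "little", signed=True)
    if key in _rho_cache:
        return _rho_cache[key]
    rng = np.random.default_rng(seed)
    n = R.shape[0]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(n))
    Z = rng.standard_normal((mc_draws, n)) @ L.T
    P = 2.0 * stats.norm.sf(np.abs(Z))
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    m = meff(R)
    s1, s2 = lam.sum(), (lam**2).sum()
    pt = -np.expm1(m * np.log1p(-np.clip(P.min(axis=1), None, 1 - 1e-16)))
    pm = stats.chi2.sf((Z**2).sum(axis=1) / (s2 / s1), s1**2 / s2)
    zt = np.clip(stats.norm.isf(np.clip(pt, 1e-300, 1.0)), -_Z_CAP, _Z_CAP)
    zm = np.clip(stats.norm.isf(np.clip(pm, 1e-300, 1.0)), -_Z_CAP, _Z_CAP)
    rho = float(np.corrcoef(zt, zm)[0, 1]) if zt.std() > 0 and zm.std() > 0 else 1.0
    rho = float(np.clip(rho, -0.999, 1.0))
    _rho_cache[key] = rho
    return rho


def gene_p_combined(
    p_top: float,
    p_mean: float,
    R: np.ndarray,
    mc_draws: int = 1000,
    seed: int = 0,
    rho: float | None = None,
) -> float:
    """Stouffer combination of the top and mean models.

    The two probit scores are summed and standardized by ``sqrt(2 + 2 rho)``
    where rho is their null correlation, estimated by ``mc_draws`` seeded
    Monte-Carlo draws of SNP Z-scores from MVN(0, R) unless supplied.
    """
    if mc_draws < 100:
        warnings.warn("mc_draws < 100 gives an unstable null correlation estimate")
    if rho is None:
        rho = _null_probit_correlation(np.asarray(R, dtype=float), mc_draws, seed)
    zt, zm = probit_z(p_top), probit_z(p_mean)
    z = (zt + zm) / np.sqrt(2.0 + 2.0 * rho)
    p = stats.norm.sf(z)
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def score_gene(
    gene_id: str,
    snp_ps,
    snp_zs,
    R: np.ndarray,
    mc_draws: int = 1000,
    seed: int = 0,
) -> GeneResult:
    """Compute all gene-level statistics for one gene."""
    pt = gene_p_top(snp_ps, R)
    pm = gene_p_mean(snp_zs, R)
    pc = gene_p_combined(pt, pm, R, mc_draws=mc_draws, seed=seed)
    return GeneResult(
        gene_id=gene_id,
        n_snps=int(np.asarray(snp_ps).size),
        p_top=pt,
        p_mean=pm,
        p_combined=pc,
        z=probit_z(pc),
    )


def default_covariates(gene_table: pd.DataFrame) -> np.ndarray:
    """Standard competitive-test covariates: gene size, SNP density, their
    logs, and a log minor-allele-count proxy (n_snps x mean MAF)."""
    size = (gene_table["end"] - gene_table["start"] + 1).to_numpy(float)
    nsnps = gene_table["n_snps"].to_numpy(float)
    density = nsnps / size
    if "mean_maf" in gene_table:
        mac = np.log(np.clip(nsnps * gene_table["mean_maf"].to_numpy(float), 1e-12, None))
    else:
        mac = np.log(np.clip(nsnps, 1e-12, None))
    return np.column_stack([size, np.log(size), density, np.log(density), mac])


def competitive_set_test(
    gene_z: np.ndarray,
    membership: np.ndarray,
    covariates: np.ndarray | None = None,
    gene_corr: np.ndarray | None = None,
    set_id: str = "",
) -> SetResult:
    """Competitive GLS regression of gene Z on set membership.

    Fits ``Z = b0 + beta * membership + Gamma * covariates`` with error
    covariance ``gene_corr`` (identity by default, i.e. OLS) and returns the
    one-sided p-value for ``beta > 0`` — enrichment of association inside
    the set relative to the rest of the gene universe.
    """
    z = np.asarray(gene_z, dtype=float)
    s = np.asarray(membership, dtype=float)
    n = z.size
    if s.sum() == 0 or s.sum() == n:
        raise ValueError("set empty or equals universe")
    cols = [np.ones(n), s]
    names = ["intercept", "set"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        for j in range(C.shape[1]):
            cols.append(C[:, j])
            names.append(f"cov{j}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column by greedy rank check
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"singular design: collinear columns {bad}")
    if gene_corr is not None:
        L = np.linalg.cholesky(np.asarray(gene_corr, dtype=float))
        X = np.linalg.solve(L, X)
        z = np.linalg.solve(L, z)
    beta_hat, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta_hat
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= np.finfo(float).eps * max(1.0, float(z @ z)):
        warnings.warn(f"zero-variance response for set {set_id!r}; p set to 1")
        return SetResult(set_id, n, int(s.sum()), 0.0, 0.0, 1.0)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(beta_hat[1])
    t = beta / se
    p = float(stats.t.sf(t, dof))
    return SetResult(set_id, n, int(s.sum()), beta, se, p)


def adjust_pvalues(ps, method: str = "bh", meff: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment.

    ``bh``/``by`` are the Benjamini-Hochberg and Benjamini-Yekutieli step-up
    procedures; ``bonferroni`` is ``min(1, m p)``; ``bonferroni_meff``
    replaces the nominal test count m with a supplied effective number of
    independent tests.
    """
    ps = np.asarray(ps, dtype=float)
    if method == "bonferroni_meff":
        if meff is None:
            raise ValueError("bonferroni_meff requires meff")
        return np.minimum(1.0, ps * meff)
    mapping = {"bonferroni": "bonferroni", "bh": "fdr_bh", "by": "fdr_by"}
    if method not in mapping:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(ps, method=mapping[method])[1]


def druggable_thresholds(
    n_druggable: int, n_protein_coding: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Bonferroni significance cut-offs for the druggable genome and for the
    whole protein-coding genome (``alpha / n`` for each count)."""
    if n_druggable < 1 or n_protein_coding < 1:
        raise ValueError("counts must be >= 1")
    return alpha / n_druggable, alpha / n_protein_coding


def annotate_set_results(results: list[SetResult]) -> pd.DataFrame:
    """Attach BH/BY q-values and Bonferroni-adjusted p-values to a scan."""
    ps = np.array([r.p_competitive for r in results])
    qbh = adjust_pvalues(ps, "bh")
    qby = adjust_pvalues(ps, "by")
    pbf = adjust_pvalues(ps, "bonferroni")
    for r, a, b, c in zip(results, qbh, qby, pbf):
        r.q_bh, r.q_by, r.p_bonf = float(a), float(b), float(c)
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "n_genes": [r.n_genes_in_set for r in results],
            "beta": [r.beta for r in results],
            "p_competitive": [r.p_competitive for r in results],
            "q_bh": [r.q_bh for r in results],
            "q_by": [r.q_by for r in results],
            "p_bonf": [r.p_bonf for r in results],
        }
    )
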