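"""Enrichment-curve AUC statistics for groups of gene-sets.

A therapeutic class (e.g. an ATC code) is a group of drugs, each drug being a
gene-set scored by its competitive association p-value.  The class is judged
enriched when its member drugs ("hits") rank high in the score
``-log10(p_competitive)`` relative to all other scored drugs ("non-hits").
The enrichment curve tracks the fraction of hits recovered as the ranked list
is descended; its trapezoidal area (as a percentage) equals the normalized
Wilcoxon-Mann-Whitney U statistic, ``AUC = 100 * U / (n_hits * n_nonhits)``,
with 50% the random expectation and 100% perfect separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedSets",
    "EnrichmentResult",
    "enrichment_curve",
    "auc",
    "wmw_pvalue",
    "class_enrichment_scan",
]


@dataclass
class RankedSets:
    """Gene-sets sorted by association score with hit labels for one class.

    ``scores`` are association strengths in -log10(p) units (higher = more
    associated); ``hits`` flags membership of the class under test.
    """

    set_ids: list[str]
    scores: np.ndarray
    hits: np.ndarray  # boolean, aligned with set_ids

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.hits = np.asarray(self.hits, dtype=bool)
        if self.scores.shape != self.hits.shape:
            raise ValueError("scores and hits must be aligned")
        order = np.argsort(-self.scores, kind="stable")
        self.set_ids = [self.set_ids[i] for i in order]
        self.scores = self.scores[order]
        self.hits = self.hits[order]

    @property
    def n_hits(self) -> int:
        return int(self.hits.sum())

    @property
    def n_nonhits(self) -> int:
        return int((~self.hits).sum())


@dataclass
class EnrichmentResult:
    class_code: str
    n_hits: int
    n_nonhits: int
    auc: float  # percentage in [0, 100]
    u_statistic: float
    p_wmw: float
    p_bonf: float = field(default=np.nan)
    significant: bool = field(default=False)


def _as_ranked(ranked: RankedSets | tuple) -> RankedSets:
    if isinstance(ranked, RankedSets):
        return ranked
    scores, hits = ranked
    scores = np.asarray(scores, dtype=float)
    return RankedSets([str(i) for i in range(scores.size)], scores, hits)


def enrichment_curve(ranked: RankedSets) -> np.ndarray:
    """Stepwise hit-recovery curve over the ranked list.

    Returns an (n_points, 2) array of (x, y) vertices where x is the fraction
    of non-hits passed and y the fraction of hits found, from (0, 0) to
    (1, 1).  Groups of tied scores are processed as a block and contribute a
    single diagonal segment, so the trapezoidal area credits ties 0.5 per
    hit/non-hit pair, matching the Wilcoxon-Mann-Whitney convention.
    """
    ranked = _as_ranked(ranked)
    n1, n2 = ranked.n_hits, ranked.n_nonhits
    if n1 == 0:
        raise ValueError("enrichment curve requires at least one hit")
    ch, cn = _tie_blocks(ranked)
    x = cn / n2 if n2 else np.zeros_like(cn, dtype=float)
    y = ch / n1
    return np.column_stack([x, y])


def _tie_blocks(ranked: RankedSets) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative hit / non-hit counts at the tie-block boundaries,
    starting from (0, 0)."""
    # block boundaries = positions where the sorted score changes
    change = np.flatnonzero(np.diff(ranked.scores)) + 1
    ends = np.r_[change, ranked.scores.size]
    cum_hits = np.cumsum(ranked.hits)
    ch = np.r_[0, cum_hits[ends - 1]]
    cn = np.r_[0, ends - cum_hits[ends - 1]]
    return ch, cn


def auc(ranked: RankedSets) -> float:
    """Trapezoidal area under the enrichment curve, as a percentage.

    Equals ``100 * U / (n_hits * n_nonhits)`` with tied hit/non-hit pairs
    credited 0.5 in U.
    """
    ranked = _as_ranked(ranked)
    n1, n2 = ranked.n_hits, ranked.n_nonhits
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC requires at least one hit and one non-hit")
    ch, cn = _tie_blocks(ranked)
    # trapezoid rule on the curve vertices, accumulated in integer
    # arithmetic so boundary cases (perfect separation) are exact:
    # sum dx*(y0+y1)/2 = sum (dn/n2)*(ch0+ch1)/(2*n1)
    num = int(np.sum(np.diff(cn) * (ch[:-1] + ch[1:])))
    return float(100.0 * num / (2 * n1 * n2))


def u_statistic(hit_scores, nonhit_scores) -> float:
    """Mann-Whitney U for hits vs non-hits (ties credited 0.5)."""
    hit_scores = np.asarray(hit_scores, dtype=float)
    nonhit_scores = np.asarray(nonhit_scores, dtype=float)
    pooled = np.concatenate([hit_scores, nonhit_scores])
    ranks = stats.rankdata(pooled)
    n1 = hit_scores.size
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def wmw_pvalue(hit_scores, nonhit_scores, alternative: str = "greater") -> float:
    """One-sided Wilcoxon-Mann-Whitney p-value that hits score higher.

    Exact enumeration when the pooled sample is small (n1+n2 <= 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    hit_scores = np.asarray(hit_scores, dtype=float)
    nonhit_scores = np.asarray(nonhit_scores, dtype=float)
    if hit_scores.size == 0 or nonhit_scores.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([hit_scores, nonhit_scores])
    small = pooled.size <= 20
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        hit_scores, nonhit_scores, alternative=alternative, method=method
    )
    return float(res.pvalue)


def class_enrichment_scan(
    set_results: pd.DataFrame,
    classes: dict[str, list[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Scan therapeutic classes for enrichment among scored gene-sets.

    Parameters
    ----------
    set_results
        DataFrame with columns ``set_id`` and ``p_competitive`` (one row per
        scored drug/gene-set).
    classes
        Mapping of class code to member set_ids (e.g. ATC classes).
    alpha
        Familywise error rate; the Bonferroni threshold is ``alpha`` divided
        by the number of classes actually scanned.
    """
    scores = dict(
        zip(
            set_results["set_id"],
            -np.log10(np.clip(set_results["p_competitive"].to_numpy(float), 1e-300, 1.0)),
        )
    )
    all_ids = list(scores)
    scanned: list[tuple[str, np.ndarray, np.ndarray]] = []
    for code, members in classes.items():
        member_set = {m for m in members if m in scores}
        if not member_set or len(member_set) == len(all_ids):
            warnings.warn(f"class {code} has no scored members (or is the whole universe); skipped")
            continue
        hit = np.array([scores[s] for s in member_set])
        non = np.array([scores[s] for s in all_ids if s not in member_set])
        scanned.append((code, hit, non))
    n_classes = len(scanned)
    results = []
    for code, hit, non in scanned:
        u = u_statistic(hit, non)
        a = 100.0 * u / (hit.size * non.size)
        p = wmw_pvalue(hit, non)
        p_bonf = min(1.0, p * n_classes)
        results.append(
            EnrichmentResult(
                class_code=code,
                n_hits=hit.size,
                n_nonhits=non.size,
                auc=a,
                u_statistic=u,
                p_wmw=p,
                p_bonf=p_bonf,
                significant=bool(p <= alpha / n_classes),
            )
        )
    results.sort(key=lambda r: r.p_wmw)
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.class_code for r in results],
            "n_drugs": [r.n_hits for r in results],
            "auc": [r.auc for r in results],
            "p": [r.p_wmw for r in results],
            "p_bonf": [r.p_bonf for r in results],
            "significant": [r.significant for r in results],
        }
    )
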