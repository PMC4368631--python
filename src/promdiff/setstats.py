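"""Gene-set over-representation and group-vs-background comparisons.

Over-representation of a gene set inside a cluster is scored with the
upper-tail hypergeometric probability P(X >= observed overlap) where X
counts set members among ``cluster size`` draws without replacement from
the universe of quantified genes. Benjamini-Hochberg adjustment across
sets is available. The distributional comparison of a gene group's log2
fold changes against the whole-genome background uses the two-sample
Mann-Whitney U test (exact when small and tie-free, otherwise the normal
approximation with tie and continuity corrections); a paired t-test is
provided for paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSet, ValidationError

__all__ = [
    "hypergeom_enrichment",
    "bh_adjust",
    "mannwhitney_compare",
    "paired_t_compare",
    "GroupComparisonResult",
]

EXACT_MW_LIMIT = 400  # max n1*n2 for exact Mann-Whitney enumeration


def hypergeom_enrichment(
    cluster_genes: Iterable[str],
    gene_sets: Mapping[str, GeneSet],
    universe_genes: Iterable[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a cluster.

    The universe is the quantified-gene background; sets are intersected
    with it before testing, and the cluster must be a subset of it.
    Returns a DataFrame sorted by p with overlap counts, p, optional
    BH-adjusted p and -log10(p).
    """
    universe = set(universe_genes)
    cluster = set(cluster_genes)
    if not universe:
        raise ValidationError("empty universe")
    if not cluster:
        raise ValidationError("empty cluster")
    if not cluster <= universe:
        raise ValidationError(
            f"cluster contains genes outside the universe: {sorted(cluster - universe)[:5]}"
        )
    n_universe, n_cluster = len(universe), len(cluster)
    rows = []
    for name, gs in gene_sets.items():
        in_universe = gs.genes & universe
        overlap = len(in_universe & cluster)
        k_set = len(in_universe)
        # P(X >= overlap), X ~ Hypergeom(N=n_universe, K=k_set, n=n_cluster)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_set, n_cluster))
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "cluster_size": n_cluster,
                "set_size": k_set,
                "universe_size": n_universe,
                "pval": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_set")
    if adjust and len(df):
        df["padj"] = bh_adjust(df["pval"].to_numpy())
    df["neg_log10_p"] = -np.log10(df["pval"])
    return df.sort_values("pval")


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(slots=True)
class GroupComparisonResult:
    test: str
    statistic: float
    pvalue: float
    n_group: int
    n_background: int
    median_group: float
    median_background: float


def mannwhitney_compare(
    group_values: Sequence[float] | np.ndarray,
    background_values: Sequence[float] | np.ndarray,
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U comparison of a gene group vs background.

    The exact null distribution is enumerated when n1*n2 <= 400 and there
    are no ties; otherwise the normal approximation with mid-rank tie
    correction and continuity correction is used.
    """
    x = np.asarray(group_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size * y.size <= EXACT_MW_LIMIT and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparisonResult(
        test=f"mannwhitney_{method}",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_group=x.size,
        n_background=y.size,
        median_group=float(np.median(x)),
        median_background=float(np.median(y)),
    )


def paired_t_compare(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
) -> GroupComparisonResult:
    """Two-sided paired t-test for matched measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValidationError("paired test needs two equal-length samples of size >= 2")
    res = stats.ttest_rel(a, b)
    return GroupComparisonResult(
        test="paired_t",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_group=a.size,
        n_background=b.size,
        median_group=float(np.median(a)),
        median_background=float(np.median(b)),
    )
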