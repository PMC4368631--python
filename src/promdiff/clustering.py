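"""Hierarchical clustering of significant promoters into chromatin-state groups.

Selected genes are clustered on their per-mark log2 fold-change vectors
(Euclidean distance, complete linkage). The agglomeration is written out
explicitly so tie-breaking is deterministic (among equally distant pairs
the lowest index pair merges first) and the merge heights are directly
comparable to a naive O(n^3) reference. Cut clusters are labeled by the
joint direction of their active (H3K4me3, H3K9ac) and repressive
(H3K27me3) marks: "silenced" (active down, repressive up), "active"
(active up, repressive down), "poised_up"/"poised_down" (all concordant)
or "mixed".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, MetaProfile, meta_profile
from .differential import normalized_counts
from .io_formats import ValidationError
from .promoters import PromoterCountMatrix

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "zscale_counts",
    "hier_cluster",
    "cut_clusters",
    "classify_cluster_phenotype",
    "cluster_summary",
    "cluster_meta_profiles",
]

DEFAULT_ACTIVE_MARKS = frozenset({"H3K4me3", "H3K9ac"})
DEFAULT_REPRESSIVE_MARKS = frozenset({"H3K27me3"})


def zscale_counts(matrix: PromoterCountMatrix, factors: np.ndarray) -> pd.DataFrame:
    """Row-wise z-scores of size-factor-normalized promoter counts.

    Each gene's normalized counts are centered and scaled to unit standard
    deviation (n-1 denominator); constant rows become all zeros. Used for
    heatmap display, not for clustering.
    """
    z = normalized_counts(matrix.counts, factors)
    mean = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (z - mean) / sd
    scaled = np.where(sd > 0, scaled, 0.0)
    return pd.DataFrame(scaled, index=pd.Index(matrix.gene_ids, name="gene_id"),
                        columns=matrix.sample_ids)


def group_average(z: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Average z-scores within patient and control groups (heatmap columns)."""
    out = {}
    for g in ("patient", "control"):
        cols = [s for s in z.columns if groups[s] == g]
        out[g] = z[cols].mean(axis=1)
    return pd.DataFrame(out)


@dataclass(slots=True)
class Dendrogram:
    """Agglomerative merge sequence over n leaves.

    ``merges`` holds (cluster_a, cluster_b, height) triples; leaves are
    numbered 0..n-1 and the cluster formed by merge k gets id n + k, as in
    the usual linkage encoding. ``leaf_order`` is the left-to-right order a
    dendrogram plot would show.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def leaf_order(self) -> list[int]:
        members: dict[int, list[int]] = {i: [i] for i in range(self.n_leaves)}
        for k, (a, b, _h) in enumerate(self.merges):
            members[self.n_leaves + k] = members.pop(a) + members.pop(b)
        order: list[int] = []
        for leaves in members.values():
            order.extend(leaves)
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height"])


def hier_cluster(
    data: np.ndarray | pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering with complete linkage on a Euclidean distance matrix.

    D(A, B) is the maximum pairwise distance between members; at every step
    the closest active pair merges, lowest pair index first on ties, so the
    result is fully deterministic. Heights are non-decreasing.
    """
    if metric != "euclidean":
        raise ValidationError(f"unsupported metric {metric!r}")
    if linkage != "complete":
        raise ValidationError(f"unsupported linkage {linkage!r}")
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("clustering needs a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValidationError("clustering input must be finite")
    n = X.shape[0]
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    ids = np.arange(n)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = np.where(active)[0]
        Dsub = D[np.ix_(sub, sub)]
        iu = np.triu_indices(sub.size, k=1)
        flat = Dsub[iu]
        k = int(np.argmin(flat))  # first minimum = lowest (i, j) in row-major order
        i, j = sub[iu[0][k]], sub[iu[1][k]]
        h = float(D[i, j])
        merges.append((int(ids[i]), int(ids[j]), h))
        # complete linkage: new distances are pairwise maxima
        new_row = np.maximum(D[i], D[j])
        D[i] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        active[j] = False
        D[j] = np.inf
        D[:, j] = np.inf
        ids[i] = n + step
    return Dendrogram(n_leaves=n, merges=merges)


@dataclass(slots=True)
class ClusterAssignment:
    """Flat clusters from a dendrogram cut: ids contiguous from 1, in leaf order."""

    labels: pd.Series  # gene/row -> cluster id
    k: int

    def members(self, cluster_id: int) -> list:
        return self.labels.index[self.labels == cluster_id].tolist()

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cut_clusters(
    dendrogram: Dendrogram, k: int, index: Sequence | None = None
) -> ClusterAssignment:
    """Cut the merge sequence so exactly k flat clusters remain.

    Cluster ids are assigned 1..k following the dendrogram leaf order.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h) in enumerate(dendrogram.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    raw = np.empty(n, dtype=int)
    for leaf in dendrogram.leaf_order:
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        raw[leaf] = roots[r]
    idx = pd.Index(index if index is not None else np.arange(n))
    return ClusterAssignment(labels=pd.Series(raw, index=idx, name="cluster"), k=k)


def classify_cluster_phenotype(
    mark_means: Mapping[str, float],
    active_marks: frozenset[str] | set[str] = DEFAULT_ACTIVE_MARKS,
    repressive_marks: frozenset[str] | set[str] = DEFAULT_REPRESSIVE_MARKS,
    magnitude_threshold: float = 0.5,
) -> str:
    """Label a cluster by the direction of its per-mark mean log2FCs.

    silenced: all active marks <= -t and all repressive >= +t;
    active: the mirror image; poised_up / poised_down: every mark moves
    the same way by >= t; anything else is mixed.
    """
    marks = set(mark_means)
    assigned = set(active_marks) | set(repressive_marks)
    if marks - assigned or (set(active_marks) & set(repressive_marks)):
        raise ValidationError(
            "every mark must belong to exactly one of active/repressive: "
            f"unassigned {sorted(marks - assigned)}"
        )
    t = magnitude_threshold
    act = [mark_means[m] for m in mark_means if m in active_marks]
    rep = [mark_means[m] for m in mark_means if m in repressive_marks]
    allv = list(mark_means.values())
    if act and rep and all(v <= -t for v in act) and all(v >= t for v in rep):
        return "silenced"
    if act and rep and all(v >= t for v in act) and all(v <= -t for v in rep):
        return "active"
    if all(v >= t for v in allv):
        return "poised_up"
    if all(v <= -t for v in allv):
        return "poised_down"
    return "mixed"


def cluster_summary(
    fold_changes: pd.DataFrame,
    assignment: ClusterAssignment,
    active_marks: frozenset[str] | set[str] = DEFAULT_ACTIVE_MARKS,
    repressive_marks: frozenset[str] | set[str] = DEFAULT_REPRESSIVE_MARKS,
    magnitude_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster size, per-mark mean log2FC and phenotype label."""
    rows = []
    for cid in range(1, assignment.k + 1):
        members = assignment.members(cid)
        sub = fold_changes.loc[members]
        means = sub.mean(axis=0).to_dict()
        label = classify_cluster_phenotype(
            means, active_marks, repressive_marks, magnitude_threshold
        )
        rows.append({"cluster": cid, "size": len(members), **{f"mean_log2FC_{m}": v for m, v in means.items()}, "phenotype": label})
    return pd.DataFrame(rows).set_index("cluster")


def cluster_meta_profiles(
    cluster_genes: Sequence[str],
    tracks_by_sample: Mapping[str, CoverageTrack],
    tss_by_gene: Mapping[str, tuple[str, int, str]],
    groups: Mapping[str, str],
    flank_bp: int = 2000,
    bin_bp: int = 50,
) -> MetaProfile:
    """Average TSS profile over a cluster's genes, one curve per group."""
    if not cluster_genes:
        raise ValidationError("empty cluster")
    sites = [tss_by_gene[g] for g in cluster_genes]
    per_sample = meta_profile(tracks_by_sample, sites, flank_bp, bin_bp)
    out: dict[str, np.ndarray] = {}
    for g in sorted(set(groups.values())):
        members = [s for s in tracks_by_sample if groups[s] == g]
        out[g] = np.mean([per_sample.profiles[s] for s in members], axis=0)
    return MetaProfile(per_sample.bin_centers, out, per_sample.n_sites)
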