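"""Cluster the selected promoters on their per-mark log2FC vectors.

Complete-linkage hierarchical clustering on the Euclidean distances of
the 3-mark fold-change vectors, cut at k = 4, with each cluster labeled
silenced / active / poised / mixed from its per-mark mean log2FC. Writes
cluster assignments, the per-cluster summary and the group-averaged
z-scaled heatmap matrix to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from _common import MARKS, RESULTS, SAMPLES, SCRATCH, ensure_dirs

from promdiff.clustering import (
    cluster_summary,
    cut_clusters,
    group_average,
    hier_cluster,
    zscale_counts,
)
from promdiff.differential import size_factors
from promdiff.promoters import PromoterCountMatrix

K = 4


def main() -> None:
    ensure_dirs()
    truth = pd.read_csv(SCRATCH / "data" / "truth.tsv", sep="\t", index_col="gene_id")
    sig = pd.read_csv(SCRATCH / "significance.tsv", sep="\t", index_col="gene_id")
    selected = sig.index[sig["selected"]].tolist()
    tables = {
        m: pd.read_csv(SCRATCH / f"diff_{m}.tsv", sep="\t", index_col="gene_id")
        for m in MARKS
    }
    fc = pd.DataFrame({m: tables[m].loc[selected, "log2FC"] for m in MARKS})

    dendro = hier_cluster(fc.to_numpy())
    assignment = cut_clusters(dendro, min(K, len(selected)), index=fc.index)
    summary = cluster_summary(fc, assignment)

    out = assignment.labels.to_frame()
    out["phenotype"] = summary.loc[assignment.labels, "phenotype"].to_numpy()
    out = out.join(truth["archetype"])
    out.to_csv(RESULTS / "cluster_assignments.tsv", sep="\t")
    summary.round(3).to_csv(RESULTS / "cluster_summary.tsv", sep="\t")

    heat = {}
    for mark in MARKS:
        mat = PromoterCountMatrix.from_tsv(
            SCRATCH / f"counts_{mark}.tsv", SCRATCH / "samples.tsv", mark
        )
        z = zscale_counts(mat, size_factors(mat.counts)).loc[selected]
        ga = group_average(z, SAMPLES)
        heat[f"{mark}_patient"] = ga["patient"].round(4)
        heat[f"{mark}_control"] = ga["control"].round(4)
    pd.DataFrame(heat).to_csv(RESULTS / "heatmap_zscores.tsv", sep="\t")

    print(summary.round(2).to_string())
    agreement = pd.crosstab(out["phenotype"], out["archetype"])
    print("\nphenotype label vs implanted archetype:")
    print(agreement.to_string())


if __name__ == "__main__":
    main()
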