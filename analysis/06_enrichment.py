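"""Gene-set over-representation per cluster and a group-vs-background test.

Builds demo gene sets against the simulated universe: an
"antigen-presentation-like" set that overlaps the implanted silenced
genes (standing in for the MHC/HLA gene group), an "immune-response-like"
set overlapping the active genes, and random control sets. Each cluster
is tested for over-representation with the upper-tail hypergeometric
test (BH-adjusted across sets); the silenced-like group's active-mark
log2FCs are compared against all genes with the Mann-Whitney U test.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from _common import MARKS, RESULTS, SCRATCH, ensure_dirs

from promdiff.io_formats import GeneSet, write_gmt
from promdiff.setstats import hypergeom_enrichment, mannwhitney_compare


def build_demo_sets(truth: pd.DataFrame, rng: np.random.Generator) -> dict[str, GeneSet]:
    """Synthetic gene sets keyed to the simulation ground truth."""
    silenced = list(truth.index[truth["archetype"] == "silenced"])
    active = list(truth.index[truth["archetype"] == "active"])
    background = list(truth.index[truth["archetype"] == "unchanged"])
    sets = {
        "ANTIGEN_PRESENTATION_LIKE": GeneSet(
            "ANTIGEN_PRESENTATION_LIKE", "synthetic: overlaps silenced implants",
            frozenset(silenced[: max(3, len(silenced) * 3 // 4)]
                      + list(rng.choice(background, size=5, replace=False))),
        ),
        "IMMUNE_RESPONSE_LIKE": GeneSet(
            "IMMUNE_RESPONSE_LIKE", "synthetic: overlaps active implants",
            frozenset(active[: max(3, len(active) * 3 // 4)]
                      + list(rng.choice(background, size=5, replace=False))),
        ),
    }
    for i in range(3):
        members = rng.choice(truth.index, size=15, replace=False)
        sets[f"RANDOM_{i}"] = GeneSet(f"RANDOM_{i}", "synthetic: random control", frozenset(members))
    return sets


def main() -> None:
    ensure_dirs()
    truth = pd.read_csv(SCRATCH / "data" / "truth.tsv", sep="\t", index_col="gene_id")
    assignments = pd.read_csv(RESULTS / "cluster_assignments.tsv", sep="\t", index_col="gene_id")
    rng = np.random.default_rng(4242)
    sets = build_demo_sets(truth, rng)
    write_gmt(sets, SCRATCH / "demo_sets.gmt")
    universe = truth.index.tolist()

    frames = []
    for cid, sub in assignments.groupby("cluster"):
        enr = hypergeom_enrichment(sub.index.tolist(), sets, universe)
        enr.insert(0, "cluster", cid)
        enr.insert(1, "phenotype", sub["phenotype"].iloc[0])
        frames.append(enr.reset_index())
    enrichment = pd.concat(frames, ignore_index=True)
    enrichment.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

    hits = enrichment[enrichment["padj"] <= 0.05]
    print("significant over-representations (BH <= 0.05):")
    print(hits[["cluster", "phenotype", "gene_set", "overlap", "pval", "padj"]].to_string(index=False))

    group = sets["ANTIGEN_PRESENTATION_LIKE"].genes
    rows = []
    for mark in MARKS:
        lfc = pd.read_csv(SCRATCH / f"diff_{mark}.tsv", sep="\t", index_col="gene_id")["log2FC"]
        res = mannwhitney_compare(lfc[lfc.index.isin(group)], lfc)
        rows.append({
            "mark": mark, "test": res.test, "U": res.statistic, "pval": res.pvalue,
            "median_group": round(res.median_group, 3),
            "median_background": round(res.median_background, 3),
        })
    comparison = pd.DataFrame(rows)
    comparison.to_csv(RESULTS / "group_comparison.tsv", sep="\t", index=False)
    print("\nantigen-presentation-like group vs all genes (Mann-Whitney):")
    print(comparison.to_string(index=False))


if __name__ == "__main__":
    main()
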