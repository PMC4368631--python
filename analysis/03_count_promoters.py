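"""Count deduplicated reads in +-1 kb promoter windows, per mark.

Writes one genes x samples count matrix per mark to scratch/analysis and
a per-sample summary (column totals, fraction of the library falling in
promoters) to results/count_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from _common import MARKS, RESULTS, SAMPLES, SCRATCH, ensure_dirs

from promdiff.coverage import deduplicate_reads
from promdiff.io_formats import read_annotation, read_bed_reads, read_chrom_sizes
from promdiff.promoters import assemble_count_matrix, count_reads_in_windows, promoter_windows


def main() -> None:
    ensure_dirs()
    data = SCRATCH / "data"
    sizes = read_chrom_sizes(data / "chrom.sizes")
    genes = read_annotation(data / "annotation.tsv")
    windows = promoter_windows(genes, sizes)

    rows = []
    for mark in MARKS:
        per_sample = {}
        for sid in SAMPLES:
            reads = deduplicate_reads(read_bed_reads(data / f"{mark}_{sid}.bed"))
            per_sample[sid] = count_reads_in_windows(reads, windows)
            rows.append({
                "mark": mark, "sample": sid,
                "reads_after_dedup": len(reads),
                "promoter_reads": int(per_sample[sid].sum()),
                "promoter_fraction": round(per_sample[sid].sum() / len(reads), 4),
            })
        mat = assemble_count_matrix(per_sample, [w.gene_id for w in windows], mark, SAMPLES)
        mat.to_tsv(SCRATCH / f"counts_{mark}.tsv", SCRATCH / "samples.tsv")
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "count_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\ncounted {len(windows)} promoters; matrices under {SCRATCH}")


if __name__ == "__main__":
    main()
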