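"""Promoter windows and gene x sample read-count matrices.

The promoter of a gene is the fixed window around its TSS (default -1 kb /
+1 kb). Windows are strand-aware: upstream/downstream are measured along
the direction of transcription, so a minus-strand gene's window mirrors a
plus-strand one under genome reflection.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignedRead, GeneRecord, GenomicInterval, ValidationError

__all__ = [
    "PromoterWindow",
    "PromoterCountMatrix",
    "promoter_windows",
    "count_reads_in_windows",
    "assemble_count_matrix",
]

COUNT_MODES = ("read_5prime", "fragment_overlap")


@dataclass(frozen=True, slots=True)
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval
    tss: int


def promoter_windows(
    genes: Iterable[GeneRecord],
    chrom_sizes: Mapping[str, int],
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
) -> list[PromoterWindow]:
    """Strand-aware promoter windows around each TSS, clipped to the chromosome.

    For a + gene with TSS t the window is ``[t - upstream, t + downstream)``;
    for a - gene (TSS at ``end - 1``) it is ``[t - downstream + 1,
    t + upstream + 1)`` — the exact mirror image.
    """
    if upstream_bp < 0 or downstream_bp < 0 or (upstream_bp == 0 and downstream_bp == 0):
        raise ValidationError("window bounds must be >= 0 and not both zero")
    windows: list[PromoterWindow] = []
    for g in genes:
        if g.txn.chrom not in chrom_sizes:
            raise ValidationError(f"gene {g.gene_id} on unknown chromosome {g.txn.chrom!r}")
        length = chrom_sizes[g.txn.chrom]
        t = g.tss
        if g.txn.strand == "+":
            lo, hi = t - upstream_bp, t + downstream_bp
        else:
            lo, hi = t - downstream_bp + 1, t + upstream_bp + 1
        lo, hi = max(0, lo), min(length, hi)
        windows.append(
            PromoterWindow(g.gene_id, GenomicInterval(g.txn.chrom, lo, hi, g.txn.strand), t)
        )
    return windows


def count_reads_in_windows(
    reads: Sequence[AlignedRead] | Sequence[GenomicInterval],
    windows: Sequence[PromoterWindow],
    mode: str = "read_5prime",
) -> np.ndarray:
    """Count reads per promoter window.

    ``read_5prime`` (default): a read is counted iff its 5' base falls in
    the half-open window. ``fragment_overlap``: the items are treated as
    extended fragments and counted iff they overlap the window by >= 1 bp.
    A read counts at most once per window but may hit several overlapping
    windows.
    """
    if mode not in COUNT_MODES:
        raise ValidationError(f"unknown counting mode {mode!r}")
    counts = np.zeros(len(windows), dtype=np.int64)
    if mode == "read_5prime":
        pos_by_chrom: dict[str, list[int]] = {}
        for r in reads:
            pos_by_chrom.setdefault(r.chrom, []).append(r.five_prime)  # type: ignore[union-attr]
        for positions in pos_by_chrom.values():
            positions.sort()
        for i, w in enumerate(windows):
            positions = pos_by_chrom.get(w.interval.chrom)
            if positions is None:
                continue
            counts[i] = bisect_left(positions, w.interval.end) - bisect_left(
                positions, w.interval.start
            )
    else:
        starts_by_chrom: dict[str, list[int]] = {}
        ends_by_chrom: dict[str, list[int]] = {}
        for f in reads:
            starts_by_chrom.setdefault(f.chrom, []).append(f.start)
            ends_by_chrom.setdefault(f.chrom, []).append(f.end)
        for c in starts_by_chrom:
            starts_by_chrom[c].sort()
            ends_by_chrom[c].sort()
        for i, w in enumerate(windows):
            starts = starts_by_chrom.get(w.interval.chrom)
            if starts is None:
                continue
            ends = ends_by_chrom[w.interval.chrom]
            n = len(starts)
            # overlap iff start < window.end and end > window.start
            n_start_right = n - bisect_left(starts, w.interval.end)
            n_end_left = bisect_right(ends, w.interval.start)
            counts[i] = n - n_start_right - n_end_left
    return counts


@dataclass(slots=True)
class PromoterCountMatrix:
    """Raw promoter read counts for one histone mark: genes x samples."""

    mark: str
    gene_ids: list[str]
    sample_ids: list[str]
    groups: dict[str, str]  # sample id -> "patient" | "control"
    counts: np.ndarray  # int64, genes x samples

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("count matrix dimensions inconsistent with labels")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sample_ids) if self.groups[s] == group])

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "gene_id", self.gene_ids)
        df.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            pd.DataFrame(
                {"sample": self.sample_ids, "group": [self.groups[s] for s in self.sample_ids]}
            ).to_csv(sidecar, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path, mark: str) -> "PromoterCountMatrix":
        df = pd.read_csv(path, sep="\t")
        side = pd.read_csv(sidecar, sep="\t")
        groups = dict(zip(side["sample"].astype(str), side["group"]))
        sample_ids = [c for c in df.columns if c != "gene_id"]
        return cls(
            mark=mark,
            gene_ids=df["gene_id"].astype(str).tolist(),
            sample_ids=sample_ids,
            groups=groups,
            counts=df[sample_ids].to_numpy(),
        )


def assemble_count_matrix(
    per_sample_counts: Mapping[str, np.ndarray],
    gene_ids: Sequence[str],
    mark: str,
    groups: Mapping[str, str],
) -> PromoterCountMatrix:
    """Stack per-sample count vectors (identical gene order) into a matrix."""
    sample_ids = list(per_sample_counts)
    n = len(gene_ids)
    for s, v in per_sample_counts.items():
        if len(v) != n:
            raise ValidationError(
                f"sample {s}: count vector length {len(v)} != {n} genes"
            )
    counts = np.column_stack([per_sample_counts[s] for s in sample_ids])
    return PromoterCountMatrix(mark, list(gene_ids), sample_ids, dict(groups), counts)
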