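"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are 0-based, half-open everywhere in this package:
an interval ``[start, end)`` has length ``end - start``. BED and
refFlat-style annotation files are native to this convention. Browser-style
printed ranges ("102,282,711-102,874,166") are imported as
``start=first, end=second`` so that the printed span length equals
``end - start``.

Chromosome names are preserved verbatim; no chr-prefix munging is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomicInterval",
    "AlignedRead",
    "GeneRecord",
    "GeneSet",
    "interval_from_printed_range",
    "read_bed_reads",
    "write_bed_reads",
    "read_sam_reads",
    "read_annotation",
    "write_annotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gmt",
    "write_gmt",
    "write_bedgraph",
    "read_bedgraph",
    "check_chrom_consistency",
]

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval with strand.

    Invariants: ``0 <= start < end``, non-empty chromosome name and
    strand in ``{+, -, .}``, enforced at construction.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "requires 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """A single aligned read in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    score: str = "0"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"read {self.name}: start {self.start} >= end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"read {self.name}: invalid strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """5' base of the read: ``start`` on +, ``end - 1`` on -."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One gene/transcript: unique id, display name, transcript bounds."""

    gene_id: str
    gene_name: str
    txn: GenomicInterval

    def __post_init__(self) -> None:
        if self.txn.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.txn.strand!r}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: the 5'-most transcribed base.

        ``txStart`` on the + strand; ``end - 1`` on the - strand under the
        half-open convention.
        """
        if self.txn.strand == "+":
            return self.txn.start
        return self.txn.end - 1


@dataclass(slots=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def interval_from_printed_range(chrom: str, printed: str, strand: str = ".") -> GenomicInterval:
    """Interpret a browser-style printed range like ``102,282,711-102,874,166``.

    The two printed numbers become ``start`` and ``end`` directly, so the
    region length is ``end - start``.
    """
    cleaned = printed.replace(",", "").replace("–", "-")
    try:
        first, second = cleaned.split("-")
        start, end = int(first), int(second)
    except ValueError as exc:
        raise FormatError(f"cannot parse printed range {printed!r}") from exc
    return GenomicInterval(chrom, start, end, strand)


# ---------------------------------------------------------------------------
# BED6 reads
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | Path) -> list[AlignedRead]:
    """Read aligned reads from a BED6 file (>= 6 columns), order preserved."""
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 BED columns")
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            try:
                reads.append(AlignedRead(chrom, start, end, strand, name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return reads


def write_bed_reads(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def read_sam_reads(path: str | Path) -> list[AlignedRead]:
    """Read primary, mapped, single-end records from a SAM text file.

    Secondary (0x100), supplementary (0x800) and unmapped (0x4) records are
    dropped; the alignment span on the reference (POS to POS + sum of
    M/D/N/=/X CIGAR lengths) becomes the read interval.
    """
    import re

    cig_re = re.compile(r"(\d+)([MIDNSHP=X])")
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}: line {lineno}: truncated SAM record")
            name, flag_s, chrom, pos_s, _mapq, cigar = fields[:6]
            flag = int(flag_s)
            if flag & 0x4 or flag & 0x100 or flag & 0x800:
                continue
            span = sum(
                int(n) for n, op in cig_re.findall(cigar) if op in "MDN=X"
            )
            if span == 0:
                continue
            start = int(pos_s) - 1  # SAM is 1-based
            strand = "-" if flag & 0x10 else "+"
            reads.append(AlignedRead(chrom, start, start + span, strand, name))
    return reads


# ---------------------------------------------------------------------------
# Gene annotation (refFlat-style TSV)
# ---------------------------------------------------------------------------

_ANNOT_HEADER = ("geneName", "name", "chrom", "strand", "txStart", "txEnd")


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a refFlat-style annotation: geneName, name, chrom, strand, txStart, txEnd.

    ``txStart`` is 0-based, ``txEnd`` exclusive. Duplicate transcript ids are
    rejected. A header line starting with ``geneName`` or ``#`` is skipped.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "geneName":
                continue
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 columns")
            gene_name, gene_id, chrom, strand, start_s, end_s = fields[:6]
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer bounds") from exc
            if gene_id in seen:
                raise ValidationError(f"{path}: line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneRecord(gene_id, gene_name, GenomicInterval(chrom, start, end, strand)))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_HEADER) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_name}\t{g.gene_id}\t{g.txn.chrom}\t{g.txn.strand}"
                f"\t{g.txn.start}\t{g.txn.end}\n"
            )


# ---------------------------------------------------------------------------
# Chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            name, length_s = fields[0], fields[1]
            length = int(length_s)
            if length <= 0:
                raise ValidationError(f"{path}: line {lineno}: non-positive length")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file: setName TAB description TAB gene1 TAB gene2 ...

    Within-set duplicate genes collapse to one (set semantics).
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, description = fields[0], fields[1]
            sets[name] = GeneSet(name, description, frozenset(fields[2:]))
    return sets


def write_gmt(sets: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets.values():
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage export
# ---------------------------------------------------------------------------

def write_bedgraph(track, path: str | Path) -> None:
    """Write a coverage track as a run-length-merged 4-column bedGraph.

    Zero-valued runs are omitted; lines are sorted by chromosome name then
    start. ``track`` is anything with a ``data`` mapping of chromosome name
    to a per-base value vector (a ``CoverageTrack``), or such a mapping
    itself. NaN or infinite values are rejected.
    """
    import numpy as np

    data = getattr(track, "data", track)
    with open(path, "w") as fh:
        for chrom in sorted(data):
            values = np.asarray(data[chrom], dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"{chrom}: non-finite coverage value")
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(values[1:] != values[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, "np.ndarray"]:
    """Reconstruct per-base vectors from a bedGraph; absent runs are zero."""
    import numpy as np

    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise ValidationError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            data[chrom][start:end] = value
    return data


def check_chrom_consistency(
    reads_chroms: Iterable[str], annot_chroms: Iterable[str]
) -> list[str]:
    """Report chromosome names present in only one of two sources.

    Returns human-readable warnings; an empty list means the name sets agree.
    """
    r, a = set(reads_chroms), set(annot_chroms)
    warnings = []
    if r - a:
        warnings.append(f"chromosomes only in reads: {sorted(r - a)}")
    if a - r:
        warnings.append(f"chromosomes only in annotation: {sorted(a - r)}")
    if not (r & a):
        warnings.append("reads and annotation share no chromosome names")
    return warnings
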