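"""Synthetic multi-mark ChIP-seq datasets with implanted differential
chromatin-state archetypes.

The generator emulates the structure of a two-group (2 patients vs 4
controls) promoter histone-modification study with three marks (H3K4me3,
H3K27me3, H3K9ac) plus an input library:

* a toy genome of evenly spaced, strand-alternating genes whose +-1 kb
  promoter windows never overlap;
* per-gene baseline promoter intensities (lognormal across genes) scaled
  so promoter reads make up ``1 - background_fraction`` of the library;
* archetype genes ("silenced": active marks down, H3K27me3 up; "active":
  the mirror image) whose patient-group means are shifted by per-mark
  log2 effects;
* per-sample promoter read counts drawn negative-binomial with mean
  ``baseline * 2^effect * size_factor`` and configurable dispersion
  (dispersion 0 means Poisson);
* promoter reads whose fragment midpoints follow a symmetric triangular
  distribution over TSS +- 1 kb, giving the peaked average TSS profile
  real marks show; remaining reads are uniform background. Input-control
  samples are pure background.

Randomness is decomposed into one independent stream per (sample, mark),
derived from the master seed via ``SeedSequence(seed, spawn_key=...)``
with documented keys, so adding a sample never perturbs the others'
data. Everything is byte-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignedRead,
    GeneRecord,
    GenomicInterval,
    ValidationError,
    write_annotation,
    write_bed_reads,
    write_chrom_sizes,
)

__all__ = [
    "SimulationConfig",
    "DEFAULT_ARCHETYPE_TABLE",
    "simulate_genome",
    "assign_archetypes",
    "simulate_promoter_counts",
    "simulate_sample_reads",
    "simulate_dataset",
    "sample_sheet",
]

DEFAULT_MARKS = ("H3K4me3", "H3K27me3", "H3K9ac")

# per-archetype, per-mark log2 effects (patients vs controls)
DEFAULT_ARCHETYPE_TABLE: dict[str, dict[str, float]] = {
    "silenced": {"H3K4me3": -2.0, "H3K9ac": -2.0, "H3K27me3": 2.0},
    "active": {"H3K4me3": 2.0, "H3K9ac": 2.0, "H3K27me3": -2.0},
}

# spawn-key prefixes of the per-purpose random streams
_KEY_GENOME = 0
_KEY_ARCHETYPES = 1
_KEY_SAMPLE = 2

_PROMOTER_HALF_WIDTH = 1000  # bp; matches the +-1 kb promoter window
_EDGE_MARGIN = 2000  # min distance of any TSS from a chromosome end


@dataclass(slots=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the emulated design."""

    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 2000
    marks: tuple[str, ...] = DEFAULT_MARKS
    group_sizes: tuple[int, int] = (2, 4)  # (patients, controls)
    library_size: int = 200_000
    fragment_length: int = 200
    read_length: int = 50
    background_fraction: float = 0.3
    dispersion: float = 0.05
    baseline_log_sd: float = 1.0
    archetype_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ARCHETYPE_TABLE.items()}
    )
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {"silenced": 0.05, "active": 0.05}
    )
    size_factor_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.n_genes < 1 or self.chrom_length < 1:
            raise ValidationError("genome dimensions must be positive")
        if min(self.group_sizes) < 1:
            raise ValidationError("each group needs >= 1 sample")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.background_fraction <= 1:
            raise ValidationError("background_fraction must lie in [0, 1]")
        for name, frac in self.archetype_fractions.items():
            if name not in self.archetype_table:
                raise ValidationError(f"archetype {name!r} missing from archetype_table")
            if not 0 <= frac <= 1:
                raise ValidationError(f"archetype fraction for {name!r} outside [0, 1]")
        if sum(self.archetype_fractions.values()) > 1 + 1e-9:
            raise ValidationError("archetype fractions sum to more than 1")
        for name, effects in self.archetype_table.items():
            unknown = set(effects) - set(self.marks)
            if unknown:
                raise ValidationError(
                    f"archetype {name!r} references unknown marks {sorted(unknown)}"
                )

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)

    def sample_ids(self) -> list[str]:
        n_p, n_c = self.group_sizes
        return [f"P{i + 1}" for i in range(n_p)] + [f"C{i + 1}" for i in range(n_c)]

    def group_of(self, sample_id: str) -> str:
        return "patient" if sample_id.startswith("P") else "control"

    def global_sample_index(self, group: str, sample_index: int) -> int:
        if group == "patient":
            return sample_index
        return self.group_sizes[0] + sample_index

    def size_factor(self, group: str, sample_index: int) -> float:
        """True per-sample depth multiplier: the multipliers cycle over samples."""
        g = self.global_sample_index(group, sample_index)
        return self.size_factor_multipliers[g % len(self.size_factor_multipliers)]

    def _rng(self, *spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))

    def sample_rng(self, mark: str, group: str, sample_index: int) -> np.random.Generator:
        """Independent stream per (mark, sample); ``input`` is its own mark slot."""
        if mark == "input":
            mark_index = len(self.marks)
        else:
            mark_index = self.marks.index(mark)
        return self._rng(_KEY_SAMPLE, mark_index, self.global_sample_index(group, sample_index))


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, int], list[GeneRecord]]:
    """Place genes with disjoint +-1 kb promoter windows on a toy genome.

    Genes alternate strand along each chromosome; TSSs keep >= 2 kb from
    chromosome ends. Deterministic given the seed.
    """
    rng = config._rng(_KEY_GENOME)
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    min_spacing = 2 * _PROMOTER_HALF_WIDTH + 100
    genes: list[GeneRecord] = []
    gene_no = 0
    for ci, chrom in enumerate(sizes):
        n = per_chrom[ci]
        if n == 0:
            continue
        usable = config.chrom_length - 2 * _EDGE_MARGIN
        if usable < n * min_spacing:
            raise ValidationError(
                f"{config.n_genes} genes do not fit: chromosome {chrom} can hold at "
                f"most {usable // min_spacing} promoter windows"
            )
        spacing = usable / n
        for k in range(n):
            jitter = rng.integers(0, max(1, int(spacing - min_spacing) + 1))
            tss = int(_EDGE_MARGIN + k * spacing + jitter)
            strand = "+" if gene_no % 2 == 0 else "-"
            tx_len = int(rng.integers(2000, 10001))
            if strand == "+":
                start, end = tss, min(tss + tx_len, config.chrom_length)
            else:
                start, end = max(0, tss - tx_len + 1), tss + 1
            genes.append(
                GeneRecord(
                    gene_id=f"SIM{gene_no:05d}",
                    gene_name=f"Gene{gene_no:05d}",
                    txn=GenomicInterval(chrom, start, end, strand),
                )
            )
            gene_no += 1
    return sizes, genes


def assign_archetypes(genes: Sequence[GeneRecord], config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table: archetype label, per-mark log2 effect and baseline mean.

    ``round(fraction * n_genes)`` genes per archetype are drawn without
    replacement; the remainder is "unchanged" with all effects 0.
    Baseline promoter means are lognormal across genes, normalized so the
    expected promoter reads of an effect-free sample at size factor 1 sum
    to ``(1 - background_fraction) * library_size``.
    """
    rng = config._rng(_KEY_ARCHETYPES)
    n = len(genes)
    labels = np.array(["unchanged"] * n, dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for name, frac in config.archetype_fractions.items():
        count = int(round(frac * n))
        labels[order[cursor : cursor + count]] = name
        cursor += count
    weights = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=n)
    target_total = (1 - config.background_fraction) * config.library_size
    baseline = weights / weights.sum() * target_total
    truth = pd.DataFrame(
        {
            "archetype": labels,
            "baseline_mean": baseline,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    for mark in config.marks:
        effects = np.zeros(n)
        for name, table in config.archetype_table.items():
            effects[labels == name] = table.get(mark, 0.0)
        truth[f"effect_{mark}"] = effects
    return truth


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, alpha) draws; alpha = 0 is the Poisson limit."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def _promoter_means(
    truth: pd.DataFrame, mark: str, group: str, size_factor: float
) -> np.ndarray:
    effects = truth[f"effect_{mark}"].to_numpy() if group == "patient" else 0.0
    return truth["baseline_mean"].to_numpy() * np.exp2(effects) * size_factor


def simulate_promoter_counts(
    truth: pd.DataFrame, mark: str, config: SimulationConfig
) -> np.ndarray:
    """Genes x samples promoter count matrix for one mark (no read placement).

    Uses the same count model and random streams as the read-level
    simulator; a fast path for statistics-level experiments.
    """
    if mark not in config.marks:
        raise ValidationError(f"unknown mark {mark!r}")
    columns = []
    for sid in config.sample_ids():
        group = config.group_of(sid)
        idx = int(sid[1:]) - 1
        rng = config.sample_rng(mark, group, idx)
        means = _promoter_means(truth, mark, group, config.size_factor(group, idx))
        columns.append(_draw_counts(rng, means, config.dispersion))
    return np.column_stack(columns)


def simulate_sample_reads(
    genome: tuple[Mapping[str, int], Sequence[GeneRecord]],
    truth: pd.DataFrame,
    mark: str,
    group: str,
    sample_index: int,
    config: SimulationConfig,
) -> list[AlignedRead]:
    """Aligned reads for one sample and one mark (or ``"input"``).

    Promoter reads: per-gene NB counts, fragment midpoints triangular over
    TSS +- 1 kb, random strand, the read being the 5' ``read_length`` bases
    of the fragment. Background reads are uniform over the genome.
    Input-control samples are pure background. Deterministic given
    (seed, mark, group, sample_index).
    """
    if mark != "input" and mark not in config.marks:
        raise ValidationError(f"unknown mark {mark!r}")
    if group not in ("patient", "control"):
        raise ValidationError(f"unknown group {group!r}")
    chrom_sizes, genes = genome
    rng = config.sample_rng(mark, group, sample_index)
    s = config.size_factor(group, sample_index)
    half = _PROMOTER_HALF_WIDTH
    frag, rlen = config.fragment_length, config.read_length

    reads: list[AlignedRead] = []
    read_no = 0

    def emit(chrom: str, frag_start: int, strand: str) -> None:
        nonlocal read_no
        length = chrom_sizes[chrom]
        frag_start = min(max(frag_start, 0), length - frag)
        if strand == "+":
            start, end = frag_start, frag_start + rlen
        else:
            start, end = frag_start + frag - rlen, frag_start + frag
        reads.append(
            AlignedRead(chrom, start, end, strand, name=f"r{read_no}", score="0")
        )
        read_no += 1

    if mark == "input":
        n_bg = int(round(config.library_size * s))
    else:
        n_bg = int(round(config.background_fraction * config.library_size * s))
        means = _promoter_means(truth, mark, group, s)
        counts = _draw_counts(rng, means, config.dispersion)
        for gene, n_reads in zip(genes, counts):
            if n_reads == 0:
                continue
            tss = gene.tss
            mids = rng.triangular(tss - half, tss, tss + half, size=int(n_reads))
            strands = rng.random(int(n_reads)) < 0.5
            for mid, plus in zip(mids, strands):
                emit(gene.txn.chrom, int(mid) - frag // 2, "+" if plus else "-")

    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
    positions = rng.random(n_bg)
    strands = rng.random(n_bg) < 0.5
    for ci, u, plus in zip(chrom_idx, positions, strands):
        chrom = chroms[ci]
        emit(chrom, int(u * (chrom_sizes[chrom] - frag)), "+" if plus else "-")

    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand, r.name))
    return reads


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample": sid, "group": config.group_of(sid), "size_factor": config.size_factor(config.group_of(sid), int(sid[1:]) - 1)}
        for sid in config.sample_ids()
    ]
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    include_input: bool = True,
    write_reads: bool = True,
) -> dict:
    """Generate the full study dataset; optionally write it to ``out_dir``.

    Returns a dict with chrom_sizes, genes, truth, the sample sheet and —
    when reads are generated — a ``{(mark, sample_id): [AlignedRead]}``
    mapping. On disk: per-sample BED files named ``<mark>_<sample>.bed``,
    ``annotation.tsv``, ``chrom.sizes``, ``truth.tsv``, ``samples.tsv``.
    """
    chrom_sizes, genes = simulate_genome(config)
    truth = assign_archetypes(genes, config)
    sheet = sample_sheet(config)
    result: dict = {
        "chrom_sizes": chrom_sizes,
        "genes": genes,
        "truth": truth,
        "samples": sheet,
        "reads": {},
    }
    marks = list(config.marks) + (["input"] if include_input else [])
    if write_reads:
        for mark in marks:
            for sid in config.sample_ids():
                group = config.group_of(sid)
                idx = int(sid[1:]) - 1
                result["reads"][(mark, sid)] = simulate_sample_reads(
                    (chrom_sizes, genes), truth, mark, group, idx, config
                )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(chrom_sizes, out / "chrom.sizes")
        write_annotation(genes, out / "annotation.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t")
        sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
        for (mark, sid), reads in result["reads"].items():
            write_bed_reads(reads, out / f"{mark}_{sid}.bed")
    return result
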