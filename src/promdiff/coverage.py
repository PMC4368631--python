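"""Coverage tracks: fragment extension, per-base coverage, normalization,
smoothing, quantile normalization and TSS meta-profiles.

A :class:`CoverageTrack` carries one per-base float vector per chromosome
plus a normalization *state*. States move forward only, in the order

    raw -> per_million -> smoothed -> quantile_normalized

so e.g. smoothing an already quantile-normalized track is rejected. This
mirrors the processing order applied to the binding profiles: reads are
extended to fragments, per-base coverage is computed, scaled to reads per
million, smoothed in a 1000 bp window and finally quantile-normalized
across samples (within each mark by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignedRead, GenomicInterval, ValidationError

__all__ = [
    "CoverageTrack",
    "MetaProfile",
    "deduplicate_reads",
    "extend_reads",
    "build_coverage",
    "normalize_per_million",
    "smooth",
    "quantile_normalize",
    "meta_profile",
]

STATE_ORDER = ("raw", "per_million", "smoothed", "quantile_normalized")


@dataclass(slots=True)
class CoverageTrack:
    """Per-base signal vectors keyed by chromosome, with normalization state."""

    data: dict[str, np.ndarray]
    library_size: int | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATE_ORDER:
            raise ValidationError(f"unknown track state {self.state!r}")

    def total(self) -> float:
        """Sum of signal over the whole genome."""
        return float(sum(v.sum() for v in self.data.values()))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: v.size for c, v in self.data.items()}


def _require_state_before(track: CoverageTrack, target: str) -> None:
    if STATE_ORDER.index(track.state) >= STATE_ORDER.index(target):
        raise ValidationError(
            f"track in state {track.state!r} cannot move to {target!r}: "
            "states advance forward only"
        )


@dataclass(slots=True)
class MetaProfile:
    """Mean signal in fixed-width bins around a set of TSSs, 5'->3' oriented."""

    bin_centers: np.ndarray  # offsets from the TSS, bp
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    n_sites: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"bin_center": self.bin_centers, **self.profiles})


def deduplicate_reads(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Keep at most one read per (chromosome, 5' position, strand).

    The first occurrence wins; the output is sorted by coordinate so the
    result is deterministic regardless of input order among duplicates.
    """
    seen: set[tuple[str, int, str]] = set()
    kept: list[AlignedRead] = []
    for r in reads:
        key = (r.chrom, r.five_prime, r.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    kept.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand, r.name))
    return kept


def extend_reads(
    reads: Iterable[AlignedRead],
    fragment_length: int,
    chrom_sizes: Mapping[str, int],
) -> list[GenomicInterval]:
    """Extend each read to its presumed fragment, anchored at the 5' end.

    A + read starting at ``s`` becomes ``[s, s + L)``; a - read ending at
    ``e`` becomes ``[e - L, e)``. If the fragment length is shorter than the
    read, the read's own span is kept. Fragments are clipped to chromosome
    bounds; reads lying outside their chromosome are an error.
    """
    if fragment_length < 1:
        raise ValidationError("fragment_length must be >= 1")
    out: list[GenomicInterval] = []
    for r in reads:
        if r.chrom not in chrom_sizes:
            raise ValidationError(f"read on unknown chromosome {r.chrom!r}")
        length = chrom_sizes[r.chrom]
        if r.start < 0 or r.end > length:
            raise ValidationError(
                f"read {r.chrom}:{r.start}-{r.end} outside chromosome (length {length})"
            )
        span = max(fragment_length, r.end - r.start)
        if r.strand == "-":
            start, end = r.end - span, r.end
        else:
            start, end = r.start, r.start + span
        out.append(GenomicInterval(r.chrom, max(0, start), min(length, end), r.strand))
    return out


def build_coverage(
    fragments: Iterable[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    library_size: int | None = None,
) -> CoverageTrack:
    """Per-base fragment pileup: value at base b = number of fragments covering b."""
    data = {c: np.zeros(n + 1) for c, n in chrom_sizes.items()}
    n_frag = 0
    for f in fragments:
        if f.chrom not in data:
            raise ValidationError(f"fragment on unknown chromosome {f.chrom!r}")
        data[f.chrom][f.start] += 1
        data[f.chrom][f.end] -= 1
        n_frag += 1
    vectors = {c: np.cumsum(d[:-1]) for c, d in data.items()}
    if library_size is None:
        library_size = n_frag
    return CoverageTrack(vectors, library_size=library_size, state="raw")


def normalize_per_million(track: CoverageTrack) -> CoverageTrack:
    """Scale the track by 1e6 / library_size (reads-per-million units)."""
    _require_state_before(track, "per_million")
    if not track.library_size:
        raise ValidationError("library_size must be positive for per-million scaling")
    scale = 1e6 / track.library_size
    return replace(
        track,
        data={c: v * scale for c, v in track.data.items()},
        state="per_million",
    )


def smooth(track: CoverageTrack, window_bp: int = 1000) -> CoverageTrack:
    """Centered moving average; even windows widen by 1 bp (1000 -> 1001).

    Near chromosome ends the window truncates to the available bases, so a
    constant vector stays constant all the way to the edge.
    """
    _require_state_before(track, "smoothed")
    if window_bp < 1:
        raise ValidationError("window_bp must be >= 1")
    w = window_bp + 1 if window_bp % 2 == 0 else window_bp
    half = w // 2
    out: dict[str, np.ndarray] = {}
    for chrom, v in track.data.items():
        n = v.size
        csum = np.concatenate(([0.0], np.cumsum(v)))
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        out[chrom] = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(track, data=out, state="smoothed")


def _qn_reference(sorted_stack: np.ndarray) -> np.ndarray:
    return sorted_stack.mean(axis=0)


def quantile_normalize(
    tracks: Sequence[CoverageTrack], ties: str = "average"
) -> list[CoverageTrack]:
    """Rank-based quantile normalization across samples, genome-wide.

    The per-base values of all chromosomes are concatenated per sample; the
    value at rank r in each sample is replaced by the mean of the rank-r
    values across samples. With ``ties="average"`` (default) tied values
    within a sample receive the mean of the reference values their ranks
    span; ``ties="stable"`` assigns reference values by stable sort order,
    which keeps every sample's value multiset exactly equal to the
    reference (and the operation exactly idempotent) at the cost of giving
    tied inputs distinct outputs.
    """
    if ties not in ("average", "stable"):
        raise ValidationError(f"unknown tie mode {ties!r}")
    if not tracks:
        return []
    chroms = sorted(tracks[0].data)
    sizes = tracks[0].chrom_sizes()
    for t in tracks[1:]:
        if t.chrom_sizes() != sizes:
            raise ValidationError("tracks cover different genomes")
        if t.state != tracks[0].state:
            raise ValidationError("tracks must share normalization state")
    _require_state_before(tracks[0], "quantile_normalized")

    flat = [np.concatenate([t.data[c] for c in chroms]) for t in tracks]
    orders = [np.argsort(v, kind="stable") for v in flat]
    ref = _qn_reference(np.stack([v[o] for v, o in zip(flat, orders)]))

    out_tracks: list[CoverageTrack] = []
    bounds = np.cumsum([sizes[c] for c in chroms])
    for v, order in zip(flat, orders):
        assigned = ref.copy()
        if ties == "average":
            vs = v[order]
            starts = np.concatenate(([0], np.flatnonzero(vs[1:] != vs[:-1]) + 1))
            counts = np.diff(np.concatenate((starts, [vs.size])))
            means = np.add.reduceat(ref, starts) / counts
            assigned = np.repeat(means, counts)
        normalized = np.empty_like(assigned)
        normalized[order] = assigned
        pieces = np.split(normalized, bounds[:-1])
        out_tracks.append(
            CoverageTrack(
                dict(zip(chroms, pieces)),
                library_size=None,
                state="quantile_normalized",
            )
        )
    for src, dst in zip(tracks, out_tracks):
        dst.library_size = src.library_size
    return out_tracks


def meta_profile(
    tracks: Mapping[str, CoverageTrack],
    tss_sites: Sequence[tuple[str, int, str]],
    flank_bp: int,
    bin_bp: int = 50,
) -> MetaProfile:
    """Average signal in ``bin_bp`` windows across TSSs, oriented 5'->3'.

    ``tss_sites`` is a sequence of (chromosome, tss position, strand). For
    each site the +-``flank_bp`` window is extracted (minus-strand windows
    reversed so downstream of the TSS is always to the right), cut into
    bins, and the per-base mean taken per bin; the profile is the mean over
    sites. Sites closer than ``flank_bp`` to a chromosome end are skipped
    with a warning.
    """
    if flank_bp % bin_bp != 0:
        raise ValidationError("flank_bp must be a multiple of bin_bp")
    if not tss_sites:
        raise ValidationError("empty TSS set")
    n_bins = 2 * flank_bp // bin_bp
    centers = (np.arange(n_bins) - n_bins / 2 + 0.5) * bin_bp

    profiles: dict[str, np.ndarray] = {}
    n_used = 0
    for name, track in tracks.items():
        acc = np.zeros(n_bins)
        used = 0
        for chrom, tss, strand in tss_sites:
            v = track.data[chrom]
            if strand == "-":
                lo, hi = tss - flank_bp + 1, tss + flank_bp + 1
            else:
                lo, hi = tss - flank_bp, tss + flank_bp
            if lo < 0 or hi > v.size:
                warnings.warn(
                    f"TSS {chrom}:{tss} within {flank_bp} bp of chromosome end; skipped",
                    stacklevel=2,
                )
                continue
            window = v[lo:hi]
            if strand == "-":
                window = window[::-1]
            acc += window.reshape(n_bins, bin_bp).mean(axis=1)
            used += 1
        if used == 0:
            raise ValidationError("no TSS usable for meta-profile")
        profiles[name] = acc / used
        n_used = used
    return MetaProfile(bin_centers=centers, profiles=profiles, n_sites=n_used)
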