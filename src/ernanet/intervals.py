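"""Genomic interval data model and interval algebra.

All coordinates are 0-based half-open (BED convention): an interval covers
``start <= pos < end``. GTF input is converted on read. The merge used
throughout requires at least 1 bp of overlap — intervals that merely touch
(``a.end == b.start``) are kept separate, matching the default semantics of
the interval-merge command this algebra mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class UnknownChromosomeError(KeyError):
    """An interval references a chromosome absent from the genome layout."""


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    id : str, optional
        Feature identifier (BED name column).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor of (start+end)/2 for even-length intervals."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class GenomeLayout:
    """Ordered chromosome names and lengths, optionally with sequence.

    The layout is the background space for window clipping and for the
    permutation null that re-places elements uniformly on the genome.
    """

    chromosomes: list[tuple[str, int]]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self._lengths = dict(self.chromosomes)
        for name, seq in self.sequences.items():
            if name not in self._lengths:
                raise UnknownChromosomeError(name)
            if len(seq) != self._lengths[name]:
                raise ValueError(
                    f"sequence length {len(seq)} != declared length "
                    f"{self._lengths[name]} for {name}"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        """Raise if any interval falls outside its chromosome."""
        for iv in intervals:
            length = self.length_of(iv.chrom)
            if iv.end > length:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {length}"
                )

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        length = self.length_of(chrom)
        return max(0, start), min(length, end)

    def sequence(self, iv: GenomicInterval) -> str:
        seq = self.sequences.get(iv.chrom)
        if seq is None:
            raise KeyError(f"no sequence loaded for chromosome {iv.chrom}")
        return seq[iv.start : iv.end]


@dataclass
class AnnotationRecord:
    """A gene or ncRNA model with its TSS.

    TSS is the start for + strand records and ``end - 1`` for - strand.
    """

    interval: GenomicInterval
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


NCRNA_BIOTYPES = ("miRNA", "misc_RNA", "rRNA", "snoRNA", "snRNA", "tRNA", "lncRNA")


@dataclass
class AnnotationSet:
    """Gene and non-coding RNA records used for eRNA region exclusion."""

    genes: list[AnnotationRecord] = field(default_factory=list)
    ncrnas: list[AnnotationRecord] = field(default_factory=list)

    @property
    def all_records(self) -> list[AnnotationRecord]:
        return list(self.genes) + list(self.ncrnas)

    def bodies(self) -> list[GenomicInterval]:
        return [r.interval for r in self.all_records]

    def tss_positions(self) -> list[tuple[str, int]]:
        return [(r.interval.chrom, r.tss) for r in self.all_records]


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge into maximal non-overlapping intervals (>=1 bp overlap only)."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        cur_s = cur_e = None
        for iv in _by_chrom(intervals)[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start < cur_e:  # strict overlap; touching stays separate
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """All pairwise intersections of a x b (may overlap each other)."""
    out: list[GenomicInterval] = []
    b_by = _by_chrom(b)
    for chrom, a_list in sorted(_by_chrom(a).items()):
        b_list = b_by.get(chrom, [])
        starts = [iv.start for iv in b_list]
        ends = [iv.end for iv in b_list]
        for iv in a_list:
            for j in range(len(b_list)):
                if starts[j] >= iv.end:  # starts sorted: nothing further overlaps
                    break
                s = max(iv.start, starts[j])
                e = min(iv.end, ends[j])
                if s < e:
                    out.append(GenomicInterval(chrom, s, e))
    return out


def intersect_then_merge(
    peaks_rep1: Sequence[GenomicInterval],
    peaks_rep2: Sequence[GenomicInterval],
    layout: GenomeLayout | None = None,
) -> list[GenomicInterval]:
    """Replicate-supported regions: pairwise intersections, then merged.

    Mirrors running an interval ``intersect`` between the two replicates'
    peak sets followed by ``merge``. Output is sorted and non-overlapping.
    """
    if layout is not None:
        layout.validate(peaks_rep1)
        layout.validate(peaks_rep2)
    return merge_intervals(intersect_intervals(peaks_rep1, peaks_rep2))


def subtract_intervals(
    region: GenomicInterval, blockers: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Parts of ``region`` not covered by any blocker, in order."""
    relevant = sorted(
        (iv for iv in blockers if iv.overlaps(region)), key=lambda iv: iv.start
    )
    pieces: list[GenomicInterval] = []
    cursor = region.start
    for iv in relevant:
        if iv.start > cursor:
            pieces.append(GenomicInterval(region.chrom, cursor, iv.start))
        cursor = max(cursor, iv.end)
        if cursor >= region.end:
            break
    if cursor < region.end:
        pieces.append(GenomicInterval(region.chrom, cursor, region.end))
    return pieces


def exclude_near_features(
    regions: Sequence[GenomicInterval],
    anchors: Sequence[tuple[str, int]],
    flank: int,
) -> list[GenomicInterval]:
    """Drop regions overlapping any [anchor-flank, anchor+flank+1) window."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows = [
        GenomicInterval(chrom, max(0, pos - flank), pos + flank + 1)
        for chrom, pos in anchors
    ]
    return exclude_overlapping(regions, windows)


def exclude_overlapping(
    regions: Sequence[GenomicInterval], blockers: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop regions with >=1 bp overlap with any blocker interval."""
    blk = _by_chrom(blockers)
    kept = []
    for iv in regions:
        lst = blk.get(iv.chrom, [])
        if not any(b.start < iv.end and iv.start < b.end for b in lst):
            kept.append(iv)
    return kept


def center_window(
    region: GenomicInterval, flank: int, layout: GenomeLayout | None = None
) -> GenomicInterval:
    """[center-flank, center+flank) around the region midpoint, clipped.

    ``flank`` must be >= 1: a zero flank yields an empty window, which has
    no meaning in this coordinate system.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1 (zero flank yields an empty window)")
    c = region.center
    start, end = c - flank, c + flank
    if layout is not None:
        start, end = layout.clip(region.chrom, start, end)
    else:
        start = max(0, start)
    return GenomicInterval(region.chrom, start, end, region.strand, region.id)


def expand_interval(
    region: GenomicInterval, flank: int, layout: GenomeLayout | None = None
) -> GenomicInterval:
    """Extend both ends by ``flank`` bp, clipped to chromosome bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start, end = region.start - flank, region.end + flank
    if layout is not None:
        start, end = layout.clip(region.chrom, start, end)
    else:
        start = max(0, start)
    return GenomicInterval(region.chrom, start, end, region.strand, region.id)


class OverlapIndex:
    """Sorted-array overlap queries against a fixed interval set.

    Built once over (possibly overlapping) intervals; queries use the merged
    cover, which is sufficient for any/overlap-count-by-element semantics.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, lst in _by_chrom(merge_intervals(intervals)).items():
            self._merged[chrom] = (
                np.array([x.start for x in lst], dtype=np.int64),
                np.array([x.end for x in lst], dtype=np.int64),
            )

    def arrays(self, chrom: str) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Merged (starts, ends) arrays for a chromosome, or (None, None)."""
        pair = self._merged.get(chrom)
        return pair if pair is not None else (None, None)

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._merged:
            return False
        starts, ends = self._merged[iv.chrom]
        j = int(np.searchsorted(starts, iv.end, side="left"))
        return j > 0 and ends[j - 1] > iv.start

    def count_overlapping(self, intervals: Sequence[GenomicInterval]) -> int:
        """Number of query elements overlapping >=1 indexed interval."""
        return sum(self.overlaps_any(iv) for iv in intervals)

    def covered_bases(self, iv: GenomicInterval) -> int:
        """Bases of ``iv`` covered by the indexed set."""
        if iv.chrom not in self._merged:
            return 0
        starts, ends = self._merged[iv.chrom]
        total = 0
        for s, e in zip(starts, ends):
            if s >= iv.end:
                break
            total += max(0, min(int(e), iv.end) - max(int(s), iv.start))
        return total
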