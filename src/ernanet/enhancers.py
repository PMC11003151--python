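"""Enhancer activity quantification and super-enhancer calling.

Enhancer activity is the H3K27ac ChIP signal over the +/-1 kb window around
the enhancer center, library-normalized to reads per million (RPM) in the IP
and INPUT libraries; activity strength is the IP_RPM / INPUT_RPM fold change.

Super-enhancers are called ROSE-style in simplified form: enhancers within a
stitch distance (default 12,500 bp) are stitched, stitched regions are ranked
by total background-corrected signal, both axes of the rank-signal curve are
min-max scaled to [0, 1], and the cutoff is the first rank at which the
slope of the curve exceeds 1; regions above the cutoff are super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    AnnotationSet,
    GenomeLayout,
    GenomicInterval,
    exclude_near_features,
    intersect_then_merge,
    merge_intervals,
)

logger = logging.getLogger(__name__)


def derive_enhancer_set(
    peaks: Mapping[tuple[str, int], Sequence[GenomicInterval]],
    annotation: AnnotationSet,
    layout: GenomeLayout | None = None,
    tss_flank: int = 1000,
) -> list[GenomicInterval]:
    """Replicate-consistent, TSS-distal enhancers with coordinate-order ids.

    Per tissue the two replicates' peaks are intersected then merged;
    tissue sets are union-merged; regions overlapping any TSS +/-flank
    window are dropped. Ids are assigned in coordinate order (enh_0000...),
    so any caller deriving from the same peaks gets the same ids.
    """
    tissues = sorted({t for t, _ in peaks})
    per_tissue = [
        intersect_then_merge(peaks[(t, 1)], peaks[(t, 2)], layout) for t in tissues
    ]
    union = merge_intervals([iv for lst in per_tissue for iv in lst])
    distal = exclude_near_features(union, annotation.tss_positions(), tss_flank)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"enh_{i:04d}")
        for i, iv in enumerate(distal)
    ]


class MissingCountError(KeyError):
    """Raised when enhancer ids lack count entries."""

    def __init__(self, ids: Sequence[str]):
        self.ids = list(ids)
        super().__init__(f"missing counts for {len(self.ids)} enhancer(s): {self.ids[:5]}")


@dataclass
class EnhancerActivity:
    """IP/INPUT RPM over the center +/-1 kb window and their fold change."""

    enhancer_id: str
    ip_rpm: float
    input_rpm: float
    fold_change: float | None

    def __post_init__(self) -> None:
        if self.ip_rpm < 0 or self.input_rpm < 0:
            raise ValueError("rpm values must be non-negative")


@dataclass
class SuperEnhancer:
    stitched: GenomicInterval
    member_ids: list[str]
    total_signal: float
    rank: int
    is_super: bool


def quantify_activity(
    enhancers: Sequence[GenomicInterval],
    ip_counts: Mapping[str, float],
    input_counts: Mapping[str, float],
    ip_lib_size: float,
    input_lib_size: float,
) -> list[EnhancerActivity]:
    """RPM-normalize IP/INPUT counts and compute the activity fold change.

    Counts are read totals over the center +/-1 kb window, keyed by enhancer
    id. ``fold_change`` is None (with a warning) where INPUT RPM is zero.
    """
    if ip_lib_size <= 0 or input_lib_size <= 0:
        raise ValueError("library sizes must be positive")
    missing = [
        iv.id for iv in enhancers
        if iv.id not in ip_counts or iv.id not in input_counts
    ]
    if missing:
        raise MissingCountError(missing)
    out = []
    for iv in enhancers:
        ip_rpm = ip_counts[iv.id] / ip_lib_size * 1e6
        input_rpm = input_counts[iv.id] / input_lib_size * 1e6
        if input_rpm > 0:
            fc = ip_rpm / input_rpm
        else:
            fc = None
            logger.warning("enhancer %s: INPUT rpm is 0, fold change undefined", iv.id)
        out.append(EnhancerActivity(iv.id, ip_rpm, input_rpm, fc))
    return out


def stitch_enhancers(
    enhancers: Sequence[GenomicInterval], stitch_distance: int = 12_500
) -> list[tuple[GenomicInterval, list[str]]]:
    """Stitch enhancers whose gap is <= stitch_distance into regions.

    Returns (stitched interval, member enhancer ids) sorted by coordinate;
    independent of input ordering.
    """
    ordered = sorted(enhancers, key=lambda iv: (iv.chrom, iv.start, iv.end))
    result: list[tuple[GenomicInterval, list[str]]] = []
    cur: list[GenomicInterval] = []
    for iv in ordered:
        if cur and iv.chrom == cur[-1].chrom and iv.start - max(m.end for m in cur) <= stitch_distance:
            cur.append(iv)
        else:
            if cur:
                result.append(_finish_cluster(cur))
            cur = [iv]
    if cur:
        result.append(_finish_cluster(cur))
    return result


def _finish_cluster(members: list[GenomicInterval]) -> tuple[GenomicInterval, list[str]]:
    stitched = GenomicInterval(
        members[0].chrom, min(m.start for m in members), max(m.end for m in members)
    )
    return stitched, [m.id for m in members]


def call_super_enhancers(
    enhancers: Sequence[GenomicInterval],
    signal: Mapping[str, float],
    stitch_distance: int = 12_500,
) -> list[SuperEnhancer]:
    """Stitch, rank by total signal, and apply the slope-1 tangent cutoff.

    The rank-signal curve is min-max scaled on both axes; slopes are centered
    finite differences (one-sided at the ends). The cutoff is the first rank
    where the slope exceeds 1; regions ranked above it are flagged super.
    Fewer than 3 stitched regions leaves all non-super (curve undefined).
    """
    for eid, s in signal.items():
        if s < 0:
            raise ValueError(f"negative signal for {eid}")
    stitched = stitch_enhancers(enhancers, stitch_distance)
    totals = [sum(signal[m] for m in members) for _, members in stitched]
    order = np.argsort(totals, kind="stable")  # ascending
    n = len(stitched)
    results: list[SuperEnhancer | None] = [None] * n
    if n < 3:
        if n > 0:
            logger.warning("only %d stitched region(s): super-enhancer curve undefined", n)
        flags = [False] * n
    else:
        y = np.asarray([totals[i] for i in order], dtype=float)
        x = np.arange(n, dtype=float)
        yr = y.max() - y.min()
        ys = (y - y.min()) / yr if yr > 0 else np.zeros(n)
        xs = x / (n - 1)
        slopes = np.gradient(ys, xs)
        above = np.nonzero(slopes > 1.0)[0]
        cutoff = int(above[0]) if len(above) else n  # no rank above => none super
        flags_sorted = [i > cutoff for i in range(n)]
        flags = [False] * n
        for rank_pos, idx in enumerate(order):
            flags[idx] = flags_sorted[rank_pos]
    rank_of = {int(idx): pos + 1 for pos, idx in enumerate(order)}
    for i, (iv, members) in enumerate(stitched):
        results[i] = SuperEnhancer(iv, members, totals[i], rank_of[i], flags[i])
    return [r for r in results if r is not None]
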