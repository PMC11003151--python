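"""eRNA region definition, strand-specific quantification and classification.

An eRNA's transcription region is the +/-3 kb window around its source
enhancer's center. Because the RNA signal inside annotated genes or ncRNAs
cannot be attributed to the enhancer, quantification windows are the region
minus every gene/ncRNA body expanded by +/-1 kb; records whose windows are
empty are dropped.

An eRNA is detectable in a tissue when its mean RPM over that tissue's
biological replicates is >= 1. Transcription is bidirectional when the
plus-strand read fraction lies in [0.05, 0.95] (bounds inclusive), else
unidirectional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    AnnotationSet,
    GenomeLayout,
    GenomicInterval,
    center_window,
    expand_interval,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

ERNA_FLANK = 3_000
ANNOTATION_FLANK = 1_000
DETECTABLE_MEAN_RPM = 1.0
BIDIRECTIONAL_BOUNDS = (0.05, 0.95)


@dataclass
class ERnaRecord:
    """An enhancer-linked eRNA with its quantification geometry and signal."""

    erna_id: str
    enhancer_id: str
    region: GenomicInterval
    windows: list[GenomicInterval]
    rpm: dict[str, float] = field(default_factory=dict)  # sample -> rpm
    plus_fraction: dict[str, float | None] = field(default_factory=dict)  # tissue key -> frac
    direction: str | None = None  # "bidirectional" | "unidirectional"
    gc_fraction: float | None = None

    @property
    def center(self) -> int:
        return self.region.center


@dataclass
class TranscribedEnhancerLabel:
    enhancer_id: str
    label: str  # "TEn" | "non-TEn"


def define_erna_regions(
    enhancers: Sequence[GenomicInterval],
    annotation: AnnotationSet,
    layout: GenomeLayout | None = None,
) -> list[ERnaRecord]:
    """Transcription regions (+/-3 kb of enhancer centers) minus annotation.

    Gene and ncRNA bodies expanded by +/-1 kb are subtracted from each
    region; enhancers whose windows vanish yield no record.
    """
    blockers = [expand_interval(b, ANNOTATION_FLANK) for b in annotation.bodies()]
    records = []
    for i, enh in enumerate(enhancers):
        region = center_window(enh, ERNA_FLANK, layout)
        windows = subtract_intervals(region, blockers)
        if not windows:
            continue
        eid = enh.id if enh.id is not None else f"enh_{i}"
        records.append(
            ERnaRecord(
                erna_id=f"eRNA_{eid}",
                enhancer_id=eid,
                region=GenomicInterval(region.chrom, region.start, region.end, ".", f"eRNA_{eid}"),
                windows=windows,
            )
        )
    return records


def quantify_rpm(
    records: Sequence[ERnaRecord],
    stranded_counts: pd.DataFrame,
    lib_sizes: Mapping[str, float],
    samples: pd.DataFrame,
) -> list[ERnaRecord]:
    """Per-sample RPM and per-tissue plus-strand fractions, in place.

    Parameters
    ----------
    stranded_counts : DataFrame
        Columns ``erna_id, sample, plus_count, minus_count`` — window-filtered
        read counts summed over each record's quantification windows.
    lib_sizes : mapping sample -> total mapped reads.
    samples : DataFrame
        Sample sheet with columns ``sample, breed, tissue, replicate``.
    """
    if (stranded_counts[["plus_count", "minus_count"]] < 0).any().any():
        raise ValueError("negative read counts")
    counts = stranded_counts.set_index(["erna_id", "sample"])
    tissue_of = samples.set_index("sample")[["breed", "tissue"]]
    for rec in records:
        pooled: dict[str, list[float]] = {}
        for sample, lib in lib_sizes.items():
            try:
                row = counts.loc[(rec.erna_id, sample)]
                plus, minus = float(row["plus_count"]), float(row["minus_count"])
            except KeyError:
                plus = minus = 0.0
            rec.rpm[sample] = (plus + minus) / lib * 1e6
            breed, tissue = tissue_of.loc[sample]
            key = f"{breed}:{tissue}"
            acc = pooled.setdefault(key, [0.0, 0.0])
            acc[0] += plus
            acc[1] += minus
        for key, (plus, minus) in pooled.items():
            total = plus + minus
            rec.plus_fraction[key] = plus / total if total > 0 else None
    return list(records)


def call_detectable(
    records: Sequence[ERnaRecord], samples: pd.DataFrame, breed: str, tissue: str
) -> set[str]:
    """eRNAs with mean RPM >= 1 across the tissue's biological replicates."""
    sel = samples[(samples["breed"] == breed) & (samples["tissue"] == tissue)]
    reps = list(sel["sample"])
    if len(reps) != 2:
        logger.warning(
            "%s/%s has %d replicate(s); mean taken over available samples",
            breed, tissue, len(reps),
        )
    if not reps:
        return set()
    out = set()
    for rec in records:
        vals = [rec.rpm.get(s, 0.0) for s in reps]
        if float(np.mean(vals)) >= DETECTABLE_MEAN_RPM:
            out.add(rec.erna_id)
    return out


def classify_direction(plus_fraction: float | None) -> str | None:
    """Bidirectional iff the plus-strand fraction is within [0.05, 0.95]."""
    if plus_fraction is None:
        return None
    if not (0.0 <= plus_fraction <= 1.0):
        raise ValueError("plus_fraction must be in [0, 1]")
    lo, hi = BIDIRECTIONAL_BOUNDS
    return "bidirectional" if lo <= plus_fraction <= hi else "unidirectional"


def assign_directions(records: Sequence[ERnaRecord], samples: pd.DataFrame) -> None:
    """Per-record global direction from the tissue with highest detectable mean RPM.

    Direction is classified per (breed, tissue) from pooled replicate counts;
    the record's single label comes from the tissue where it is detectable
    with the highest mean RPM (no label if nowhere detectable/defined).
    """
    groups = samples.groupby(["breed", "tissue"])["sample"].apply(list)
    for rec in records:
        best_key, best_mean = None, -1.0
        for (breed, tissue), reps in groups.items():
            mean_rpm = float(np.mean([rec.rpm.get(s, 0.0) for s in reps]))
            key = f"{breed}:{tissue}"
            if (
                mean_rpm >= DETECTABLE_MEAN_RPM
                and rec.plus_fraction.get(key) is not None
                and mean_rpm > best_mean
            ):
                best_key, best_mean = key, mean_rpm
        rec.direction = (
            classify_direction(rec.plus_fraction[best_key]) if best_key else None
        )


def gc_fraction(sequence: str) -> float:
    """(G+C) / length, case-insensitive; N counts toward the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def binned_activity_correlation(
    expression: Mapping[str, float],
    activity: Mapping[str, float],
    n_bins: int = 8,
) -> tuple[float, float]:
    """Pearson r between bin-mean expression and bin-mean enhancer activity.

    Features are sorted by expression descending and split into ``n_bins``
    near-equal bins (earlier bins absorb remainders); per-bin means of both
    quantities give the ``n_bins`` points correlated.
    """
    ids = [k for k in expression if k in activity]
    n = len(ids)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} matched features, got {n}")
    ids.sort(key=lambda k: -expression[k])
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    expr_means, act_means = [], []
    pos = 0
    for size in sizes:
        chunk = ids[pos : pos + size]
        pos += size
        expr_means.append(float(np.mean([expression[k] for k in chunk])))
        act_means.append(float(np.mean([activity[k] for k in chunk])))
    r, p = stats.pearsonr(expr_means, act_means)
    return float(r), float(p)


def label_transcribed_enhancers(
    enhancers: Sequence[GenomicInterval],
    erna_records: Sequence[ERnaRecord],
    detectable_ids: set[str] | None = None,
) -> list[TranscribedEnhancerLabel]:
    """TEn iff the enhancer interval contains >=1 eRNA center point."""
    centers = [
        (rec.region.chrom, rec.center)
        for rec in erna_records
        if detectable_ids is None or rec.erna_id in detectable_ids
    ]
    labels = []
    for enh in enhancers:
        ten = any(enh.contains_point(c, p) for c, p in centers)
        labels.append(TranscribedEnhancerLabel(enh.id, "TEn" if ten else "non-TEn"))
    return labels
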