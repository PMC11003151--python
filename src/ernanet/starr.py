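"""Candidate-SNP screening and STARR-seq allelic activity testing.

Candidate SNPs for the reporter assay lie inside an eRNA region, show a
minor-allele-frequency (MAF) difference > 0.3 between the eastern and
western populations, and have mixed-pool MAF > 0.05.

A SNP's regulatory effect is the fold change in allele ratios between the
output (self-transcribed) and input (plasmid) libraries,
(output_alt/output_ref) / (input_alt/input_ref); significance is a
two-tailed Fisher exact test on the 2x2 allele-count table, BH-corrected
across tested SNPs. Only SNPs with allele coverage strictly exceeding 20 in
both libraries are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .intervals import GenomicInterval, OverlapIndex

logger = logging.getLogger(__name__)

MIN_COVERAGE = 20
MAF_DIFF_THRESHOLD = 0.3
MIXED_MAF_THRESHOLD = 0.05
REGULATORY_Q = 0.05


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p: sum of probabilities of all tables with the
    observed margins whose point probability is <= the observed table's."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class SnpPopulationFreqs:
    snp_id: str
    chrom: str
    pos: int
    east_maf: float
    west_maf: float
    mixed_maf: float

    def __post_init__(self) -> None:
        for name in ("east_maf", "west_maf", "mixed_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name}={v} outside [0, 0.5] for {self.snp_id}")


@dataclass
class AllelicActivityResult:
    snp_id: str
    input_ref: int
    input_alt: int
    output_ref: int
    output_alt: int
    effect_size: float | None
    p: float
    q: float | None = None
    is_regulatory: bool = False


def screen_candidate_snps(
    freqs: Sequence[SnpPopulationFreqs],
    erna_regions: Sequence[GenomicInterval],
    maf_diff: float = MAF_DIFF_THRESHOLD,
    mixed_maf: float = MIXED_MAF_THRESHOLD,
) -> list[str]:
    """SNPs inside an eRNA region with |east-west MAF| > 0.3 and mixed MAF > 0.05."""
    index = OverlapIndex(erna_regions)
    kept = []
    for f in freqs:
        point = GenomicInterval(f.chrom, f.pos, f.pos + 1)
        if (
            index.overlaps_any(point)
            and abs(f.east_maf - f.west_maf) > maf_diff
            and f.mixed_maf > mixed_maf
        ):
            kept.append(f.snp_id)
    return kept


def merge_output_replicates(
    rep1: pd.DataFrame, rep2: pd.DataFrame
) -> tuple[pd.DataFrame, float | None]:
    """Sum allele counts across replicates; report replicate correlation.

    Both frames must carry the same SNP set with columns
    ``snp_id, ref_count, alt_count``. The Pearson correlation of per-SNP
    total counts between replicates is the merge QC; r < 0.8 warns.
    """
    a = rep1.set_index("snp_id")[["ref_count", "alt_count"]]
    b = rep2.set_index("snp_id")[["ref_count", "alt_count"]]
    if set(a.index) != set(b.index):
        raise ValueError("replicate SNP sets differ")
    b = b.loc[a.index]
    merged = (a + b).reset_index()
    t1 = (a["ref_count"] + a["alt_count"]).to_numpy(dtype=float)
    t2 = (b["ref_count"] + b["alt_count"]).to_numpy(dtype=float)
    r: float | None
    if len(t1) < 2 or np.std(t1) == 0 or np.std(t2) == 0:
        r = None
        logger.warning("replicate correlation undefined (constant or tiny count vectors)")
    else:
        r = float(stats.pearsonr(t1, t2)[0])
        if r < 0.8:
            logger.warning("replicate total-count correlation r=%.3f < 0.8", r)
    return merged, r


def allelic_activity_test(
    input_counts: Mapping[str, tuple[int, int]],
    output_counts: Mapping[str, tuple[int, int]],
    min_coverage: int = MIN_COVERAGE,
    q_threshold: float = REGULATORY_Q,
) -> list[AllelicActivityResult]:
    """Per-SNP allelic activity from input/output (ref, alt) allele counts.

    SNPs whose total coverage is <= ``min_coverage`` in either library are
    excluded before testing. The effect size is undefined (None) when any
    cell is zero; the Fisher test is computed regardless. ``is_regulatory``
    flags BH q < 0.05 among the tested SNPs.
    """
    results = []
    for snp_id in input_counts:
        if snp_id not in output_counts:
            raise KeyError(f"SNP {snp_id} missing from output counts")
        ir, ia = input_counts[snp_id]
        orf, oa = output_counts[snp_id]
        if min(ir, ia, orf, oa) < 0:
            raise ValueError(f"negative counts for {snp_id}")
        if ir + ia <= min_coverage or orf + oa <= min_coverage:
            continue
        if min(ir, ia, orf, oa) > 0:
            effect = (oa / orf) / (ia / ir)
        else:
            effect = None
        p = fisher_two_sided([[ir, ia], [orf, oa]])
        results.append(AllelicActivityResult(snp_id, ir, ia, orf, oa, effect, p))
    if results:
        qs = bh_fdr([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
            r.is_regulatory = bool(q < q_threshold)
    return results


def collapse_output_libraries(
    lib_a: pd.DataFrame, lib_b: pd.DataFrame
) -> pd.DataFrame:
    """Sum the two output NGS libraries of one biological replicate."""
    a = lib_a.set_index("snp_id")[["ref_count", "alt_count"]]
    b = lib_b.set_index("snp_id")[["ref_count", "alt_count"]]
    if set(a.index) != set(b.index):
        raise ValueError("library SNP sets differ")
    return (a + b.loc[a.index]).reset_index()


def results_to_frame(results: Sequence[AllelicActivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "input_ref": r.input_ref,
                "input_alt": r.input_alt,
                "output_ref": r.output_ref,
                "output_alt": r.output_alt,
                "effect_size": r.effect_size,
                "p": r.p,
                "q": r.q,
                "is_regulatory": r.is_regulatory,
            }
            for r in results
        ]
    )
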