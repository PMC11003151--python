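"""Hypergeometric and permutation enrichment machinery with BH FDR control.

The permutation null re-places every query element uniformly at random on
the genome: a chromosome is drawn with probability proportional to its
length, then a start uniformly from [0, chrom_len - element_len] so no
clipping occurs; element lengths are preserved. The Monte-Carlo p-value is
(1 + #{null >= observed}) / (R + 1), which never returns 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomeLayout, GenomicInterval, OverlapIndex, expand_interval


@dataclass
class PermutationResult:
    observed: int
    null_draws: np.ndarray
    p_value: float
    q_value: float | None = None
    seed: int | None = None


def hypergeom_enrichment(T: int, M: int, t: int, m: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= m).

    Drawing ``t`` detectable features from a universe of ``T`` of which ``M``
    are marked, the p-value is the probability of seeing at least the
    observed ``m`` marked features among the draws.
    """
    if not (0 <= M <= T and 0 <= t <= T and 0 <= m <= min(M, t)):
        raise ValueError(f"inconsistent counts T={T}, M={M}, t={t}, m={m}")
    return float(stats.hypergeom.sf(m - 1, T, M, t))


def expand_points(
    hits: Sequence[GenomicInterval | tuple[str, int]],
    flank: int = 20_000,
    layout: GenomeLayout | None = None,
) -> list[GenomicInterval]:
    """+/-flank windows around hits; points become [pos-flank, pos+flank+1).

    Interval hits are expanded from both ends. Windows are clipped to
    chromosome bounds when a layout is supplied.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for h in hits:
        if isinstance(h, GenomicInterval):
            out.append(expand_interval(h, flank, layout))
        else:
            chrom, pos = h
            start, end = pos - flank, pos + flank + 1
            if layout is not None:
                start, end = layout.clip(chrom, start, end)
            else:
                start = max(0, start)
            out.append(GenomicInterval(chrom, start, end))
    return out


def permutation_enrichment(
    query: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    layout: GenomeLayout,
    R: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Element-level overlap enrichment against a random-placement null.

    ``observed`` counts query elements overlapping >=1 feature (an element
    overlapping several features counts once). Each of the R null draws
    re-places every query element uniformly on the genome (chromosomes
    weighted by length, clip-free starts, lengths preserved).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    index = OverlapIndex(features)
    observed = index.count_overlapping(query)
    lengths = np.array([len(q) for q in query], dtype=np.int64)
    chrom_names = layout.names
    chrom_lens = np.array([layout.length_of(c) for c in chrom_names], dtype=np.int64)
    for L in lengths:
        if not (chrom_lens >= L).any():
            raise ValueError(f"query element of length {L} exceeds every chromosome")
    probs = chrom_lens / chrom_lens.sum()
    nq = len(query)
    null = np.zeros(R, dtype=np.int64)
    if nq > 0:
        chrom_idx = rng.choice(len(chrom_names), size=(R, nq), p=probs)
        # re-draw placements that cannot fit (element longer than chromosome)
        for _ in range(1000):
            bad = chrom_lens[chrom_idx] < lengths[None, :]
            if not bad.any():
                break
            chrom_idx[bad] = rng.choice(len(chrom_names), size=int(bad.sum()), p=probs)
        max_start = chrom_lens[chrom_idx] - lengths[None, :]
        starts = (rng.random(size=(R, nq)) * (max_start + 1)).astype(np.int64)
        ends = starts + lengths[None, :]
        hit = np.zeros((R, nq), dtype=bool)
        for ci, cname in enumerate(chrom_names):
            f_starts, f_ends = index.arrays(cname)
            mask = chrom_idx == ci
            if f_starts is None or not mask.any():
                continue
            j = np.searchsorted(f_starts, ends[mask], side="left")
            ok = j > 0
            ok[ok] = f_ends[j[ok] - 1] > starts[mask][ok]
            hit[mask] = ok
        null = hit.sum(axis=1).astype(np.int64)
    p = (1 + int((null >= observed).sum())) / (R + 1)
    return PermutationResult(int(observed), null, float(p), seed=seed)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def transposon_insertion_test(
    ten_ids: Sequence[str],
    non_ten_ids: Sequence[str],
    enhancers: dict[str, GenomicInterval],
    repeats: pd.DataFrame,
    layout: GenomeLayout,
    R: int = 1000,
    seed: int | None = None,
) -> dict:
    """Transposon insertion comparison between transcribed (TEn) and
    non-transcribed (non-TEn) enhancers.

    Returns the two-sided Fisher p on the 2x2 insertion table, per-class
    base fractions (transposon bases / enhancer bases, per group), and a
    per-family permutation-enrichment table with BH q-values computed
    across all (family x group) tests.
    """
    if not ten_ids or not non_ten_ids:
        raise ValueError("both TEn and non-TEn groups must be non-empty")
    all_repeats = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in repeats.itertuples()
    ]
    index = OverlapIndex(all_repeats)
    groups = {
        "TEn": [enhancers[i] for i in ten_ids],
        "non-TEn": [enhancers[i] for i in non_ten_ids],
    }
    with_te = {g: index.count_overlapping(ivs) for g, ivs in groups.items()}
    table = [
        [with_te["TEn"], len(groups["TEn"]) - with_te["TEn"]],
        [with_te["non-TEn"], len(groups["non-TEn"]) - with_te["non-TEn"]],
    ]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")

    base_fractions: dict[str, dict[str, float]] = {}
    for cls, sub in repeats.groupby("repeat_class"):
        cls_index = OverlapIndex(
            [GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in sub.itertuples()]
        )
        base_fractions[str(cls)] = {}
        for g, ivs in groups.items():
            covered = sum(cls_index.covered_bases(iv) for iv in ivs)
            total = sum(len(iv) for iv in ivs)
            base_fractions[str(cls)][g] = covered / total if total else 0.0

    rng = np.random.default_rng(seed)
    rows = []
    for fam, sub in repeats.groupby("repeat_family"):
        fam_ivs = [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in sub.itertuples()
        ]
        for g, ivs in groups.items():
            res = permutation_enrichment(ivs, fam_ivs, layout, R=R, rng=rng)
            rows.append(
                {"family": str(fam), "group": g, "observed": res.observed, "p": res.p_value}
            )
    fam_table = pd.DataFrame(rows)
    if len(fam_table):
        fam_table["q"] = bh_fdr(fam_table["p"].to_numpy())
    return {
        "fisher_p": float(fisher_p),
        "table": table,
        "base_fractions": base_fractions,
        "family_enrichment": fam_table,
    }
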