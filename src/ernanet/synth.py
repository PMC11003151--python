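"""Synthetic multi-omics bundle with planted, recoverable structure.

The generator lays out a small multi-chromosome genome on a fixed slot grid
(15 kb slots, 6 slots per TAD) and plants:

* enhancer peaks with outward replicate jitter (<= 200 bp), so replicate
  intersection-then-merge retains every planted enhancer;
* gene models (incl. TF genes and ncRNAs) in their own slots, far enough
  from enhancers that eRNA quantification windows stay clear;
* TF -> eRNA -> gene chains: one enhancer and one gene per chain TAD share
  a per-TF latent factor mixed into log-expression so pairwise Spearman
  approximates a target (default 0.9) at n = 20 samples;
* tissue-specific features (fold 20 in one tissue of both breeds);
* exact motif consensus instances inside chain enhancers, with the rest of
  the genome scrubbed of above-threshold matches;
* GWAS hits inside chain-eRNA +/-20 kb windows plus hits on a featureless
  background chromosome; QTL intervals; repeat annotation skewed toward
  transcribed enhancers;
* STARR-seq allele counts with a planted 3x allelic skew for true
  regulatory SNPs at depth 500 per library.

A fixed seed yields a byte-identical bundle. Ground-truth tables reference
the same enhancer/eRNA ids the pipeline derives, because the generator runs
the package's own peak -> enhancer derivation.

The latent-factor mixing weight uses the Gaussian-copula relation
rho_pearson = 2 sin(pi * rho_spearman / 6): mixing weight a = sqrt(r) gives
two features sharing the factor a latent Pearson correlation of a^2 = r and
hence the requested Spearman after the monotone lognormal transform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .enhancers import derive_enhancer_set
from .intervals import (
    AnnotationRecord,
    AnnotationSet,
    GenomeLayout,
    GenomicInterval,
)
from .motifs import MotifPwm, format_homer_motifs, reverse_complement

SLOT = 15_000
TAD_SLOTS = 6
TISSUES = ("muscle", "fat", "heart", "liver", "spleen")
BREEDS = ("ES", "Duroc")
REPLICATES = (1, 2)


@dataclass
class SyntheticConfig:
    """Knobs of the planted-structure generator (defaults are the study
    conditions every test and the acceptance run assume)."""

    seed: int = 0
    chrom_slots: tuple[int, ...] = (258, 144)  # feature chromosomes, slots each
    background_chrom_len: int = 540_000  # featureless chromosome for null placement
    enhancer_count: int = 240
    gene_count: int = 70
    tf_count: int = 30
    ncrna_count: int = 8
    fraction_transcribed: float = 0.75
    n_chains: int = 50
    target_rho: float = 0.9
    n_specific_erna: int = 30
    n_specific_genes: int = 10
    specific_fold: float = 20.0
    meanlog: float = 1.0
    sdlog: float = 0.7
    fraction_unidirectional: float = 0.3
    motif_length: int = 12
    motif_prob: float = 0.997
    motif_threshold: float = 12.0
    jitter: int = 200
    n_gwas_inside: int = 50
    n_gwas_outside: int = 40
    n_qtl: int = 6
    starr_depth: int = 500
    starr_effect: float = 3.0
    n_true_snps: int = 40
    n_null_snps: int = 60
    n_screened_out_snps: int = 20
    rna_lib_base: float = 1.2e7

    def validate(self) -> None:
        if not (0 < abs(self.target_rho) < 1):
            raise ValueError("target_rho must lie in (-1, 1), non-zero")
        for name in ("enhancer_count", "gene_count", "tf_count", "n_chains"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_tads = sum(s // TAD_SLOTS for s in self.chrom_slots)
        if self.n_chains > n_tads:
            raise ValueError(f"{self.n_chains} chains need {self.n_chains} TADs, have {n_tads}")
        pool = sum(self.chrom_slots) - self.n_chains * 2
        needed = (
            (self.enhancer_count - self.n_chains)
            + (self.gene_count - self.n_chains)
            + self.tf_count
            + self.ncrna_count
        )
        if needed > pool or self.enhancer_count < self.n_chains or self.gene_count < self.n_chains:
            raise ValueError(
                f"infeasible packing: {needed} pool features for {pool} free slots"
            )


@dataclass
class SyntheticTruth:
    chains: pd.DataFrame  # tf, motif, enhancer_id, erna_id, gene
    specific: pd.DataFrame  # feature, kind, tissue
    regulatory_snps: pd.DataFrame  # snp_id, chrom, pos, effect, is_true
    nontranscribed: list[str]


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    layout: GenomeLayout
    annotation: AnnotationSet
    peaks: dict[tuple[str, int], list[GenomicInterval]]  # (tissue, rep) -> peaks
    enhancers: list[GenomicInterval]  # derived, id-assigned
    enhancer_counts: pd.DataFrame
    chip_lib_sizes: dict[str, float]
    samples: pd.DataFrame
    erna_counts: pd.DataFrame
    rna_lib_sizes: dict[str, float]
    tpm: pd.DataFrame
    tads: list[GenomicInterval]
    gwas: pd.DataFrame
    qtl: list[GenomicInterval]
    repeats: pd.DataFrame
    motifs: list[MotifPwm]
    tf_motifs: pd.DataFrame
    snp_freqs: pd.DataFrame
    starr_input: pd.DataFrame
    starr_outputs: dict[str, pd.DataFrame]  # "rep1_lib1" ...
    truth: SyntheticTruth


def sample_sheet() -> pd.DataFrame:
    rows = [
        {"sample": f"{b}_{t}_rep{r}", "breed": b, "tissue": t, "replicate": r}
        for b in BREEDS
        for t in TISSUES
        for r in REPLICATES
    ]
    return pd.DataFrame(rows)


def _spearman_mixing_weight(target_rho: float) -> float:
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    return float(np.sqrt(r))


def _random_consensus(rng: np.random.Generator, length: int, existing: set[str]) -> str:
    while True:
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if (
            cons not in existing
            and reverse_complement(cons) not in existing
            and reverse_complement(cons) != cons  # palindromes double-count
        ):
            return cons


def _scrub_sequence(seq: list[str], patterns: list[str], keep: set[int], rng) -> None:
    """Destroy every occurrence of each pattern (and its reverse complement)
    outside ``keep`` positions by mutating the occurrence's middle base."""
    text = "".join(seq)
    for _ in range(4):
        dirty = False
        for pat in patterns:
            for needle in (pat, reverse_complement(pat)):
                start = text.find(needle)
                while start != -1:
                    if start not in keep:
                        mid = start + len(needle) // 2
                        old = text[mid]
                        new = "ACGT"[(("ACGT".index(old)) + 1 + int(rng.integers(0, 3))) % 4]
                        text = text[:mid] + new + text[mid + 1 :]
                        dirty = True
                    start = text.find(needle, start + 1)
        if not dirty:
            break
    seq[:] = list(text)


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate the full in-memory bundle (see module docstring)."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- genome scaffold -------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chrom_slots))]
    bg_chrom = f"chr{len(cfg.chrom_slots) + 1}"
    chromosomes = [
        (name, slots * SLOT) for name, slots in zip(chrom_names, cfg.chrom_slots)
    ] + [(bg_chrom, cfg.background_chrom_len)]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        name: base_codes[rng.integers(0, 4, size=length)].tobytes().decode()
        for name, length in chromosomes
    }

    # ---- TADs and slot bookkeeping --------------------------------------
    tads: list[GenomicInterval] = []
    slots: list[tuple[str, int]] = []  # (chrom, slot_start)
    tad_of_slot: dict[tuple[str, int], int] = {}
    for name, n_slots in zip(chrom_names, cfg.chrom_slots):
        for t in range(n_slots // TAD_SLOTS):
            tad_id = len(tads)
            start = t * TAD_SLOTS * SLOT
            tads.append(
                GenomicInterval(name, start, start + TAD_SLOTS * SLOT, ".", f"tad_{tad_id:03d}")
            )
            for s in range(TAD_SLOTS):
                slot = (name, start + s * SLOT)
                slots.append(slot)
                tad_of_slot[slot] = tad_id
    # background chromosome: one TAD covering it, no features
    tads.append(
        GenomicInterval(bg_chrom, 0, cfg.background_chrom_len, ".", f"tad_{len(tads):03d}")
    )

    tad_order = rng.permutation(len(tads) - 1)
    chain_tads = [int(t) for t in tad_order[: cfg.n_chains]]

    chain_gene_slots, chain_enh_slots, pool = [], [], []
    chain_tad_set = set(chain_tads)
    by_tad: dict[int, list[tuple[str, int]]] = {}
    for slot in slots:
        by_tad.setdefault(tad_of_slot[slot], []).append(slot)
    for tid, tslots in by_tad.items():
        tslots.sort(key=lambda s: s[1])
        if tid in chain_tad_set:
            chain_gene_slots.append((tid, tslots[0]))
            chain_enh_slots.append((tid, tslots[2]))
            pool.extend([tslots[1], tslots[3], tslots[4], tslots[5]])
        else:
            pool.extend(tslots)
    chain_gene_slots.sort(key=lambda x: chain_tads.index(x[0]))
    chain_enh_slots.sort(key=lambda x: chain_tads.index(x[0]))
    pool = [pool[i] for i in rng.permutation(len(pool))]

    def take(n: int) -> list[tuple[str, int]]:
        out, rest = pool[:n], pool[n:]
        pool[:] = rest
        return out

    # ---- gene / TF / ncRNA models ---------------------------------------
    genes: list[AnnotationRecord] = []
    ncrnas: list[AnnotationRecord] = []

    def add_gene(slot: tuple[str, int], gid: str, biotype: str = "protein_coding"):
        chrom, s = slot
        strand = "+" if rng.random() < 0.5 else "-"
        rec = AnnotationRecord(
            GenomicInterval(chrom, s + 2000, s + 8000, strand, gid), biotype
        )
        (ncrnas if biotype != "protein_coding" else genes).append(rec)
        return rec

    chain_genes = [
        add_gene(slot, f"gene_{i:03d}")
        for i, (_, slot) in enumerate(chain_gene_slots)
    ]
    decoy_genes = [
        add_gene(slot, f"gene_{cfg.n_chains + i:03d}")
        for i, slot in enumerate(take(cfg.gene_count - cfg.n_chains))
    ]
    tf_genes = [
        add_gene(slot, f"TF_{i:02d}") for i, slot in enumerate(take(cfg.tf_count))
    ]
    nc_biotypes = ("miRNA", "snoRNA", "lncRNA", "tRNA")
    for i, slot in enumerate(take(cfg.ncrna_count)):
        add_gene(slot, f"ncrna_{i:02d}", nc_biotypes[i % len(nc_biotypes)])
    annotation = AnnotationSet(genes=genes, ncrnas=ncrnas)

    # ---- planted enhancers and peaks ------------------------------------
    chain_enh = [
        GenomicInterval(chrom, s + 6500, s + 8500)
        for _, (chrom, s) in chain_enh_slots
    ]
    decoy_enh = [
        GenomicInterval(chrom, s + 6500, s + 8500)
        for chrom, s in take(cfg.enhancer_count - cfg.n_chains)
    ]
    planted_enh = chain_enh + decoy_enh

    peaks: dict[tuple[str, int], list[GenomicInterval]] = {}
    for tissue in TISSUES:
        for rep in REPLICATES:
            jit_lo = rng.integers(0, cfg.jitter + 1, size=len(planted_enh))
            jit_hi = rng.integers(0, cfg.jitter + 1, size=len(planted_enh))
            peaks[(tissue, rep)] = [
                GenomicInterval(iv.chrom, iv.start - int(a), iv.end + int(b))
                for iv, a, b in zip(planted_enh, jit_lo, jit_hi)
            ]

    layout = GenomeLayout(chromosomes, sequences={})
    enhancers = derive_enhancer_set(peaks, annotation, layout)
    if len(enhancers) != len(planted_enh):  # construction guarantees 1:1
        raise RuntimeError("planted enhancers lost during derivation")

    # map planted -> derived id by containment of the planted center
    def derived_id(planted: GenomicInterval) -> str:
        for iv in enhancers:
            if iv.chrom == planted.chrom and iv.start <= planted.center < iv.end:
                return iv.id
        raise RuntimeError("planted enhancer not found")

    chain_enh_ids = [derived_id(iv) for iv in chain_enh]
    decoy_enh_ids = [derived_id(iv) for iv in decoy_enh]
    all_enh_ids = [iv.id for iv in enhancers]

    # ---- motifs: one PWM per TF, consensus planted in chain enhancers ----
    existing: set[str] = set()
    pwms: list[MotifPwm] = []
    for i in range(cfg.tf_count):
        cons = _random_consensus(rng, cfg.motif_length, existing)
        existing.add(cons)
        probs = np.full((cfg.motif_length, 4), (1 - cfg.motif_prob) / 3)
        for j, base in enumerate(cons):
            probs[j, "ACGT".index(base)] = cfg.motif_prob
        pwms.append(MotifPwm(f"motif_TF_{i:02d}", cons, probs, cfg.motif_threshold))
    tf_of_chain = [i % cfg.tf_count for i in range(cfg.n_chains)]

    # scrub accidental matches genome-wide, then plant chain consensi
    keep_positions: dict[str, set[int]] = {n: set() for n, _ in chromosomes}
    planted_sites = []
    for ci, enh_iv in enumerate(chain_enh):
        pwm = pwms[tf_of_chain[ci]]
        pos = enh_iv.center - cfg.motif_length // 2
        planted_sites.append((enh_iv.chrom, pos, pwm.consensus))
        keep_positions[enh_iv.chrom].add(pos)
    patterns = [p.consensus for p in pwms]
    for name in list(sequences):
        seq_list = list(sequences[name])
        for chrom, pos, cons in planted_sites:
            if chrom == name:
                seq_list[pos : pos + len(cons)] = list(cons)
        _scrub_sequence(seq_list, patterns, keep_positions[name], rng)
        # re-plant in case scrubbing grazed a planted site (disjoint keeps prevent it)
        for chrom, pos, cons in planted_sites:
            if chrom == name:
                seq_list[pos : pos + len(cons)] = list(cons)
        sequences[name] = "".join(seq_list)
    # construction guarantee: each consensus occurs exactly at its planted sites
    genome_text = {n: s for n, s in sequences.items()}
    planted_count = {p.consensus: 0 for p in pwms}
    for _, _, cons in planted_sites:
        planted_count[cons] += 1
    for pwm in pwms:
        n_occ = sum(
            s.count(pwm.consensus) + s.count(reverse_complement(pwm.consensus))
            for s in genome_text.values()
        )
        if n_occ != planted_count[pwm.consensus]:
            raise RuntimeError(
                f"motif {pwm.name}: {n_occ} genome occurrences, "
                f"expected {planted_count[pwm.consensus]} planted"
            )
    layout = GenomeLayout(chromosomes, sequences=sequences)

    # ---- expression ------------------------------------------------------
    samples = sample_sheet()
    sample_ids = list(samples["sample"])
    n_samples = len(sample_ids)
    a = _spearman_mixing_weight(cfg.target_rho)
    z_tf = rng.standard_normal((cfg.tf_count, n_samples))

    chain_erna_ids = [f"eRNA_{e}" for e in chain_enh_ids]
    decoy_erna_ids = [f"eRNA_{e}" for e in decoy_enh_ids]

    def log_expr(latent: np.ndarray | None) -> np.ndarray:
        noise = rng.standard_normal(n_samples)
        eps = noise if latent is None else a * latent + np.sqrt(1 - a**2) * noise
        return np.exp(cfg.meanlog + cfg.sdlog * eps)

    expr: dict[str, np.ndarray] = {}
    for i, g in enumerate(chain_genes):
        expr[g.interval.id] = log_expr(z_tf[tf_of_chain[i]])
    for g in decoy_genes:
        expr[g.interval.id] = log_expr(None)
    for i, g in enumerate(tf_genes):
        expr[g.interval.id] = log_expr(z_tf[i])
    for i, eid in enumerate(chain_erna_ids):
        expr[eid] = log_expr(z_tf[tf_of_chain[i]])
    for eid in decoy_erna_ids:
        expr[eid] = log_expr(None)

    # non-transcribed enhancers: near-zero eRNA signal (decoys only)
    n_non = int(round((1 - cfg.fraction_transcribed) * cfg.enhancer_count))
    non_idx = rng.choice(len(decoy_erna_ids), size=min(n_non, len(decoy_erna_ids)), replace=False)
    nontranscribed = sorted(decoy_erna_ids[i] for i in non_idx)
    for eid in nontranscribed:
        expr[eid] = expr[eid] * 0.01

    # planted tissue-specific features (transcribed decoys / decoy genes)
    tissue_idx = {t: [i for i, s in samples.iterrows() if s["tissue"] == t] for t in TISSUES}
    spec_rows = []
    specific_pool = [e for e in decoy_erna_ids if e not in set(nontranscribed)]
    spec_ernas = [specific_pool[i] for i in rng.choice(len(specific_pool), cfg.n_specific_erna, replace=False)]
    for j, eid in enumerate(spec_ernas):
        tissue = TISSUES[j % len(TISSUES)]
        mask = np.zeros(n_samples, dtype=bool)
        mask[tissue_idx[tissue]] = True
        expr[eid] = np.where(mask, expr[eid] * cfg.specific_fold, expr[eid])
        spec_rows.append({"feature": eid, "kind": "eRNA", "tissue": tissue})
    spec_genes = [decoy_genes[i].interval.id for i in rng.choice(len(decoy_genes), cfg.n_specific_genes, replace=False)]
    for j, gid in enumerate(spec_genes):
        tissue = TISSUES[j % len(TISSUES)]
        mask = np.zeros(n_samples, dtype=bool)
        mask[tissue_idx[tissue]] = True
        expr[gid] = np.where(mask, expr[gid] * cfg.specific_fold, expr[gid])
        spec_rows.append({"feature": gid, "kind": "gene", "tissue": tissue})

    # TPM matrix (genes + TFs) with one pathological all-zero row
    gene_ids = [g.interval.id for g in chain_genes + decoy_genes + tf_genes]
    tpm = pd.DataFrame(
        {s: [expr[g][k] for g in gene_ids] for k, s in enumerate(sample_ids)},
        index=pd.Index(gene_ids, name="feature"),
    )
    tpm.loc["gene_zero"] = 0.0
    tpm = tpm.round(4)

    # stranded eRNA counts; plus fraction fixed per eRNA
    rna_lib = {
        s: float(int(cfg.rna_lib_base * (0.8 + 0.4 * rng.random())))
        for s in sample_ids
    }
    erna_ids = chain_erna_ids + decoy_erna_ids
    uni = rng.random(len(erna_ids)) < cfg.fraction_unidirectional
    pf = np.where(
        uni, rng.beta(8, 1, size=len(erna_ids)), rng.beta(5, 5, size=len(erna_ids))
    )
    count_rows = []
    for i, eid in enumerate(erna_ids):
        for k, s in enumerate(sample_ids):
            total = int(round(expr[eid][k] * rna_lib[s] / 1e6))
            plus = int(round(total * pf[i]))
            count_rows.append(
                {"erna_id": eid, "sample": s, "plus_count": plus, "minus_count": total - plus}
            )
    erna_counts = pd.DataFrame(count_rows)

    # ---- ChIP activity counts (IP / INPUT) -------------------------------
    mean_expr = {f"eRNA_{e}": float(np.mean(expr[f"eRNA_{e}"])) for e in all_enh_ids}
    chip_lib = {"ip": 1e7, "input": 1e7}
    enhancer_counts = pd.DataFrame(
        {
            "enhancer_id": all_enh_ids,
            "ip_count": [
                int(round(500 * mean_expr[f"eRNA_{e}"] * (0.9 + 0.2 * rng.random())))
                for e in all_enh_ids
            ],
            "input_count": [int(300 + rng.integers(0, 51)) for _ in all_enh_ids],
        }
    )

    # ---- GWAS hits and QTL -----------------------------------------------
    gwas_rows = []
    enh_by_id = {iv.id: iv for iv in enhancers}
    for i, eid in enumerate(chain_enh_ids[: cfg.n_gwas_inside]):
        c = enh_by_id[eid]
        pos = c.center + int(rng.integers(-20_000, 20_001))
        gwas_rows.append(
            {"hit_id": f"gwas_{i:03d}", "chrom": c.chrom, "pos": max(0, pos), "trait_class": "Meat and Carcass"}
        )
    for i in range(cfg.n_gwas_outside):
        pos = int(rng.integers(1000, cfg.background_chrom_len - 1000))
        gwas_rows.append(
            {"hit_id": f"gwas_bg_{i:03d}", "chrom": bg_chrom, "pos": pos, "trait_class": "Health"}
        )
    gwas = pd.DataFrame(gwas_rows)

    qtl = []
    for i in range(cfg.n_qtl):
        chrom, length = chromosomes[i % len(chromosomes)]
        start = int(rng.integers(0, max(1, length - 200_000)))
        qtl.append(GenomicInterval(chrom, start, start + 200_000, ".", f"qtl_{i:02d}"))

    # ---- repeats ----------------------------------------------------------
    repeat_rows = []
    transcribed_enh_ids = [e for e in all_enh_ids if f"eRNA_{e}" not in set(nontranscribed)]
    nont_enh_ids = [e for e in all_enh_ids if f"eRNA_{e}" in set(nontranscribed)]
    k = 0
    for e in transcribed_enh_ids:
        if rng.random() < 0.6:
            iv = enh_by_id[e]
            repeat_rows.append((iv.chrom, iv.start + 100, iv.start + 500, "LTR/ERV1"))
            k += 1
    for e in nont_enh_ids:
        if rng.random() < 0.1:
            iv = enh_by_id[e]
            repeat_rows.append((iv.chrom, iv.start + 100, iv.start + 500, "LTR/ERV1"))
    for e in all_enh_ids:
        if rng.random() < 0.15:
            iv = enh_by_id[e]
            repeat_rows.append((iv.chrom, iv.end - 300, iv.end - 100, "SINE/tRNA"))
    for _ in range(30):
        chrom, length = chromosomes[int(rng.integers(0, len(chromosomes)))]
        s = int(rng.integers(0, length - 600))
        repeat_rows.append((chrom, s, s + 600, "LINE/L1"))
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "name"])
    cls = repeats["name"].str.partition("/")
    repeats["repeat_class"] = cls[0]
    repeats["repeat_family"] = repeats["name"]

    # ---- STARR SNPs --------------------------------------------------------
    snp_rows, freq_rows = [], []
    n_cand = cfg.n_true_snps + cfg.n_null_snps
    for i in range(n_cand):
        chain = i % cfg.n_chains
        enh_iv = enh_by_id[chain_enh_ids[chain]]
        offset = -1200 if i < cfg.n_chains else 800
        pos = enh_iv.center + offset
        is_true = i < cfg.n_true_snps
        snp_rows.append(
            {
                "snp_id": f"snp_{i:03d}",
                "chrom": enh_iv.chrom,
                "pos": pos,
                "is_true": is_true,
                "effect": cfg.starr_effect if is_true else 1.0,
            }
        )
        freq_rows.append(
            {
                "snp_id": f"snp_{i:03d}",
                "chrom": enh_iv.chrom,
                "pos": pos,
                "east_maf": round(0.40 + 0.08 * rng.random(), 3),
                "west_maf": round(0.02 + 0.05 * rng.random(), 3),
                "mixed_maf": round(0.10 + 0.30 * rng.random(), 3),
            }
        )
    for i in range(cfg.n_screened_out_snps):
        mode = i % 3
        if mode == 0:  # too-small MAF difference
            enh_iv = enh_by_id[chain_enh_ids[i % cfg.n_chains]]
            freq_rows.append(
                {"snp_id": f"snp_x_{i:02d}", "chrom": enh_iv.chrom, "pos": enh_iv.center + 300,
                 "east_maf": 0.30, "west_maf": 0.15, "mixed_maf": 0.2}
            )
        elif mode == 1:  # mixed-pool MAF too low
            enh_iv = enh_by_id[chain_enh_ids[i % cfg.n_chains]]
            freq_rows.append(
                {"snp_id": f"snp_x_{i:02d}", "chrom": enh_iv.chrom, "pos": enh_iv.center + 320,
                 "east_maf": 0.45, "west_maf": 0.05, "mixed_maf": 0.01}
            )
        else:  # outside every eRNA region
            freq_rows.append(
                {"snp_id": f"snp_x_{i:02d}", "chrom": bg_chrom,
                 "pos": int(rng.integers(0, cfg.background_chrom_len)),
                 "east_maf": 0.45, "west_maf": 0.05, "mixed_maf": 0.2}
            )
    snp_truth = pd.DataFrame(snp_rows)
    snp_freqs = pd.DataFrame(freq_rows)

    def allele_counts(depth: int, p_alt: float) -> tuple[int, int]:
        alt = int(rng.binomial(depth, p_alt))
        return depth - alt, alt

    input_rows = []
    out_libs: dict[str, list[dict]] = {f"rep{r}_lib{l}": [] for r in (1, 2) for l in (1, 2)}
    skew = cfg.starr_effect / (1 + cfg.starr_effect)
    for row in snp_rows:
        ref, alt = allele_counts(cfg.starr_depth, 0.5)
        input_rows.append({"snp_id": row["snp_id"], "ref_count": ref, "alt_count": alt})
        p_alt = skew if row["is_true"] else 0.5
        for lib in out_libs:
            ref, alt = allele_counts(cfg.starr_depth, p_alt)
            out_libs[lib].append({"snp_id": row["snp_id"], "ref_count": ref, "alt_count": alt})
    # pathological records: low coverage and a zero alt cell
    input_rows.append({"snp_id": "snp_lowcov", "ref_count": 5, "alt_count": 5})
    for lib in out_libs:
        out_libs[lib].append({"snp_id": "snp_lowcov", "ref_count": 3, "alt_count": 2})
    input_rows.append({"snp_id": "snp_zerocell", "ref_count": cfg.starr_depth, "alt_count": 0})
    for lib in out_libs:
        out_libs[lib].append({"snp_id": "snp_zerocell", "ref_count": cfg.starr_depth, "alt_count": 0})

    # ---- truth -------------------------------------------------------------
    chains = pd.DataFrame(
        {
            "tf": [tf_genes[tf_of_chain[i]].interval.id for i in range(cfg.n_chains)],
            "motif": [pwms[tf_of_chain[i]].name for i in range(cfg.n_chains)],
            "enhancer_id": chain_enh_ids,
            "erna_id": chain_erna_ids,
            "gene": [g.interval.id for g in chain_genes],
        }
    )
    truth = SyntheticTruth(
        chains=chains,
        specific=pd.DataFrame(spec_rows),
        regulatory_snps=snp_truth,
        nontranscribed=nontranscribed,
    )
    tf_motifs = pd.DataFrame(
        {
            "tf": [g.interval.id for g in tf_genes],
            "motif": [p.name for p in pwms],
        }
    )
    return SyntheticBundle(
        config=cfg,
        layout=layout,
        annotation=annotation,
        peaks=peaks,
        enhancers=enhancers,
        enhancer_counts=enhancer_counts,
        chip_lib_sizes=chip_lib,
        samples=samples,
        erna_counts=erna_counts,
        rna_lib_sizes=rna_lib,
        tpm=tpm,
        tads=tads,
        gwas=gwas,
        qtl=qtl,
        repeats=repeats,
        motifs=pwms,
        tf_motifs=tf_motifs,
        snp_freqs=snp_freqs,
        starr_input=pd.DataFrame(input_rows),
        starr_outputs={k: pd.DataFrame(v) for k, v in out_libs.items()},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write every bundle file under ``outdir`` and return the manifest."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    eio.write_fasta(bundle.layout.sequences, outdir / "genome.fa")
    eio.write_chrom_sizes(bundle.layout, outdir / "chrom.sizes")
    eio.write_gtf(bundle.annotation, outdir / "annotation.gtf")
    for (tissue, rep), pk in sorted(bundle.peaks.items()):
        eio.write_bed(pk, outdir / "peaks" / f"{tissue}_rep{rep}.bed")
    bundle.enhancer_counts.to_csv(outdir / "enhancer_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"library": k, "size": int(v)} for k, v in bundle.chip_lib_sizes.items()]
    ).to_csv(outdir / "chip_lib_sizes.tsv", sep="\t", index=False)
    bundle.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    bundle.erna_counts.to_csv(outdir / "erna_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample": k, "size": int(v)} for k, v in bundle.rna_lib_sizes.items()]
    ).to_csv(outdir / "rna_lib_sizes.tsv", sep="\t", index=False)
    bundle.tpm.to_csv(outdir / "tpm.tsv", sep="\t")
    eio.write_bed(bundle.tads, outdir / "tads.bed")
    bundle.gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    eio.write_bed(bundle.qtl, outdir / "qtl.bed")
    eio.write_bed(
        [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), ".", str(r.name))
            for r in bundle.repeats.itertuples()
        ],
        outdir / "repeats.bed",
    )
    with open(outdir / "custom.motifs", "w") as fh:
        fh.write(format_homer_motifs(bundle.motifs))
    bundle.tf_motifs.to_csv(outdir / "tf_motifs.tsv", sep="\t", index=False)
    bundle.snp_freqs.to_csv(outdir / "snp_freqs.tsv", sep="\t", index=False)
    bundle.starr_input.to_csv(outdir / "starr_input.tsv", sep="\t", index=False)
    for lib, df in sorted(bundle.starr_outputs.items()):
        df.to_csv(outdir / f"starr_output_{lib}.tsv", sep="\t", index=False)
    bundle.truth.chains.to_csv(outdir / "truth" / "planted_chains.tsv", sep="\t", index=False)
    bundle.truth.specific.to_csv(outdir / "truth" / "planted_specific.tsv", sep="\t", index=False)
    bundle.truth.regulatory_snps.to_csv(
        outdir / "truth" / "planted_regulatory_snps.tsv", sep="\t", index=False
    )
    pd.DataFrame({"erna_id": bundle.truth.nontranscribed}).to_csv(
        outdir / "truth" / "nontranscribed.tsv", sep="\t", index=False
    )
    cfg_dict = asdict(bundle.config)
    cfg_dict["chrom_slots"] = list(cfg_dict["chrom_slots"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(outdir))] = digest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
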