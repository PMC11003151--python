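"""End-to-end orchestration: bundle directory -> refined eGRN + run report.

Stage order: enhancer catalog -> eRNA quantification -> tissue specificity
-> enrichment statistics -> motif scan -> eGRN inference -> GWAS filter ->
STARR allelic refinement -> independent network validation. The report
records survivor counts along each filter chain; permutation stages consume
the config seed, so two runs with the same config and bundle are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import egrn, enrichment, erna, io as eio, motifs as motif_mod, specificity, starr
from .enhancers import call_super_enhancers, derive_enhancer_set, quantify_activity
from .intervals import GenomicInterval, OverlapIndex

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """The stated analysis cutoffs; deviations from defaults are logged."""

    detectable_mean_rpm: float = 1.0
    direction_bounds: tuple[float, float] = (0.05, 0.95)
    tsi: float = 0.8
    rho_tf: float = 0.5
    rho_gene: float = 0.3
    fdr: float = 0.05
    max_gene_distance: int = 1_000_000
    gwas_flank: int = 20_000
    erna_flank: int = 3_000
    annotation_flank: int = 1_000
    tss_flank: int = 1_000
    min_coverage: int = 20
    maf_diff: float = 0.3
    mixed_maf: float = 0.05
    permutations: int = 1000
    stitch_distance: int = 12_500
    motif_q: float = 0.01


@dataclass
class RunConfig:
    bundle_dir: str
    output_dir: str
    seed: int = 0
    network_tissue: str = "fat"
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        t = self.thresholds
        if not (0 <= t.direction_bounds[0] <= t.direction_bounds[1] <= 1):
            raise ValueError("direction bounds must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= t.fdr <= 1 and 0 <= t.tsi <= 1):
            raise ValueError("fdr and tsi thresholds must lie in [0, 1]")
        for name in (
            "max_gene_distance", "gwas_flank", "erna_flank", "annotation_flank",
            "tss_flank", "min_coverage", "permutations", "stitch_distance",
        ):
            if getattr(t, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        defaults = Thresholds()
        for name, value in asdict(t).items():
            if value != getattr(defaults, name):
                logger.warning("threshold %s deviates from default: %r", name, value)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    thr = raw.pop("thresholds", {})
    if "direction_bounds" in thr:
        thr["direction_bounds"] = tuple(thr["direction_bounds"])
    return RunConfig(thresholds=Thresholds(**thr), **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input file {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a bundle directory; return the run report."""
    config.validate()
    thr = config.thresholds
    bdir = Path(config.bundle_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "filter_chains": {}, "seed": config.seed}

    # ---- load reference --------------------------------------------------
    layout = eio.read_genome(_require(bdir / "genome.fa", "reference"))
    annotation = eio.read_gtf(_require(bdir / "annotation.gtf", "reference"))
    samples = pd.read_csv(_require(bdir / "samples.tsv", "reference"), sep="\t")
    tads = eio.read_bed(_require(bdir / "tads.bed", "reference"))

    # ---- enhancer catalog ------------------------------------------------
    peak_files = sorted((bdir / "peaks").glob("*_rep*.bed"))
    if not peak_files:
        raise StageError("enhancers", f"no peak files under {bdir / 'peaks'}")
    peaks = {}
    for pf in peak_files:
        tissue, rep = pf.stem.rsplit("_rep", 1)
        peaks[(tissue, int(rep))] = eio.read_bed(pf)
    enhancers = derive_enhancer_set(peaks, annotation, layout, thr.tss_flank)
    eio.write_bed(enhancers, outdir / "enhancers.bed")
    report["stages"]["enhancers"] = {"count": len(enhancers)}

    counts = pd.read_csv(_require(bdir / "enhancer_counts.tsv", "activity"), sep="\t")
    chip_lib = pd.read_csv(_require(bdir / "chip_lib_sizes.tsv", "activity"), sep="\t")
    lib = dict(zip(chip_lib["library"], chip_lib["size"].astype(float)))
    activity = quantify_activity(
        enhancers,
        dict(zip(counts["enhancer_id"], counts["ip_count"])),
        dict(zip(counts["enhancer_id"], counts["input_count"])),
        lib["ip"],
        lib["input"],
    )
    act_df = pd.DataFrame(
        [
            {"enhancer_id": a.enhancer_id, "ip_rpm": a.ip_rpm,
             "input_rpm": a.input_rpm, "fold_change": a.fold_change}
            for a in activity
        ]
    )
    act_df.to_csv(outdir / "enhancer_activity.tsv", sep="\t", index=False)
    signal = {
        a.enhancer_id: max(a.ip_rpm - a.input_rpm, 0.0) for a in activity
    }
    supers = call_super_enhancers(enhancers, signal, thr.stitch_distance)
    pd.DataFrame(
        [
            {"chrom": s.stitched.chrom, "start": s.stitched.start, "end": s.stitched.end,
             "members": ",".join(s.member_ids), "total_signal": s.total_signal,
             "rank": s.rank, "is_super": s.is_super}
            for s in supers
        ]
    ).to_csv(outdir / "super_enhancers.tsv", sep="\t", index=False)
    report["stages"]["super_enhancers"] = {
        "stitched": len(supers), "super": sum(s.is_super for s in supers)
    }

    # ---- eRNA quantification --------------------------------------------
    records = erna.define_erna_regions(enhancers, annotation, layout)
    stranded = pd.read_csv(_require(bdir / "erna_counts.tsv", "erna"), sep="\t")
    rna_lib_df = pd.read_csv(_require(bdir / "rna_lib_sizes.tsv", "erna"), sep="\t")
    rna_lib = dict(zip(rna_lib_df["sample"], rna_lib_df["size"].astype(float)))
    erna.quantify_rpm(records, stranded, rna_lib, samples)
    erna.assign_directions(records, samples)
    for rec in records:
        rec.gc_fraction = erna.gc_fraction(layout.sequence(rec.region))

    detectable: dict[tuple[str, str], set[str]] = {}
    for breed in samples["breed"].unique():
        for tissue in samples["tissue"].unique():
            detectable[(breed, tissue)] = erna.call_detectable(records, samples, breed, tissue)
    detectable_union = set().union(*detectable.values()) if detectable else set()
    sample_ids = list(samples["sample"])
    rpm_matrix = pd.DataFrame(
        {s: [rec.rpm.get(s, 0.0) for rec in records] for s in sample_ids},
        index=pd.Index([rec.erna_id for rec in records], name="feature"),
    )
    rpm_matrix.to_csv(outdir / "erna_rpm.tsv", sep="\t")
    pd.DataFrame(
        [
            {"erna_id": r.erna_id, "enhancer_id": r.enhancer_id,
             "chrom": r.region.chrom, "start": r.region.start, "end": r.region.end,
             "n_windows": len(r.windows), "direction": r.direction,
             "gc_fraction": r.gc_fraction}
            for r in records
        ]
    ).to_csv(outdir / "erna_records.tsv", sep="\t", index=False)
    report["stages"]["erna"] = {
        "records": len(records),
        "detectable_union": len(detectable_union),
        "bidirectional": sum(r.direction == "bidirectional" for r in records),
        "unidirectional": sum(r.direction == "unidirectional" for r in records),
    }
    report["filter_chains"]["erna"] = [
        len(enhancers), len(records), len(detectable_union)
    ]

    # activity-expression coupling across eight expression bins
    mean_rpm = {r.erna_id: float(np.mean([r.rpm[s] for s in sample_ids])) for r in records}
    fold = {
        f"eRNA_{a.enhancer_id}": a.fold_change
        for a in activity if a.fold_change is not None
    }
    try:
        bin_r, bin_p = erna.binned_activity_correlation(mean_rpm, fold)
        report["stages"]["activity_expression"] = {"pearson_r": bin_r, "p": bin_p}
    except ValueError as exc:
        report["stages"]["activity_expression"] = {"error": str(exc)}

    # ---- tissue specificity ----------------------------------------------
    tsi_frames = []
    specific_ernas: dict[str, set[str]] = {}
    specific_genes: dict[str, set[str]] = {}
    tpm = pd.read_csv(_require(bdir / "tpm.tsv", "specificity"), sep="\t", index_col=0)
    tf_map = pd.read_csv(_require(bdir / "tf_motifs.tsv", "specificity"), sep="\t")
    tf_ids = [t for t in tf_map["tf"] if t in tpm.index]
    gene_tpm = tpm.drop(index=tf_ids)
    for breed in samples["breed"].unique():
        res_e = specificity.call_tissue_specific(rpm_matrix, samples, breed, thr.tsi)
        res_g = specificity.call_tissue_specific(gene_tpm, samples, breed, thr.tsi)
        specific_ernas[breed] = {
            r.feature_id for r in res_e if r.is_specific and r.feature_id in detectable_union
        }
        specific_genes[breed] = {r.feature_id for r in res_g if r.is_specific}
        for res, kind in ((res_e, "eRNA"), (res_g, "gene")):
            df = specificity.tsi_results_to_frame(res)
            df["kind"] = kind
            tsi_frames.append(df)
    pd.concat(tsi_frames).to_csv(outdir / "tsi.tsv", sep="\t", index=False)
    report["stages"]["specificity"] = {
        breed: {"ernas": len(specific_ernas[breed]), "genes": len(specific_genes[breed])}
        for breed in specific_ernas
    }

    # ---- enrichment -------------------------------------------------------
    rng_seed = config.seed
    enrich_rows = []
    region_of = {r.erna_id: r.region for r in records}
    super_index = OverlapIndex([s.stitched for s in supers if s.is_super])
    gene_tss = {
        rec.interval.id: (rec.interval.chrom, rec.tss)
        for rec in annotation.genes
        if rec.interval.id not in tf_ids
    }
    for breed in samples["breed"].unique():
        for tissue in samples["tissue"].unique():
            det = detectable[(breed, tissue)]
            spec_here = {
                e for e in specific_ernas[breed]
                if e in det
            }
            in_se = {e for e in det if super_index.overlaps_any(region_of[e])}
            T, M = len(det), len(in_se)
            t_, m_ = len(spec_here), len(spec_here & in_se)
            if T and t_ <= T and m_ <= min(M, t_):
                p = enrichment.hypergeom_enrichment(T, M, t_, m_)
                enrich_rows.append(
                    {"test": f"SE:{breed}:{tissue}", "observed": m_, "p": p}
                )
    # genes within 1 Mb of tissue-specific eRNAs (per breed)
    for breed in samples["breed"].unique():
        spec_regions = [region_of[e] for e in specific_ernas[breed]]
        near = OverlapIndex(
            enrichment.expand_points(spec_regions, thr.max_gene_distance, layout)
        ) if spec_regions else None
        det_genes = set().union(
            *(
                specificity.detectable_genes(gene_tpm, samples, breed, t)
                for t in samples["tissue"].unique()
            )
        )
        def _near(g: str) -> bool:
            chrom, tss = gene_tss[g]
            return near is not None and near.overlaps_any(GenomicInterval(chrom, tss, tss + 1))
        X = {g for g in gene_tss if g in det_genes}
        Y = {g for g in X if _near(g)}
        x_ = specific_genes[breed] & X
        y_ = {g for g in x_ if _near(g)}
        if X:
            p = enrichment.hypergeom_enrichment(len(X), len(Y), len(x_), len(y_))
            enrich_rows.append({"test": f"genes_near_eRNA:{breed}", "observed": len(y_), "p": p})

    gwas = pd.read_csv(_require(bdir / "gwas.tsv", "enrichment"), sep="\t")
    gwas_hits = [(str(r.chrom), int(r.pos)) for r in gwas.itertuples()]
    gwas_windows = enrichment.expand_points(gwas_hits, thr.gwas_flank, layout)
    qtl = eio.read_bed(_require(bdir / "qtl.bed", "enrichment"))
    spec_all = sorted(set().union(*specific_ernas.values())) if specific_ernas else []
    spec_regions_all = [region_of[e] for e in spec_all]
    if spec_regions_all:
        res = enrichment.permutation_enrichment(
            spec_regions_all, gwas_windows, layout, R=thr.permutations, seed=rng_seed
        )
        enrich_rows.append({"test": "GWAS_permutation", "observed": res.observed, "p": res.p_value})
        res = enrichment.permutation_enrichment(
            spec_regions_all, qtl, layout, R=thr.permutations, seed=rng_seed + 1
        )
        enrich_rows.append({"test": "QTL_permutation", "observed": res.observed, "p": res.p_value})

    repeats = eio.read_repeat_bed(_require(bdir / "repeats.bed", "transposons"))
    labels = erna.label_transcribed_enhancers(enhancers, records, detectable_union)
    ten = [l.enhancer_id for l in labels if l.label == "TEn"]
    non_ten = [l.enhancer_id for l in labels if l.label == "non-TEn"]
    enh_by_id = {iv.id: iv for iv in enhancers}
    if ten and non_ten:
        te = enrichment.transposon_insertion_test(
            ten, non_ten, enh_by_id, repeats, layout, R=thr.permutations, seed=rng_seed + 2
        )
        enrich_rows.append({"test": "transposon_fisher", "observed": te["table"][0][0], "p": te["fisher_p"]})
        te["family_enrichment"].to_csv(outdir / "transposon_families.tsv", sep="\t", index=False)
        report["stages"]["transposons"] = {
            "ten": len(ten), "non_ten": len(non_ten), "fisher_p": te["fisher_p"]
        }
    enrich_df = pd.DataFrame(enrich_rows)
    if len(enrich_df):
        enrich_df["q"] = enrichment.bh_fdr(enrich_df["p"].to_numpy())
    enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # ---- motif scan (network tissue) --------------------------------------
    pwms = motif_mod.parse_homer_motifs((bdir / "custom.motifs").read_text())
    tissue = config.network_tissue
    net_detectable = sorted(
        set().union(
            *(detectable[(b, tissue)] for b in samples["breed"].unique())
        )
    )
    net_records = [r for r in records if r.erna_id in set(net_detectable)]
    enh_seqs = {
        r.erna_id: layout.sequence(enh_by_id[r.enhancer_id]) for r in net_records
    }
    hits = motif_mod.scan_sequences(pwms, enh_seqs)
    pd.DataFrame(
        [
            {"motif": h.motif, "erna_id": h.sequence_id, "offset": h.offset,
             "strand": h.strand, "score": h.score}
            for h in hits
        ]
    ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    report["stages"]["motifs"] = {"pwms": len(pwms), "hits": len(hits)}

    # known-motif enrichment: tissue-specific vs non-specific detectable eRNAs
    spec_net = {
        e: layout.sequence(enh_by_id[r.enhancer_id])
        for r in net_records
        for e in [r.erna_id]
        if any(e in specific_ernas[b] for b in specific_ernas)
    }
    bg_net = {e: s for e, s in enh_seqs.items() if e not in spec_net}
    if spec_net and bg_net:
        enr = motif_mod.known_motif_enrichment(spec_net, bg_net, pwms, thr.motif_q)
        pd.DataFrame(
            [
                {"motif": m.motif, "fg": m.fg_hits, "bg": m.bg_hits, "p": m.p, "q": m.q}
                for m in enr
            ]
        ).to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)

    # ---- eGRN -------------------------------------------------------------
    motif_of_tf = dict(zip(tf_map["tf"], tf_map["motif"]))
    tissue_samples = samples[samples["tissue"] == tissue]["sample"]
    tf_expression = tpm.loc[[t for t in tf_ids]][sample_ids]
    tf_expressed = {
        t: bool(tpm.loc[t, list(tissue_samples)].mean() >= thr.detectable_mean_rpm)
        for t in tf_ids
    }
    erna_expression = rpm_matrix.loc[net_detectable]
    gene_expression = gene_tpm[sample_ids]
    tad_ivs = tads
    tf_edges = egrn.link_tf_to_erna(
        tf_ids, net_detectable, hits, tf_expression, erna_expression,
        tf_expressed, motif_of_tf, thr.rho_tf, thr.fdr,
    )
    net_regions = {r.erna_id: r.region for r in net_records}
    gene_edges = egrn.link_erna_to_genes(
        net_regions, gene_tss, erna_expression, gene_expression, tad_ivs,
        thr.rho_gene, thr.fdr, thr.max_gene_distance,
    )
    network = egrn.assemble(
        tf_edges + gene_edges,
        {
            "seed": config.seed,
            "network_tissue": tissue,
            "thresholds": asdict(thr),
            "input_digest": egrn.input_digest(rpm_matrix, tpm),
        },
    )
    gwas_kept = egrn.filter_by_gwas(net_regions, gwas_hits, thr.gwas_flank)
    egrn.mark_gwas_support(network, gwas_kept)
    filtered = egrn.restrict_ernas(network, gwas_kept, "gwas")
    egrn.write_exports(network, outdir, "egrn_full")
    egrn.write_exports(filtered, outdir, "egrn_gwas")
    report["stages"]["egrn"] = {
        "tf_edges": sum(e.edge_type == "TF->eRNA" for e in network.edges),
        "gene_edges": sum(e.edge_type == "eRNA->gene" for e in network.edges),
        "ernas": len(network.ernas),
        "ernas_after_gwas": len(filtered.ernas),
    }

    # ---- STARR refinement --------------------------------------------------
    freqs_df = pd.read_csv(_require(bdir / "snp_freqs.tsv", "starr"), sep="\t")
    freqs = [
        starr.SnpPopulationFreqs(
            str(r.snp_id), str(r.chrom), int(r.pos),
            float(r.east_maf), float(r.west_maf), float(r.mixed_maf),
        )
        for r in freqs_df.itertuples()
    ]
    network_regions = {e: net_regions[e] for e in filtered.ernas if e in net_regions}
    candidates = starr.screen_candidate_snps(
        freqs, list(network_regions.values()), thr.maf_diff, thr.mixed_maf
    )
    cand_set = set(candidates)
    read_counts = lambda name: pd.read_csv(_require(bdir / name, "starr"), sep="\t")
    rep1 = starr.collapse_output_libraries(
        read_counts("starr_output_rep1_lib1.tsv"), read_counts("starr_output_rep1_lib2.tsv")
    )
    rep2 = starr.collapse_output_libraries(
        read_counts("starr_output_rep2_lib1.tsv"), read_counts("starr_output_rep2_lib2.tsv")
    )
    merged, rep_corr = starr.merge_output_replicates(rep1, rep2)
    input_df = read_counts("starr_input.tsv")
    in_counts = {
        str(r.snp_id): (int(r.ref_count), int(r.alt_count))
        for r in input_df.itertuples() if str(r.snp_id) in cand_set
    }
    out_counts = {
        str(r.snp_id): (int(r.ref_count), int(r.alt_count))
        for r in merged.itertuples() if str(r.snp_id) in cand_set
    }
    missing = sorted(set(in_counts) - set(out_counts))
    for snp_id in missing:
        in_counts.pop(snp_id)
    results = starr.allelic_activity_test(in_counts, out_counts, thr.min_coverage, thr.fdr)
    starr.results_to_frame(results).to_csv(outdir / "starr_results.tsv", sep="\t", index=False)
    reg_positions = [
        (f.chrom, f.pos) for f in freqs
        if f.snp_id in {r.snp_id for r in results if r.is_regulatory}
    ]
    refined = egrn.refine_by_starr(filtered, network_regions, reg_positions)
    egrn.write_exports(refined, outdir, "egrn_refined")
    report["stages"]["starr"] = {
        "snps_in_table": len(freqs),
        "candidates": len(candidates),
        "tested": len(results),
        "regulatory": sum(r.is_regulatory for r in results),
        "replicate_correlation": rep_corr,
    }
    report["filter_chains"]["snps"] = [
        len(freqs), len(candidates), len(results), sum(r.is_regulatory for r in results)
    ]
    report["filter_chains"]["egrn_ernas"] = [
        len(network.ernas), len(filtered.ernas), len(refined.ernas)
    ]

    # ---- independent validation -------------------------------------------
    violations = egrn.validate_network(
        refined, tf_expression, erna_expression, gene_expression,
        net_regions, gene_tss, tad_ivs, hits, motif_of_tf,
        thr.rho_tf, thr.rho_gene, thr.fdr, thr.max_gene_distance,
    )
    report["stages"]["validation"] = {"violations": violations}
    if violations:
        raise StageError("validation", f"{len(violations)} constraint violations")

    report["stages"]["refined_egrn"] = {
        "tf_edges": sum(e.edge_type == "TF->eRNA" for e in refined.edges),
        "gene_edges": sum(e.edge_type == "eRNA->gene" for e in refined.edges),
        "ernas": len(refined.ernas),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
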