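"""Directed eRNA-mediated gene regulatory network (eGRN) assembly.

Edges are typed and evidence-gated:

* TF -> eRNA: the TF's motif hits the eRNA's enhancer sequence, the TF is
  expressed in the tissue, and Spearman rho > 0.5 with FDR q < 0.05 across
  the 20 samples.
* eRNA -> gene: Spearman rho > 0.3 with q < 0.05, gene TSS within 1 Mb of
  the eRNA center, and both anchors inside the same TAD.

eRNA nodes may additionally be filtered to those near trait GWAS hits
(+/-20 kb), and refined by STARR-seq regulatory SNPs (eRNAs without a
regulatory SNP in their region are pruned with their edges).

FDR families: all TF-eRNA pairs tested form one BH batch; all eRNA-gene
candidate pairs form another.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr, expand_points
from .intervals import GenomicInterval, OverlapIndex
from .motifs import MotifHit

logger = logging.getLogger(__name__)

TF_RHO_THRESHOLD = 0.5
GENE_RHO_THRESHOLD = 0.3
FDR_THRESHOLD = 0.05
MAX_GENE_DISTANCE = 1_000_000
GWAS_FLANK = 20_000


@dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    rho: float
    p: float
    q: float | None = None


@dataclass
class EgrnEdge:
    edge_type: str  # "TF->eRNA" | "eRNA->gene"
    source: str
    target: str
    rho: float
    q: float
    motif_hit: bool = False
    distance: int | None = None
    tad_id: str | None = None
    gwas_supported: bool = False
    starr_supported: bool = False


@dataclass
class Egrn:
    tfs: set[str] = field(default_factory=set)
    ernas: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    edges: list[EgrnEdge] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def spearman_fdr(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> list[CorrelationResult]:
    """Spearman rho (average ranks for ties) with t-approximation p and BH q.

    Both matrices must share the same sample column order; each requested
    (row-of-a, row-of-b) pair yields one result. Pairs with a constant
    vector are dropped with a warning. The BH correction spans exactly the
    pairs tested in this call — callers batch per linking task.
    """
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("matrices must share the same sample column order")
    results = []
    for a, b in pairs:
        va = matrix_a.loc[a].to_numpy(dtype=float)
        vb = matrix_b.loc[b].to_numpy(dtype=float)
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            logger.warning("constant expression vector in pair (%s, %s); dropped", a, b)
            continue
        rho, p = stats.spearmanr(va, vb)
        results.append(CorrelationResult(a, b, float(rho), float(p)))
    if results:
        qs = bh_fdr([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def link_tf_to_erna(
    tf_ids: Sequence[str],
    erna_ids: Sequence[str],
    motif_hits: Sequence[MotifHit],
    tf_expression: pd.DataFrame,
    erna_expression: pd.DataFrame,
    tf_expressed: Mapping[str, bool],
    motif_of_tf: Mapping[str, str],
    rho_threshold: float = TF_RHO_THRESHOLD,
    q_threshold: float = FDR_THRESHOLD,
) -> list[EgrnEdge]:
    """TF -> eRNA edges gated on motif evidence, expression and correlation.

    ``motif_hits`` are hits of TF motifs over each eRNA's enhancer sequence
    (sequence_id = eRNA id); ``motif_of_tf`` names each TF's motif. Only
    pairs with motif evidence and an expressed TF are correlation-tested
    (one BH family).
    """
    hit_pairs = {
        (tf, h.sequence_id)
        for h in motif_hits
        for tf in tf_ids
        if motif_of_tf.get(tf) == h.motif
    }
    candidates = [
        (tf, e)
        for tf in tf_ids
        for e in erna_ids
        if (tf, e) in hit_pairs and tf_expressed.get(tf, False)
    ]
    corr = spearman_fdr(tf_expression, erna_expression, candidates)
    return [
        EgrnEdge("TF->eRNA", c.feature_a, c.feature_b, c.rho, c.q, motif_hit=True)
        for c in corr
        if c.rho > rho_threshold and c.q is not None and c.q < q_threshold
    ]


def _tad_of(anchor: tuple[str, int], tads: Sequence[GenomicInterval]) -> str | None:
    """Smallest TAD strictly containing the anchor point, or None."""
    best: GenomicInterval | None = None
    chrom, pos = anchor
    for tad in tads:
        if tad.contains_point(chrom, pos) and (best is None or len(tad) < len(best)):
            best = tad
    return best.id if best is not None else None


def link_erna_to_genes(
    erna_regions: Mapping[str, GenomicInterval],
    gene_tss: Mapping[str, tuple[str, int]],
    erna_expression: pd.DataFrame,
    gene_expression: pd.DataFrame,
    tads: Sequence[GenomicInterval],
    rho_threshold: float = GENE_RHO_THRESHOLD,
    q_threshold: float = FDR_THRESHOLD,
    max_distance: int = MAX_GENE_DISTANCE,
) -> list[EgrnEdge]:
    """eRNA -> gene edges: correlation + <=1 Mb anchor distance + same TAD.

    Anchors are the eRNA region center and the gene TSS. Candidate pairs
    (within 1 Mb, both anchors in a shared TAD) form one BH family.
    Anchors outside every TAD drop the candidate (logged).
    """
    candidates: list[tuple[str, str, int, str]] = []
    dropped_no_tad = 0
    erna_tad = {
        e: _tad_of((iv.chrom, iv.center), tads) for e, iv in erna_regions.items()
    }
    gene_tad = {g: _tad_of(anchor, tads) for g, anchor in gene_tss.items()}
    for e, iv in erna_regions.items():
        e_anchor = iv.center
        for g, (gchrom, gtss) in gene_tss.items():
            if gchrom != iv.chrom:
                continue
            dist = abs(gtss - e_anchor)
            if dist > max_distance:
                continue
            te, tg = erna_tad[e], gene_tad[g]
            if te is None or tg is None:
                dropped_no_tad += 1
                continue
            if te != tg:
                continue
            candidates.append((e, g, dist, te))
    if dropped_no_tad:
        logger.info("%d eRNA-gene candidates dropped (anchor outside all TADs)", dropped_no_tad)
    corr = spearman_fdr(
        erna_expression, gene_expression, [(e, g) for e, g, _, _ in candidates]
    )
    meta = {(e, g): (dist, tad) for e, g, dist, tad in candidates}
    edges = []
    for c in corr:
        if c.rho > rho_threshold and c.q is not None and c.q < q_threshold:
            dist, tad = meta[(c.feature_a, c.feature_b)]
            edges.append(
                EgrnEdge(
                    "eRNA->gene", c.feature_a, c.feature_b, c.rho, c.q,
                    distance=dist, tad_id=tad,
                )
            )
    return edges


def filter_by_gwas(
    erna_regions: Mapping[str, GenomicInterval],
    gwas_hits: Sequence[GenomicInterval | tuple[str, int]],
    flank: int = GWAS_FLANK,
) -> set[str]:
    """eRNAs whose region overlaps any GWAS hit expanded by +/-flank."""
    if not gwas_hits:
        return set()
    windows = expand_points(gwas_hits, flank)
    index = OverlapIndex(windows)
    return {e for e, iv in erna_regions.items() if index.overlaps_any(iv)}


def assemble(edges: Sequence[EgrnEdge], metadata: dict | None = None) -> Egrn:
    """Deduplicate edges, derive node sets, and attach provenance."""
    seen: dict[tuple, EgrnEdge] = {}
    for e in edges:
        if e.edge_type == "TF->eRNA" and not e.motif_hit:
            raise ValueError(f"TF edge {e.source}->{e.target} lacks motif evidence")
        if e.edge_type == "eRNA->gene":
            if e.distance is None or e.distance > MAX_GENE_DISTANCE or e.tad_id is None:
                raise ValueError(f"gene edge {e.source}->{e.target} violates distance/TAD constraints")
        seen.setdefault((e.edge_type, e.source, e.target), e)
    net = Egrn(provenance=dict(metadata or {}))
    for e in seen.values():
        net.edges.append(e)
        if e.edge_type == "TF->eRNA":
            net.tfs.add(e.source)
            net.ernas.add(e.target)
        elif e.edge_type == "eRNA->gene":
            net.ernas.add(e.source)
            net.genes.add(e.target)
        else:
            raise ValueError(f"unknown edge type {e.edge_type}")
    net.edges.sort(key=lambda e: (e.edge_type, e.source, e.target))
    return net


def restrict_ernas(network: Egrn, keep: set[str], reason: str) -> Egrn:
    """Drop eRNA nodes outside ``keep`` with their edges; prune orphans."""
    edges = [
        e for e in network.edges
        if (e.target in keep if e.edge_type == "TF->eRNA" else e.source in keep)
    ]
    pruned = assemble(edges, {**network.provenance, f"filter_{reason}": len(keep)})
    return pruned


def refine_by_starr(
    network: Egrn,
    erna_regions: Mapping[str, GenomicInterval],
    regulatory_snp_positions: Sequence[tuple[str, int]],
) -> Egrn:
    """Keep only eRNAs whose region contains a regulatory SNP ("hub eRNAs").

    Monotone pruning: never adds nodes or edges; TF/gene nodes left with
    degree zero disappear with their eRNA.
    """
    keep = set()
    for e in network.ernas:
        iv = erna_regions.get(e)
        if iv is None:
            continue
        if any(iv.contains_point(c, p) for c, p in regulatory_snp_positions):
            keep.add(e)
    refined = restrict_ernas(network, keep, "starr")
    for edge in refined.edges:
        edge.starr_supported = True
    return refined


def mark_gwas_support(network: Egrn, gwas_kept: set[str]) -> None:
    for e in network.edges:
        erna = e.target if e.edge_type == "TF->eRNA" else e.source
        e.gwas_supported = erna in gwas_kept


# ---------------------------------------------------------------------------
# export / validation
# ---------------------------------------------------------------------------


def edges_to_frame(network: Egrn) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "type": e.edge_type,
                "rho": e.rho,
                "q": e.q,
                "distance": e.distance,
                "tad": e.tad_id,
                "gwas": e.gwas_supported,
                "starr": e.starr_supported,
            }
            for e in network.edges
        ],
        columns=["source", "target", "type", "rho", "q", "distance", "tad", "gwas", "starr"],
    )


def to_networkx(network: Egrn) -> nx.DiGraph:
    g = nx.DiGraph(**{k: str(v) for k, v in network.provenance.items()})
    for tf in sorted(network.tfs):
        g.add_node(tf, kind="TF")
    for e in sorted(network.ernas):
        g.add_node(e, kind="eRNA")
    for gene in sorted(network.genes):
        g.add_node(gene, kind="gene")
    for e in network.edges:
        g.add_edge(
            e.source, e.target, type=e.edge_type, rho=e.rho, q=e.q,
            distance=-1 if e.distance is None else e.distance,
            tad="" if e.tad_id is None else e.tad_id,
            gwas=e.gwas_supported, starr=e.starr_supported,
        )
    return g


def write_exports(network: Egrn, outdir, prefix: str = "egrn") -> dict[str, str]:
    """GraphML + SIF + edge TSV + provenance JSON under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    g = to_networkx(network)
    graphml = outdir / f"{prefix}.graphml"
    nx.write_graphml(g, graphml)
    paths["graphml"] = str(graphml)
    sif = outdir / f"{prefix}.sif"
    with open(sif, "w") as fh:
        for e in network.edges:
            rel = "activates" if e.edge_type == "TF->eRNA" else "regulates"
            fh.write(f"{e.source}\t{rel}\t{e.target}\n")
    paths["sif"] = str(sif)
    tsv = outdir / f"{prefix}_edges.tsv"
    edges_to_frame(network).to_csv(tsv, sep="\t", index=False)
    paths["edges_tsv"] = str(tsv)
    prov = outdir / f"{prefix}_provenance.json"
    with open(prov, "w") as fh:
        json.dump(network.provenance, fh, indent=2, sort_keys=True, default=str)
    paths["provenance"] = str(prov)
    return paths


def input_digest(*frames: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for df in frames:
        h.update(pd.util.hash_pandas_object(df, index=True).values.tobytes())
    return h.hexdigest()[:16]


def validate_network(
    network: Egrn,
    tf_expression: pd.DataFrame,
    erna_expression: pd.DataFrame,
    gene_expression: pd.DataFrame,
    erna_regions: Mapping[str, GenomicInterval],
    gene_tss: Mapping[str, tuple[str, int]],
    tads: Sequence[GenomicInterval],
    motif_hits: Sequence[MotifHit],
    motif_of_tf: Mapping[str, str],
    rho_tf: float = TF_RHO_THRESHOLD,
    rho_gene: float = GENE_RHO_THRESHOLD,
    q_threshold: float = FDR_THRESHOLD,
    max_distance: int = MAX_GENE_DISTANCE,
) -> list[str]:
    """Independent re-check of every emitted edge from raw inputs.

    Recomputes rho, distance, TAD membership and motif evidence per edge
    and returns a list of violation messages (empty = valid network).
    """
    violations = []
    hit_index = {(h.motif, h.sequence_id) for h in motif_hits}
    for e in network.edges:
        if e.edge_type == "TF->eRNA":
            motif = motif_of_tf.get(e.source)
            if motif is None or (motif, e.target) not in hit_index:
                violations.append(f"{e.source}->{e.target}: no motif hit")
            va = tf_expression.loc[e.source].to_numpy(dtype=float)
            vb = erna_expression.loc[e.target].to_numpy(dtype=float)
            rho = float(stats.spearmanr(va, vb)[0])
            if not rho > rho_tf:
                violations.append(f"{e.source}->{e.target}: rho {rho:.3f} <= {rho_tf}")
            if abs(rho - e.rho) > 1e-9:
                violations.append(f"{e.source}->{e.target}: stored rho mismatch")
        elif e.edge_type == "eRNA->gene":
            va = erna_expression.loc[e.source].to_numpy(dtype=float)
            vb = gene_expression.loc[e.target].to_numpy(dtype=float)
            rho = float(stats.spearmanr(va, vb)[0])
            if not rho > rho_gene:
                violations.append(f"{e.source}->{e.target}: rho {rho:.3f} <= {rho_gene}")
            iv = erna_regions[e.source]
            gchrom, gtss = gene_tss[e.target]
            if gchrom != iv.chrom or abs(gtss - iv.center) > max_distance:
                violations.append(f"{e.source}->{e.target}: distance violation")
            ta = _tad_of((iv.chrom, iv.center), tads)
            tb = _tad_of((gchrom, gtss), tads)
            if ta is None or ta != tb:
                violations.append(f"{e.source}->{e.target}: TAD violation")
        else:
            violations.append(f"unknown edge type {e.edge_type}")
        if e.q is None or not (0 <= e.q < q_threshold):
            violations.append(f"{e.source}->{e.target}: q {e.q} not < {q_threshold}")
    return violations
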