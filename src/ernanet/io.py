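"""Readers and writers for BED, GTF, FASTA and the TSV tables used throughout.

BED is 0-based half-open; GTF is 1-based closed and converted on read.
Canonical BED6 records round-trip byte-stably.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    AnnotationRecord,
    AnnotationSet,
    GenomeLayout,
    GenomicInterval,
    NCRNA_BIOTYPES,
)


def _open(path_or_handle, mode="r"):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; score column is ignored."""
    handle, close = _open(path)
    out = []
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    finally:
        if close:
            handle.close()
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, score: str = "0") -> None:
    """Write BED6 (BED3 fields always present; name defaults to '.')."""
    handle, close = _open(path, "w")
    try:
        for iv in intervals:
            name = iv.id if iv.id is not None else "."
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
    finally:
        if close:
            handle.close()


def interval_to_bed_line(iv: GenomicInterval, score: str = "0") -> str:
    name = iv.id if iv.id is not None else "."
    return f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"


def bed_line_to_interval(line: str) -> GenomicInterval:
    f = line.rstrip("\n").split("\t")
    name = f[3] if len(f) > 3 and f[3] != "." else None
    strand = f[5] if len(f) > 5 else "."
    return GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name)


# ---------------------------------------------------------------------------
# chromosome sizes / FASTA
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout([(str(r.chrom), int(r.length)) for r in df.itertuples()])


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    handle, close = _open(path, "w")
    try:
        for name, length in layout.chromosomes:
            handle.write(f"{name}\t{length}\n")
    finally:
        if close:
            handle.close()


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome(fasta_path) -> GenomeLayout:
    """Layout (names, lengths and sequence) from a FASTA file."""
    seqs = read_fasta(fasta_path)
    return GenomeLayout([(n, len(s)) for n, s in seqs.items()], sequences=seqs)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path) -> AnnotationSet:
    """Gene-level records from a GTF; 1-based closed converted to 0-based half-open.

    Only ``gene`` features are consumed; biotype is taken from the
    ``gene_biotype`` (or ``gene_type``) attribute, defaulting to protein_coding.
    """
    genes: list[AnnotationRecord] = []
    ncrnas: list[AnnotationRecord] = []
    handle, close = _open(path)
    try:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = _parse_gtf_attributes(f[8])
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding"))
            iv = GenomicInterval(
                f[0], int(f[3]) - 1, int(f[4]), f[6] if f[6] in "+-" else ".",
                attrs.get("gene_id"),
            )
            rec = AnnotationRecord(iv, biotype)
            (ncrnas if biotype in NCRNA_BIOTYPES else genes).append(rec)
    finally:
        if close:
            handle.close()
    return AnnotationSet(genes=genes, ncrnas=ncrnas)


def write_gtf(annotation: AnnotationSet, path, source: str = "ernanet") -> None:
    handle, close = _open(path, "w")
    try:
        for rec in annotation.all_records:
            iv = rec.interval
            attrs = f'gene_id "{iv.id}"; gene_biotype "{rec.biotype}";'
            handle.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# RepeatMasker
# ---------------------------------------------------------------------------


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Parse RepeatMasker .out into chrom/start/end/name/class/family.

    Coordinates in .out are 1-based closed; converted to 0-based half-open.
    """
    rows = []
    handle, close = _open(path)
    try:
        for line in handle:
            f = line.split()
            if len(f) < 11 or not f[0].replace(".", "").isdigit():
                continue  # header / blank lines
            cls_fam = f[10]
            cls, _, fam = cls_fam.partition("/")
            rows.append(
                {
                    "chrom": f[4],
                    "start": int(f[5]) - 1,
                    "end": int(f[6]),
                    "name": f[9],
                    "repeat_class": cls,
                    "repeat_family": cls_fam if fam else cls,
                }
            )
    finally:
        if close:
            handle.close()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "repeat_class", "repeat_family"])


def read_repeat_bed(path) -> pd.DataFrame:
    """BED fallback for repeats: name column 'class/family' or 'class'."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3],
    )
    cls = df["name"].str.partition("/")
    df["repeat_class"] = cls[0]
    df["repeat_family"] = df["name"]
    return df[["chrom", "start", "end", "name", "repeat_class", "repeat_family"]]


def repeats_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end), ".", str(r.name))
        for r in df.itertuples()
    ]
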