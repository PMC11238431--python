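"""Readers, writers and interval primitives for the formats the pipeline
touches: GFF3 (genes, transcripts, repeats), FASTA, VCF with cuteSV-style
INFO keys, and the per-cytosine CX-report / expression / homolog-pair /
m6A-site TSV dialects.

Coordinate convention: everything in memory is 0-based half-open
(``[start, end)``); GFF3 and VCF are converted at the I/O boundary (both
are 1-based inclusive on disk), and the conversion is an involution.

Bulk per-cytosine data is held in a pandas DataFrame (columns
``chrom, pos, strand, context, count_methylated, count_unmethylated`` with
``pos`` 1-based as in the Bismark CX report); the ``CytosineCall``
dataclass models a single record where that is clearer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TranscriptModel",
    "RepeatFeature",
    "SVRecord",
    "CytosineCall",
    "ExpressionRecord",
    "Annotation",
    "CX_COLUMNS",
    "REPEAT_CLASSES",
    "SV_TYPES",
    "parse_gff3",
    "write_gff3",
    "parse_cx_report",
    "write_cx_report",
    "parse_sv_vcf",
    "write_sv_vcf",
    "parse_fasta",
    "write_fasta",
    "tile_genome",
    "interval_overlap",
    "read_expression",
    "write_expression",
    "read_homolog_pairs",
    "write_homolog_pairs",
]

CONTEXTS = ("CG", "CHG", "CHH")
REPEAT_CLASSES = ("Copia", "Gypsy", "LINE", "DNA_TE", "other")
SV_TYPES = ("INS", "DEL", "DUP", "INV", "TRANS")
CX_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    transcripts: tuple = ()

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position)."""
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware 3' end (0-based position)."""
        return self.interval.end - 1 if self.interval.strand != "-" else self.interval.start


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError("region lengths must be >= 0")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


@dataclass(frozen=True)
class RepeatFeature:
    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"repeat_class must be one of {REPEAT_CLASSES}")


@dataclass(frozen=True)
class SVRecord:
    """One structural variant; ``pos``/``end`` are 1-based as in VCF."""

    sv_type: str
    chrom: str
    pos: int
    length: int
    id: str
    end: int | None = None
    chrom2: str | None = None  # mate contig for TRANS

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"sv_type must be one of {SV_TYPES}")
        if self.sv_type != "TRANS" and self.length <= 0:
            raise ValueError("length must be > 0 for INS/DEL/DUP/INV")
        if self.end is not None and self.chrom2 in (None, self.chrom) and self.end < self.pos:
            raise ValueError("end must be >= pos")


@dataclass(frozen=True)
class CytosineCall:
    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def level(self) -> float:
        """Methylation level; NaN when the site has no coverage."""
        cov = self.coverage
        return self.count_methylated / cov if cov else float("nan")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError("fpkm must be >= 0")


@dataclass
class Annotation:
    """Parsed annotation bundle: gene models, transcript models, repeats."""

    genes: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)
    repeats: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_DEFAULT_REPEAT_TYPES = ("repeat_region", "transposable_element", "dispersed_repeat")
_DEFAULT_REPEAT_CLASS_KEYS = ("repeat_class", "Class", "class", "Name")


def _map_repeat_class(token: str) -> str:
    low = token.lower()
    if "copia" in low:
        return "Copia"
    if "gypsy" in low:
        return "Gypsy"
    if "line" in low:
        return "LINE"
    if "dna" in low or "hat" in low or "harbinger" in low:
        return "DNA_TE"
    return "other"


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"malformed GFF3 line {lineno}: end < start")
            if fields[6] not in ("+", "-", "."):
                raise ValueError(f"malformed GFF3 line {lineno}: unknown strand {fields[6]!r}")


def parse_gff3(
    path,
    repeat_types: tuple = _DEFAULT_REPEAT_TYPES,
    repeat_class_keys: tuple = _DEFAULT_REPEAT_CLASS_KEYS,
) -> Annotation:
    """Parse a GFF3 file into gene/transcript models and repeat features.

    1-based inclusive coordinates on disk become 0-based half-open in
    memory.  Repeat features are recognized by ``repeat_types`` with their
    class read from the first attribute key in ``repeat_class_keys``.
    Malformed lines raise with the offending line number.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    ann = Annotation()
    for g in db.features_of_type("gene"):
        iv = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        tx_ids = []
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            tx_ids.append(t.id)
            utr5 = sum(c.end - c.start + 1 for c in db.children(t, featuretype="five_prime_UTR"))
            cds = sum(c.end - c.start + 1 for c in db.children(t, featuretype="CDS"))
            utr3 = sum(c.end - c.start + 1 for c in db.children(t, featuretype="three_prime_UTR"))
            ann.transcripts[t.id] = TranscriptModel(t.id, g.id, utr5, cds, utr3)
        ann.genes[g.id] = GeneModel(g.id, iv, tuple(tx_ids))
    for rtype in repeat_types:
        for r in db.features_of_type(rtype):
            token = "other"
            for key in repeat_class_keys:
                if key in r.attributes:
                    token = r.attributes[key][0]
                    break
            ann.repeats.append(
                RepeatFeature(
                    GenomicInterval(r.seqid, r.start - 1, r.end, r.strand),
                    _map_repeat_class(token),
                )
            )
    return ann


def write_gff3(annotation: Annotation, path) -> None:
    """Emit the annotation as GFF3 (1-based inclusive on disk).

    Single-exon transcript architecture is written explicitly as
    five_prime_UTR / CDS / three_prime_UTR children so region lengths
    round-trip.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(
            annotation.genes.values(), key=lambda g: (g.interval.chrom, g.interval.start)
        ):
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\ttriplimeth\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gene.gene_id}\n"
            )
            for tid in gene.transcripts:
                tx = annotation.transcripts[tid]
                fh.write(
                    f"{iv.chrom}\ttriplimeth\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID={tid};Parent={gene.gene_id}\n"
                )
                # lay the regions 5'->3' along the strand
                if iv.strand == "-":
                    segs = [("three_prime_UTR", tx.utr3_len), ("CDS", tx.cds_len),
                            ("five_prime_UTR", tx.utr5_len)]
                else:
                    segs = [("five_prime_UTR", tx.utr5_len), ("CDS", tx.cds_len),
                            ("three_prime_UTR", tx.utr3_len)]
                cursor = iv.start
                for ftype, length in segs:
                    if length <= 0:
                        continue
                    fh.write(
                        f"{iv.chrom}\ttriplimeth\t{ftype}\t{cursor + 1}\t{cursor + length}"
                        f"\t.\t{iv.strand}\t.\tID={tid}.{ftype};Parent={tid}\n"
                    )
                    cursor += length
        for i, rep in enumerate(
            sorted(annotation.repeats, key=lambda r: (r.interval.chrom, r.interval.start))
        ):
            iv = rep.interval
            fh.write(
                f"{iv.chrom}\ttriplimeth\trepeat_region\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID=repeat{i};repeat_class={rep.repeat_class}\n"
            )


# ---------------------------------------------------------------------------
# CX report
# ---------------------------------------------------------------------------

def parse_cx_report(path) -> pd.DataFrame:
    """Read a Bismark-style CX report (TSV, no header).

    Columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context, trinucleotide.  Zero-coverage rows are
    retained (their level is undefined, not zero).  Context tokens outside
    {CG, CHG, CHH} raise.
    """
    df = pd.read_csv(
        path, sep="\t", names=CX_COLUMNS, header=None,
        dtype={"chrom": str, "pos": np.int64, "strand": str,
               "count_methylated": np.int64, "count_unmethylated": np.int64,
               "context": str, "trinucleotide": str},
    )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        tok = df.loc[bad, "context"].iloc[0]
        raise ValueError(f"unknown cytosine context token {tok!r}")
    return df


def write_cx_report(calls: pd.DataFrame, path) -> None:
    df = calls.copy()
    if "trinucleotide" not in df.columns:
        df["trinucleotide"] = df["context"]
    df[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# SV VCF (cuteSV-style INFO keys)
# ---------------------------------------------------------------------------

_TRANS_ALIASES = {"BND", "TRA", "TRANS"}


def parse_sv_vcf(path):
    """Parse a VCF with cuteSV-style INFO keys into SVRecords.

    SVLEN signs are discarded; BND/TRA records map to TRANS with the mate
    position taken from CHR2/END.  Records with an unknown SVTYPE are
    skipped with a warning; a missing SVTYPE raises.
    """
    records = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            if "SVTYPE" not in info:
                raise ValueError(f"record {rec.id or rec.pos} lacks SVTYPE")
            svtype = info["SVTYPE"]
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype in _TRANS_ALIASES:
                svtype = "TRANS"
            if svtype not in SV_TYPES:
                skipped += 1
                continue
            svlen = info.get("SVLEN", 0)
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            length = abs(int(svlen)) if svlen is not None else 0
            chrom2 = info.get("CHR2")
            if isinstance(chrom2, tuple):
                chrom2 = chrom2[0]
            end = rec.stop if svtype != "INS" else None
            if svtype == "TRANS":
                end = info.get("END", rec.stop)
                if isinstance(end, tuple):
                    end = end[0]
                length = max(length, 1)
            if svtype in ("DEL", "DUP", "INV") and length == 0 and end is not None:
                length = int(end) - rec.pos
            records.append(
                SVRecord(
                    sv_type=svtype, chrom=rec.chrom, pos=rec.pos,
                    length=length, id=rec.id or f"sv_{len(records)}",
                    end=int(end) if end is not None else None,
                    chrom2=str(chrom2) if chrom2 is not None else None,
                )
            )
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) with unknown SVTYPE", stacklevel=2)
    return records


def write_sv_vcf(records, path, contigs: dict | None = None) -> None:
    """Write SVRecords as a minimal VCF 4.2 with cuteSV-style INFO keys."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate contig of translocation">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in sorted({r.chrom for r in records} | {r.chrom2 for r in records if r.chrom2}):
            lines.append(f"##contig=<ID={name}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        info = [f"SVTYPE={'BND' if r.sv_type == 'TRANS' else r.sv_type}",
                f"SVLEN={r.length}"]
        if r.end is not None:
            info.append(f"END={r.end}")
        if r.chrom2 is not None:
            info.append(f"CHR2={r.chrom2}")
        alt = f"<{r.sv_type}>" if r.sv_type != "TRANS" else f"N[{r.chrom2 or r.chrom}:{r.end}["
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.id}\tN\t{alt}\t.\tPASS\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA and genome tiling
# ---------------------------------------------------------------------------

def parse_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path), "fasta",
    )


def tile_genome(seqs, window: int = 10_000, step: int = 100):
    """Tile sequences into overlapping windows (the 10-kb/100-bp scheme used
    to re-map one assembly onto another).

    ``seqs`` is a ``{name: sequence}`` dict or a FASTA path.  Windows start
    at 0 and advance by ``step``; the terminal window is truncated at the
    sequence end and emitted only when it is at least ``step`` long.
    Headers encode ``chrom:start-end`` 0-based half-open.  Yields
    ``(header, subsequence)`` pairs.
    """
    if window < step or step < 1:
        raise ValueError("require window >= step >= 1")
    if not isinstance(seqs, dict):
        seqs = parse_fasta(seqs)
    for name, seq in seqs.items():
        length = len(seq)
        start = 0
        while start < length:
            end = min(start + window, length)
            if end == start + window:
                yield f"{name}:{start}-{end}", seq[start:end]
                if end == length:
                    break
            else:  # truncated terminal window
                if end - start >= step:
                    yield f"{name}:{start}-{end}", seq[start:end]
                break
            start += step


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp under half-open semantics (0 across chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


# ---------------------------------------------------------------------------
# Simple TSV tables
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Long-format expression table: gene_id, sample_id, fpkm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    if (df["fpkm"] < 0).any():
        raise ValueError("fpkm must be >= 0")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df[["gene_id", "sample_id", "fpkm"]].to_csv(path, sep="\t", index=False)


def read_homolog_pairs(path) -> pd.DataFrame:
    """Unordered, deduplicated homolog pairs: gene_a, gene_b, score."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if (df["gene_a"] == df["gene_b"]).any():
        raise ValueError("self-pairs are not allowed")
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df


def write_homolog_pairs(df: pd.DataFrame, path) -> None:
    df[["gene_a", "gene_b", "score"]].to_csv(path, sep="\t", index=False)
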