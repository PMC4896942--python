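"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; VCF positions stay
1-based only at the parse/emit boundary, and GFF3's 1-based inclusive
coordinates are converted on read.  All readers reject out-of-range
coordinates rather than reinterpreting them.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .variant_filtering import VariantRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Gff3ParseError",
    "read_gff3",
    "read_vcf_subset",
    "write_vcf_subset",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: ``start`` inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """One gene (one transcript) with exon/CDS/UTR structure."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    phase: int = 0

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def validate(self) -> list[str]:
        """Collect non-fatal structural warnings."""
        warnings: list[str] = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                warnings.append(f"{self.gene_id}: overlapping exons {a} / {b}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                warnings.append(f"{self.gene_id}: CDS {c} outside any exon")
        if self.cds and self.cds_length % 3 != 0:
            warnings.append(
                f"{self.gene_id}: CDS length {self.cds_length} not a multiple of 3"
            )
        return warnings


class Gff3ParseError(ValueError):
    pass


_GFF_EXON = {"exon"}
_GFF_CDS = {"CDS"}
_GFF_UTR5 = {"five_prime_UTR", "5UTR"}
_GFF_UTR3 = {"three_prime_UTR", "3UTR"}


def _gff3_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for token in raw.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            raise Gff3ParseError(f"line {lineno}: malformed attribute {token!r}")
        key, _, value = token.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path, report: list[str] | None = None) -> list[GeneModel]:
    """Parse a GFF3 subset into GeneModels (0-based half-open coordinates).

    One GeneModel per ``gene`` feature; exon/CDS/UTR children are matched via
    Parent chains.  Malformed lines raise :class:`Gff3ParseError` naming the
    line; structural oddities (CDS outside exon, CDS length not a multiple of
    3) are appended to ``report`` when given, never fatal.
    """
    genes: dict[str, GeneModel] = {}
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    pending: list[tuple[str, str, GenomicInterval, int]] = []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, phase_s, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise Gff3ParseError(f"line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise Gff3ParseError(
                    f"line {lineno}: out-of-range coordinates {start1}..{end1}"
                )
            attrs = _gff3_attributes(attr_s, lineno)
            interval = GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            if ftype == "gene":
                gene_id = attrs.get("ID", f"gene_line{lineno}")
                genes[gene_id] = GeneModel(gene_id=gene_id, interval=interval)
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID", f"tx_line{lineno}")
                parent_of[tid] = attrs.get("Parent", tid)
            elif ftype in _GFF_EXON | _GFF_CDS | _GFF_UTR5 | _GFF_UTR3:
                parent = attrs.get("Parent", "")
                phase = int(phase_s) if phase_s in ("0", "1", "2") else 0
                pending.append((ftype, parent, interval, phase))

    for ftype, parent, interval, phase in pending:
        gene_id = parent_of.get(parent, parent)
        model = genes.get(gene_id)
        if model is None:
            # orphan subfeature: synthesize a gene container
            model = GeneModel(gene_id=gene_id or "orphan", interval=interval)
            genes[model.gene_id] = model
        if ftype in _GFF_EXON:
            model.exons.append(interval)
        elif ftype in _GFF_CDS:
            if not model.cds:
                model.phase = phase
            model.cds.append(interval)
        elif ftype in _GFF_UTR5:
            model.utr5.append(interval)
        else:
            model.utr3.append(interval)

    models = list(genes.values())
    for model in models:
        model.exons.sort(key=lambda iv: iv.start)
        model.cds.sort(key=lambda iv: iv.start)
        model.utr5.sort(key=lambda iv: iv.start)
        model.utr3.sort(key=lambda iv: iv.start)
        if report is not None:
            report.extend(model.validate())
    models.sort(key=lambda m: (m.interval.chrom, m.interval.start))
    return models


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_BQ_KEYS = ("BQ", "BaseQRankSum")


def read_vcf_subset(
    path: str | Path,
    caller: str = "",
    bq_key: str = "auto",
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF 4.x subset.

    Requires per-sample AD and site INFO keys MQ, DP and BQ (or
    BaseQRankSum; ``bq_key`` selects the dialect, default auto-detect).
    Positions stay 1-based.  Records missing a required key are still
    yielded — with the corresponding field ``None`` — so downstream filtering
    can route them to its *unfilterable* bucket instead of dropping them.
    """
    samples: list[str] = []
    fmt_idx: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            chrom, pos_s, _vid, ref, alt_s, qual_s, _filter, info_s = fields[:8]
            pos = int(pos_s)
            if pos < 1:
                raise ValueError(f"{path}: line {lineno}: POS must be >= 1")
            alts = tuple(alt_s.split(",")) if alt_s != "." else ()
            qual = None if qual_s == "." else float(qual_s)
            info: dict[str, str] = {}
            for token in info_s.split(";"):
                if not token or token == ".":
                    continue
                key, _, value = token.partition("=")
                info[key] = value
            mq = float(info["MQ"]) if "MQ" in info else None
            if bq_key == "auto":
                bq = next(
                    (float(info[k]) for k in _BQ_KEYS if k in info), None
                )
            else:
                bq = float(info[bq_key]) if bq_key in info else None

            depths: list[int | None] = []
            counts: list[tuple[int, ...] | None] = []
            gqs: list[float | None] = []
            if len(fields) > 9:
                fmt = fields[8].split(":")
                fmt_idx = {k: i for i, k in enumerate(fmt)}
                for sample_field in fields[9:]:
                    parts = sample_field.split(":")

                    def get(key: str) -> str | None:
                        i = fmt_idx.get(key)
                        if i is None or i >= len(parts):
                            return None
                        return parts[i]

                    gt = get("GT")
                    ad = get("AD")
                    if gt in (None, ".", "./.", ".|.") and (ad in (None, ".")):
                        depths.append(None)
                        counts.append(None)
                        gqs.append(None)
                        continue
                    if ad in (None, "."):
                        counts.append(None)
                        depths.append(None)
                    else:
                        ac = tuple(int(x) for x in ad.split(","))
                        counts.append(ac)
                        dp = get("DP")
                        depths.append(int(dp) if dp not in (None, ".") else sum(ac))
                    gq = get("GQ")
                    gqs.append(float(gq) if gq not in (None, ".") else None)

            yield VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                qual=qual,
                mq=mq,
                bq=bq,
                samples=tuple(samples),
                depths=tuple(depths),
                allele_counts=tuple(counts),
                gqs=tuple(gqs),
                caller=caller,
            )


def write_vcf_subset(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Emit the VCF subset dialect: INFO MQ/BQ/DP, FORMAT GT:AD:DP:GQ."""
    records = list(records)
    samples: tuple[str, ...] = records[0].samples if records else ()
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=BQ,Number=1,Type=Float,Description="Base quality">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        if samples
        else "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for rec in records:
        info_parts = []
        if rec.mq is not None:
            info_parts.append(f"MQ={rec.mq:g}")
        if rec.bq is not None:
            info_parts.append(f"BQ={rec.bq:g}")
        total = sum(d for d in rec.depths if d is not None) if rec.depths else None
        if total is not None:
            info_parts.append(f"DP={total}")
        info = ";".join(info_parts) or "."
        qual = f"{rec.qual:g}" if rec.qual is not None else "."
        cols = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            ",".join(rec.alts) if rec.alts else ".",
            qual,
            ".",
            info,
        ]
        if rec.samples:
            cols.append("GT:AD:DP:GQ")
            for i in range(len(rec.samples)):
                counts = rec.allele_counts[i] if i < len(rec.allele_counts) else None
                if counts is None:
                    cols.append("./.")
                    continue
                gt = "0/1" if len(counts) > 1 and counts[1] > 0 else "0/0"
                ad = ",".join(str(c) for c in counts)
                dp = rec.depths[i] if i < len(rec.depths) and rec.depths[i] is not None else sum(counts)
                gq = rec.gqs[i] if i < len(rec.gqs) and rec.gqs[i] is not None else None
                field = f"{gt}:{ad}:{dp}"
                field += f":{gq:g}" if gq is not None else ":."
                cols.append(field)
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED3 / FASTA / TSV
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end <= start:
                raise ValueError(f"line {lineno}: bad BED interval {start}-{end}")
            intervals.append(GenomicInterval(chrom, start, end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_SPECIALS = set("():;, \t'\"[]")


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick; internal node names act as support labels.

    Deterministic (child order preserved); raises on duplicate or
    Newick-unsafe leaf labels so the output always round-trips.
    """
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    for label in labels:
        if label is None or any(c in _NEWICK_SPECIALS for c in label):
            raise ValueError(f"leaf label {label!r} not representable in Newick")

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            out = node.name
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name is not None:
                out += str(node.name)
        if node.length is not None:
            out += f":{node.length:g}"
        return out

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")
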