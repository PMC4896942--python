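"""Positional and coding-consequence annotation of SNPs and InDels.

Region classes are mutually exclusive with priority
exon(CDS) > UTR > splice_site > intron > intergenic; there are no
up/downstream classes (upstream/downstream distance is zero).  Coding
effects are computed on the transcript strand from the spliced CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel

__all__ = [
    "AnnotationResult",
    "classify_region",
    "coding_effect",
    "indel_frame_class",
    "density_summary",
    "annotate_variant",
]

SPLICE_WINDOW = 2  # intronic bases on each side of an exon-intron junction

REGION_CLASSES = ("exon", "utr5", "utr3", "splice_site", "intron", "intergenic")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class AnnotationResult:
    chrom: str
    pos: int  # 1-based
    region: str
    coding_effect: str = "none"  # synonymous|nonsynonymous|stop_gained|start_lost|unknown|none
    frame_class: str = "none"  # in_frame|frameshift|none
    gene_id: str = ""
    all_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.coding_effect not in ("none", "unknown") and self.region != "exon":
            raise ValueError("coding effect only defined for exonic variants")


def _region_within_gene(pos0: int, model: GeneModel) -> str:
    """Region class for a 0-based position known to lie inside the gene."""
    if any(c.contains(pos0) for c in model.cds):
        return "exon"
    if any(u.contains(pos0) for u in model.utr5):
        return "utr5"
    if any(u.contains(pos0) for u in model.utr3):
        return "utr3"
    if any(e.contains(pos0) for e in model.exons):
        # exonic but neither CDS nor annotated UTR: fall back to exon
        return "exon"
    # intronic: check the splice window around each junction
    for exon in model.exons:
        if exon.start - SPLICE_WINDOW <= pos0 < exon.start:
            return "splice_site"
        if exon.end <= pos0 < exon.end + SPLICE_WINDOW:
            return "splice_site"
    return "intron"


def classify_region(
    chrom: str, pos: int, models: Sequence[GeneModel]
) -> AnnotationResult:
    """Assign the region class of a variant (``pos`` 1-based).

    Variants overlapping several genes are assigned to all of them; the
    primary gene is the one with the longest CDS.
    """
    pos0 = pos - 1
    hits = [
        m
        for m in models
        if m.interval.chrom == chrom and m.interval.contains(pos0)
    ]
    if not hits:
        return AnnotationResult(chrom, pos, "intergenic")
    primary = max(hits, key=lambda m: (m.cds_length, m.gene_id))
    region = _region_within_gene(pos0, primary)
    return AnnotationResult(
        chrom,
        pos,
        region,
        gene_id=primary.gene_id,
        all_genes=[m.gene_id for m in hits],
    )


def _spliced_cds(model: GeneModel, genome: Mapping[str, str]) -> str:
    chrom_seq = genome[model.interval.chrom]
    spliced = "".join(chrom_seq[c.start : c.end] for c in model.cds)
    if model.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


def _cds_offset(model: GeneModel, pos0: int) -> int | None:
    """Transcript-strand offset of a genomic position within the spliced CDS."""
    offset = 0
    for c in model.cds:
        if c.contains(pos0):
            offset += pos0 - c.start
            break
        offset += len(c)
    else:
        return None
    if model.strand == "-":
        total = model.cds_length
        offset = total - 1 - offset
    return offset


def coding_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome: Mapping[str, str],
) -> str:
    """Coding consequence of a SNP inside the CDS of ``model``.

    Builds the affected codon from the spliced CDS honoring strand and
    phase, substitutes the alternate base (complemented for minus-strand
    genes) and compares translations.  Priority:
    start_lost > stop_gained > nonsynonymous/synonymous.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("coding_effect handles SNPs only")
    pos0 = pos - 1
    cds_seq = _spliced_cds(model, genome)
    if (len(cds_seq) - model.phase) % 3 != 0:
        return "unknown"
    offset = _cds_offset(model, pos0)
    if offset is None:
        raise ValueError(f"position {chrom}:{pos} not in CDS of {model.gene_id}")
    base = ref.upper()
    alt_base = alt.upper()
    if model.strand == "-":
        base = str(Seq(base).complement())
        alt_base = str(Seq(alt_base).complement())
    if cds_seq[offset] != base:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos} ({cds_seq[offset]} vs {base})"
        )
    coding_offset = offset - model.phase
    if coding_offset < 0:
        return "unknown"  # inside the phase-trimmed leading bases
    codon_start = model.phase + 3 * (coding_offset // 3)
    within = offset - codon_start
    ref_codon = cds_seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return "unknown"
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    if codon_start == 0 and model.phase == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if alt_codon in _STOPS and ref_codon not in _STOPS:
        return "stop_gained"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def indel_frame_class(pos: int, ref: str, alt: str, model: GeneModel) -> str:
    """in_frame iff the indel length is a multiple of 3 and it lies in CDS."""
    length = abs(len(ref) - len(alt))
    if length == 0:
        raise ValueError("not an indel")
    pos0 = pos - 1
    in_cds = any(c.contains(pos0) for c in model.cds)
    if not in_cds:
        return "none"
    return "in_frame" if length % 3 == 0 else "frameshift"


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Sequence[GeneModel],
    genome: Mapping[str, str] | None = None,
) -> AnnotationResult:
    """Full annotation: region class plus coding effect / frame class."""
    result = classify_region(chrom, pos, models)
    is_indel = len(ref) != len(alt)
    if result.region == "exon" and result.gene_id:
        model = next(m for m in models if m.gene_id == result.gene_id)
        if is_indel:
            result.frame_class = indel_frame_class(pos, ref, alt, model)
        elif genome is not None:
            try:
                result.coding_effect = coding_effect(chrom, pos, ref, alt, model, genome)
            except ValueError:
                # exonic but outside annotated CDS (UTRs absent from model)
                result.coding_effect = "unknown"
    return result


def density_summary(
    variants: Iterable[tuple[str, int]],
    window_size: int = 1_000_000,
    gene_models: Sequence[GeneModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant counts per fixed window and per gene.

    Returns (window table, gene table).  Windows are non-overlapping,
    0-based, per chromosome; densities are reported both as bases-per-variant
    and variants-per-kb.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    variants = list(variants)
    window_counts: dict[tuple[str, int], int] = {}
    for chrom, pos in variants:
        window_counts[(chrom, (pos - 1) // window_size)] = (
            window_counts.get((chrom, (pos - 1) // window_size), 0) + 1
        )
    window_rows = [
        {
            "chrom": chrom,
            "window_start": idx * window_size,
            "window_end": (idx + 1) * window_size,
            "n_variants": n,
            "variants_per_kb": 1000.0 * n / window_size,
        }
        for (chrom, idx), n in sorted(window_counts.items())
    ]
    windows = pd.DataFrame(
        window_rows,
        columns=["chrom", "window_start", "window_end", "n_variants", "variants_per_kb"],
    )

    gene_rows = []
    if gene_models:
        for model in gene_models:
            iv = model.interval
            n = sum(
                1
                for chrom, pos in variants
                if chrom == iv.chrom and iv.contains(pos - 1)
            )
            gene_rows.append(
                {
                    "gene_id": model.gene_id,
                    "length": len(iv),
                    "n_variants": n,
                    "bases_per_variant": len(iv) / n if n else np.inf,
                    "variants_per_kb": 1000.0 * n / len(iv),
                }
            )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "length", "n_variants", "bases_per_variant", "variants_per_kb"],
    )
    return windows, genes
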