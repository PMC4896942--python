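"""Pairwise gene CNV and PAV detection from normalized read depths.

Depth normalization: ``1e9 * reads / (total_mapped * gene_length)``.
CNVs are percentile outliers of the per-pair log2 depth-ratio distribution;
PAVs are zero-coverage genes with robust depth on the other side.  The two
call sets are disjoint by construction (zero-depth genes are excluded from
the ratio distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_depth",
    "build_pair_table",
    "call_cnv",
    "call_pav",
    "pairwise_matrix",
    "CnvPavCall",
]

CALL_TYPES = ("up_cnv", "down_cnv", "pav_absent_in_query", "pav_absent_in_subject")


@dataclass(frozen=True)
class CnvPavCall:
    gene_id: str
    query: str
    subject: str
    call_type: str
    statistic: float

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")


def normalize_depth(reads: float, total_mapped: float, gene_length: float) -> float:
    """Normalized gene read depth: 1e9 * reads / (total_mapped * length)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if reads < 0:
        raise ValueError("reads must be >= 0")
    return 1e9 * reads / (total_mapped * gene_length)


def build_pair_table(
    genes: pd.DataFrame,
    query_total: int,
    subject_total: int,
    query: str = "query",
    subject: str = "subject",
    ploidy_divisors: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Attach normalized depths and log2 ratio to a per-gene count table.

    ``genes`` needs columns gene_id, length, query_reads, subject_reads.
    ``ploidy_divisors`` optionally divides each side's normalized depth by
    its accession ploidy before the ratio (off by default).  The log2 ratio
    is NaN wherever either normalized depth is zero.
    """
    required = {"gene_id", "length", "query_reads", "subject_reads"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = genes.copy()
    out["query_norm"] = [
        normalize_depth(r, query_total, l) for r, l in zip(out.query_reads, out.length)
    ]
    out["subject_norm"] = [
        normalize_depth(r, subject_total, l)
        for r, l in zip(out.subject_reads, out.length)
    ]
    if ploidy_divisors is not None:
        out["query_norm"] /= ploidy_divisors[0]
        out["subject_norm"] /= ploidy_divisors[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(out.query_norm.to_numpy() / out.subject_norm.to_numpy())
    ratio[(out.query_norm == 0) | (out.subject_norm == 0)] = np.nan
    out["log2_ratio"] = ratio
    out.attrs["query"] = query
    out.attrs["subject"] = subject
    return out


def call_cnv(
    pair_table: pd.DataFrame,
    percentile: float = 99.0,
    min_eligible: int = 100,
) -> list[CnvPavCall]:
    """Percentile-outlier CNV calls on the per-pair log2 ratio distribution.

    up_cnv: ratio strictly above the ``percentile``-th percentile;
    down_cnv: ratio strictly below the mirrored (100 - percentile)-th
    percentile.  Genes with zero depth on either side are excluded (they are
    PAV candidates).  Percentiles use linear interpolation between order
    statistics.
    """
    query = pair_table.attrs.get("query", "query")
    subject = pair_table.attrs.get("subject", "subject")
    eligible = pair_table[np.isfinite(pair_table.log2_ratio)]
    if len(eligible) < min_eligible:
        raise ValueError(
            f"only {len(eligible)} genes with defined log2 ratio; need {min_eligible}"
        )
    ratios = eligible.log2_ratio.to_numpy()
    upper = np.percentile(ratios, percentile)
    lower = np.percentile(ratios, 100.0 - percentile)
    calls = []
    for gene_id, ratio in zip(eligible.gene_id, ratios):
        if ratio > upper:
            calls.append(CnvPavCall(gene_id, query, subject, "up_cnv", float(ratio)))
        elif ratio < lower:
            calls.append(CnvPavCall(gene_id, query, subject, "down_cnv", float(ratio)))
    return calls


def call_pav(
    pair_table: pd.DataFrame,
    min_subject_reads: int = 10,
    min_subject_norm_depth: float = 0.1,
) -> list[CnvPavCall]:
    """Presence/absence calls: zero reads one side, robust depth the other.

    pav_absent_in_query iff query reads == 0 AND subject reads >=
    ``min_subject_reads`` AND subject normalized depth >=
    ``min_subject_norm_depth``; the subject-side rule is symmetric.
    """
    query = pair_table.attrs.get("query", "query")
    subject = pair_table.attrs.get("subject", "subject")
    calls = []
    for row in pair_table.itertuples():
        if (
            row.query_reads == 0
            and row.subject_reads >= min_subject_reads
            and row.subject_norm >= min_subject_norm_depth
        ):
            calls.append(
                CnvPavCall(row.gene_id, query, subject, "pav_absent_in_query", row.subject_norm)
            )
        elif (
            row.subject_reads == 0
            and row.query_reads >= min_subject_reads
            and row.query_norm >= min_subject_norm_depth
        ):
            calls.append(
                CnvPavCall(row.gene_id, query, subject, "pav_absent_in_subject", row.query_norm)
            )
    return calls


def pairwise_matrix(
    calls_by_pair: Mapping[tuple[str, str], Sequence[CnvPavCall]],
    accessions: Sequence[str],
) -> pd.DataFrame:
    """Accession x accession summary, cells "up/down (present/absent)".

    "present" counts genes present in the query but absent in the subject
    (pav_absent_in_subject); "absent" the converse.  Every ordered pair of
    distinct accessions must appear in ``calls_by_pair``.
    """
    matrix = pd.DataFrame("", index=list(accessions), columns=list(accessions))
    for q in accessions:
        for s in accessions:
            if q == s:
                matrix.loc[q, s] = "-"
                continue
            if (q, s) not in calls_by_pair:
                raise ValueError(f"missing calls for pair ({q}, {s})")
            calls = calls_by_pair[(q, s)]
            up = sum(c.call_type == "up_cnv" for c in calls)
            down = sum(c.call_type == "down_cnv" for c in calls)
            present = sum(c.call_type == "pav_absent_in_subject" for c in calls)
            absent = sum(c.call_type == "pav_absent_in_query" for c in calls)
            matrix.loc[q, s] = f"{up}/{down} ({present}/{absent})"
    return matrix
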