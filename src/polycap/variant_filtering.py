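"""Hard-filter cascade, caller concordance sets, and Ts/Tv summaries.

The six-rule cascade applies conjunctively; the printed rule order matters
only for attributing a rejected record to its first failing rule.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "VariantKey",
    "FilterResult",
    "apply_hard_filters",
    "concordance_sets",
    "ts_tv_ratio",
    "TsTvSummary",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class VariantKey:
    """Identity of a variant site for cross-caller comparison."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alts", tuple(sorted(self.alts)))


@dataclass
class VariantRecord:
    """One multi-allelic site with per-accession allele depths.

    ``allele_counts[i]`` holds read counts for (ref, alt1, ...) of sample
    ``i``, or ``None`` when the genotype is missing.  ``mq``/``bq`` may be
    ``None`` when the producing caller omitted the INFO key; such records are
    routed to the *unfilterable* bucket rather than silently dropped.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    mq: float | None = None
    bq: float | None = None
    samples: tuple[str, ...] = ()
    depths: tuple[int | None, ...] = ()
    allele_counts: tuple[tuple[int, ...] | None, ...] = ()
    gqs: tuple[float | None, ...] = ()
    caller: str = ""

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alts)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)


@dataclass
class FilterConfig:
    """Thresholds of the six-rule hard-filter cascade (all strict)."""

    min_mq: float = 30.0
    min_bq: float = 20.0
    min_alt_reads: int = 2
    max_total_depth: int = 3000
    min_total_depth: int = 600
    min_qual: float = 80.0
    n_accessions: int = 12
    #: rule (5) is ambiguous in its source: "overall minimum depth ...
    #: quality >600".  ``depth_sum`` (default) reads it as a summed depth,
    #: ``gq_sum`` as a summed per-sample genotype quality.
    rule5_metric: str = "depth_sum"

    def __post_init__(self) -> None:
        for name in ("min_mq", "min_bq", "min_alt_reads", "max_total_depth",
                     "min_total_depth", "min_qual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rule5_metric not in ("depth_sum", "gq_sum"):
            raise ValueError("rule5_metric must be 'depth_sum' or 'gq_sum'")


@dataclass
class FilterResult:
    passed: list[VariantRecord]
    rejected: list[VariantRecord]
    unfilterable: list[VariantRecord]
    tally: Counter = field(default_factory=Counter)  # first failing rule -> n


def _total_depth(record: VariantRecord) -> int | None:
    depths = [d for d in record.depths if d is not None]
    if not depths:
        return None
    return sum(depths)


def _first_failing_rule(record: VariantRecord, cfg: FilterConfig) -> int | None:
    """Return index (1-6) of the first failing rule, None if all pass.

    Raises KeyError when a required annotation is missing.
    """
    if record.mq is None:
        raise KeyError("MQ")
    if not record.mq > cfg.min_mq:
        return 1
    if record.bq is None:
        raise KeyError("BQ")
    if not record.bq > cfg.min_bq:
        return 2
    # rule 3: every non-missing accession carrying an alternate allele must
    # support it with > min_alt_reads reads
    for counts in record.allele_counts:
        if counts is None:
            continue
        for alt_reads in counts[1:]:
            if 0 < alt_reads <= cfg.min_alt_reads:
                return 3
    total = _total_depth(record)
    if total is None:
        raise KeyError("DP")
    if not total < cfg.max_total_depth:
        return 4
    if cfg.rule5_metric == "depth_sum":
        metric = total
    else:
        gqs = [g for g in record.gqs if g is not None]
        if not gqs:
            raise KeyError("GQ")
        metric = sum(gqs)
    if not metric > cfg.min_total_depth:
        return 5
    if record.qual is None:
        raise KeyError("QUAL")
    if not record.qual > cfg.min_qual:
        return 6
    return None


def apply_hard_filters(
    records: Iterable[VariantRecord], config: FilterConfig | None = None
) -> FilterResult:
    """Apply the six-rule cascade; tally counts the first failing rule.

    A record passes iff MQ > min_mq, BQ > min_bq, every accession carrying an
    alternate allele supports it with > min_alt_reads reads, the summed depth
    across accessions is < max_total_depth and > min_total_depth, and
    QUAL > min_qual.  Records missing a required annotation land in the
    ``unfilterable`` bucket, never in ``passed``.
    """
    cfg = config or FilterConfig()
    result = FilterResult([], [], [])
    for rec in records:
        try:
            rule = _first_failing_rule(rec, cfg)
        except KeyError:
            result.unfilterable.append(rec)
            continue
        if rule is None:
            result.passed.append(rec)
        else:
            result.rejected.append(rec)
            result.tally[rule] += 1
    return result


@dataclass
class ConcordanceResult:
    membership: dict[VariantKey, frozenset[str]]
    region_counts: dict[frozenset[str], int]
    union_count: int
    concordant: set[VariantKey]


def concordance_sets(sets_by_caller: Mapping[str, set]) -> ConcordanceResult:
    """Venn-style membership across >= 2 named caller sets.

    Region counts are keyed by the exact caller subset containing each key;
    they partition the non-redundant union.  The intersect-all set is the
    "concordant" set (the retention rule used for InDels).
    """
    if len(sets_by_caller) < 2:
        raise ValueError("need at least two caller sets")
    callers = list(sets_by_caller)
    membership: dict[VariantKey, frozenset[str]] = {}
    for name in callers:
        for key in sets_by_caller[name]:
            membership[key] = membership.get(key, frozenset()) | {name}
    region_counts: dict[frozenset[str], int] = Counter(membership.values())
    all_callers = frozenset(callers)
    concordant = {k for k, v in membership.items() if v == all_callers}
    return ConcordanceResult(
        membership=membership,
        region_counts=dict(region_counts),
        union_count=len(membership),
        concordant=concordant,
    )


@dataclass
class TsTvSummary:
    transitions: int
    transversions: int
    ratio: float
    is_infinite: bool

    per_class: dict[tuple[str, str], int] = field(default_factory=dict)


def ts_tv_ratio(records: Iterable[VariantRecord]) -> TsTvSummary:
    """Transition/transversion ratio over SNP ref->alt substitution pairs.

    Multi-allelic sites are decomposed into one ref->alt pair per alternate
    allele.  Transitions are A<->G and C<->T; everything else is a
    transversion.  Zero transversions yields an infinite ratio with a flag.
    """
    per_class: Counter = Counter()
    ts = tv = 0
    for rec in records:
        if not rec.is_snp:
            continue
        for alt in rec.alts:
            pair = (rec.ref, alt)
            per_class[pair] += 1
            if pair in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if tv == 0:
        return TsTvSummary(ts, tv, math.inf, True, dict(per_class))
    return TsTvSummary(ts, tv, ts / tv, False, dict(per_class))
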