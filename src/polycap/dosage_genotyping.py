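"""Ploidy-aware allele-dosage genotyping and single-dose-marker calling.

Dosage is assigned by maximum binomial (bi-allelic) or multinomial
(multi-allelic) likelihood over all copy-number compositions of the ploidy,
with a symmetric per-read miscall rate folded into the expected allele
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "DosageGenotype",
    "DosageModelConfig",
    "call_dosage",
    "call_dosage_array",
    "call_multiallelic_dosage",
    "sdm_table",
    "heterozygosity_rate",
]


@dataclass
class DosageModelConfig:
    error_rate: float = 0.01
    min_depth: int = 5
    prior: Sequence[float] | None = None  # over dosages 0..m; None = uniform

    def __post_init__(self) -> None:
        if not (0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class DosageGenotype:
    accession: str
    locus: str
    ploidy: int
    dosage: tuple[int, ...]  # copy number per allele (ref first), sums to ploidy
    log_likelihood: float
    second_log_likelihood: float
    genotype_class: str  # hom-ref | hom-alt | het | no-call
    is_single_dose: bool
    is_strict_single_dose: bool = False  # alternate allele at exactly one copy

    def __post_init__(self) -> None:
        if self.genotype_class != "no-call" and sum(self.dosage) != self.ploidy:
            raise ValueError("dosage must sum to ploidy")


def _expected_alt_fraction(d: int, m: int, e: float) -> float:
    """Expected alternate-read fraction at alt dosage d of ploidy m."""
    f = d / m
    return f * (1 - e) + (1 - f) * e


def call_dosage(
    ref_count: int,
    alt_count: int,
    ploidy: int,
    config: DosageModelConfig | None = None,
    accession: str = "",
    locus: str = "",
) -> DosageGenotype:
    """ML alternate-allele dosage at a bi-allelic locus.

    For each d in 0..m the expected alt fraction is
    ``f_d = (d/m)(1-e) + (1-d/m)e``; the call maximizes
    ``Binomial(alt | n, f_d)`` under the prior.  Ties go to the smaller d.
    Depth below ``min_depth`` yields a no-call.
    """
    cfg = config or DosageModelConfig()
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be >= 0")
    if ploidy % 2 != 0 or not (2 <= ploidy <= 12):
        raise ValueError("ploidy must be even and in [2, 12]")
    n = ref_count + alt_count
    m = ploidy
    if n < cfg.min_depth:
        return DosageGenotype(
            accession, locus, m, (0,) * 2, -math.inf, -math.inf, "no-call", False
        )
    e = cfg.error_rate
    fs = np.array([_expected_alt_fraction(d, m, e) for d in range(m + 1)])
    loglik = binom.logpmf(alt_count, n, fs)
    if cfg.prior is not None:
        prior = np.asarray(cfg.prior, dtype=float)
        if prior.shape != (m + 1,):
            raise ValueError("prior must have ploidy+1 weights")
        loglik = loglik + np.log(prior)
    order = np.argsort(-loglik, kind="stable")  # stable: ties -> smaller d first
    best, second = int(order[0]), int(order[1])
    if best == 0:
        cls = "hom-ref"
    elif best == m:
        cls = "hom-alt"
    else:
        cls = "het"
    return DosageGenotype(
        accession=accession,
        locus=locus,
        ploidy=m,
        dosage=(m - best, best),
        log_likelihood=float(loglik[best]),
        second_log_likelihood=float(loglik[second]),
        genotype_class=cls,
        is_single_dose=best in (1, m - 1),
        is_strict_single_dose=best == 1,
    )


def call_dosage_array(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    ploidy: int,
    config: DosageModelConfig | None = None,
) -> pd.DataFrame:
    """Vectorized bi-allelic dosage calling over many loci at one ploidy.

    Same model as :func:`call_dosage` (the binomial coefficient is constant
    across dosages, so the argmax needs only the kernel).  Returns a frame
    with alt_dosage (-1 for no-calls), genotype class and single-dose flags.
    """
    cfg = config or DosageModelConfig()
    if ploidy % 2 != 0 or not (2 <= ploidy <= 12):
        raise ValueError("ploidy must be even and in [2, 12]")
    ref = np.asarray(ref_counts, dtype=float)
    alt = np.asarray(alt_counts, dtype=float)
    m = ploidy
    e = cfg.error_rate
    fs = np.array([_expected_alt_fraction(d, m, e) for d in range(m + 1)])
    kernel = alt[:, None] * np.log(fs)[None, :] + ref[:, None] * np.log1p(-fs)[None, :]
    if cfg.prior is not None:
        prior = np.asarray(cfg.prior, dtype=float)
        if prior.shape != (m + 1,):
            raise ValueError("prior must have ploidy+1 weights")
        kernel = kernel + np.log(prior)[None, :]
    dosage = kernel.argmax(axis=1)  # ties -> smaller d (first occurrence)
    no_call = (ref + alt) < cfg.min_depth
    classes = np.where(
        dosage == 0, "hom-ref", np.where(dosage == m, "hom-alt", "het")
    ).astype(object)
    classes[no_call] = "no-call"
    out = pd.DataFrame(
        {
            "alt_dosage": np.where(no_call, -1, dosage),
            "genotype_class": classes,
            "is_single_dose": ~no_call & np.isin(dosage, (1, m - 1)),
            "is_strict_single_dose": ~no_call & (dosage == 1),
        }
    )
    return out


def _compositions(total: int, parts: int):
    """All tuples of `parts` non-negative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def call_multiallelic_dosage(
    counts: Sequence[int],
    ploidy: int,
    config: DosageModelConfig | None = None,
    accession: str = "",
    locus: str = "",
) -> DosageGenotype:
    """ML dosage over 2-4 alleles by exhaustive multinomial search.

    Expected fractions are error-smoothed as
    ``f_i = (d_i/m)(1-2e) + 2e/k`` (reduces to the bi-allelic model at k=2).
    """
    cfg = config or DosageModelConfig()
    k = len(counts)
    if not (2 <= k <= 4):
        raise ValueError("2-4 alleles supported")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    if ploidy % 2 != 0 or ploidy < 2:
        raise ValueError("ploidy must be even and >= 2")
    m = ploidy
    n = sum(counts)
    if n < cfg.min_depth:
        return DosageGenotype(
            accession, locus, m, (0,) * k, -math.inf, -math.inf, "no-call", False
        )
    e = cfg.error_rate
    counts_arr = np.asarray(counts, dtype=float)
    best_ll = second_ll = -math.inf
    best_d: tuple[int, ...] | None = None
    for d in _compositions(m, k):
        fs = np.array([(di / m) * (1 - 2 * e) + 2 * e / k for di in d])
        ll = float(np.dot(counts_arr, np.log(fs)))  # multinomial kernel
        if ll > best_ll:
            best_ll, second_ll, best_d = ll, best_ll, d
        elif ll > second_ll:
            second_ll = ll
    assert best_d is not None
    nonzero = [d for d in best_d if d > 0]
    if len(nonzero) == 1:
        cls = "hom-ref" if best_d[0] == m else "hom-alt"
    else:
        cls = "het"
    alt_dosage = sum(best_d[1:])
    return DosageGenotype(
        accession=accession,
        locus=locus,
        ploidy=m,
        dosage=best_d,
        log_likelihood=best_ll,
        second_log_likelihood=second_ll,
        genotype_class=cls,
        is_single_dose=alt_dosage in (1, m - 1),
        is_strict_single_dose=alt_dosage == 1,
    )


def sdm_table(genotypes_by_accession: Mapping[str, Sequence[DosageGenotype]]) -> pd.DataFrame:
    """Per-accession single-dose-marker counts and rates.

    ``sdm`` counts loci with one allele at exactly one copy (d in {1, m-1});
    ``sdm_strict`` counts the alternate-allele-single-copy reading (d=1).
    Rates divide by called bi-allelic loci.
    """
    rows = []
    for accession, genotypes in genotypes_by_accession.items():
        called = [g for g in genotypes if g.genotype_class != "no-call"]
        sdm = sum(g.is_single_dose for g in called)
        strict = sum(g.is_strict_single_dose for g in called)
        het = sum(g.genotype_class == "het" for g in called)
        n = len(called)
        rows.append(
            {
                "accession": accession,
                "called_loci": n,
                "het_loci": het,
                "sdm": sdm,
                "sdm_strict": strict,
                "sdm_rate": sdm / n if n else float("nan"),
                "sdm_strict_rate": strict / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def heterozygosity_rate(genotypes: Sequence[DosageGenotype], aligned_length: int) -> float:
    """Heterozygous site count divided by aligned-region length."""
    if aligned_length <= 0:
        raise ValueError("aligned_length must be > 0")
    het = sum(g.genotype_class == "het" for g in genotypes)
    return het / aligned_length
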