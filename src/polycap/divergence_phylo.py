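"""Pairwise Ka/Ks from aligned CDS, divergence dating, and bootstrap NJ trees.

Ka/Ks uses Nei-Gojobori-style site and pathway counting with Jukes-Cantor
correction — a deterministic counting estimator standing in for
maximum-likelihood codon models.  Trees are neighbor-joining on SNP-mismatch
distances, with bootstrap support from locus resampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "CdsPairDivergence",
    "kaks_counting",
    "divergence_time",
    "snp_distance_matrix",
    "nj_tree_with_bootstrap",
    "GRASS_SYNONYMOUS_RATE",
]

GRASS_SYNONYMOUS_RATE = 6.9e-9  # synonymous substitutions / site / year

_BASES = "ACGT"
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in _STOP_CODONS
)


def translate_codon(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Fraction-weighted count of synonymous sites in one codon (NG86).

    Each position contributes (synonymous changes among its 3 alternatives)/3;
    changes to stop codons count as nonsynonymous.
    """
    if codon in _STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = translate_codon(codon)
    s = 0.0
    for i in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[i]:
                continue
            mutant = codon[:i] + base + codon[i + 1 :]
            if mutant not in _STOP_CODONS and translate_codon(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal single-step mutational pathways; pathways
    passing through stop codons are excluded.  If every pathway is blocked,
    all pathways are used with steps to/from stops counted nonsynonymous.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)

    def walk(exclude_stops: bool) -> tuple[float, float, int]:
        total_s = total_n = 0.0
        n_paths = 0
        for order in itertools.permutations(diff_positions):
            current = codon_a
            s = n = 0.0
            blocked = False
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt in _STOP_CODONS and exclude_stops:
                    blocked = True
                    break
                if (
                    nxt not in _STOP_CODONS
                    and current not in _STOP_CODONS
                    and translate_codon(nxt) == translate_codon(current)
                ):
                    s += 1
                else:
                    n += 1
                current = nxt
            if not blocked:
                total_s += s
                total_n += n
                n_paths += 1
        return total_s, total_n, n_paths

    total_s, total_n, n_paths = walk(exclude_stops=True)
    if n_paths == 0:
        total_s, total_n, n_paths = walk(exclude_stops=False)
    return (total_s / n_paths, total_n / n_paths)


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); NaN when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class CdsPairDivergence:
    pair: str
    codons_compared: int
    syn_sites: float  # S
    nonsyn_sites: float  # N
    syn_diffs: float  # Sd
    nonsyn_diffs: float  # Nd
    ps: float
    pn: float
    ks: float
    ka: float
    ka_ks: float
    saturated: bool
    divergence_years: float = float("nan")


def _strip_gapped_codons(a: str, b: str) -> tuple[str, str]:
    keep_a, keep_b = [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) <= set(_BASES) and set(cb) <= set(_BASES):
            keep_a.append(ca)
            keep_b.append(cb)
    return "".join(keep_a), "".join(keep_b)


def kaks_counting(
    cds_a: str,
    cds_b: str,
    pair: str = "",
    rate: float = GRASS_SYNONYMOUS_RATE,
) -> CdsPairDivergence:
    """Counting (NG86-style) Ka/Ks with Jukes-Cantor correction.

    Sites are counted per codon and averaged over the two sequences;
    differences average over all minimal mutational pathways.  Symmetric in
    its inputs.  Internal stop codons are an error; gapped or ambiguous
    codon columns are stripped pairwise before counting.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS must be equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")
    a, b = _strip_gapped_codons(cds_a.upper(), cds_b.upper())
    n_codons = len(a) // 3
    if n_codons == 0:
        raise ValueError("no comparable codons after gap stripping")
    s_a = s_b = sd = nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in _STOP_CODONS or cb in _STOP_CODONS:
            raise ValueError(f"internal stop codon at alignment position {i}")
        s_a += synonymous_sites(ca)
        s_b += synonymous_sites(cb)
        step_s, step_n = pathway_differences(ca, cb)
        sd += step_s
        nd += step_n
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    if saturated or ks == 0:
        ratio = float("nan")
    else:
        ratio = ka / ks
    years = divergence_time(ks, rate) if not math.isnan(ks) else float("nan")
    return CdsPairDivergence(
        pair=pair,
        codons_compared=n_codons,
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ka_ks=ratio,
        saturated=saturated,
        divergence_years=years,
    )


def divergence_time(ks: float, rate: float = GRASS_SYNONYMOUS_RATE) -> float:
    """Divergence time in years: T = Ks / (2 * rate)."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return ks / (2.0 * rate)


# ---------------------------------------------------------------------------
# SNP distance matrix and NJ bootstrap tree
# ---------------------------------------------------------------------------


def snp_distance_matrix(
    genotypes: pd.DataFrame,
    metric: str = "mismatch",
    ploidy_map: dict[str, int] | None = None,
) -> DistanceMatrix:
    """Pairwise accession distances from a loci x accessions genotype table.

    Loci with any missing value are dropped (complete-case).  ``mismatch``
    (default) is the fraction of loci with differing calls; ``dosage`` is the
    mean absolute dosage difference divided by the larger ploidy of the pair
    (requires ``ploidy_map``).
    """
    if genotypes.shape[1] < 2:
        raise ValueError("need >= 2 accessions")
    complete = genotypes.dropna(axis=0)
    if complete.empty:
        raise ValueError("zero shared loci after removing missing data")
    labels = list(complete.columns)
    n = len(labels)
    mat = np.zeros((n, n))
    values = complete.to_numpy()
    for i, j in itertools.combinations(range(n), 2):
        if metric == "mismatch":
            d = float(np.mean(values[:, i] != values[:, j]))
        elif metric == "dosage":
            if ploidy_map is None:
                raise ValueError("dosage metric needs ploidy_map")
            m = max(ploidy_map[labels[i]], ploidy_map[labels[j]])
            d = float(np.mean(np.abs(values[:, i] - values[:, j])) / m)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def _splits(tree: TreeNode, labels: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to its smaller side."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(canonical)
    return out


def nj_tree_with_bootstrap(
    genotypes: pd.DataFrame,
    replicates: int = 1000,
    seed: int | None = None,
    metric: str = "mismatch",
    ploidy_map: dict[str, int] | None = None,
) -> TreeNode:
    """Neighbor-joining tree with bootstrap split support (percent).

    Bootstrap resamples loci with replacement, rebuilds the distance matrix
    and NJ tree, and records split frequencies onto the internal nodes of the
    full-data tree.  Deterministic under ``seed``.  ``replicates=0`` returns
    the tree without support values.
    """
    if genotypes.shape[1] < 3:
        raise ValueError("need >= 3 accessions")
    dm = snp_distance_matrix(genotypes, metric=metric, ploidy_map=ploidy_map)
    if not np.isfinite(dm.data).all():
        raise ValueError("non-finite distances")
    tree = nj(dm)
    if replicates <= 0:
        return tree
    labels = frozenset(genotypes.columns)
    complete = genotypes.dropna(axis=0)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    n_loci = len(complete)
    for _ in range(replicates):
        idx = rng.integers(0, n_loci, size=n_loci)
        resampled = complete.iloc[idx]
        rep_dm = snp_distance_matrix(resampled, metric=metric, ploidy_map=ploidy_map)
        for split in _splits(nj(rep_dm), labels):
            counts[split] = counts.get(split, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * counts.get(canonical, 0) / replicates
        node.name = f"{support:g}"
    return tree
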