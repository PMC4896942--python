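"""Capture-probe thermodynamic features and the capture-efficiency model.

Feature definitions:

* GC — percent G+C.
* Tm — RNA/DNA hybrid nearest-neighbor melting temperature (the probe read
  as the RNA strand), with a monovalent-salt correction.
* PHFE — probe hybridization free energy: summed nearest-neighbor dG at the
  hybridization temperature (65 C default); more negative = more stable.
* PMFE — probe minimum folding energy from a weighted maximum-pairing
  recursion (pair weights GC:-3, AT:-2, GT:-1; minimum loop 3); an
  approximation of full thermodynamic folding, negative = stable.
* hairpin — length of the longest self-complementary stem with loop >= 3.
* dimer — longest contiguous complementary run between two antiparallel
  copies of the probe.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ProbeFeatures",
    "CaptureModel",
    "compute_features",
    "select_successful_probes",
    "prune_correlated",
    "fit_capture_model",
    "coverage_summary",
    "FEATURE_PRIORITY",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_MIN_LOOP = 3
_GAS_CONSTANT = 1.987  # cal / (mol K)

FEATURE_PRIORITY = ("gc", "tm", "phfe", "pmfe", "hairpin", "dimer")


def _load_nn_table() -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    path = resources.files("polycap.data") / "rna_dna_nn.tsv"
    table = pd.read_csv(path, sep="\t", comment="#")
    params = {row.nn: (row.dH, row.dS) for row in table.itertuples()}
    init = params.pop("init")
    return params, init


_NN_PARAMS, _NN_INIT = _load_nn_table()


@dataclass
class ProbeFeatures:
    probe_id: str
    length: int
    gc: float  # percent
    tm: float  # Celsius
    pmfe: float  # kcal/mol (weighted-score convention)
    phfe: float  # kcal/mol
    hairpin: float
    dimer: float
    read_count: float = float("nan")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = [i for i, base in enumerate(seq) if base not in "ACGT"]
    if bad:
        raise ValueError(f"ambiguous bases at positions {bad}")
    return seq


def pmfe_score(seq: str) -> float:
    """Minimum weighted-pairing folding score (bottom-up DP).

    E(i,j) = min(E(i+1,j), min_k w(i,k) + E(i+1,k-1) + E(k+1,j)) over
    k >= i + MIN_LOOP + 1; minimum loop 3.  0 for unfoldable sequences;
    negative = stable.  Inner minimization is vectorized over k.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    # pairwise weight matrix W[i, k]
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    W = np.zeros((n, n))
    for (x, y), w in (
        ((ord("G"), ord("C")), -3.0),
        ((ord("A"), ord("T")), -2.0),
        ((ord("G"), ord("T")), -1.0),
    ):
        W[np.ix_(codes == x, codes == y)] = w
        W[np.ix_(codes == y, codes == x)] = w
    # E is (n+2)x(n+2) so that E[i+1, k-1] and E[k+1, j] never go out of
    # bounds; unfilled cells are 0 (empty subsequence).
    E = np.zeros((n + 2, n + 2))
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            ks = np.arange(i + _MIN_LOOP + 1, j + 1)
            cand = W[i, ks] + E[i + 1, ks - 1] + E[ks + 1, j]
            E[i, j] = min(E[i + 1, j], cand.min())
    return float(E[0, n - 1])


def hairpin_score(seq: str) -> float:
    """Longest self-complementary stem closable with a loop >= 3 nt."""
    n = len(seq)
    best = 0
    for a in range(n):
        for b in range(a + _MIN_LOOP + 1, n):
            # grow a stem outside-in from pair (a, b)
            length = 0
            while (
                a + length < b - length
                and (b - length) - (a + length) - 1 >= _MIN_LOOP
                and seq[b - length] == _COMPLEMENT[seq[a + length]]
            ):
                length += 1
            best = max(best, length)
    return float(best)


def dimer_score(seq: str) -> float:
    """Longest contiguous complementary run between two antiparallel copies."""
    n = len(seq)
    best = 0
    # antiparallel alignment: position i of copy 1 faces position c - i of copy 2
    for c in range(2 * n - 1):
        run = 0
        for i in range(max(0, c - n + 1), min(n, c + 1)):
            j = c - i
            if seq[j] == _COMPLEMENT[seq[i]]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return float(best)


def melting_temperature(
    seq: str, probe_conc: float = 5e-7, sodium: float = 0.05
) -> float:
    """Nearest-neighbor RNA/DNA hybrid Tm (Celsius) with Na+ correction."""
    rna = seq.replace("T", "U")
    dh, ds = _NN_INIT
    for i in range(len(rna) - 1):
        pair_dh, pair_ds = _NN_PARAMS[rna[i : i + 2]]
        dh += pair_dh
        ds += pair_ds
    tm_kelvin = 1000.0 * dh / (ds + _GAS_CONSTANT * math.log(probe_conc / 4.0))
    return tm_kelvin - 273.15 + 16.6 * math.log10(sodium)


def hybridization_free_energy(seq: str, temperature: float = 65.0) -> float:
    """Summed nearest-neighbor dG (kcal/mol) at the given temperature."""
    rna = seq.replace("T", "U")
    kelvin = temperature + 273.15
    dh, ds = _NN_INIT
    dg = dh - kelvin * ds / 1000.0
    for i in range(len(rna) - 1):
        pair_dh, pair_ds = _NN_PARAMS[rna[i : i + 2]]
        dg += pair_dh - kelvin * pair_ds / 1000.0
    return dg


def compute_features(
    sequence: str,
    probe_id: str = "",
    read_count: float = float("nan"),
    temperature: float = 65.0,
) -> ProbeFeatures:
    """All thermodynamic/sequence descriptors for one probe."""
    seq = _check_sequence(sequence)
    if len(seq) < 20:
        raise ValueError("probe must be >= 20 nt")
    gc = 100.0 * sum(base in "GC" for base in seq) / len(seq)
    return ProbeFeatures(
        probe_id=probe_id,
        length=len(seq),
        gc=gc,
        tm=melting_temperature(seq),
        pmfe=pmfe_score(seq),
        phfe=hybridization_free_energy(seq, temperature),
        hairpin=hairpin_score(seq),
        dimer=dimer_score(seq),
        read_count=read_count,
    )


def features_frame(features: Sequence[ProbeFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [f.probe_id for f in features],
            "length": [f.length for f in features],
            "gc": [f.gc for f in features],
            "tm": [f.tm for f in features],
            "pmfe": [f.pmfe for f in features],
            "phfe": [f.phfe for f in features],
            "hairpin": [f.hairpin for f in features],
            "dimer": [f.dimer for f in features],
            "read_count": [f.read_count for f in features],
        }
    )


def select_successful_probes(
    table: pd.DataFrame, count_column: str = "read_count"
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Probes with counts strictly between 10% of the mean and the 99th pct.

    Returns the surviving subset and the (lower, upper) bounds used.
    """
    if table.empty:
        raise ValueError("empty probe table")
    counts = table[count_column].to_numpy(dtype=float)
    lower = 0.10 * counts.mean()
    upper = np.percentile(counts, 99)
    keep = (counts > lower) & (counts < upper)
    if not keep.any():
        warnings.warn("no probes inside the success window", stacklevel=2)
    return table[keep].copy(), (float(lower), float(upper))


def prune_correlated(
    features: pd.DataFrame,
    threshold: float = 0.95,
    priority: Sequence[str] = FEATURE_PRIORITY,
) -> list[str]:
    """One representative feature per |r| > threshold correlation group.

    Groups are connected components of the thresholded correlation graph;
    the representative is the first member by ``priority`` (then column
    order).  Constant features are excluded with a warning.
    """
    columns = list(features.columns)
    if len(columns) < 2:
        raise ValueError("need at least two features")
    usable = []
    for col in columns:
        if features[col].nunique() <= 1:
            warnings.warn(f"feature {col!r} is constant; excluded", stacklevel=2)
        else:
            usable.append(col)
    corr = features[usable].corr().abs()
    # union-find over the threshold graph
    parent = {c: c for c in usable}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in itertools.combinations(usable, 2):
        if corr.loc[a, b] > threshold:
            parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for c in usable:
        groups.setdefault(find(c), []).append(c)

    def rank(col: str) -> tuple[int, int]:
        try:
            p = priority.index(col)
        except ValueError:
            p = len(priority)
        return (p, columns.index(col))

    representatives = [min(members, key=rank) for members in groups.values()]
    return sorted(representatives, key=rank)


@dataclass
class CaptureModel:
    features: list[str]
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    relative_importance: dict[str, float]  # shares of R^2 (LMG)
    pvalues: dict[str, float] = field(default_factory=dict)
    success_window: tuple[float, float] | None = None
    n_observations: int = 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for name, coef in self.coefficients.items():
            out = out + coef * X[name].to_numpy(dtype=float)
        return out


def _r_squared(X: pd.DataFrame, y: np.ndarray, subset: tuple[str, ...]) -> float:
    if not subset:
        return 0.0
    design = sm.add_constant(X[list(subset)].to_numpy(dtype=float))
    return float(sm.OLS(y, design).fit().rsquared)


def _lmg_importance(X: pd.DataFrame, y: np.ndarray, names: list[str]) -> dict[str, float]:
    """Average sequential R^2 contribution over all feature orderings (exact)."""
    cache: dict[tuple[str, ...], float] = {}

    def r2(subset: tuple[str, ...]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = _r_squared(X, y, key)
        return cache[key]

    totals = {name: 0.0 for name in names}
    orderings = list(itertools.permutations(names))
    for ordering in orderings:
        seen: tuple[str, ...] = ()
        for name in ordering:
            totals[name] += r2(seen + (name,)) - r2(seen)
            seen = seen + (name,)
    return {name: totals[name] / len(orderings) for name in names}


def fit_capture_model(
    features: pd.DataFrame,
    read_counts: Sequence[float],
    alpha: float = 0.001,
    min_obs_per_feature: int = 10,
) -> CaptureModel:
    """OLS capture-efficiency model with backward significance pruning.

    Features whose partial-F p-value exceeds ``alpha`` are dropped (worst
    first) and the model refit.  Relative importance is the exact LMG
    decomposition (average sequential R^2 over all orderings); importances
    sum to the final R^2.
    """
    y = np.asarray(read_counts, dtype=float)
    names = list(features.columns)
    if len(y) < min_obs_per_feature * max(len(names), 1):
        raise ValueError(
            f"need >= {min_obs_per_feature} observations per feature"
        )
    X_full = features.astype(float)
    rank = np.linalg.matrix_rank(np.c_[np.ones(len(X_full)), X_full.to_numpy()])
    if rank < len(names) + 1:
        raise ValueError(f"rank-deficient design over features {names}")

    current = list(names)
    while current:
        design = sm.add_constant(X_full[current].to_numpy())
        fit = sm.OLS(y, design).fit()
        pvals = dict(zip(current, fit.pvalues[1:]))
        worst = max(current, key=lambda n: pvals[n])
        if pvals[worst] <= alpha:
            break
        current.remove(worst)

    if not current:
        intercept = float(y.mean())
        return CaptureModel([], {}, intercept, 0.0, {}, {}, None, len(y))

    design = sm.add_constant(X_full[current].to_numpy())
    fit = sm.OLS(y, design).fit()
    coefficients = dict(zip(current, fit.params[1:]))
    pvalues = dict(zip(current, fit.pvalues[1:]))
    importance = _lmg_importance(X_full, y, current)
    return CaptureModel(
        features=current,
        coefficients={k: float(v) for k, v in coefficients.items()},
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        relative_importance=importance,
        pvalues={k: float(v) for k, v in pvalues.items()},
        success_window=None,
        n_observations=len(y),
    )


def merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/touching half-open intervals per chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def coverage_summary(
    depth_table: pd.DataFrame,
    probe_intervals: Sequence,
    flank: int = 100,
    depth_grid: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target median depth (MSD) and a cumulative coverage curve.

    Targets are probe intervals extended by ``flank`` on both sides (floored
    at 0) and merged when overlapping.  ``depth_table`` needs columns
    chrom, pos (0-based), depth; positions absent from the table count as
    depth 0 (with a warning when a whole target is uncovered).
    """
    extended = [
        (iv.chrom, max(0, iv.start - flank), iv.end + flank) for iv in probe_intervals
    ]
    targets = merge_intervals(extended)
    depth_by_chrom = {
        chrom: dict(zip(group.pos, group.depth))
        for chrom, group in depth_table.groupby("chrom")
    }
    rows = []
    for chrom, start, end in targets:
        lookup = depth_by_chrom.get(chrom, {})
        depths = np.array([lookup.get(p, 0) for p in range(start, end)], dtype=float)
        if chrom not in depth_by_chrom:
            warnings.warn(f"target {chrom}:{start}-{end} outside depth table", stacklevel=2)
        rows.append(
            {"chrom": chrom, "start": start, "end": end, "msd": float(np.median(depths))}
        )
    per_target = pd.DataFrame(rows)
    if depth_grid is None:
        top = per_target.msd.max() if len(per_target) else 0
        depth_grid = np.arange(0, max(top, 1) + 10, 10)
    cumulative = pd.DataFrame(
        {
            "depth": list(depth_grid),
            "fraction_targets": [
                float((per_target.msd >= d).mean()) if len(per_target) else 0.0
                for d in depth_grid
            ],
        }
    )
    return per_target, cumulative
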