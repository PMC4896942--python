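import functools

import numpy as np
import pandas as pd
import pytest

from polycap.io_formats import GenomicInterval
from polycap.probe_model import (
    compute_features,
    coverage_summary,
    dimer_score,
    fit_capture_model,
    hairpin_score,
    hybridization_free_energy,
    melting_temperature,
    merge_intervals,
    pmfe_score,
    prune_correlated,
    select_successful_probes,
)
from polycap.synthetic_data import (
    SimulationConfig,
    plant_hairpin,
    simulate_capture_observations,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
WEIGHT = {frozenset("GC"): -3.0, frozenset("AT"): -2.0, frozenset("GT"): -1.0}


def brute_pmfe(seq):
    """Top-down memoized recursion over all non-crossing structures."""

    @functools.lru_cache(maxsize=None)
    def best(i, j):
        if j - i < 4:
            return 0.0
        options = [best(i + 1, j)]
        for k in range(i + 4, j + 1):
            w = WEIGHT.get(frozenset((seq[i], seq[k])), 0.0)
            if w < 0:
                options.append(w + best(i + 1, k - 1) + best(k + 1, j))
        return min(options)

    return best(0, len(seq) - 1)


def brute_hairpin(seq):
    """Exhaustive enumeration of every stem/loop placement."""
    n = len(seq)
    best = 0
    for i in range(n):  # stem 5' start
        for j in range(i, n):  # stem 3' end
            for length in range(1, n):
                # stem pairs (i+t, j-t); innermost pair must leave loop >= 3
                if i + length - 1 >= j - length + 1:
                    break
                if (j - length + 1) - (i + length - 1) - 1 < 3:
                    break
                if all(seq[j - t] == COMP[seq[i + t]] for t in range(length)):
                    best = max(best, length)
                else:
                    break
    return float(best)


def brute_dimer(seq):
    """Exhaustive enumeration of contiguous antiparallel duplex runs."""
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(n):
            length = 0
            while i + length < n and j - length >= 0:
                if seq[j - length] != COMP[seq[i + length]]:
                    break
                length += 1
            best = max(best, length)
    return float(best)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFeatureScores:
    def test_gc_of_fixed_string(self):
        feats = compute_features("ATGC" * 30)
        assert feats.gc == 50.0

    def test_gc_zero(self):
        assert compute_features("A" * 40).gc == 0.0

    def test_poly_a_no_structure(self):
        feats = compute_features("A" * 40)
        assert feats.hairpin == 0.0
        assert feats.dimer == 0.0
        assert feats.pmfe == 0.0

    def test_ambiguous_bases_error_lists_positions(self):
        with pytest.raises(ValueError, match=r"\[2, 5\]"):
            compute_features("ATNGCNATGCATGCATGCAT" + "A" * 10)

    def test_short_probe_rejected(self):
        with pytest.raises(ValueError):
            compute_features("ATGCATGCAT")

    def test_planted_hairpin_scores_at_least_stem(self, rng):
        cfg = SimulationConfig(seed=2)
        for trial in range(5):
            seq = random_seq(rng, 120)
            planted = plant_hairpin(rng, seq, stem=10, loop=4)
            assert hairpin_score(planted) >= 10

    def test_pmfe_brute_force_oracle(self, rng):
        for trial in range(30):
            seq = random_seq(rng, int(rng.integers(10, 31)))
            assert pmfe_score(seq) == pytest.approx(brute_pmfe(seq))

    def test_hairpin_brute_force_oracle(self, rng):
        for trial in range(30):
            seq = random_seq(rng, int(rng.integers(10, 31)))
            assert hairpin_score(seq) == brute_hairpin(seq)

    def test_dimer_brute_force_oracle(self, rng):
        for trial in range(30):
            seq = random_seq(rng, int(rng.integers(10, 31)))
            assert dimer_score(seq) == brute_dimer(seq)

    def test_features_pure(self):
        seq = "ACGTACGTGGCCATATGGCCACGTACGT"
        a = compute_features(seq)
        b = compute_features(seq)
        assert (a.gc, a.tm, a.pmfe, a.phfe, a.hairpin, a.dimer) == (
            b.gc, b.tm, b.pmfe, b.phfe, b.hairpin, b.dimer
        )

    def test_tm_increases_with_gc(self):
        low = melting_temperature("AT" * 30)
        high = melting_temperature("GC" * 30)
        assert high > low

    def test_phfe_more_stable_for_gc_rich(self):
        assert hybridization_free_energy("GC" * 30) < hybridization_free_energy("AT" * 30)


class TestSelectSuccessfulProbes:
    def test_degenerate_constant_counts(self):
        table = pd.DataFrame({"probe_id": list("abc"), "read_count": [100.0] * 3})
        with pytest.warns(UserWarning):
            kept, (lower, upper) = select_successful_probes(table)
        assert kept.empty
        assert (lower, upper) == (10.0, 100.0)

    def test_paper_lower_bound_rule(self, rng):
        # mean 260 reads -> lower bound 26
        counts = rng.permutation(np.full(100, 260.0) + np.linspace(-50, 50, 100) * 0)
        counts = np.concatenate([np.full(99, 260.0), [260.0]])
        table = pd.DataFrame({"probe_id": range(100), "read_count": counts})
        with pytest.warns(UserWarning):
            _, (lower, _) = select_successful_probes(table)
        assert lower == pytest.approx(26.0)

    def test_brute_force_predicate(self, rng):
        counts = rng.gamma(2.0, 150.0, size=10_000)
        table = pd.DataFrame({"probe_id": range(len(counts)), "read_count": counts})
        kept, (lower, upper) = select_successful_probes(table)
        expected = {i for i, c in enumerate(counts) if lower < c < upper}
        assert set(kept.probe_id) == expected

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_successful_probes(pd.DataFrame({"read_count": []}))


class TestPruneCorrelated:
    def test_collinear_pair_dropped(self, rng):
        gc = rng.uniform(20, 80, 500)
        table = pd.DataFrame({"gc": gc, "tm": 0.6 * gc + 40, "dimer": rng.normal(size=500)})
        kept = prune_correlated(table)
        assert "gc" in kept and "tm" not in kept and "dimer" in kept

    def test_independent_features_all_kept(self, rng):
        table = pd.DataFrame(rng.normal(size=(500, 3)), columns=["gc", "pmfe", "dimer"])
        assert set(prune_correlated(table)) == {"gc", "pmfe", "dimer"}

    def test_representatives_mutually_below_threshold(self, rng):
        base = rng.normal(size=(400, 2))
        table = pd.DataFrame(
            {
                "gc": base[:, 0],
                "tm": base[:, 0] * 0.99 + rng.normal(scale=0.01, size=400),
                "pmfe": base[:, 1],
                "hairpin": -base[:, 1] + rng.normal(scale=0.01, size=400),
            }
        )
        kept = prune_correlated(table)
        corr = table[kept].corr().abs()
        off_diag = corr.to_numpy()[~np.eye(len(kept), dtype=bool)]
        assert (off_diag <= 0.95).all()

    def test_constant_feature_warned_and_excluded(self, rng):
        table = pd.DataFrame({"gc": rng.normal(size=100), "tm": np.ones(100)})
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(table)
        assert kept == ["gc"]


class TestFitCaptureModel:
    def test_exact_recovery_sigma_zero(self):
        X, y = simulate_capture_observations(500, noise_sigma=0.0, seed=4)
        model = fit_capture_model(X, y)
        assert model.coefficients["gc"] == pytest.approx(5.08, abs=1e-8)
        assert model.coefficients["pmfe"] == pytest.approx(13.3, abs=1e-8)
        assert model.coefficients["dimer"] == pytest.approx(-2.11, abs=1e-8)
        assert model.coefficients["hairpin"] == pytest.approx(-10.67, abs=1e-8)
        assert model.intercept == pytest.approx(164.46, abs=1e-6)

    def test_pure_noise_intercept_only(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=["gc", "pmfe", "dimer"])
        y = rng.normal(size=500)
        model = fit_capture_model(X, y)
        assert model.features == []
        assert model.r_squared == 0.0

    def test_importances_sum_to_r_squared(self):
        X, y = simulate_capture_observations(2000, noise_sigma=25.0, seed=9)
        model = fit_capture_model(X, y)
        assert sum(model.relative_importance.values()) == pytest.approx(
            model.r_squared, abs=1e-8
        )
        assert all(v >= 0 for v in model.relative_importance.values())

    def test_rank_deficient_error(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"gc": x, "tm": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_capture_model(X, x)

    def test_too_few_observations(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            fit_capture_model(X, rng.normal(size=15))


class TestCoverage:
    def test_uniform_depth(self):
        depth = pd.DataFrame({"chrom": "chr1", "pos": range(1000), "depth": 50})
        probes = [GenomicInterval("chr1", 200, 320)]
        per_target, cumulative = coverage_summary(depth, probes, flank=100)
        assert per_target.msd.iloc[0] == 50.0
        assert cumulative[cumulative.depth == 50].fraction_targets.iloc[0] == 1.0

    def test_zero_flank_targets_equal_probes(self):
        depth = pd.DataFrame({"chrom": "chr1", "pos": range(500), "depth": 10})
        probes = [GenomicInterval("chr1", 100, 220)]
        per_target, _ = coverage_summary(depth, probes, flank=0)
        assert (per_target.start.iloc[0], per_target.end.iloc[0]) == (100, 220)

    def test_overlapping_probes_merged_once(self):
        depth = pd.DataFrame({"chrom": "chr1", "pos": range(2000), "depth": 30})
        probes = [GenomicInterval("chr1", 100, 220), GenomicInterval("chr1", 150, 270),
                  GenomicInterval("chr1", 1000, 1120)]
        per_target, _ = coverage_summary(depth, probes, flank=100)
        assert len(per_target) == 2
        # merged target spans both probes plus flanks
        assert (per_target.start.iloc[0], per_target.end.iloc[0]) == (0, 370)

    def test_merge_oracle(self, rng):
        intervals = [("chr1", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 5000, 50), rng.integers(10, 400, 50))]
        merged = merge_intervals(intervals)
        # merged intervals are sorted, non-overlapping, and cover the same bases
        for a, b in zip(merged, merged[1:]):
            assert a[2] < b[1] or a[0] != b[0]
        covered = set()
        for _, s, e in intervals:
            covered.update(range(s, e))
        merged_covered = set()
        for _, s, e in merged:
            merged_covered.update(range(s, e))
        assert covered == merged_covered

    def test_uncovered_target_warns_zero_depth(self):
        depth = pd.DataFrame({"chrom": ["chr1"], "pos": [0], "depth": [10]})
        probes = [GenomicInterval("chr2", 100, 220)]
        with pytest.warns(UserWarning, match="outside depth table"):
            per_target, _ = coverage_summary(depth, probes)
        assert per_target.msd.iloc[0] == 0.0
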