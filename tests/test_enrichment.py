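"""Distance-bin enrichment, class enrichment, and Fisher overlap."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hpinet import (
    class_enrichment,
    distance_bin_enrichment,
    distance_to_nearest,
    fisher_overlap,
)
from conftest import gene_set, make_network, random_small_network


def exhaustive_null_fraction(net, reference, feature_size):
    """Oracle: mean per-bin fraction over ALL feature placements."""
    prof = distance_to_nearest(net, reference)
    bins = prof.bins()
    nodes = sorted(net.nodes)
    totals = {d: 0.0 for d in bins}
    count = 0
    for combo in itertools.combinations(nodes, feature_size):
        s = set(combo)
        count += 1
        for d, members in bins.items():
            totals[d] += len(s & members) / len(members)
    return {d: t / count for d, t in totals.items()}


class TestDistanceBinEnrichment:
    def test_path_example_against_exhaustive_enumeration(self, path6):
        """Path a-b-c-d-e-f, reference {a}, feature {b,c}: the d=1 bin is {b}
        with f=1; the exhaustive null over all 15 two-node placements gives
        f_r(1) = 2/6 = 1/3, so E(1) = log2(3)."""
        ref = gene_set("ref", "targets", ["a"])
        oracle = exhaustive_null_fraction(path6, ref, 2)
        assert oracle[1] == pytest.approx(1 / 3)
        prof = distance_bin_enrichment(
            path6, ref, gene_set("f", "required", ["b", "c"]),
            n_resamples=40_000, seed=0,
        )
        b1 = prof.bins[1]
        assert b1.observed_fraction == 1.0
        # Monte-Carlo null within 3 SE of the exhaustive value
        se = math.sqrt(oracle[1] * (1 - oracle[1]) / 40_000)
        assert abs(b1.null_mean_fraction - oracle[1]) < 3 * se
        assert b1.enrichment == pytest.approx(math.log2(3), abs=0.05)

    def test_saturated_feature_gives_zero_enrichment(self, path6):
        ref = gene_set("ref", "targets", ["a"])
        prof = distance_bin_enrichment(
            path6, ref, gene_set("all", "required", path6.nodes),
            n_resamples=50, seed=1,
        )
        for b in prof.bins:
            assert b.observed_fraction == 1.0
            assert b.null_mean_fraction == 1.0
            assert b.enrichment == 0.0

    def test_conservation_across_bins(self):
        """Feature members in reachable bins sum to |feature ∩ reachable|."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            net = random_small_network(rng)
            nodes = sorted(net.nodes)
            ref = gene_set("r", "targets", nodes[:1])
            k = max(1, net.n_nodes // 2)
            feature = gene_set("f", "required", list(rng.choice(nodes, k, replace=False)))
            prof = distance_bin_enrichment(net, ref, feature, n_resamples=10, seed=0)
            reachable = distance_to_nearest(net, ref).reachable_nodes()
            assert sum(b.observed_count for b in prof.bins) == len(
                set(feature.require_mapped()) & reachable
            )

    def test_empirical_p_never_zero(self, path6):
        ref = gene_set("ref", "targets", ["a"])
        prof = distance_bin_enrichment(
            path6, ref, gene_set("f", "required", ["b"]), n_resamples=100, seed=0
        )
        for b in prof.bins:
            assert 1 / 101 <= b.p_value <= 1.0

    def test_empty_feature_errors(self, path6):
        from hpinet import GeneSet

        empty = GeneSet.from_nodes("f", "required", ["zz"], mapped=False).map_to(path6)
        with pytest.raises(ValueError):
            distance_bin_enrichment(path6, gene_set("r", "targets", ["a"]), empty)

    def test_zero_observed_reported_as_neg_inf_with_counts(self, path6):
        ref = gene_set("ref", "targets", ["a"])
        prof = distance_bin_enrichment(
            path6, ref, gene_set("f", "required", ["f"]), n_resamples=200, seed=0
        )
        b1 = prof.bins[1]
        assert b1.observed_count == 0
        assert b1.enrichment == float("-inf")
        assert b1.flag == "zero_observed"

    def test_unreachable_nodes_excluded_from_bins(self):
        net = make_network([("a", "b"), ("b", "c")], extra_nodes=["z"])
        ref = gene_set("r", "targets", ["a"])
        prof = distance_bin_enrichment(
            net, ref, gene_set("f", "required", ["b", "z"]), n_resamples=50, seed=0
        )
        assert sum(b.bin_size for b in prof.bins) == 3  # z excluded

    def test_reference_resampling_variant_runs(self, path6):
        ref = gene_set("ref", "targets", ["a"])
        prof = distance_bin_enrichment(
            path6, ref, gene_set("f", "required", ["b", "c"]),
            n_resamples=200, seed=0, resample_reference=True,
        )
        assert prof.resample_reference
        assert all(np.isfinite(b.null_mean_fraction) for b in prof.bins)

    def test_exclude_reference_flag_shifts_null(self, path6):
        ref = gene_set("ref", "targets", ["a"])
        feat = gene_set("f", "required", ["b", "c"])
        with_ref = distance_bin_enrichment(path6, ref, feat, n_resamples=5000, seed=0)
        without = distance_bin_enrichment(
            path6, ref, feat, n_resamples=5000, seed=0, exclude_reference=True
        )
        # removing the d=0 node from the pool raises every other bin's null
        assert without.bins[1].null_mean_fraction > with_ref.bins[1].null_mean_fraction


class TestClassEnrichment:
    def test_query_equals_universe_zero_enrichment(self):
        universe = [f"g{i}" for i in range(30)]
        classes = [
            gene_set("c1", "class", universe[:10]),
            gene_set("c2", "class", universe[10:]),
        ]
        df = class_enrichment(
            classes, gene_set("q", "other", universe), universe,
            n_resamples=50, seed=0,
        )
        assert (df["enrichment"] == 0.0).all()

    def test_concentrated_class_matches_hypergeometric_oracle(self):
        """Class = query of 5 in a universe of 50: observed fraction 1; the
        null mean fraction is the hypergeometric expectation 5/50 = 0.1, so
        E = log2(10)."""
        universe = [f"g{i}" for i in range(50)]
        query = gene_set("q", "other", universe[:5])
        classes = [gene_set("c", "class", universe[:5])]
        df = class_enrichment(classes, query, universe, n_resamples=40_000, seed=1)
        row = df.iloc[0]
        assert row["observed_fraction"] == 1.0
        # closed form: E[|draw ∩ class|]/|class| = |query|/|universe|
        se = math.sqrt(0.1 * 0.9 / (5 * 40_000))  # loose per-mean bound
        assert abs(row["null_mean_fraction"] - 0.1) < 5 * se
        assert row["enrichment"] == pytest.approx(math.log2(10), abs=0.05)
        assert row["p_value"] >= 1 / 40_001

    def test_empty_class_flagged(self):
        universe = [f"g{i}" for i in range(10)]
        classes = [gene_set("empty", "class", ["not_in_universe"])]
        df = class_enrichment(
            classes, gene_set("q", "other", universe[:3]), universe,
            n_resamples=20, seed=0,
        )
        assert df.iloc[0]["flag"] == "empty_class"

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            class_enrichment([], gene_set("q", "other", ["a"]), [])


class TestFisherOverlap:
    def test_worked_table_exact(self):
        """Universe 10, |A|=5, |B|=4, overlap 4: the one-sided p is the
        hypergeometric tail C(5,4)C(5,0)/C(10,4) = 5/210."""
        universe = [str(i) for i in range(10)]
        a, b = universe[:5], universe[:4]
        res = fisher_overlap(a, b, universe)
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)
        assert res.overlap == 4

    def test_matches_hypergeometric_tail_closed_form(self):
        """200 random tables: Fisher one-sided p equals the survival-function
        closed form sum_{k>=ov} C(K,k)C(N-K,n-k)/C(N,n) within 1e-10."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n_univ = int(rng.integers(5, 60))
            universe = [str(i) for i in range(n_univ)]
            ka = int(rng.integers(1, n_univ + 1))
            kb = int(rng.integers(1, n_univ + 1))
            a = list(rng.choice(universe, ka, replace=False))
            b = list(rng.choice(universe, kb, replace=False))
            res = fisher_overlap(a, b, universe)
            closed = stats.hypergeom.sf(res.overlap - 1, n_univ, ka, kb)
            assert abs(res.p_value - closed) < 1e-10

    def test_disjoint_small_sets_not_enriched(self):
        universe = [str(i) for i in range(100)]
        res = fisher_overlap(universe[:3], universe[50:53], universe)
        assert res.p_value > 0.5

    def test_degenerate_full_overlap(self):
        universe = [str(i) for i in range(8)]
        res = fisher_overlap(universe, universe, universe)
        assert res.overlap == 8
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_triggers_continuity_flag(self):
        universe = [str(i) for i in range(6)]
        res = fisher_overlap(universe[:3], universe[:3], universe)
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            fisher_overlap([], [], [])
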