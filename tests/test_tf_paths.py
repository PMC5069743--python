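"""TF-to-nearest-target distances, path comparisons, enzyme enrichment."""

import numpy as np
import pytest

from hpinet import (
    UNREACHABLE,
    SyntheticScenario,
    enzyme_path_enrichment,
    generate_scenario,
    path_length_comparison,
    tf_target_distances,
)
from conftest import gene_set, make_network


class TestTfTargetDistances:
    def test_adjacent_tf(self):
        net = make_network([("tf1", "t1"), ("t1", "x")])
        d = tf_target_distances(net, gene_set("tf", "tf", ["tf1"]),
                                gene_set("t", "targets", ["t1"]))
        assert d["tf1"] == 1

    def test_tf_that_is_target_distance_zero(self):
        net = make_network([("a", "b")])
        d = tf_target_distances(net, gene_set("tf", "tf", ["a"]),
                                gene_set("t", "targets", ["a"]))
        assert d["a"] == 0

    def test_unreachable_tf_flagged(self):
        net = make_network([("a", "b"), ("x", "y")])
        d = tf_target_distances(net, gene_set("tf", "tf", ["x"]),
                                gene_set("t", "targets", ["a"]))
        assert d["x"] is UNREACHABLE

    def test_empty_sets_error(self):
        net = make_network([("a", "b")])
        empty = gene_set("tf", "tf", []).map_to(net)
        with pytest.raises(ValueError):
            tf_target_distances(net, empty, gene_set("t", "targets", ["a"]))


class TestPathLengthComparison:
    def test_null_self_consistency(self):
        """TFs at typical positions: empirical p spreads around the middle."""
        data = generate_scenario(SyntheticScenario(
            seed=5, n_nodes=300, er_edge_prob=0.02, target_module_size=15,
            required_size=30, essential_size=30, n_complexes=10,
            complex_size_range=(3, 4), tf_size=10, enzyme_size=10,
        ))
        net = data.network
        rng = np.random.default_rng(0)
        nodes = sorted(net.nodes)
        # TFs drawn uniformly -> the observed set behaves like a null draw
        ps = []
        for i in range(40):
            tfs = gene_set("tf", "tf", rng.choice(nodes, 10, replace=False))
            comp = path_length_comparison(net, tfs, data.targets,
                                          n_resamples=99, seed=int(rng.integers(2**31)))
            ps.append(comp.empirical_p)
        assert 0.15 < np.mean(ps) < 0.85

    def test_planted_short_paths_detected(self):
        """Sparse background where the d=2 TF shell lies closer to the planted
        module than a random target set does: the comparison reports
        significantly shorter observed paths."""
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            data = generate_scenario(SyntheticScenario(
                seed=s, n_nodes=1500, er_edge_prob=0.0015, target_module_size=50,
                required_size=100, essential_size=100, n_complexes=30,
                complex_size_range=(3, 5), tf_size=60, enzyme_size=40,
            ))
            comp = path_length_comparison(
                data.network, data.gene_set("tf"), data.targets,
                n_resamples=99, seed=s,
            )
            if comp.empirical_p <= 0.05:
                hits += 1
        assert hits >= int(0.8 * n_seeds)

    def test_too_few_finite_distances_error(self):
        net = make_network([("a", "b"), ("x", "y")])
        with pytest.raises(ValueError):
            path_length_comparison(net, gene_set("tf", "tf", ["x"]),
                                   gene_set("t", "targets", ["a"]),
                                   n_resamples=5, seed=0)


class TestEnzymePathEnrichment:
    def test_line_example_exhaustive_oracle(self):
        """Line t-m-g with TF {t}, target {g}, enzymes {m}: the L=2 bin's
        interior is {m}, so f = 1.  Enumerating all 3 single-node target
        placements, only target={g} produces an L=2 bin at all (target={t}
        gives L=0, target={m} gives L=1), and it reproduces the observed
        configuration, so the length-conditioned null mean is also 1 and the
        exhaustive-oracle enrichment is exactly 0 with p = 1 — the
        self-draw degeneracy of a 3-node line.  Roughly a third of uniform
        draws land on that bin."""
        net = make_network([("t", "m"), ("m", "g")])
        tfs = gene_set("tf", "tf", ["t"])
        targets = gene_set("tg", "targets", ["g"])
        enzymes = gene_set("e", "enzyme", ["m"])
        res = enzyme_path_enrichment(net, tfs, targets, enzymes,
                                     n_resamples=300, seed=0)
        row = res.bins.iloc[0]
        assert row["path_length"] == 2
        assert row["observed_fraction"] == 1.0
        assert row["null_mean_fraction"] == 1.0
        assert row["enrichment"] == 0.0
        assert row["p_value"] == 1.0
        assert 0 < row["n_null_draws"] < 300

    def test_enzymes_everywhere_zero_enrichment(self):
        net = make_network([("t", "m"), ("m", "g"), ("g", "h")])
        res = enzyme_path_enrichment(
            net, gene_set("tf", "tf", ["t"]), gene_set("tg", "targets", ["g"]),
            gene_set("e", "enzyme", net.nodes), n_resamples=100, seed=0,
        )
        row = res.bins.iloc[0]
        assert row["observed_fraction"] == 1.0
        assert row["enrichment"] == pytest.approx(0.0)

    def test_enzymes_off_path_neg_inf(self):
        net = make_network([("t", "m"), ("m", "g"), ("g", "h")])
        res = enzyme_path_enrichment(
            net, gene_set("tf", "tf", ["t"]), gene_set("tg", "targets", ["g"]),
            gene_set("e", "enzyme", ["h"]), n_resamples=100, seed=0,
        )
        row = res.bins.iloc[0]
        assert row["observed_fraction"] == 0.0
        assert row["enrichment"] == float("-inf")
        assert row["flag"] == "zero_observed"

    def test_stored_paths_satisfy_validity_invariants(self, small_scenario):
        data = small_scenario
        res = enzyme_path_enrichment(
            data.network, data.gene_set("tf"), data.targets,
            data.gene_set("enzyme"), n_resamples=5, seed=0,
            store_paths=True, max_paths_per_tf=50,
        )
        t = set(data.targets.require_mapped())
        checked = 0
        for tf, paths in res.paths.items():
            for p in paths:
                assert p[0] == tf
                assert p[-1] in t
                assert len(p) - 1 == res.tf_distances[tf]
                for interior in p[1:-1]:
                    assert interior not in t and interior != tf
                # consecutive nodes adjacent
                for u, v in zip(p, p[1:]):
                    assert data.network.graph.has_edge(u, v)
                checked += 1
        assert checked > 0

    def test_all_shortest_vs_single_identical_when_unique(self):
        # unique shortest paths: a tree
        net = make_network([("tf1", "a"), ("a", "b"), ("b", "tgt"), ("a", "c")])
        tfs = gene_set("tf", "tf", ["tf1"])
        targets = gene_set("tg", "targets", ["tgt"])
        enzymes = gene_set("e", "enzyme", ["a"])
        r_all = enzyme_path_enrichment(net, tfs, targets, enzymes,
                                       n_resamples=50, seed=1, all_shortest=True)
        r_one = enzyme_path_enrichment(net, tfs, targets, enzymes,
                                       n_resamples=50, seed=1, all_shortest=False)
        cols = ["path_length", "n_nodes", "n_enzyme", "observed_fraction"]
        assert r_all.bins[cols].equals(r_one.bins[cols])

    def test_per_path_occurrence_weighting(self):
        # two equally short paths t-m1-g and t-m2-g; m1 enzyme, m2 not
        net = make_network([("t", "m1"), ("t", "m2"), ("m1", "g"), ("m2", "g")])
        res = enzyme_path_enrichment(
            net, gene_set("tf", "tf", ["t"]), gene_set("tg", "targets", ["g"]),
            gene_set("e", "enzyme", ["m1"]), n_resamples=20, seed=0, per_path=True,
        )
        row = res.bins.iloc[0]
        # 2 paths, one enzyme occurrence out of 2 interior occurrences
        assert row["observed_fraction"] == pytest.approx(0.5)

    def test_planted_enzymes_recovered(self):
        hits = 0
        for s in range(10):
            data = generate_scenario(SyntheticScenario(seed=s, enzyme_on_path_fraction=1.0))
            res = enzyme_path_enrichment(
                data.network, data.gene_set("tf"), data.targets,
                data.gene_set("enzyme"), n_resamples=50, seed=s, store_paths=False,
            )
            modal = res.bins.loc[res.bins.n_tfs.idxmax()]
            if modal["enrichment"] > 0:
                hits += 1
        assert hits >= 9
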