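"""Betweenness centrality, bottleneck proteins, and deletion robustness.

Betweenness centrality of a node v,

    c_B(v) = sum over unordered node pairs s != t != v of sigma_st(v) / sigma_st,

where sigma_st is the number of shortest s-t paths and sigma_st(v) the
number passing through v.  Pairs in different components contribute
nothing.  The top 20% most central nodes form the "bottleneck" set; gene
sets are then scored for enrichment in that set.

The robustness analysis orders a node set by decreasing degree in the full
network and deletes its members one at a time, recording the number of
connected components of the remaining graph after each step; equal-sized
comparison sets are taken from the first-step neighbourhood of the targets
and from the remaining nodes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import NEG_INF, fisher_overlap
from .net_core import GeneSet, Network, neighbors_of_set

logger = logging.getLogger("hpinet")


@dataclass
class CentralityMap:
    """Exact (non-normalised, unordered-pair) betweenness per node."""

    values: Dict[str, float]
    per_component: bool = True

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.values.items()), columns=["node", "betweenness"]
        )


def betweenness(network: Network) -> CentralityMap:
    """Exact betweenness via Brandes accumulation (unordered pairs).

    Disconnected graphs are handled naturally: unreachable pairs have no
    shortest paths and contribute nothing.
    """
    vals = nx.betweenness_centrality(network.graph, normalized=False)
    return CentralityMap(values={n: float(v) for n, v in vals.items()})


def bottleneck_set(centrality: CentralityMap, fraction: float = 0.20) -> set:
    """Top ``ceil(fraction * |V|)`` nodes by betweenness.

    Ties at the threshold are broken by lexicographic node identifier so
    the set is deterministic; a tie across the cut is warned about.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    items = sorted(centrality.values.items(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(fraction * len(items))
    if k < len(items) and items[k - 1][1] == items[k][1]:
        warnings.warn(
            "betweenness tie at the bottleneck threshold; broke tie by node id",
            stacklevel=2,
        )
    return {n for n, _ in items[:k]}


def bottleneck_enrichment(
    network: Network,
    partition_sets: Sequence[GeneSet],
    fraction: float = 0.20,
    centrality: CentralityMap | None = None,
) -> pd.DataFrame:
    """Enrichment of each set in the bottleneck (top-betweenness) set.

    E = log2( fraction of the set that is bottleneck / bottleneck fraction
    of the network ), with a one-sided Fisher exact p-value for the
    overlap.  Typical partitions: targets; required/essential genes in the
    target neighbourhood; required/essential genes outside it; remaining
    nodes.
    """
    if centrality is None:
        centrality = betweenness(network)
    bset = bottleneck_set(centrality, fraction)
    universe = set(network.graph.nodes)
    expected = len(bset) / len(universe)
    rows = []
    for gs in partition_sets:
        members = set(gs.require_mapped())
        if not members:
            rows.append(
                dict(set_name=gs.name, set_size=0, n_bottleneck=0,
                     observed_fraction=float("nan"), expected_fraction=expected,
                     enrichment=float("nan"), p_value=float("nan"), flag="empty_set")
            )
            continue
        ov = len(members & bset)
        f = ov / len(members)
        e = math.log2(f / expected) if f > 0 else NEG_INF
        test = fisher_overlap(members, bset, universe)
        rows.append(
            dict(
                set_name=gs.name,
                set_size=len(members),
                n_bottleneck=ov,
                observed_fraction=f,
                expected_fraction=expected,
                enrichment=e,
                p_value=test.p_value,
                flag="" if f > 0 else "zero_observed",
            )
        )
    df = pd.DataFrame(rows)
    df.attrs["bottleneck_fraction"] = fraction
    df.attrs["bottleneck_size"] = len(bset)
    return df


# ---------------------------------------------------------------------------
# Robustness (sequential deletion)
# ---------------------------------------------------------------------------


@dataclass
class RobustnessCurve:
    """Component counts after successive degree-ordered node deletions."""

    label: str
    deleted_nodes: List[str]
    degrees: List[int]
    n_components: List[int]
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.deleted_nodes) + 1),
                "deleted_node": self.deleted_nodes,
                "degree": self.degrees,
                "n_components": self.n_components,
                "label": self.label,
            }
        )


def _degree_sorted(network: Network, nodes: Iterable[str]) -> List[str]:
    # secondary key: node id, for bit-reproducibility
    return sorted(nodes, key=lambda n: (-network.graph.degree(n), n))


def _deletion_curve(
    network: Network, ordered: List[str], label: str, include_isolated: bool,
    truncated: bool = False,
) -> RobustnessCurve:
    g = network.graph.copy()
    degrees = [network.graph.degree(n) for n in ordered]
    counts: List[int] = []
    for n in ordered:
        g.remove_node(n)
        comps = nx.connected_components(g)
        if include_isolated:
            counts.append(sum(1 for _ in comps))
        else:
            counts.append(sum(1 for c in comps if len(c) > 1))
    return RobustnessCurve(label, list(ordered), degrees, counts, truncated)


def robustness_analysis(
    network: Network,
    targets: GeneSet,
    seed=None,
    *,
    comparison: str = "top_degree",
    include_isolated: bool = True,
) -> List[RobustnessCurve]:
    """Degree-ordered deletion curves for targets, Γ(targets), and the rest.

    Each curve deletes an equal-sized node set in order of decreasing
    full-network degree (ties broken by node id) and records the number of
    connected components after every step.  When the neighbourhood or
    remainder exceeds the target count, the comparison subset is either the
    highest-degree members (``comparison="top_degree"``, deterministic,
    default) or a seeded uniform draw (``comparison="random"``); when it is
    smaller, the curve is truncated with a warning.
    """
    if comparison not in ("top_degree", "random"):
        raise ValueError("comparison must be 'top_degree' or 'random'")
    t = set(targets.require_mapped())
    if not t:
        raise ValueError(f"target set {targets.name!r} is empty after mapping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(t)
    gamma = neighbors_of_set(network, t)
    remaining = set(network.graph.nodes) - t - gamma

    def pick(pool: set, label: str) -> tuple[List[str], bool]:
        truncated = False
        if len(pool) < k:
            warnings.warn(
                f"robustness comparison set {label!r} has only {len(pool)} nodes "
                f"(< {k} targets); curve truncated",
                stacklevel=3,
            )
            truncated = True
            chosen = list(pool)
        elif comparison == "top_degree":
            chosen = _degree_sorted(network, pool)[:k]
        else:
            arr = np.array(sorted(pool), dtype=object)
            chosen = list(rng.choice(arr, size=k, replace=False))
        return _degree_sorted(network, chosen), truncated

    curves = [
        _deletion_curve(network, _degree_sorted(network, t), "targets", include_isolated)
    ]
    for pool, label in ((gamma, "neighbors"), (remaining, "remaining")):
        ordered, truncated = pick(pool, label)
        curves.append(
            _deletion_curve(network, ordered, label, include_isolated, truncated)
        )
    return curves
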