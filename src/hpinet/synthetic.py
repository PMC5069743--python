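"""Synthetic interactomes with planted pathogen-infection structure.

Every downstream analysis in this package is exercised, without any
download, on generated networks that carry the statistical structure the
analyses assume:

* a sparse background interactome (Erdős–Rényi by default; a heavy-tailed
  configuration model is available for degree-distribution sensitivity
  checks);
* a planted, connected "targeted" module: the pathogen-targeted proteins,
  wired together by a random spanning tree plus extra intra-module edges;
* infection-required and essential gene sets sampled without replacement
  with probability weight exp(-λ · d), where d is a node's distance to the
  nearest target — λ tunes how tightly these sets hug the targets (λ = 0
  is uniform);
* disjoint protein complexes (cliques) covering part of the node set;
* transcription factors placed at distance >= 2 from targets, and
  methylation/acetylation-style enzymes of which a tunable fraction sits
  on TF-to-nearest-target shortest-path interiors;
* COG-style functional classes partitioning the node set uniformly.

Default parameters are desk-scale versions of a real host interactome:
2,000 nodes at mean degree 10, a 50-protein target module, 200 required
and 300 essential genes at decay λ = 1.5, 150 TFs and 90 enzymes (roughly
the TF/enzyme share of the human proteome), and 100 complexes of 3–8
members.  A single integer seed drives one explicit pseudorandom stream;
identical seed and parameters give bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np

from .complexes import ComplexCatalog
from .net_core import GeneSet, Network

logger = logging.getLogger("hpinet")


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameter record for one synthetic interactome scenario."""

    seed: int = 0
    n_nodes: int = 2000
    background_model: str = "erdos_renyi"  # or "configuration"
    er_edge_prob: float = 0.005
    degree_exponent: float = 2.5
    mean_degree: float = 10.0
    target_module_size: int = 50
    target_intra_edge_prob: float = 0.10
    required_size: int = 200
    essential_size: int = 300
    proximity_decay: float = 1.5  # λ; sampling weight ∝ exp(-λ d)
    n_complexes: int = 100
    complex_size_range: Tuple[int, int] = (3, 8)
    tf_size: int = 150
    enzyme_size: int = 90
    enzyme_on_path_fraction: float = 0.7
    n_functional_classes: int = 8

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.background_model not in ("erdos_renyi", "configuration"):
            raise ValueError("background_model must be 'erdos_renyi' or 'configuration'")
        for name in ("target_module_size", "required_size", "essential_size",
                     "tf_size", "enzyme_size"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_nodes:
                raise ValueError(f"{name}={v} must be in [0, n_nodes]")
        for name in ("er_edge_prob", "target_intra_edge_prob",
                     "enzyme_on_path_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability")
        if self.proximity_decay < 0:
            raise ValueError("proximity_decay must be nonnegative")
        lo, hi = self.complex_size_range
        if not (1 <= lo <= hi):
            raise ValueError("complex_size_range must satisfy 1 <= lo <= hi")
        if self.n_complexes * hi > self.n_nodes:
            raise ValueError(
                "complexes cannot be disjoint: n_complexes * max size exceeds n_nodes"
            )
        if self.target_module_size < 1:
            raise ValueError("target module must have at least one node")


@dataclass
class ScenarioData:
    """Generated network, annotation sets, complexes, and the ground truth."""

    params: SyntheticScenario
    network: Network
    gene_sets: List[GeneSet]
    catalog: ComplexCatalog
    ground_truth: Dict

    def gene_set(self, name: str) -> GeneSet:
        for gs in self.gene_sets:
            if gs.name == name:
                return gs
        raise KeyError(name)

    @property
    def targets(self) -> GeneSet:
        return self.gene_set("targets")


def _node_names(n: int) -> List[str]:
    width = max(4, len(str(n - 1)))
    return [f"P{i:0{width}d}" for i in range(n)]


def _background_graph(params: SyntheticScenario, rng: np.random.Generator) -> nx.Graph:
    names = _node_names(params.n_nodes)
    gseed = int(rng.integers(2**31))
    if params.background_model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(params.n_nodes, params.er_edge_prob, seed=gseed)
    else:
        # discrete power-law degrees, truncated and adjusted to even sum
        raw = rng.zipf(params.degree_exponent, size=params.n_nodes)
        raw = np.clip(raw, 1, max(2, params.n_nodes // 10))
        scale = params.mean_degree / raw.mean()
        degs = np.maximum(1, np.round(raw * scale).astype(int))
        if degs.sum() % 2:
            degs[int(rng.integers(params.n_nodes))] += 1
        multigraph = nx.configuration_model(degs.tolist(), seed=gseed)
        g = nx.Graph(multigraph)
        g.remove_edges_from(nx.selfloop_edges(g))
    # interactome edge lists contain only interacting proteins: attach any
    # isolated node by a single uniformly chosen edge
    isolated = sorted(nx.isolates(g))
    if isolated:
        others = [v for v in g if g.degree(v) > 0] or list(g)
        for u in isolated:
            v = others[int(rng.integers(len(others)))]
            if v != u:
                g.add_edge(u, v)
    return nx.relabel_nodes(g, dict(enumerate(names)))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """Efraimidis–Spirakis via Gumbel keys: exact weighted sampling w/o repl."""
    if k > np.count_nonzero(weights > 0):
        raise ValueError("cannot sample more items than have positive weight")
    keys = np.full(items.shape, -np.inf)
    pos = weights > 0
    keys[pos] = np.log(weights[pos]) + rng.gumbel(size=int(pos.sum()))
    top = np.argpartition(-keys, k - 1)[:k]
    return items[top]


def generate_scenario(params: SyntheticScenario) -> ScenarioData:
    """Generate a full scenario: network, gene sets, complexes, ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    g = _background_graph(params, rng)
    names = sorted(g.nodes)
    name_arr = np.array(names, dtype=object)

    # --- planted target module: spanning tree + extra intra edges ----------
    m = params.target_module_size
    module = sorted(rng.choice(name_arr, size=m, replace=False))
    order = list(rng.permutation(module))
    for i in range(1, m):
        anchor = order[int(rng.integers(i))]
        g.add_edge(order[i], anchor)
    if params.target_intra_edge_prob > 0:
        for i in range(m):
            for j in range(i + 1, m):
                if not g.has_edge(module[i], module[j]):
                    if rng.random() < params.target_intra_edge_prob:
                        g.add_edge(module[i], module[j])

    net = Network(g)
    targets = GeneSet.from_nodes("targets", "targets", module)

    # --- required / essential: distance-decay sampling ---------------------
    dist = net.distances_from(module)
    finite = np.isfinite(dist)
    weights = np.zeros(net.n_nodes)
    weights[finite] = np.exp(-params.proximity_decay * dist[finite])
    node_arr = np.array(net.node_list, dtype=object)
    required = sorted(
        _weighted_sample_without_replacement(rng, node_arr, weights, params.required_size)
    )
    essential = sorted(
        _weighted_sample_without_replacement(rng, node_arr, weights, params.essential_size)
    )

    # --- complexes: disjoint cliques ---------------------------------------
    lo, hi = params.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_complexes)
    pool = list(rng.permutation(node_arr))
    complexes: List[Tuple[str, frozenset]] = []
    cursor = 0
    for ci, size in enumerate(sizes):
        members = pool[cursor : cursor + int(size)]
        cursor += int(size)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j])
        complexes.append((f"complex_{ci:04d}", frozenset(members)))
    catalog = ComplexCatalog(tuple(complexes))

    # complex edges changed the topology: refresh caches and distances
    net = Network(g)
    dist = net.distances_from(module)
    node_arr = np.array(net.node_list, dtype=object)

    # --- transcription factors at distance >= 2 from targets ---------------
    # Preferentially on the second-step shell (d == 2), spilling outward to
    # d == 3, 4, ... only when the shell is too small.
    far_total = int(np.count_nonzero(np.isfinite(dist) & (dist >= 2)))
    if far_total < params.tf_size:
        raise ValueError(
            f"only {far_total} nodes lie at distance >= 2 from targets; "
            f"cannot place {params.tf_size} TFs"
        )
    tf_chosen: List[str] = []
    shell_d = 2
    while len(tf_chosen) < params.tf_size:
        shell = node_arr[np.isfinite(dist) & (dist == shell_d)]
        need = params.tf_size - len(tf_chosen)
        if shell.size <= need:
            tf_chosen.extend(shell)
        else:
            tf_chosen.extend(rng.choice(shell, size=need, replace=False))
        shell_d += 1
    tf_nodes = sorted(tf_chosen)

    # --- enzymes: a fraction on TF->nearest-target shortest-path interiors -
    idx = net.index
    on_path_pool: set = set()
    for tf in tf_nodes:
        d_tf = net.distances_from([tf])
        L = dist[idx[tf]]
        with np.errstate(invalid="ignore"):
            on = np.isfinite(d_tf) & np.isfinite(dist) & (d_tf + dist == L)
        on &= dist > 0  # interiors exclude targets
        on[idx[tf]] = False
        on_path_pool.update(node_arr[on])
    n_on = int(round(params.enzyme_on_path_fraction * params.enzyme_size))
    pool_arr = np.array(sorted(on_path_pool), dtype=object)
    if pool_arr.size < n_on:
        raise ValueError(
            f"only {pool_arr.size} nodes lie on TF->target shortest-path "
            f"interiors; cannot place {n_on} on-path enzymes"
        )
    on_enzymes = list(rng.choice(pool_arr, size=n_on, replace=False)) if n_on else []
    rest_pool = np.array(sorted(set(names) - set(on_enzymes)), dtype=object)
    off_enzymes = list(
        rng.choice(rest_pool, size=params.enzyme_size - n_on, replace=False)
    ) if params.enzyme_size > n_on else []
    enzymes = sorted(on_enzymes + off_enzymes)

    # --- COG-style functional classes: uniform partition --------------------
    class_sets: List[GeneSet] = []
    if params.n_functional_classes > 0:
        assignment = rng.integers(params.n_functional_classes, size=len(names))
        perm = rng.permutation(len(names))
        for ci in range(params.n_functional_classes):
            members = [names[j] for j in perm if assignment[j] == ci]
            if members:
                class_sets.append(
                    GeneSet.from_nodes(f"class_{ci}", "class", members)
                )

    gene_sets = [
        targets.map_to(net),
        GeneSet.from_nodes("required", "required", required).map_to(net),
        GeneSet.from_nodes("essential", "essential", essential).map_to(net),
        GeneSet.from_nodes("tf", "tf", tf_nodes).map_to(net),
        GeneSet.from_nodes("enzyme", "enzyme", enzymes).map_to(net),
    ] + [cs.map_to(net) for cs in class_sets]

    ground_truth = {
        "seed": params.seed,
        "proximity_decay": params.proximity_decay,
        "targets": list(module),
        "required": list(required),
        "essential": list(essential),
        "tf": list(tf_nodes),
        "enzyme": list(enzymes),
        "enzyme_on_path": sorted(on_enzymes),
        "complexes": {name: sorted(m) for name, m in complexes},
        "params": asdict(params),
    }
    return ScenarioData(
        params=params,
        network=net,
        gene_sets=gene_sets,
        catalog=catalog,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Writing scenarios to disk (formats net_core reads back)
# ---------------------------------------------------------------------------


def write_scenario(
    data: ScenarioData, directory: str | Path, *, overwrite: bool = False
) -> Dict[str, Path]:
    """Write edge list, GMT gene sets, complex GMT, ground truth, manifest.

    Refuses to clobber an existing non-empty directory unless
    ``overwrite=True``.  Output is deterministic (sorted) so identical
    scenarios produce byte-identical files.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty (pass overwrite=True)"
        )
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": directory / "network.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "complexes": directory / "complexes.gmt",
        "ground_truth": directory / "ground_truth.json",
        "manifest": directory / "manifest.txt",
    }
    with open(paths["network"], "wt") as fh:
        fh.write("# synthetic interactome edge list\n")
        for a, b in sorted(tuple(sorted(e)) for e in data.network.graph.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["gene_sets"], "wt") as fh:
        for gs in data.gene_sets:
            fh.write("\t".join([gs.name, gs.role, *sorted(gs.raw_members)]) + "\n")
    with open(paths["complexes"], "wt") as fh:
        for name, members in data.catalog.complexes:
            fh.write("\t".join([name, "complex", *sorted(members)]) + "\n")
    with open(paths["ground_truth"], "wt") as fh:
        json.dump(data.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(paths["manifest"], "wt") as fh:
        for key, value in sorted(asdict(data.params).items()):
            fh.write(f"{key}={value}\n")
        fh.write(f"n_nodes_generated={data.network.n_nodes}\n")
        fh.write(f"n_edges_generated={data.network.n_edges}\n")
    logger.info("wrote scenario (seed=%d) to %s", data.params.seed, directory)
    return paths
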