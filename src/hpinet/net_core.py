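"""Graph data model, file I/O and elementary graph algorithms.

The analyses in this package all operate on an undirected, simple host
protein-interaction network (the interactome) together with named sets of
nodes that carry a biological role: pathogen-targeted proteins, genes
required for infection, essential genes, transcription factors, enzymes,
or broad functional classes.  This module provides

* :class:`Network` -- a thin wrapper around a :class:`networkx.Graph` that
  enforces the simple-graph invariants and caches an index/CSR view used by
  the heavier resampling machinery elsewhere in the package;
* :class:`GeneSet` -- a named, role-tagged node set with explicit
  bookkeeping of how many raw identifiers mapped into a given network;
* :class:`DistanceProfile` -- the result of a multi-source breadth-first
  search: the shortest distance from every node to the nearest member of a
  reference set, with an explicit :data:`UNREACHABLE` sentinel for nodes in
  other components;
* loaders for two-column edge lists and GMT gene-set files, plus the
  elementary operations (connected components, induced subgraphs,
  first-step neighbourhoods) every downstream analysis consumes.

Identifiers are opaque, case-sensitive strings; no identifier translation
is attempted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Union

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

logger = logging.getLogger("hpinet")

#: Recognised gene-set roles; anything else read from a GMT description
#: field is stored as ``"other"``.
KNOWN_ROLES = frozenset(
    {"targets", "required", "essential", "tf", "enzyme", "class", "other"}
)


class NetworkParseError(ValueError):
    """Raised for malformed edge-list or gene-set input."""


class _Unreachable:
    """Singleton sentinel for nodes with no path to a reference set.

    Deliberately not an integer so it can never be confused with a
    distance; downstream binning excludes unreachable nodes.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNREACHABLE"


UNREACHABLE = _Unreachable()

Distance = Union[int, _Unreachable]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network:
    """Undirected simple graph of host proteins.

    Parameters
    ----------
    graph:
        A :class:`networkx.Graph`.  Self-loops are removed on construction
        (networkx already collapses duplicate edges).
    n_self_loops_dropped, n_duplicates_dropped:
        Normalisation counts recorded by :func:`load_network`.
    """

    def __init__(
        self,
        graph: nx.Graph,
        *,
        n_self_loops_dropped: int = 0,
        n_duplicates_dropped: int = 0,
    ) -> None:
        loops = list(nx.selfloop_edges(graph))
        if loops:
            graph = graph.copy()
            graph.remove_edges_from(loops)
            n_self_loops_dropped += len(loops)
        self.graph = graph
        self.n_self_loops_dropped = n_self_loops_dropped
        self.n_duplicates_dropped = n_duplicates_dropped
        # Lazy caches for index-based algorithms.
        self._node_list: List[str] | None = None
        self._index: Dict[str, int] | None = None
        self._csr: sparse.csr_matrix | None = None
        self._adj: Dict[str, frozenset] | None = None

    # -- basic views ----------------------------------------------------

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    # -- cached index/CSR views used by resampling code -----------------

    @property
    def node_list(self) -> List[str]:
        """Nodes in sorted order; the canonical index order of the CSR view."""
        if self._node_list is None:
            self._node_list = sorted(self.graph.nodes)
        return self._node_list

    @property
    def index(self) -> Dict[str, int]:
        if self._index is None:
            self._index = {n: i for i, n in enumerate(self.node_list)}
        return self._index

    @property
    def csr(self) -> sparse.csr_matrix:
        if self._csr is None:
            self._csr = nx.to_scipy_sparse_array(
                self.graph, nodelist=self.node_list, format="csr", dtype=np.int8
            )
        return self._csr

    @property
    def adjacency_sets(self) -> Dict[str, frozenset]:
        if self._adj is None:
            self._adj = {n: frozenset(self.graph[n]) for n in self.graph}
        return self._adj

    def indices_of(self, nodes: Iterable[str]) -> np.ndarray:
        idx = self.index
        return np.fromiter((idx[n] for n in nodes), dtype=np.int64)

    def distances_from(self, source_nodes: Iterable[str]) -> np.ndarray:
        """Multi-source BFS distances to every node, in ``node_list`` order.

        Returns a float array with ``np.inf`` for unreachable nodes.
        """
        src = self.indices_of(source_nodes)
        if src.size == 0:
            raise ValueError("distances_from requires at least one source node")
        return csgraph.dijkstra(
            self.csr, directed=False, unweighted=True, indices=src, min_only=True
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# GeneSet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named, role-tagged set of node identifiers.

    ``raw_members`` holds the identifiers exactly as read; ``members`` is
    filled by :meth:`map_to` with the intersection against a network's node
    set.  The (raw size, mapped size) pair is always recoverable, so nothing
    is discarded silently.
    """

    name: str
    role: str
    raw_members: FrozenSet[str]
    members: FrozenSet[str] | None = None

    def __post_init__(self) -> None:
        if self.role not in KNOWN_ROLES:
            raise ValueError(f"unknown role {self.role!r} for gene set {self.name!r}")
        if self.members is not None and not self.members <= self.raw_members:
            raise ValueError("members must be a subset of raw_members")

    @property
    def raw_size(self) -> int:
        return len(self.raw_members)

    @property
    def mapped_size(self) -> int:
        if self.members is None:
            raise ValueError(f"gene set {self.name!r} has not been mapped to a network")
        return len(self.members)

    def map_to(self, network: Network) -> "GeneSet":
        """Intersect the raw members with the network's node set."""
        mapped = frozenset(self.raw_members & network.graph.nodes.keys())
        logger.info(
            "gene set %s (role=%s): %d raw members, %d mapped to network",
            self.name,
            self.role,
            len(self.raw_members),
            len(mapped),
        )
        return replace(self, members=mapped)

    def require_mapped(self) -> FrozenSet[str]:
        if self.members is None:
            raise ValueError(f"gene set {self.name!r} has not been mapped to a network")
        return self.members

    @classmethod
    def from_nodes(
        cls, name: str, role: str, nodes: Iterable[str], *, mapped: bool = True
    ) -> "GeneSet":
        """Build a gene set directly from node identifiers (no file)."""
        members = frozenset(nodes)
        return cls(name, role, members, members if mapped else None)


# ---------------------------------------------------------------------------
# DistanceProfile
# ---------------------------------------------------------------------------


@dataclass
class DistanceProfile:
    """Shortest distance from every node to the nearest reference node."""

    reference_set_name: str
    distances: Mapping[str, Distance]

    def reachable_nodes(self) -> set:
        return {n for n, d in self.distances.items() if d is not UNREACHABLE}

    def unreachable_nodes(self) -> set:
        return {n for n, d in self.distances.items() if d is UNREACHABLE}

    def bins(self) -> Dict[int, FrozenSet[str]]:
        """Partition reachable nodes by distance: ``{d: nodes at distance d}``."""
        out: Dict[int, set] = {}
        for n, d in self.distances.items():
            if d is UNREACHABLE:
                continue
            out.setdefault(d, set()).add(n)
        return {d: frozenset(s) for d, s in sorted(out.items())}


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

Source = Union[str, Path, io.TextIOBase, Iterable[str]]


def _iter_lines(source: Source):
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            with open(p, "rt") as fh:
                yield from enumerate(fh, start=1)
            return
        if isinstance(source, Path):
            raise FileNotFoundError(source)
        # a literal string of content
        yield from enumerate(io.StringIO(source), start=1)
        return
    yield from enumerate(source, start=1)


def load_network(source: Source) -> Network:
    """Read a two-column delimited edge list into a normalised :class:`Network`.

    Tab- or whitespace-delimited; lines starting with ``#`` and blank lines
    are ignored; an optional single header line is NOT assumed (a header
    would simply become an edge, so edge lists should not carry one).
    Self-loops and duplicate edges are dropped and counted.

    Raises
    ------
    NetworkParseError
        For a line with a number of columns different from two (the message
        names the line number), or for input containing no edges.
    """
    graph = nx.Graph()
    n_loops = 0
    n_dups = 0
    n_edges_seen = 0
    for lineno, raw in _iter_lines(source):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise NetworkParseError(
                f"edge list line {lineno}: expected 2 columns, got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        n_edges_seen += 1
        if a == b:
            n_loops += 1
            graph.add_node(a)
            continue
        if graph.has_edge(a, b):
            n_dups += 1
            continue
        graph.add_edge(a, b)
    if n_edges_seen == 0:
        raise NetworkParseError("empty edge list: no edges found in input")
    net = Network(graph, n_self_loops_dropped=n_loops, n_duplicates_dropped=n_dups)
    logger.info(
        "loaded network: %d nodes, %d edges (%d self-loops dropped, %d duplicates dropped)",
        net.n_nodes,
        net.n_edges,
        n_loops,
        n_dups,
    )
    return net


def load_gene_sets(source: Source, dialect: str = "gmt") -> List[GeneSet]:
    """Read gene sets from GMT lines (name TAB role/description TAB member...).

    The description field becomes the set's role when it matches a known
    role, else ``"other"``.  Duplicate members on one line are deduplicated.
    With ``dialect="long"`` a two-column (set name, member) long format is
    read instead.
    """
    if dialect not in ("gmt", "long"):
        raise ValueError("dialect must be 'gmt' or 'long'")
    lines = [(no, raw.rstrip("\n")) for no, raw in _iter_lines(source)]
    lines = [(no, l) for no, l in lines if l.strip() and not l.startswith("#")]
    if not lines:
        raise NetworkParseError("empty gene set input")
    split = [(no, l.split("\t")) for no, l in lines]
    if dialect == "long":
        grouped: Dict[str, set] = {}
        for no, fields in split:
            if len(fields) != 2:
                raise NetworkParseError(
                    f"gene set line {no}: long format needs exactly 2 fields"
                )
            name, member = fields
            grouped.setdefault(name.strip(), set()).add(member.strip())
        return [
            GeneSet(name, "other", frozenset(members))
            for name, members in grouped.items()
        ]
    sets: List[GeneSet] = []
    for no, fields in split:
        if len(fields) < 3:
            raise NetworkParseError(
                f"gene set line {no}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        name = fields[0].strip()
        desc = fields[1].strip()
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        if not members:
            raise NetworkParseError(f"gene set line {no}: no members")
        role = desc if desc in KNOWN_ROLES else "other"
        sets.append(GeneSet(name, role, members))
    return sets


# ---------------------------------------------------------------------------
# Elementary graph operations
# ---------------------------------------------------------------------------


def distance_to_nearest(network: Network, reference: GeneSet) -> DistanceProfile:
    """Shortest distance from every node to the nearest reference member.

    A single multi-source BFS; members of the reference set are at distance
    0, nodes in components containing no reference member get the
    :data:`UNREACHABLE` sentinel.
    """
    members = reference.require_mapped()
    if not members:
        raise ValueError(
            f"reference gene set {reference.name!r} is empty after mapping to the network"
        )
    dist = network.distances_from(members)
    nodes = network.node_list
    mapping: Dict[str, Distance] = {}
    for i, n in enumerate(nodes):
        d = dist[i]
        mapping[n] = UNREACHABLE if np.isinf(d) else int(d)
    return DistanceProfile(reference_set_name=reference.name, distances=mapping)


def connected_components(network: Network) -> List[FrozenSet[str]]:
    """Maximal connected node sets, largest first (ties broken by members)."""
    comps = [frozenset(c) for c in nx.connected_components(network.graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def induced_subgraph(network: Network, node_set: Iterable[str]) -> Network:
    """Subgraph on ``node_set`` ∩ nodes with all internal edges."""
    keep = set(node_set) & set(network.graph.nodes)
    return Network(network.graph.subgraph(keep).copy())


def neighbors_of_set(network: Network, node_set: Iterable[str]) -> set:
    """First-step neighbourhood Γ: nodes at distance exactly 1 from the set."""
    inside = set(node_set) & set(network.graph.nodes)
    out: set = set()
    for n in inside:
        out.update(network.graph[n])
    return out - inside


def largest_component_size(network: Network, node_set: Iterable[str]) -> int:
    """Node count of the largest component of the induced subgraph.

    Runs directly on cached adjacency sets; this is the hot inner loop of
    the resampling null in :mod:`hpinet.connectivity`.
    """
    adj = network.adjacency_sets
    nodes = set(node_set) & adj.keys()
    best = 0
    seen: set = set()
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in adj[u] & nodes:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if size > best:
            best = size
    return best
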