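"""Shortest paths from transcription factors to the nearest pathogen targets.

Human viruses appear to reach transcription factors (TFs) indirectly: the
shortest paths from TFs to their nearest virus-targeted proteins are
shorter than expected by chance, and the proteins mediating those paths
are enriched for methylation/acetylation enzymes.  This module implements

* per-TF distances to the nearest target (multi-source BFS);
* a comparison of observed TF-to-target path lengths against resampled
  target sets (Student's t, rank-sum, and a resampling empirical p are all
  reported);
* enrichment of an enzyme set among the nodes of TF-to-nearest-target
  shortest paths, binned by path length L, against the same
  resampled-target null.

By default every shortest path from a TF to each of its nearest targets
contributes (deterministic), nodes are counted once per length bin, and
only path interiors are scored (endpoints are TFs and targets, whose
enrichment is assessed elsewhere); flags select a single sampled path,
per-path-occurrence weighting, or endpoint-inclusive counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import _log2_ratio
from .net_core import GeneSet, Network, UNREACHABLE, Distance

logger = logging.getLogger("hpinet")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def tf_target_distances(
    network: Network, tfs: GeneSet, targets: GeneSet
) -> Dict[str, Distance]:
    """Distance from each TF to the nearest target (0 for TFs that are targets)."""
    t = targets.require_mapped()
    f = tfs.require_mapped()
    if not t or not f:
        raise ValueError("tf and target sets must be nonempty after mapping")
    dist = network.distances_from(t)
    idx = network.index
    out: Dict[str, Distance] = {}
    for tf in sorted(f):
        d = dist[idx[tf]]
        out[tf] = UNREACHABLE if np.isinf(d) else int(d)
    return out


# ---------------------------------------------------------------------------
# Path-length comparison
# ---------------------------------------------------------------------------


@dataclass
class PathLengthComparison:
    observed_mean: float
    null_mean: float
    t_statistic: float
    t_p_value: float
    ranksum_statistic: float
    ranksum_p_value: float
    empirical_p: float
    n_tfs: int
    n_unreachable: int
    n_resamples: int
    seed: object


def path_length_comparison(
    network: Network,
    tfs: GeneSet,
    targets: GeneSet,
    n_resamples: int = 10_000,
    seed=None,
) -> PathLengthComparison:
    """Observed TF-to-nearest-target distances vs resampled target sets.

    The null redraws target-sized node sets uniformly and recomputes TF
    distances; the pooled null distances feed a two-sample Student's t test
    and a rank-sum test, and the per-draw means give a one-sided (shorter)
    add-one empirical p for the observed mean.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = targets.require_mapped()
    f = tfs.require_mapped()
    dist = network.distances_from(t)
    tf_idx = network.indices_of(sorted(f))
    obs = dist[tf_idx]
    finite = np.isfinite(obs)
    n_unreachable = int((~finite).sum())
    obs = obs[finite]
    if obs.size < 2:
        raise ValueError("fewer than 2 finite TF-to-target distances")

    k = len(t)
    n = network.n_nodes
    pool = np.arange(n)
    null_all: List[np.ndarray] = []
    null_means = np.full(n_resamples, np.inf)
    for i in range(n_resamples):
        draw = rng.choice(pool, size=k, replace=False)
        d = network.distances_from([network.node_list[j] for j in draw])[tf_idx]
        d = d[np.isfinite(d)]
        if d.size:
            null_all.append(d)
            null_means[i] = d.mean()
    pooled = np.concatenate(null_all) if null_all else np.array([])
    if pooled.size < 2:
        raise ValueError("null produced fewer than 2 finite distances")

    t_stat, t_p = stats.ttest_ind(obs, pooled, equal_var=True)
    r_stat, r_p = stats.ranksums(obs, pooled)
    obs_mean = float(obs.mean())
    le = int(np.count_nonzero(null_means <= obs_mean))
    emp_p = (1 + le) / (n_resamples + 1)
    return PathLengthComparison(
        observed_mean=obs_mean,
        null_mean=float(pooled.mean()),
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        ranksum_statistic=float(r_stat),
        ranksum_p_value=float(r_p),
        empirical_p=emp_p,
        n_tfs=int(obs.size),
        n_unreachable=n_unreachable,
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Enzyme enrichment on TF->target shortest paths
# ---------------------------------------------------------------------------


@dataclass
class TFPathResult:
    """Per-TF shortest paths and per-length-bin enzyme enrichment."""

    tf_distances: Dict[str, Distance]
    bins: pd.DataFrame
    paths: Dict[str, List[List[str]]]
    n_resamples: int
    seed: object
    all_shortest: bool = True
    include_endpoints: bool = False
    per_path: bool = False


def _path_node_matrix(
    tf_dist_matrix: np.ndarray,
    dist_t: np.ndarray,
    tf_idx: np.ndarray,
    include_endpoints: bool,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean (n_tf, n_nodes) mask of nodes on each TF's shortest paths.

    A node u lies on a shortest path from TF to a nearest target iff
    d(TF, u) + d(u, targets) == d(TF, targets).  Interior mode removes
    targets (d == 0) and the source TF from each row.
    """
    L = dist_t[tf_idx]  # per-TF distance to nearest target
    with np.errstate(invalid="ignore"):
        mask = tf_dist_matrix + dist_t[None, :] == L[:, None]
    mask &= np.isfinite(dist_t)[None, :]
    mask[~np.isfinite(L)] = False
    if not include_endpoints:
        mask &= (dist_t > 0)[None, :]
        mask[np.arange(tf_idx.size), tf_idx] = False
    return mask, L


def _enumerate_paths(
    network: Network,
    tf: str,
    dist_tf: np.ndarray,
    dist_t: np.ndarray,
    cap: int = 1000,
) -> List[List[str]]:
    """All shortest paths from a TF to its nearest targets (node sequences)."""
    idx = network.index
    nodes = network.node_list
    L = dist_t[idx[tf]]
    if not np.isfinite(L):
        return []
    L = int(L)
    paths: List[List[str]] = []

    def extend(u: str, acc: List[str]) -> None:
        if len(paths) >= cap:
            return
        iu = idx[u]
        if dist_t[iu] == 0:
            paths.append(list(acc))
            return
        for v in sorted(network.graph[u]):
            iv = idx[v]
            if (
                dist_tf[iv] == dist_tf[iu] + 1
                and np.isfinite(dist_t[iv])
                and dist_tf[iv] + dist_t[iv] == L
            ):
                acc.append(v)
                extend(v, acc)
                acc.pop()

    extend(tf, [tf])
    if len(paths) >= cap:
        logger.warning("path enumeration for TF %s capped at %d paths", tf, cap)
    return paths


def _sample_one_path(
    network: Network, tf: str, dist_t: np.ndarray, rng: np.random.Generator
) -> List[str]:
    idx = network.index
    if not np.isfinite(dist_t[idx[tf]]):
        return []
    path = [tf]
    current = tf
    while dist_t[idx[current]] > 0:
        cands = sorted(
            v for v in network.graph[current]
            if np.isfinite(dist_t[idx[v]])
            and dist_t[idx[v]] == dist_t[idx[current]] - 1
        )
        current = cands[int(rng.integers(len(cands)))]
        path.append(current)
    return path


def _bin_fractions(
    mask: np.ndarray,
    L: np.ndarray,
    enzyme_mask: np.ndarray,
    min_length: int,
) -> Dict[int, Tuple[int, int, int]]:
    """Per path-length bin: (n_tfs, n_distinct_nodes, n_enzyme_nodes)."""
    out: Dict[int, Tuple[int, int, int]] = {}
    finite = np.isfinite(L)
    for length in sorted({int(x) for x in L[finite]}):
        if length < min_length:
            continue
        rows = finite & (L == length)
        union = np.logical_or.reduce(mask[rows], axis=0)
        n_nodes = int(union.sum())
        n_enz = int((union & enzyme_mask).sum())
        out[length] = (int(rows.sum()), n_nodes, n_enz)
    return out


def enzyme_path_enrichment(
    network: Network,
    tfs: GeneSet,
    targets: GeneSet,
    enzymes: GeneSet,
    n_resamples: int = 10_000,
    seed=None,
    *,
    all_shortest: bool = True,
    include_endpoints: bool = False,
    per_path: bool = False,
    store_paths: bool = True,
    max_paths_per_tf: int = 1000,
) -> TFPathResult:
    """Enrichment of enzymes among TF-to-nearest-target path nodes, by length.

    For each TF, the nodes lying on its shortest path(s) to its nearest
    target(s) are collected; per path-length bin L, f is the fraction of
    those (distinct) nodes that are enzymes.  The null redraws target sets
    of equal size uniformly and recomputes f; E = log2(f / mean null f)
    and the empirical p uses the add-one rule over draws in which bin L
    occurred.  Interior-only bins require L >= 2 (length-1 paths have no
    interior).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = targets.require_mapped()
    f_set = tfs.require_mapped()
    enz = enzymes.require_mapped()
    if not enz:
        raise ValueError("enzyme set is empty after mapping")
    if not t or not f_set:
        raise ValueError("tf and target sets must be nonempty after mapping")

    n = network.n_nodes
    tf_nodes = sorted(f_set)
    tf_idx = network.indices_of(tf_nodes)
    # per-TF single-source BFS distances; fixed across null draws
    D = np.vstack([network.distances_from([tf]) for tf in tf_nodes])
    dist_t = network.distances_from(t)
    enzyme_mask = np.zeros(n, dtype=bool)
    enzyme_mask[network.indices_of(enz)] = True

    min_length = 1 if include_endpoints else 2
    if per_path:
        obs_stats = _per_path_bin_fractions(
            network, tf_nodes, D, dist_t, enzyme_mask, include_endpoints, min_length
        )
    else:
        mask, L = _path_node_matrix(D, dist_t, tf_idx, include_endpoints)
        if not all_shortest:
            mask = _single_path_mask(network, tf_nodes, dist_t, rng, include_endpoints)
        obs_stats = {
            length: (ntf, nn, ne)
            for length, (ntf, nn, ne) in _bin_fractions(
                mask, L, enzyme_mask, min_length
            ).items()
        }
    if not obs_stats:
        raise ValueError(
            f"no TF-to-target shortest paths of length >= {min_length}"
        )

    # null: redraw target sets, recompute path-node fractions
    k = len(t)
    pool = np.arange(n)
    null_fracs: Dict[int, List[float]] = {length: [] for length in obs_stats}
    for _ in range(n_resamples):
        draw = rng.choice(pool, size=k, replace=False)
        d_null = network.distances_from([network.node_list[j] for j in draw])
        m, Ln = _path_node_matrix(D, d_null, tf_idx, include_endpoints)
        for length, (ntf, nn, ne) in _bin_fractions(
            m, Ln, enzyme_mask, min_length
        ).items():
            if length in null_fracs and nn > 0:
                null_fracs[length].append(ne / nn)

    rows = []
    for length, (ntf, nn, ne) in sorted(obs_stats.items()):
        f_obs = ne / nn if nn else float("nan")
        draws = null_fracs.get(length, [])
        n_eff = len(draws)
        if n_eff == 0:
            rows.append(
                dict(path_length=length, n_tfs=ntf, n_nodes=nn, n_enzyme=ne,
                     observed_fraction=f_obs, null_mean_fraction=float("nan"),
                     enrichment=float("nan"), p_value=float("nan"),
                     n_null_draws=0, flag="no_null_draws")
            )
            continue
        f_null = float(np.mean(draws))
        e = _log2_ratio(f_obs, f_null)
        ge = sum(1 for x in draws if x >= f_obs)
        le = sum(1 for x in draws if x <= f_obs)
        p = min(1.0, 2.0 * min((1 + ge) / (n_eff + 1), (1 + le) / (n_eff + 1)))
        flag = "zero_observed" if f_obs == 0 else ""
        rows.append(
            dict(path_length=length, n_tfs=ntf, n_nodes=nn, n_enzyme=ne,
                 observed_fraction=f_obs, null_mean_fraction=f_null,
                 enrichment=e, p_value=p, n_null_draws=n_eff, flag=flag)
        )
    bins = pd.DataFrame(rows)

    distances = {
        tf: (UNREACHABLE if np.isinf(dist_t[network.index[tf]]) else int(dist_t[network.index[tf]]))
        for tf in tf_nodes
    }
    paths: Dict[str, List[List[str]]] = {}
    if store_paths:
        for i, tf in enumerate(tf_nodes):
            if all_shortest:
                paths[tf] = _enumerate_paths(network, tf, D[i], dist_t, cap=max_paths_per_tf)
            else:
                p1 = _sample_one_path(network, tf, dist_t, rng)
                paths[tf] = [p1] if p1 else []

    return TFPathResult(
        tf_distances=distances,
        bins=bins,
        paths=paths,
        n_resamples=n_resamples,
        seed=seed,
        all_shortest=all_shortest,
        include_endpoints=include_endpoints,
        per_path=per_path,
    )


def _single_path_mask(
    network: Network,
    tf_nodes: List[str],
    dist_t: np.ndarray,
    rng: np.random.Generator,
    include_endpoints: bool,
) -> np.ndarray:
    n = network.n_nodes
    idx = network.index
    mask = np.zeros((len(tf_nodes), n), dtype=bool)
    for i, tf in enumerate(tf_nodes):
        path = _sample_one_path(network, tf, dist_t, rng)
        if not path:
            continue
        nodes = path if include_endpoints else path[1:-1]
        for u in nodes:
            mask[i, idx[u]] = True
    return mask


def _per_path_bin_fractions(
    network: Network,
    tf_nodes: List[str],
    D: np.ndarray,
    dist_t: np.ndarray,
    enzyme_mask: np.ndarray,
    include_endpoints: bool,
    min_length: int,
) -> Dict[int, Tuple[int, int, int]]:
    """Occurrence-weighted variant: each node weighted by the number of
    shortest TF->nearest-target paths through it (sigma products)."""
    sigma_t = _shortest_path_counts(network, dist_t)
    acc: Dict[int, List[Tuple[float, float]]] = {}
    idx = network.index
    for i, tf in enumerate(tf_nodes):
        L = dist_t[idx[tf]]
        if not np.isfinite(L):
            continue
        L = int(L)
        if L < min_length:
            continue
        dist_tf = D[i]
        sigma_tf = _shortest_path_counts_single(network, dist_tf)
        on = np.isfinite(dist_tf) & np.isfinite(dist_t) & (dist_tf + dist_t == L)
        if not include_endpoints:
            on &= dist_t > 0
            on[idx[tf]] = False
        w = sigma_tf * sigma_t
        tot = float(w[on].sum())
        enzw = float(w[on & enzyme_mask].sum())
        acc.setdefault(L, []).append((tot, enzw))
    result: Dict[int, Tuple[int, int, int]] = {}
    for L, pairs in acc.items():
        tot = sum(p[0] for p in pairs)
        enz = sum(p[1] for p in pairs)
        # report weights rounded into count slots for a uniform interface
        result[L] = (len(pairs), int(round(tot)), int(round(enz)))
    return result


def _shortest_path_counts(network: Network, dist: np.ndarray) -> np.ndarray:
    """sigma[u]: number of shortest paths from u to the (multi-)source set
    that defined ``dist`` (sources have sigma 1)."""
    csr = network.csr
    indptr, indices = csr.indptr, csr.indices
    n = dist.size
    sigma = np.zeros(n)
    order = np.argsort(dist, kind="stable")
    for u in order:
        du = dist[u]
        if not np.isfinite(du):
            break
        if du == 0:
            sigma[u] = 1.0
            continue
        s = 0.0
        for v in indices[indptr[u] : indptr[u + 1]]:
            if dist[v] == du - 1:
                s += sigma[v]
        sigma[u] = s
    return sigma


def _shortest_path_counts_single(network: Network, dist: np.ndarray) -> np.ndarray:
    return _shortest_path_counts(network, dist)
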