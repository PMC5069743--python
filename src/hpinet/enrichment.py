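"""Resampling enrichment statistics.

The central quantity of the package: for nodes grouped by some
characteristic ``d`` (here, shortest distance to the nearest
pathogen-targeted protein), the log2 enrichment of a feature set in each
group against a uniform resampling null,

    E_i(d) = log2[ f_i(d) / f_{i,r}(d) ],

where ``f_i(d)`` is the observed fraction of group-``d`` nodes carrying
feature ``i`` and ``f_{i,r}(d)`` the mean fraction over feature-sized node
sets drawn uniformly without replacement from the network (10,000 draws by
default).  Empirical p-values use the add-one rule
``(1 + #draws at least as extreme) / (n_draws + 1)`` so they are never 0,
and are reported two-sided as ``min(1, 2 * min(upper, lower))``.

The same machinery drives enrichment across arbitrary groupings such as
broad functional (COG-style) classes, and a Fisher exact test covers
simple two-set overlaps (e.g. targeted vs essential genes).

Null-model choices (both available):

* default: resample the FEATURE set, holding the reference distance
  profile fixed — cheap and well-conditioned;
* ``resample_reference=True``: resample the reference set and recompute
  the distance profile on every draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .net_core import GeneSet, Network

logger = logging.getLogger("hpinet")

NEG_INF = float("-inf")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _log2_ratio(obs_frac: float, null_frac: float) -> float:
    """log2(obs/null) with signed-infinity sentinels for zero fractions.

    A zero observed fraction dominates (depletion sentinel -inf), even when
    the null fraction is also zero; a zero null under a positive observation
    gives +inf.  Raw counts always accompany the sentinel in output rows.
    """
    if obs_frac == 0.0:
        return NEG_INF
    if null_frac == 0.0:
        return float("inf")
    return math.log2(obs_frac / null_frac)


def _two_sided_empirical_p(null_counts: np.ndarray, observed: int, n: int) -> float:
    """Add-one empirical p, two-sided: 2 * min(upper tail, lower tail), capped."""
    ge = int(np.count_nonzero(null_counts >= observed))
    le = int(np.count_nonzero(null_counts <= observed))
    p_hi = (1 + ge) / (n + 1)
    p_lo = (1 + le) / (n + 1)
    return min(1.0, 2.0 * min(p_hi, p_lo))


# ---------------------------------------------------------------------------
# Distance-bin enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentBin:
    distance: int
    bin_size: int
    observed_count: int
    observed_fraction: float
    null_mean_fraction: float
    enrichment: float
    p_value: float
    flag: str = ""


@dataclass
class EnrichmentProfile:
    """Per-distance-bin enrichment of a feature set around a reference set."""

    reference_name: str
    feature_name: str
    bins: List[EnrichmentBin]
    n_resamples: int
    seed: object
    resample_reference: bool = False
    exclude_reference: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "distance": b.distance,
                    "bin_size": b.bin_size,
                    "observed_count": b.observed_count,
                    "observed_fraction": b.observed_fraction,
                    "null_mean_fraction": b.null_mean_fraction,
                    "enrichment": b.enrichment,
                    "p_value": b.p_value,
                    "flag": b.flag,
                }
                for b in self.bins
            ]
        )
        df.attrs["reference"] = self.reference_name
        df.attrs["feature"] = self.feature_name
        df.attrs["n_resamples"] = self.n_resamples
        return df

    def enrichment_at(self, distance: int) -> float:
        for b in self.bins:
            if b.distance == distance:
                return b.enrichment
        raise KeyError(distance)


def _sample_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, k: int, n_draws: int
) -> np.ndarray:
    """(n_draws, k) matrix of uniform draws without replacement from pool."""
    out = np.empty((n_draws, k), dtype=np.int64)
    for i in range(n_draws):
        out[i] = rng.choice(pool, size=k, replace=False)
    return out


def distance_bin_enrichment(
    network: Network,
    reference: GeneSet,
    feature: GeneSet,
    n_resamples: int = 10_000,
    seed=None,
    *,
    resample_reference: bool = False,
    exclude_reference: bool = False,
) -> EnrichmentProfile:
    """Log2 enrichment of ``feature`` in each distance bin around ``reference``.

    Bins come from a multi-source BFS on the reference set; unreachable
    nodes are excluded.  The null draws feature-sized node sets uniformly
    without replacement from all network nodes (optionally excluding the
    reference set) and keeps the distance profile fixed; with
    ``resample_reference=True`` it instead redraws reference-sized sets and
    recomputes distances on every draw.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    feat = feature.require_mapped()
    if not feat:
        raise ValueError(f"feature gene set {feature.name!r} is empty after mapping")
    rng = _rng(seed)

    dist = network.distances_from(reference.require_mapped())
    nodes = network.node_list
    n = len(nodes)
    reachable = np.isfinite(dist)
    dist_int = np.where(reachable, dist, -1).astype(np.int64)
    max_d = int(dist_int.max())
    n_bins = max_d + 1
    bin_sizes = np.bincount(dist_int[reachable], minlength=n_bins)

    feat_idx = network.indices_of(feat)
    feat_mask = np.zeros(n, dtype=bool)
    feat_mask[feat_idx] = True
    obs_counts = np.bincount(dist_int[feat_mask & reachable], minlength=n_bins)

    k = len(feat)
    if resample_reference:
        null_counts = _null_counts_resampled_reference(
            network, reference, feat_mask, n_bins, n_resamples, rng
        )
    else:
        pool = np.arange(n)
        if exclude_reference:
            ref_idx = network.indices_of(reference.require_mapped())
            keep = np.ones(n, dtype=bool)
            keep[ref_idx] = False
            pool = pool[keep]
        if k > pool.size:
            raise ValueError("feature larger than the null sampling pool")
        draws = _sample_without_replacement(rng, pool, k, n_resamples)
        d_of_draws = dist_int[draws].ravel()  # -1 => unreachable
        rows = np.repeat(np.arange(n_resamples), k)
        valid = d_of_draws >= 0
        flat = rows[valid] * n_bins + d_of_draws[valid]
        null_counts = np.bincount(flat, minlength=n_resamples * n_bins).reshape(
            n_resamples, n_bins
        )

    bins: List[EnrichmentBin] = []
    for d in range(n_bins):
        size = int(bin_sizes[d])
        obs = int(obs_counts[d])
        if size == 0:
            bins.append(
                EnrichmentBin(d, 0, 0, float("nan"), float("nan"), float("nan"), float("nan"), flag="empty_bin")
            )
            continue
        f_obs = obs / size
        f_null = float(null_counts[:, d].mean()) / size
        e = _log2_ratio(f_obs, f_null)
        p = _two_sided_empirical_p(null_counts[:, d], obs, n_resamples)
        flag = ""
        if f_obs == 0.0:
            flag = "zero_observed"
        elif f_null == 0.0:
            flag = "zero_null"
        bins.append(EnrichmentBin(d, size, obs, f_obs, f_null, e, p, flag))

    return EnrichmentProfile(
        reference_name=reference.name,
        feature_name=feature.name,
        bins=bins,
        n_resamples=n_resamples,
        seed=seed,
        resample_reference=resample_reference,
        exclude_reference=exclude_reference,
    )


def _null_counts_resampled_reference(
    network: Network,
    reference: GeneSet,
    feat_mask: np.ndarray,
    n_bins: int,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null variant: redraw the reference set and recompute distances per draw.

    Observed bins keep their labels d = 0..max_d; draws whose profile
    reaches farther than the observed maximum accumulate into the last bin's
    overflow (counted at their own d when d < n_bins, ignored above, which
    is logged).
    """
    n = feat_mask.size
    k_ref = len(reference.require_mapped())
    counts = np.zeros((n_resamples, n_bins), dtype=np.int64)
    feat_idx = np.flatnonzero(feat_mask)
    overflow = 0
    for i in range(n_resamples):
        ref_draw_idx = rng.choice(n, size=k_ref, replace=False)
        ref_nodes = [network.node_list[j] for j in ref_draw_idx]
        d = network.distances_from(ref_nodes)
        d_feat = d[feat_idx]
        d_feat = d_feat[np.isfinite(d_feat)].astype(np.int64)
        over = d_feat >= n_bins
        overflow += int(over.sum())
        d_feat = d_feat[~over]
        counts[i] += np.bincount(d_feat, minlength=n_bins)
    if overflow:
        logger.info(
            "reference-resampling null: %d feature placements fell beyond the "
            "observed maximum distance and were ignored",
            overflow,
        )
    return counts


# ---------------------------------------------------------------------------
# Class enrichment
# ---------------------------------------------------------------------------


def class_enrichment(
    classes: Sequence[GeneSet],
    query: GeneSet,
    universe: Iterable[str],
    n_resamples: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Enrichment of a query set across functional classes vs uniform draws.

    For each class: observed count |query ∩ class|, null mean count from
    query-sized uniform draws from the universe, E = log2(observed fraction
    / null fraction), add-one two-sided empirical p.
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("empty universe")
    rng = _rng(seed)
    uindex = {u: i for i, u in enumerate(universe)}
    nu = len(universe)
    q = [m for m in query.require_mapped() if m in uindex]
    k = len(q)
    if k == 0:
        raise ValueError(f"query {query.name!r} has no members in the universe")

    masks = np.zeros((len(classes), nu), dtype=bool)
    for ci, cl in enumerate(classes):
        members = cl.members if cl.members is not None else cl.raw_members
        for m in members:
            j = uindex.get(m)
            if j is not None:
                masks[ci, j] = True
    class_sizes = masks.sum(axis=1)

    obs = np.zeros(len(classes), dtype=np.int64)
    qidx = np.fromiter((uindex[m] for m in q), dtype=np.int64)
    for ci in range(len(classes)):
        obs[ci] = int(masks[ci, qidx].sum())

    pool = np.arange(nu)
    null = np.zeros((n_resamples, len(classes)), dtype=np.int64)
    for i in range(n_resamples):
        draw = rng.choice(pool, size=k, replace=False)
        null[i] = masks[:, draw].sum(axis=1)

    rows = []
    for ci, cl in enumerate(classes):
        size = int(class_sizes[ci])
        if size == 0:
            rows.append(
                dict(class_name=cl.name, class_size=0, observed=0,
                     observed_fraction=float("nan"), null_mean_fraction=float("nan"),
                     enrichment=float("nan"), p_value=float("nan"), flag="empty_class")
            )
            continue
        f_obs = obs[ci] / size
        f_null = float(null[:, ci].mean()) / size
        rows.append(
            dict(
                class_name=cl.name,
                class_size=size,
                observed=int(obs[ci]),
                observed_fraction=f_obs,
                null_mean_fraction=f_null,
                enrichment=_log2_ratio(f_obs, f_null),
                p_value=_two_sided_empirical_p(null[:, ci], int(obs[ci]), n_resamples),
                flag="" if f_obs > 0 else "zero_observed",
            )
        )
    df = pd.DataFrame(rows)
    df.attrs["query"] = query.name
    df.attrs["n_resamples"] = n_resamples
    return df


# ---------------------------------------------------------------------------
# Fisher exact overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapTest:
    """One-sided (enrichment) Fisher exact test of two sets in a universe."""

    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    odds_ratio: float
    p_value: float
    continuity_corrected: bool = False


def fisher_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """Fisher exact (one-sided, enrichment) test of overlap between two sets.

    The odds ratio gets a 0.5 continuity correction only when a cell of the
    2x2 table is zero (flagged via ``continuity_corrected``).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if not (set(set_a) <= universe and set(set_b) <= universe):
        raise ValueError("both sets must be subsets of the universe")
    n = len(universe)
    ov = len(a & b)
    table = np.array(
        [[ov, len(a) - ov], [len(b) - ov, n - len(a) - len(b) + ov]], dtype=np.int64
    )
    _, p = stats.fisher_exact(table, alternative="greater")
    corrected = bool((table == 0).any())
    t = table.astype(float) + (0.5 if corrected else 0.0)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapTest(
        universe_size=n,
        size_a=len(a),
        size_b=len(b),
        overlap=ov,
        odds_ratio=float(odds),
        p_value=float(p),
        continuity_corrected=corrected,
    )
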