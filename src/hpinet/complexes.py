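"""Protein-complex participation coefficient.

For a protein i with interaction partners annotated to complexes, let
n_i,s be the number of partners of i belonging to complex s (a partner in
k complexes contributes to each of those k counts) and T_i = sum_s n_i,s.
The participation coefficient is the concentration index

    P_i = sum_s (n_i,s / T_i)^2,

so P_i -> 1 when i interacts predominantly with partners of one complex
and P_i -> 1/N (towards 0 for a large catalog of N complexes) when its
partners spread evenly over many complexes.  Nodes with no
complex-annotated partner are reported as undefined and excluded from the
distribution summaries.

Distributions of P are compared between targeted proteins, their
first-step neighbours, and the remaining proteins (histograms plus
rank-sum tests).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .net_core import NetworkParseError, Network, Source, _iter_lines

logger = logging.getLogger("hpinet")


@dataclass(frozen=True)
class ComplexCatalog:
    """Named protein complexes (possibly overlapping member sets)."""

    complexes: Tuple[Tuple[str, frozenset], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.complexes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate complex names in catalog")
        for name, members in self.complexes:
            if not members:
                raise ValueError(f"complex {name!r} has no members")

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    def membership_index(self) -> Dict[str, List[int]]:
        """node -> indices of the complexes it belongs to."""
        out: Dict[str, List[int]] = {}
        for ci, (_, members) in enumerate(self.complexes):
            for m in members:
                out.setdefault(m, []).append(ci)
        return out


def load_complexes(source: Source) -> ComplexCatalog:
    """Read a complex catalog from GMT lines (name, description, members...)."""
    entries: List[Tuple[str, frozenset]] = []
    seen = set()
    for lineno, raw in _iter_lines(source):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkParseError(
                f"complex line {lineno}: expected >= 3 tab-separated fields"
            )
        name = fields[0].strip()
        if name in seen:
            raise ValueError(f"duplicate complex name {name!r} (line {lineno})")
        seen.add(name)
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        if not members:
            raise NetworkParseError(f"complex line {lineno}: no members")
        entries.append((name, members))
    if not entries:
        raise NetworkParseError("empty complex catalog")
    return ComplexCatalog(tuple(entries))


@dataclass
class ParticipationResult:
    """Per-node participation coefficients plus the undefined node set."""

    values: Dict[str, float]
    partner_link_totals: Dict[str, int]
    undefined: frozenset
    n_complexes: int
    exponent: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.values.items()), columns=["node", "participation"]
        )


def participation(
    network: Network,
    catalog: ComplexCatalog,
    *,
    exponent: float = 2.0,
    partner_multiplicity: str = "per_complex",
) -> ParticipationResult:
    """Complex participation coefficient for every node with annotated partners.

    ``partner_multiplicity`` controls how a partner belonging to k
    complexes is counted: ``"per_complex"`` (default) contributes 1 to each
    of its k complex counts; ``"split"`` contributes 1/k to each, so every
    partner carries unit total weight.
    """
    if partner_multiplicity not in ("per_complex", "split"):
        raise ValueError("partner_multiplicity must be 'per_complex' or 'split'")
    membership = catalog.membership_index()
    values: Dict[str, float] = {}
    totals: Dict[str, int] = {}
    undefined = set()
    for node in network.graph:
        counts: Dict[int, float] = {}
        n_links = 0
        for partner in network.graph[node]:
            cs = membership.get(partner)
            if not cs:
                continue
            n_links += len(cs) if partner_multiplicity == "per_complex" else 1
            w = 1.0 if partner_multiplicity == "per_complex" else 1.0 / len(cs)
            for ci in cs:
                counts[ci] = counts.get(ci, 0.0) + w
        total = sum(counts.values())
        if total == 0:
            undefined.add(node)
            continue
        values[node] = float(sum((c / total) ** exponent for c in counts.values()))
        totals[node] = n_links
    return ParticipationResult(
        values=values,
        partner_link_totals=totals,
        undefined=frozenset(undefined),
        n_complexes=catalog.n_complexes,
        exponent=exponent,
    )


def participation_by_group(
    result: ParticipationResult,
    groups: Mapping[str, Iterable[str]],
    *,
    n_bins: int = 20,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram/summary of P per group plus pairwise rank-sum comparisons.

    ``groups`` maps a label (e.g. targets / neighbors / remaining) to node
    collections; only nodes with a defined P contribute.  Returns
    (summary table with per-bin histogram counts, pairwise comparison
    table).  Groups with fewer than two defined nodes are skipped from the
    comparisons with a warning.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    summaries = []
    samples: Dict[str, np.ndarray] = {}
    for label, nodes in groups.items():
        vals = np.array(
            sorted(result.values[n] for n in nodes if n in result.values)
        )
        samples[label] = vals
        hist, _ = np.histogram(vals, bins=edges) if vals.size else (np.zeros(n_bins, int), edges)
        for b in range(n_bins):
            summaries.append(
                dict(
                    group=label,
                    bin_low=edges[b],
                    bin_high=edges[b + 1],
                    count=int(hist[b]),
                    n_defined=int(vals.size),
                    mean=float(vals.mean()) if vals.size else float("nan"),
                    median=float(np.median(vals)) if vals.size else float("nan"),
                )
            )
    comparisons = []
    labels = list(groups)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = samples[labels[i]], samples[labels[j]]
            if a.size < 2 or b.size < 2:
                warnings.warn(
                    f"participation comparison {labels[i]} vs {labels[j]} skipped: "
                    "fewer than 2 defined nodes in a group",
                    stacklevel=2,
                )
                continue
            stat, p = stats.ranksums(a, b)
            comparisons.append(
                dict(
                    group_a=labels[i],
                    group_b=labels[j],
                    n_a=int(a.size),
                    n_b=int(b.size),
                    ranksum_statistic=float(stat),
                    p_value=float(p),
                )
            )
    return pd.DataFrame(summaries), pd.DataFrame(comparisons)
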