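# Methods

## Data model

The host interactome is an undirected simple graph; identifiers are
opaque, case-sensitive strings and no identifier translation is attempted.
Edge lists are normalised at load: self-loops and duplicate edges are
dropped with logged counts.  Gene sets are read from GMT lines (name,
role, members…) and carry both the raw member list and the intersection
with a given network's nodes, so nothing is discarded silently — a set's
(raw, mapped) sizes are always recoverable.  Nodes with no path to a
reference set receive an explicit `UNREACHABLE` sentinel, never a large
integer; all distance-binned statistics exclude them.

## Distance-bin enrichment

Nodes are partitioned by shortest-path distance *d* to the nearest member
of a reference set (one multi-source BFS).  For a feature set of size *k*:

    f(d)   = |feature ∩ bin_d| / |bin_d|
    f_r(d) = mean over resamples of |random_k ∩ bin_d| / |bin_d|
    E(d)   = log2( f(d) / f_r(d) )

The null draws *k*-node sets uniformly without replacement from **all**
network nodes, holding the reference distance profile fixed.  Two
documented alternatives sit behind flags: excluding the reference set from
the null pool (`exclude_reference`), and resampling the *reference* set
with full distance recomputation per draw (`resample_reference`).  The
feature-resampling default was chosen because it generalises to arbitrary
feature sets, is far cheaper (no per-draw BFS), and is better conditioned:
its per-bin null is exactly hypergeometric, with mean *k/|V|* per bin
regardless of topology.

Empirical p-values use the add-one rule `(1 + r)/(n + 1)` per tail, so
they are never 0 and never smaller than `1/(n+1)`; two-sided values are
`min(1, 2·min(upper, lower))`.  A zero observed fraction is reported as a
`-inf` sentinel together with its raw counts — no pseudocount is applied
by default (the exponent of a pseudocount would dominate small bins).  The
default resample count is 10,000.

Class enrichment reuses the same machinery with functional classes as the
"bins" (observed and null counts per class over a common universe), and
two-set overlap is tested with the one-sided Fisher exact test; its odds
ratio receives a 0.5 continuity correction only when a table cell is zero,
and the result is flagged when that happens.

## LCC permutation test

For a node set (or a union such as targets ∪ required-genes-interacting-
with-targets, built by `augment_with_interacting`), the observed statistic
is the node count of the largest connected component of the induced
subgraph.  The null draws equal-sized sets uniformly from all network
nodes — deliberately without degree matching, since the observed sets are
compared against plain random protein samples; a degree-quantile-binned
null is available behind a flag for sensitivity analysis.  The p-value is
one-sided (large components).

Because LCC sizes are small integers, null draws tie with the observation
frequently and the add-one p-value is *super-uniform* under the null
(conservative).  `lcc_test` therefore also reports a randomised
tie-broken p-value, `(#{null > obs} + U·(1 + #{null = obs}))/(n + 1)`
with U ~ Uniform(0,1), which is exactly uniform when the observation is
itself a null draw; calibration checks use that variant, while reported
significance uses the conservative add-one value.

## Centrality and robustness

Betweenness is exact (Brandes accumulation via networkx), non-normalised,
over unordered pairs; ordered-pair counting would only double every value
and cannot change top-quantile membership.  The bottleneck set is the top
`ceil(fraction·|V|)` nodes (default fraction 0.20), with ties at the
threshold broken by lexicographic node identifier (warned).  Bottleneck
enrichment of a gene set is `log2(observed bottleneck fraction /
network bottleneck fraction)` plus a Fisher exact p.

Robustness curves delete a node set in order of decreasing full-network
degree (secondary sort key: node identifier, making curves
bit-reproducible) and record the connected-component count of the
remaining graph after every step.  Comparison sets of equal size are taken
from the first-step neighbourhood Γ(targets) and from the remaining nodes;
the default picks each pool's highest-degree members (deterministic, since
the deletion order is degree-driven anyway), a seeded uniform draw is the
flagged alternative.  Nodes isolated by deletions count as components by
default (flag to exclude).  When a pool is smaller than the target count
the curve is truncated with a warning.

## Complex participation

For protein *i* with interaction partners annotated to complexes, with
*n_i,s* partners in complex *s* and *T_i = Σ_s n_i,s*:

    P_i = Σ_s ( n_i,s / T_i )²

This squared-share (concentration) form satisfies both stated limits:
P = 1 when all annotated partners share one complex, P = 1/N for an even
spread over N complexes.  The linear form `Σ_s n_i,s/T_i` is identically 1
and cannot discriminate, so the exponent is exposed as a config option
with default 2.  Partners belonging to *k* complexes contribute 1 to each
of the *k* counts by default; a `split` mode gives each partner unit total
weight (1/k per complex) instead.  Partners in no complex are excluded
from the denominator — with them included, the P = 1 limit would fail for
any protein with a single unannotated partner.  Nodes with no annotated
partner at all are reported "undefined" and excluded from the group
histograms (20 equal bins on [0,1]) and rank-sum comparisons.

## TF → target shortest paths

Per transcription factor, the distance to the nearest target comes from
one multi-source BFS.  The path-length comparison reports a two-sample
Student's t and a rank-sum statistic of observed distances against pooled
distances under target-sized uniform resamples, plus a one-sided
(shorter) add-one empirical p of the observed mean.

For enzyme enrichment, a node *u* lies on a shortest path from TF to a
nearest target iff `d(TF,u) + d(u,targets) = d(TF,targets)`; this
identifies the union of all shortest-path nodes without enumerating paths.
Per path-length bin L, *f* is the enzyme fraction among the distinct
interior nodes (endpoints are TFs and targets, whose enrichment is
assessed elsewhere; an endpoint-inclusive mode is flagged).  The null
redraws target sets of equal size and recomputes *f* conditioned on the
same bin L; E and p are computed per bin over the draws in which that bin
occurred (the count of such draws is reported).  Per-TF BFS distances are
computed once and reused across all null draws.  Flags select a single
sampled shortest path instead of the union, and occurrence weighting by
the number of shortest paths through each node (σ-product counting)
instead of distinct-node counting.  Note that on very small graphs the
length-conditioned null can be degenerate: if the only target placement
producing a bin of length L is the observed one, E is exactly 0 there.

## Synthetic scenarios

The generator emulates the statistical structure the analyses assume, with
every planted membership recorded in a ground-truth manifest:

| parameter | default | rationale |
|---|---|---|
| n_nodes | 2,000 | desk-scale stand-in for interactomes of 2.7k–12.8k proteins |
| background | Erdős–Rényi, p = 0.005 | mean degree 10, matching the 8–11 of the real networks |
| target module | 50 nodes, intra-edge prob 0.10 | ~2.5% of nodes, the scale of a per-pathogen target set; random spanning tree guarantees a connected module |
| required / essential | 200 / 300 | required ≈ 4× targets; essential ≈ 15% of nodes, the E. coli share scaled down |
| proximity decay λ | 1.5 | strong but not degenerate clustering; sampling weight ∝ exp(−λ·d) |
| complexes | 100 disjoint cliques of 3–8 | complex-to-protein ratio of the curated catalogs, scaled |
| TFs / enzymes | 150 / 90 | the TF and methylation/acetylation-enzyme shares of the human proteome, scaled |
| enzyme_on_path_fraction | 0.7 | most, not all, enzymes mediate TF→target paths |
| functional classes | 8, uniform partition | COG-style broad categories |

Generation order: background graph → target module (spanning tree + extra
intra-module edges) → required/essential sampled without replacement with
weight exp(−λ·d) against the finished module (exact weighted sampling via
Gumbel keys; λ = 0 reduces to uniform over reachable nodes) → disjoint
complex cliques (which add edges, so distances are recomputed) → TFs →
enzymes.  TFs are drawn from the second-step shell (d = 2), spilling to
d = 3, 4, … only if the shell is too small; this satisfies the d ≥ 2
placement contract while emulating the observed enrichment of TFs in
second-step neighbourhoods.  On-path enzymes are drawn from the union of
TF→nearest-target shortest-path interiors.  Isolated background nodes are
attached by one random edge, since interactome edge lists contain only
interacting proteins (and the written formats round-trip exactly).
A single `numpy` Generator seeded by one integer drives everything;
identical seed and parameters give byte-identical files.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real interactomes (a configuration-model background is
provided for sensitivity checks but is not the default), overlapping
complexes, correlated annotation noise, and any special bridging role of
target neighbours.  Consequences worth knowing: at the default density an
ER graph is highly robust, so deletion curves for 50-node sets typically
end with the graph still connected (the neighbourhood-dominance comparison
then holds as a tie); and because TFs are drawn from the d ≥ 2 shell their
paths to the planted module are *longer* than to random target sets — the
"shorter than random" signal of real TF sets only appears in scenarios
where the d = 2 shell lies closer than random expectation (e.g. sparser
backgrounds), which is how the recovery test exercises it.  Passing tests
on these scenarios demonstrate correctness and calibration of the
statistics, not biological conclusions.

## Pipeline determinism and sizes

Every stochastic stage derives its own substream from
`SeedSequence([master_seed, crc32(stage_name)])`, so one config seed fully
determines every output and stage reordering cannot change results.
Outputs are plain TSV with `%.10g` floats plus one JSON manifest (config
echo, config hash over the analytic fields, mapped set sizes); identical
config + seed gives byte-identical tables.  The test suite runs the
heavier calibrations at reduced but statistically adequate sizes — e.g.
1,000 null-feature replicates at 400 resamples each for enrichment
calibration, 100 scenario seeds at 10,000 resamples for planted-module
recovery, 500 replicates at 999 resamples for p-value uniformity — chosen
so Monte-Carlo standard errors sit well inside the asserted tolerances.

## Known limitations

* Betweenness is exact only; no sampled approximation is provided, so the
  centrality stage dominates runtime on larger networks (it is
  O(|V|·|E|)).
* Empirical p-values are bounded below by 1/(n_resamples+1); reported
  "p = 1e-4" at 10,000 resamples means "none of 10,000 draws reached the
  observation".
* The enzyme-path null conditions on path-length bins; bins that occur in
  few null draws carry wide uncertainty (the per-bin draw count is
  reported for exactly this reason).
* No multiple-testing correction is applied across bins or classes.
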