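# hpinet

Topology analysis of how pathogen-targeted, infection-required, and
essential proteins are arranged in host protein-interaction networks.

When a virus or bacteriophage infects a cell, the host proteins it binds
directly (*targets*), the host genes it needs for infection (*required*),
and the genes the cell itself cannot live without (*essential*) are not
scattered randomly through the host interactome.  `hpinet` quantifies
their arrangement with a set of resampling-based network statistics:

* **Distance-bin enrichment.**  Nodes are binned by shortest-path distance
  *d* to the nearest target.  For a feature set *i*, the observed fraction
  *f_i(d)* per bin is compared to the mean fraction *f_i,r(d)* over
  equal-sized node sets drawn uniformly from the network, giving
  *E_i(d) = log₂[f_i(d)/f_i,r(d)]* with an add-one empirical p-value.
* **Largest-connected-component (LCC) permutation tests.**  Does a gene
  set (or a union such as targets ∪ interacting required genes) induce a
  larger connected subgraph than equal-sized random sets?
* **Fisher exact overlap** between gene sets (e.g. targets vs essential).
* **Bottleneck centrality.**  Betweenness
  *c_B(v) = Σ_{s≠t≠v} σ_st(v)/σ_st*; the top 20% most central nodes form
  the bottleneck set, and each gene set is scored for enrichment in it.
* **Deletion robustness.**  Targets (and equal-sized sets of their
  neighbours and of remaining nodes) are deleted in order of decreasing
  degree, recording the number of connected components after each step.
* **Complex participation.**  Per protein,
  *P_i = Σ_s (n_i,s / Σ_s n_i,s)²*, where *n_i,s* counts interaction
  partners in complex *s*: P → 1 for proteins whose partners concentrate
  in one complex, P → 1/N for partners spread over many.
* **TF path mediators.**  Shortest paths from transcription factors to
  their nearest targets are compared against resampled target sets, and
  the path interiors are scored for enrichment of methylation/acetylation
  enzymes, per path-length bin.

A fully seeded synthetic-data generator plants all of this structure
(clustered target module, proximity-decayed required/essential sets,
complexes, TFs on the second-step shell, path-planted enzymes) in a sparse
background graph, so the entire pipeline runs and is testable with no
downloads.

## Worked example

Generate a 1,000-node scenario with a planted 40-protein target module and
ask whether the targets form an unexpectedly large connected component:

```bash
hpinet simulate --seed 7 --n-nodes 1000 --edge-prob 0.01 \
    --target-module-size 40 --required-size 100 --essential-size 120 \
    --n-complexes 40 --tf-size 60 --enzyme-size 40 --out-dir demo
hpinet lcc --network demo/network.tsv --gene-sets demo/gene_sets.gmt \
    --set targets --resamples 10000 --seed 1
```

```
set_name  mapped_size  lcc_size  lcc_fraction  null_mean  null_sd      null_max  p_value
targets   40           40        1             4.1052     1.689620798  16        9.9990001e-05
```

All 40 targets form one connected component (lcc_fraction 1.0), while
random 40-node sets average an LCC of ~4 nodes and never exceed 16; the
one-sided add-one empirical p is 1/10001, the smallest value 10,000
resamples can resolve.  Are required genes concentrated near the targets?

```bash
hpinet dist-enrich --network demo/network.tsv --gene-sets demo/gene_sets.gmt \
    --feature required --resamples 10000 --seed 1
```

```
distance  bin_size  observed_count  observed_fraction  null_mean_fraction  enrichment     p_value         flag
0         40        18              0.45               0.10035             2.164884385    0.000199980002
1         337       55              0.1632047478       0.100127003         0.7048519242   0.000199980002
2         607       27              0.04448105437      0.09988830313       -1.167124763   0.000199980002
3         16        0               0                  0.1006875           -inf           0.3599640036    zero_observed
```

Required genes are ~4.5× over-represented among the targets themselves
(E(0) ≈ 2.16) and ~1.6× in the first-step neighbourhood (E(1) ≈ 0.70),
and depleted farther away — the planted distance decay (λ = 1.5) is
recovered.  A zero observed fraction is reported as a `-inf` sentinel with
its raw counts rather than a pseudocount.

The same operations are available as library functions
(`hpinet.lcc_test`, `hpinet.distance_bin_enrichment`,
`hpinet.betweenness`, `hpinet.participation`,
`hpinet.enzyme_path_enrichment`, ...), and `hpinet run` executes the full
stage sequence into one tidy table per analysis plus a JSON manifest.

## Layout

```
src/hpinet/
  net_core.py      graph model, edge-list/GMT I/O, BFS distances, components
  synthetic.py     seeded scenario generator with recorded ground truth
  enrichment.py    distance-bin/class enrichment, Fisher exact overlap
  connectivity.py  LCC permutation tests, interacting-set augmentation
  centrality.py    betweenness, bottleneck sets, deletion robustness
  complexes.py     complex catalogs and participation coefficients
  tf_paths.py      TF-to-target shortest-path statistics
  pipeline.py      full-analysis orchestration (seeded per-stage substreams)
  cli.py           `hpinet` command-line interface
```

See `docs/methods.md` for the statistical model, parameter defaults, and
the design decisions behind the null models.
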