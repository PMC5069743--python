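"""Full-analysis orchestration.

Runs the complete topology analysis in the order the individual results
build on each other: distance-bin enrichment of targets/required/essential
around the targets; LCC permutation tests for the targets and their
augmented unions; Fisher overlap of targets with essential genes; class
enrichment; bottleneck-centrality enrichment; degree-ordered deletion
robustness; complex-participation distributions; and the TF-path
analyses.  Every stage draws its randomness from a substream derived from
(master seed, stage name), so one seed fully determines every output and
reordering stages cannot change results.  All outputs are plain delimited
text plus one machine-readable JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .centrality import betweenness, bottleneck_enrichment, robustness_analysis
from .complexes import ComplexCatalog, load_complexes, participation, participation_by_group
from .connectivity import augment_with_interacting, lcc_test
from .enrichment import class_enrichment, distance_bin_enrichment, fisher_overlap
from .net_core import GeneSet, Network, load_gene_sets, load_network, neighbors_of_set
from .tf_paths import enzyme_path_enrichment, path_length_comparison, tf_target_distances

logger = logging.getLogger("hpinet")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    File paths are checked before any computation starts; the config is
    echoed verbatim into the run manifest together with its hash.
    """

    network_path: str
    gene_sets_path: str
    output_dir: str
    complexes_path: Optional[str] = None
    n_resamples: int = 10_000
    seed: int = 0
    bottleneck_fraction: float = 0.20
    exclude_reference: bool = False
    resample_reference: bool = False
    degree_binned_null: bool = False
    robustness_comparison: str = "top_degree"
    include_isolated: bool = True
    participation_exponent: float = 2.0
    partner_multiplicity: str = "per_complex"
    all_shortest: bool = True
    include_endpoints: bool = False

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Stage-local substream: derived from (master seed, stage name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _role_set(gene_sets: List[GeneSet], role: str) -> GeneSet:
    matches = [g for g in gene_sets if g.role == role]
    if not matches:
        raise ValueError(f"no gene set with role {role!r} in input")
    if len(matches) > 1:
        merged = frozenset().union(*(g.raw_members for g in matches))
        return GeneSet("+".join(g.name for g in matches), role, merged)
    return matches[0]


def run_full_analysis(config: RunConfig) -> Dict[str, Path]:
    """Execute every analysis stage and write one tidy table per stage.

    Returns a mapping of stage name to output path.  Any stage failure
    aborts with :class:`PipelineError` naming the stage; the run manifest
    is written last, so its absence marks a partial (incomplete) output
    directory.
    """
    # pre-flight: every referenced file must exist before any computation
    for label, p in (
        ("network", config.network_path),
        ("gene sets", config.gene_sets_path),
        ("complexes", config.complexes_path),
    ):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    network = load_network(Path(config.network_path))
    gene_sets = [g.map_to(network) for g in load_gene_sets(Path(config.gene_sets_path))]
    catalog = (
        load_complexes(Path(config.complexes_path)) if config.complexes_path else None
    )
    return run_stages(network, gene_sets, catalog, config, out)


def run_stages(
    network: Network,
    gene_sets: List[GeneSet],
    catalog: Optional[ComplexCatalog],
    config: RunConfig,
    out: Path,
) -> Dict[str, Path]:
    targets = _role_set(gene_sets, "targets")
    required = _role_set(gene_sets, "required")
    essential = _role_set(gene_sets, "essential")
    tfs = _role_set(gene_sets, "tf")
    enzymes = _role_set(gene_sets, "enzyme")
    classes = [g for g in gene_sets if g.role == "class"]
    for gs in (targets, required, essential, tfs, enzymes):
        if gs.members is None:
            raise ValueError(f"gene set {gs.name!r} must be mapped to the network")

    outputs: Dict[str, Path] = {}
    seed = config.seed
    n_res = config.n_resamples
    gamma = neighbors_of_set(network, targets.require_mapped())
    t_nodes = set(targets.require_mapped())

    def run_stage(name: str, fn) -> None:
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # 1 -- distance-bin enrichment around targets
    def _dist_enrich() -> None:
        frames = []
        for feature in (targets, required, essential):
            prof = distance_bin_enrichment(
                network, targets, feature,
                n_resamples=n_res, seed=stage_rng(seed, f"dist_enrich:{feature.name}"),
                resample_reference=config.resample_reference,
                exclude_reference=config.exclude_reference,
            )
            df = prof.to_frame()
            df.insert(0, "feature", feature.name)
            frames.append(df)
        path = out / "distance_enrichment.tsv"
        _write(pd.concat(frames, ignore_index=True), path)
        outputs["distance_enrichment"] = path

    run_stage("distance_enrichment", _dist_enrich)

    # 2 -- LCC permutation tests (targets and augmented unions)
    def _lcc() -> None:
        t_req = augment_with_interacting(network, targets, required)
        t_req_ess = t_req | (set(essential.require_mapped()) & gamma)
        cases = [
            ("targets", targets),
            ("targets+interacting_required", t_req),
            ("targets+interacting_required+interacting_essential", t_req_ess),
            ("essential", essential),
        ]
        rows = []
        for name, node_set in cases:
            res = lcc_test(
                network, node_set, n_resamples=n_res,
                seed=stage_rng(seed, f"lcc:{name}"),
                degree_binned=config.degree_binned_null,
            )
            rows.append(
                dict(set_name=name, mapped_size=res.mapped_size,
                     lcc_size=res.lcc_size, lcc_fraction=res.lcc_fraction,
                     null_mean=res.null_mean, null_sd=res.null_sd,
                     null_max=res.null_max, p_value=res.p_value,
                     n_resamples=res.n_resamples)
            )
        path = out / "lcc.tsv"
        _write(pd.DataFrame(rows), path)
        outputs["lcc"] = path

    run_stage("lcc", _lcc)

    # 3 -- Fisher exact overlaps with targets
    def _fisher() -> None:
        universe = set(network.graph.nodes)
        rows = []
        for other in (essential, required):
            r = fisher_overlap(targets.require_mapped(), other.require_mapped(), universe)
            rows.append(
                dict(set_a=targets.name, set_b=other.name,
                     universe_size=r.universe_size, size_a=r.size_a, size_b=r.size_b,
                     overlap=r.overlap, odds_ratio=r.odds_ratio, p_value=r.p_value,
                     continuity_corrected=r.continuity_corrected)
            )
        path = out / "fisher_overlap.tsv"
        _write(pd.DataFrame(rows), path)
        outputs["fisher_overlap"] = path

    run_stage("fisher_overlap", _fisher)

    # 4 -- functional-class enrichment of targets plus interacting req/ess
    if classes:
        def _class_enrich() -> None:
            pooled = (
                t_nodes
                | (set(required.require_mapped()) & gamma)
                | (set(essential.require_mapped()) & gamma)
            )
            query = GeneSet.from_nodes("targets+interacting", "other", pooled)
            df = class_enrichment(
                classes, query, network.graph.nodes,
                n_resamples=n_res, seed=stage_rng(seed, "class_enrich"),
            )
            path = out / "class_enrichment.tsv"
            _write(df, path)
            outputs["class_enrichment"] = path

        run_stage("class_enrichment", _class_enrich)

    # 5 -- betweenness, bottleneck enrichment
    def _centrality() -> None:
        cmap = betweenness(network)
        path = out / "betweenness.tsv"
        _write(cmap.to_frame(), path)
        outputs["betweenness"] = path

        req = set(required.require_mapped())
        ess = set(essential.require_mapped())
        rest = set(network.graph.nodes) - t_nodes - gamma
        partition = [
            targets,
            GeneSet.from_nodes("required_in_gamma", "required", req & gamma),
            GeneSet.from_nodes("essential_in_gamma", "essential", ess & gamma),
            GeneSet.from_nodes("required_outside", "required", req - t_nodes - gamma),
            GeneSet.from_nodes("essential_outside", "essential", ess - t_nodes - gamma),
            GeneSet.from_nodes("remaining", "other", rest),
        ]
        df = bottleneck_enrichment(
            network, partition, fraction=config.bottleneck_fraction, centrality=cmap
        )
        path = out / "bottleneck_enrichment.tsv"
        _write(df, path)
        outputs["bottleneck_enrichment"] = path

    run_stage("centrality", _centrality)

    # 6 -- robustness deletion curves
    def _robustness() -> None:
        curves = robustness_analysis(
            network, targets, seed=stage_rng(seed, "robustness"),
            comparison=config.robustness_comparison,
            include_isolated=config.include_isolated,
        )
        path = out / "robustness.tsv"
        _write(pd.concat([c.to_frame() for c in curves], ignore_index=True), path)
        outputs["robustness"] = path

    run_stage("robustness", _robustness)

    # 7 -- complex participation by group
    if catalog is not None:
        def _participation() -> None:
            res = participation(
                network, catalog,
                exponent=config.participation_exponent,
                partner_multiplicity=config.partner_multiplicity,
            )
            path = out / "participation.tsv"
            _write(res.to_frame(), path)
            outputs["participation"] = path
            groups = {
                "targets": t_nodes,
                "neighbors": gamma,
                "remaining": set(network.graph.nodes) - t_nodes - gamma,
            }
            hist, comp = participation_by_group(res, groups)
            _write(hist, out / "participation_groups.tsv")
            _write(comp, out / "participation_comparisons.tsv")
            outputs["participation_groups"] = out / "participation_groups.tsv"
            outputs["participation_comparisons"] = out / "participation_comparisons.tsv"

        run_stage("participation", _participation)

    # 8 -- TF path analyses
    def _tf_paths() -> None:
        dists = tf_target_distances(network, tfs, targets)
        df = pd.DataFrame(
            [(tf, (d if isinstance(d, int) else "UNREACHABLE")) for tf, d in dists.items()],
            columns=["tf", "distance_to_nearest_target"],
        )
        _write(df, out / "tf_distances.tsv")
        outputs["tf_distances"] = out / "tf_distances.tsv"

        comp = path_length_comparison(
            network, tfs, targets,
            n_resamples=n_res,
            seed=stage_rng(seed, "tf_path_comparison"),
        )
        comp_df = pd.DataFrame([{
            "observed_mean": comp.observed_mean, "null_mean": comp.null_mean,
            "t_statistic": comp.t_statistic, "t_p_value": comp.t_p_value,
            "ranksum_statistic": comp.ranksum_statistic,
            "ranksum_p_value": comp.ranksum_p_value,
            "empirical_p": comp.empirical_p, "n_tfs": comp.n_tfs,
            "n_unreachable": comp.n_unreachable, "n_resamples": comp.n_resamples,
        }])
        _write(comp_df, out / "tf_path_comparison.tsv")
        outputs["tf_path_comparison"] = out / "tf_path_comparison.tsv"

        enr = enzyme_path_enrichment(
            network, tfs, targets, enzymes,
            n_resamples=n_res,
            seed=stage_rng(seed, "enzyme_path_enrichment"),
            all_shortest=config.all_shortest,
            include_endpoints=config.include_endpoints,
            store_paths=False,
        )
        _write(enr.bins, out / "enzyme_path_enrichment.tsv")
        outputs["enzyme_path_enrichment"] = out / "enzyme_path_enrichment.tsv"

    run_stage("tf_paths", _tf_paths)

    # manifest last: its presence marks a complete run
    manifest = {
        "package": "hpinet",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "network": {"n_nodes": network.n_nodes, "n_edges": network.n_edges},
        "gene_sets": {
            g.name: {"role": g.role, "raw": g.raw_size, "mapped": g.mapped_size}
            for g in gene_sets
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    mpath = out / "manifest.json"
    with open(mpath, "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = mpath
    return outputs
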