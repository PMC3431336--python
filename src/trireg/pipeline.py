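"""End-to-end orchestration of the regulatory-network analysis.

Stages run in a fixed order — simulate (or load) inputs, PPI topology,
CMI modulator inference, PWM confirmation, network assembly, profile
clustering, enrichment, process subnetworks — under a single global seed
that is split deterministically per stage.  Every stage persists its
outputs as TSV/SIF/JSON/FASTA in the output directory, and a manifest
records parameters, seeds, per-stage record counts and file digests
(no timestamps, so identical runs are byte-identical).

A stage may be re-run from the persisted outputs of earlier stages: when
an upstream stage is not requested, its outputs are reloaded from the
output directory instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, enrichment, io, modulators, profiles, pwm, subnetworks, synthetic, topology
from .errors import ConfigurationError, StageError

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "topology", "infer", "scan",
    "assemble", "profiles", "enrich", "subnets",
)


@dataclass
class PipelineConfig:
    outdir: str | Path = "trireg_out"
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    inference: modulators.InferenceConfig = field(
        default_factory=modulators.InferenceConfig
    )
    scan: pwm.ScanConfig = field(default_factory=pwm.ScanConfig)
    cluster_distance: str = "euclidean"
    cluster_linkage: str = "complete"
    enrichment_alpha: float = 0.05
    resampling_r: int = 10_000
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = synthetic.config_from_dict(raw.pop("synthetic"))
        if "inference" in raw:
            kwargs["inference"] = modulators.InferenceConfig(**raw.pop("inference"))
        if "scan" in raw:
            kwargs["scan"] = pwm.ScanConfig(**raw.pop("scan"))
        if "stages" in raw:
            kwargs["stages"] = tuple(raw.pop("stages"))
        kwargs.update(raw)
        return cls(**kwargs)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    values = [int(v) for v in ss.generate_state(len(STAGES)) % (2**31)]
    return dict(zip(STAGES, values))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineState:
    world: synthetic.SyntheticWorld | None = None
    stats: pd.DataFrame | None = None
    triplets: pd.DataFrame | None = None
    pwm_edges: pd.DataFrame | None = None
    network: assembly.RegulatoryNetwork | None = None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    state = PipelineState()
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages_run": list(config.stages),
        "parameters": {
            "inference": dataclasses.asdict(config.inference),
            "scan": dataclasses.asdict(config.scan),
            "cluster": {
                "distance": config.cluster_distance,
                "linkage": config.cluster_linkage,
            },
            "enrichment_alpha": config.enrichment_alpha,
            "resampling_r": config.resampling_r,
        },
        "counts": {},
        "files": {},
    }
    if config.synthetic is not None:
        manifest["parameters"]["synthetic"] = synthetic.config_to_dict(
            config.synthetic
        )

    runners = {
        "simulate": _stage_simulate,
        "topology": _stage_topology,
        "infer": _stage_infer,
        "scan": _stage_scan,
        "assemble": _stage_assemble,
        "profiles": _stage_profiles,
        "enrich": _stage_enrich,
        "subnets": _stage_subnets,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            runners[stage](config, state, outdir, seeds, manifest)
        except Exception as exc:
            _write_manifest(manifest, outdir)  # preserve partial outputs
            raise StageError(stage, str(exc)) from exc
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    for p in sorted(outdir.glob("**/*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(outdir))] = _digest(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _require_world(
    config: PipelineConfig, state: PipelineState, outdir: Path, seeds
) -> synthetic.SyntheticWorld:
    if state.world is None:
        state.world = _load_world(outdir)
    return state.world


def _stage_simulate(config, state, outdir, seeds, manifest) -> None:
    if config.synthetic is None:
        raise ConfigurationError("no synthetic block configured")
    syn = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
    world = synthetic.generate_world(syn)
    state.world = world
    io.write_edge_list(world.ppi.edges(), outdir / "ppi.tsv")
    io.write_expression(world.expression, outdir / "expression.tsv")
    io.write_roles(world.roles, outdir / "roles.tsv")
    pwm.write_transfac(world.pwms.values(), outdir / "pwms.transfac")
    with open(outdir / "tf_map.tsv", "w") as fh:
        fh.write("tf\tmatrix\n")
        for tf, mats in sorted(world.tf_to_matrix.items()):
            for m in mats:
                fh.write(f"{tf}\t{m}\n")
    io.write_fasta(world.promoters, outdir / "promoters.fasta")
    enrichment.write_gmt(world.gene_sets, outdir / "gene_sets.gmt")
    world.ground_truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "synthetic_config.json", "w") as fh:
        json.dump(synthetic.config_to_dict(syn), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["counts"]["simulate"] = {
        "genes": int(world.expression.shape[0]),
        "samples": int(world.expression.shape[1]),
        "ppi_edges": world.ppi.number_of_edges(),
        "planted_triplets": len(world.ground_truth.planted_triplets),
    }


def _load_world(outdir: Path) -> synthetic.SyntheticWorld:
    cfg_path = outdir / "synthetic_config.json"
    if not cfg_path.exists():
        raise ConfigurationError(
            f"no simulated inputs found under {outdir}; run the simulate stage"
        )
    with open(cfg_path) as fh:
        syn = synthetic.config_from_dict(json.load(fh))
    roles = io.read_roles(outdir / "roles.tsv")
    tf_map: dict[str, list[str]] = {}
    tf_df = pd.read_csv(outdir / "tf_map.tsv", sep="\t")
    for tf, m in zip(tf_df["tf"], tf_df["matrix"]):
        tf_map.setdefault(tf, []).append(m)
    return synthetic.SyntheticWorld(
        config=syn,
        ppi=topology.load_ppi(outdir / "ppi.tsv"),
        expression=io.read_expression(outdir / "expression.tsv"),
        roles=roles,
        pwms=pwm.read_transfac(outdir / "pwms.transfac"),
        tf_to_matrix=tf_map,
        promoters=io.read_fasta(outdir / "promoters.fasta"),
        gene_sets=enrichment.read_gmt(outdir / "gene_sets.gmt"),
        ground_truth=synthetic.GroundTruth.from_json(outdir / "ground_truth.json"),
    )


def _stage_topology(config, state, outdir, seeds, manifest) -> None:
    world = _require_world(config, state, outdir, seeds)
    stats = topology.topology_stats(world.ppi)
    state.stats = stats
    stats.to_csv(outdir / "topology_stats.tsv", sep="\t")
    pool = list(world.roles["gene"])
    result = topology.resampling_pvalue(
        stats, world.modulators, pool, "degree",
        n_resamples=config.resampling_r, seed=seeds["topology"],
    )
    result.to_json(outdir / "resampling_degree.json")
    sub = topology.extract_neighborhood(world.ppi, world.modulators + world.tfs)
    io.write_edge_list(sub.edges(), outdir / "neighborhood.tsv")
    manifest["counts"]["topology"] = {
        "nodes": int(stats.shape[0]),
        "neighborhood_nodes": sub.number_of_nodes(),
        "resampling_p": result.pvalue,
    }


def _stage_infer(config, state, outdir, seeds, manifest) -> None:
    world = _require_world(config, state, outdir, seeds)
    cfg = dataclasses.replace(config.inference, seed=seeds["infer"])
    candidates = modulators.CandidateSets(
        world.modulators, world.tfs, world.candidate_targets
    )
    table = modulators.infer_modulations(
        world.expression, candidates, cfg, return_all=True
    )
    table.to_csv(outdir / "triplets_all.tsv", sep="\t", index=False)
    survivors = table[table["significant"]].reset_index(drop=True)
    survivors.to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    state.triplets = survivors
    manifest["counts"]["infer"] = {
        "tested": int(len(table)),
        "significant": int(len(survivors)),
    }


def _stage_scan(config, state, outdir, seeds, manifest) -> None:
    world = _require_world(config, state, outdir, seeds)
    edges = pwm.predict_tf_targets(
        world.promoters, world.pwms, world.tf_to_matrix, config.scan
    )
    edges.to_csv(outdir / "pwm_edges.tsv", sep="\t", index=False)
    state.pwm_edges = edges
    manifest["counts"]["scan"] = {"edges": int(len(edges))}


def _stage_assemble(config, state, outdir, seeds, manifest) -> None:
    world = _require_world(config, state, outdir, seeds)
    if state.triplets is None:
        state.triplets = pd.read_csv(outdir / "triplets.tsv", sep="\t")
    if state.pwm_edges is None:
        state.pwm_edges = pd.read_csv(outdir / "pwm_edges.tsv", sep="\t")
    confirmed = assembly.intersect_edges(
        state.triplets, pwm.edge_set(state.pwm_edges)
    )
    confirmed.to_csv(outdir / "triplets_confirmed.tsv", sep="\t", index=False)
    net = assembly.build_network(confirmed, io.role_map(world.roles))
    state.network = net
    assembly.write_sif(net, outdir / "network.sif")
    assembly.write_node_attributes(net, outdir / "network_nodes.tsv")
    assembly.to_json(net, outdir / "network.json")
    deg = assembly.degree_summary(net)
    loops = assembly.detect_feedback_loops(net)
    duals = assembly.dual_role_genes(net)
    summary = dict(net.summary())
    summary.update(
        {
            "degree_pearson_r": deg.pearson_r,
            "degree_r_pvalue": deg.r_pvalue,
            "feedback_loops": [[l.tf, l.partner] for l in loops],
            "dual_role_genes": {g: sorted(r) for g, r in duals.items()},
        }
    )
    with open(outdir / "network_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["counts"]["assemble"] = {
        "confirmed_triplets": int(len(confirmed)),
        **net.summary(),
        "feedback_loops": len(loops),
        "dual_role_genes": len(duals),
    }


def _require_network(state: PipelineState, outdir: Path) -> assembly.RegulatoryNetwork:
    if state.network is None:
        state.network = assembly.from_json(outdir / "network.json")
    return state.network


def _stage_profiles(config, state, outdir, seeds, manifest) -> None:
    net = _require_network(state, outdir)
    counts = {}
    for axis in ("tf", "target"):
        profile = profiles.build_profiles(net, axis)
        profiles.write_profile(profile, outdir / f"profile_{axis}.tsv")
        counts[f"{axis}_profile_shape"] = list(profile.shape)
        if profile.shape[0] >= 2:
            result = profiles.hcluster(
                profile, config.cluster_distance, config.cluster_linkage
            )
            with open(outdir / f"dendrogram_{axis}.nwk", "w") as fh:
                fh.write(profiles.to_newick(result) + "\n")
            labels = {
                m: net.base_class.get(m, "unknown") for m in profile.index
            }
            purity = profiles.branch_purity(result, 2, labels)
            purity.to_csv(outdir / f"branch_purity_{axis}.tsv", sep="\t")
            assignment = result.cut(2)
            with open(outdir / f"clusters_{axis}.tsv", "w") as fh:
                fh.write("modulator\tbranch\n")
                for m in profile.index:
                    fh.write(f"{m}\t{assignment[str(m)]}\n")
            counts[f"{axis}_mean_purity"] = float(purity["purity"].mean())
    manifest["counts"]["profiles"] = counts


def _stage_enrich(config, state, outdir, seeds, manifest) -> None:
    world = _require_world(config, state, outdir, seeds)
    net = _require_network(state, outdir)
    background = set(world.roles["gene"])
    query = net.genes & background
    result = enrichment.enrich(
        query, world.gene_sets, background=background,
        alpha=config.enrichment_alpha,
    )
    result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    comparison = enrichment.random_list_comparison(
        query, sorted(background), world.gene_sets,
        n_random=10, seed=seeds["enrich"], background=background,
    )
    report = {
        "n_terms": int(len(result)),
        "n_significant": int(result["significant"].sum()) if len(result) else 0,
        "ks_vs_random": [
            {"D": r.statistic, "p": r.pvalue} for r in comparison.ks_results
        ],
    }
    with open(outdir / "enrichment_random_comparison.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["counts"]["enrich"] = {
        "terms": report["n_terms"],
        "significant": report["n_significant"],
    }


def _stage_subnets(config, state, outdir, seeds, manifest) -> None:
    world = _require_world(config, state, outdir, seeds)
    net = _require_network(state, outdir)
    subnets = {}
    for process, genes in sorted(world.gene_sets.items()):
        sub = subnetworks.extract_process_subnetwork(net, genes, name=process)
        subnets[process] = sub
        subnetworks.write_sif(sub, outdir / f"subnet_{process}.sif")
        subnetworks.write_membership(sub, outdir / f"subnet_{process}_members.tsv")
    rows = []
    names = sorted(subnets)
    for a in names:
        for b in names:
            if a == b:
                continue
            for role in subnetworks.OVERLAP_ROLES:
                ov = subnetworks.subnetwork_overlap(
                    subnets[a], subnets[b], role, net.base_class
                )
                rows.append(
                    {
                        "subnet_a": a, "subnet_b": b, "role": role,
                        "shared": ov.shared, "denominator": ov.denominator,
                        "fraction": ov.fraction,
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "subnet_overlaps.tsv", sep="\t", index=False)
    manifest["counts"]["subnets"] = {
        name: len(sub.members) for name, sub in subnets.items()
    }
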