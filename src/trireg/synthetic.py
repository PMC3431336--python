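"""Synthetic inputs with planted ground truth.

This module manufactures every input the pipeline consumes — a scale-free
protein-protein interaction network, a per-gene standardised expression
matrix with planted modulator-conditional TF-target dependence, PWMs with
planted promoter occurrences, role-labelled gene lists and process gene
sets — so the whole analysis can be exercised against a known answer.

The expression planting model: for a planted triplet (M, T, G) the
modulator M and the transcription factor T are i.i.d. standard normal and
the target is

    G = beta(M) * T + eps,     eps ~ N(0, noise_sd^2)

where beta(M) equals ``beta_high`` in the samples falling in M's own top
``modulator_fraction`` quantile and ``beta_low`` everywhere else (bottom
tail and middle alike).  This piecewise-constant coupling is the simplest
model with the conditional-dependence structure that conditional-mutual-
information modulator inference assumes, and it makes the within-subset
TF-target correlation closed form: rho = beta / sqrt(beta^2 + noise_sd^2).
Every gene row is finally re-standardised to mean 0, sd 1, emulating
relative expression scores.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .pwm import ALPHABET, PWM

logger = logging.getLogger(__name__)

ROLES = ("TSG", "OCG", "TF", "common")
PROCESS_NAMES = ("apoptosis", "cell_cycle", "hormone_response", "reproduction")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Defaults are the package's reference benchmark: 489 samples, 30
    modulators (18 tumor-suppressor + 12 oncogene candidates), 5 TFs, 50
    candidate targets, 40 planted triplets with coupling 0.8 in the
    modulator-high tail and 0 elsewhere, unit noise, tail fraction 0.35.
    """

    n_genes: int = 100
    n_samples: int = 489
    n_tsg: int = 18
    n_ocg: int = 12
    n_tf: int = 5
    n_common: int = 50
    n_planted_triplets: int = 40
    beta_high: float = 0.8
    beta_low: float = 0.0
    noise_sd: float = 1.0
    modulator_fraction: float = 0.35
    promoter_length: int = 1000
    motif_copies: int = 1
    motif_length: int = 10
    pwm_concentration: float = math.inf
    gc_content: float = 0.5
    ppi_edges_per_node: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.modulator_fraction <= 0.5):
            raise ConfigurationError("modulator_fraction must lie in (0, 0.5]")
        if self.role_counts_total > self.n_genes:
            raise ConfigurationError("role counts exceed n_genes")
        if self.beta_high < self.beta_low:
            raise ConfigurationError("beta_high must be >= beta_low")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_planted_triplets > self.n_common:
            raise ConfigurationError(
                "each planted triplet needs its own target gene"
            )
        if not (0 < self.gc_content < 1):
            raise ConfigurationError("gc_content must lie in (0, 1)")

    @property
    def role_counts(self) -> dict[str, int]:
        return {
            "TSG": self.n_tsg,
            "OCG": self.n_ocg,
            "TF": self.n_tf,
            "common": self.n_common,
        }

    @property
    def role_counts_total(self) -> int:
        return self.n_tsg + self.n_ocg + self.n_tf + self.n_common


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    planted_tfbs: list[tuple[str, str, int, str]] = field(default_factory=list)
    role_map: dict[str, str] = field(default_factory=dict)

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        """(TF, target) pairs carried by at least one planted triplet."""
        return {(t, g) for _, t, g in self.planted_triplets}

    def to_json(self, path) -> None:
        payload = {
            "planted_triplets": sorted(self.planted_triplets),
            "planted_tfbs": sorted(self.planted_tfbs),
            "role_map": dict(sorted(self.role_map.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_triplets={tuple(t) for t in payload["planted_triplets"]},
            planted_tfbs=[tuple(t) for t in payload["planted_tfbs"]],
            role_map=payload["role_map"],
        )


def gene_names(config: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic gene symbols per role; extras fill out the PPI."""
    names = {
        "TSG": [f"TSG{i:03d}" for i in range(1, config.n_tsg + 1)],
        "OCG": [f"OCG{i:03d}" for i in range(1, config.n_ocg + 1)],
        "TF": [f"TF{i:03d}" for i in range(1, config.n_tf + 1)],
        "common": [f"CG{i:03d}" for i in range(1, config.n_common + 1)],
    }
    n_extra = config.n_genes - config.role_counts_total
    names["extra"] = [f"XG{i:03d}" for i in range(1, n_extra + 1)]
    return names


def role_table(config: SyntheticConfig) -> pd.DataFrame:
    names = gene_names(config)
    rows = [
        {"gene": g, "role": role}
        for role in ROLES
        for g in names[role]
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def generate_ppi(
    n_genes: int,
    edges_per_new_node: int = 3,
    seed: int | None = None,
    names: Sequence[str] | None = None,
) -> nx.Graph:
    """Scale-free interactome stand-in (Barabasi-Albert preferential
    attachment): connected, simple, heavy-tailed degree distribution."""
    if edges_per_new_node < 1 or n_genes < edges_per_new_node + 1:
        raise ParameterError(
            "need n_genes >= edges_per_new_node + 1 and edges_per_new_node >= 1"
        )
    g = nx.barabasi_albert_graph(n_genes, edges_per_new_node, seed=seed)
    if names is not None:
        if len(names) != n_genes:
            raise ParameterError("names length must equal n_genes")
        g = nx.relabel_nodes(g, dict(enumerate(names)))
    return g


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def plant_triplets(
    config: SyntheticConfig, rng: np.random.Generator
) -> set[tuple[str, str, str]]:
    """Choose (modulator, TF, target) triplets; each target used once."""
    names = gene_names(config)
    modulators = names["TSG"] + names["OCG"]
    targets = rng.choice(
        names["common"], size=config.n_planted_triplets, replace=False
    )
    triplets = set()
    for g in targets:
        m = modulators[rng.integers(len(modulators))]
        t = names["TF"][rng.integers(config.n_tf)]
        triplets.add((str(m), str(t), str(g)))
    return triplets


def generate_expression(
    config: SyntheticConfig,
    triplets: set[tuple[str, str, str]],
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression matrix (genes x samples) with planted modulation.

    Non-participating genes are i.i.d. standard normal; planted targets
    follow the piecewise coupling model in the module docstring; all rows
    are re-standardised afterwards.
    """
    rng = np.random.default_rng(seed)
    names = gene_names(config)
    all_genes = [g for role in (*ROLES, "extra") for g in names[role]]
    index = {g: i for i, g in enumerate(all_genes)}
    n = config.n_samples

    target_of: dict[str, tuple[str, str]] = {}
    upstream: set[str] = set()
    for m, t, g in triplets:
        if len({m, t, g}) < 3:
            raise ConfigurationError(f"degenerate triplet {(m, t, g)}")
        if g in target_of:
            raise ConfigurationError(f"target {g} planted in two triplets")
        target_of[g] = (m, t)
        upstream.update((m, t))
    clash = upstream & target_of.keys()
    if clash:
        raise ConfigurationError(
            f"genes planted both upstream and as targets: {sorted(clash)}"
        )

    X = rng.standard_normal((len(all_genes), n))
    k = int(np.floor(config.modulator_fraction * n))
    for g, (m, t) in sorted(target_of.items()):
        m_row = X[index[m]]
        top = np.argsort(m_row, kind="stable")[n - k:]
        beta = np.full(n, config.beta_low)
        beta[top] = config.beta_high
        X[index[g]] = beta * X[index[t]] + config.noise_sd * rng.standard_normal(n)

    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    expr = pd.DataFrame(
        X, index=pd.Index(all_genes, name="gene"),
        columns=[f"S{i:04d}" for i in range(1, n + 1)],
    )
    truth = GroundTruth(
        planted_triplets=set(triplets),
        role_map={g: role for role in ROLES for g in names[role]},
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Motifs and promoters
# ---------------------------------------------------------------------------

def generate_pwm(
    consensus: str,
    concentration: float = math.inf,
    pseudocount: float = 1e-3,
    name: str | None = None,
) -> PWM:
    """PWM concentrated on a consensus sequence.

    Finite ``concentration`` c puts weight c on the consensus base and 1 on
    each alternative (so the consensus frequency is c / (c + 3)); c must
    exceed 1 for the consensus base to be modal.  Infinite concentration
    gives one-hot columns.
    """
    consensus = consensus.upper()
    if not consensus or any(b not in ALPHABET for b in consensus):
        raise ParameterError("consensus must be a non-empty ACGT string")
    if not concentration > 1:
        raise ParameterError(
            "concentration must exceed 1 so the consensus base is modal"
        )
    L = len(consensus)
    counts = np.ones((4, L))
    one_hot = math.isinf(concentration)
    for i, base in enumerate(consensus):
        b = ALPHABET.index(base)
        if one_hot:
            counts[:, i] = 0.0
            counts[b, i] = 1.0
        else:
            counts[b, i] = concentration
    return PWM(counts, name=name or f"M_{consensus}", pseudocount=pseudocount)


def random_consensus(length: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def generate_promoters(
    targets: Sequence[str],
    pwm_library: Mapping[str, PWM],
    planted_map: Mapping[tuple[str, str], int],
    promoter_length: int = 1000,
    seed: int | None = None,
    gc_content: float = 0.5,
) -> tuple[dict[str, str], list[tuple[str, str, int, str]]]:
    """Background promoters with motif copies planted for positive pairs.

    ``planted_map`` maps (matrix name, target gene) to a copy number >= 1.
    Background bases are i.i.d. with the requested GC content.  Each copy
    is sampled column-wise from the PWM's raw count distribution, placed at
    a uniform non-overlapping position on a uniform strand, and recorded as
    (target, matrix, start, strand) in forward coordinates.
    """
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    base_probs = np.array([at, gc, gc, at])  # A C G T

    copies_per_gene: dict[str, list[str]] = {g: [] for g in targets}
    for (mat, gene), copies in planted_map.items():
        if copies < 1:
            raise ParameterError(f"pair {(mat, gene)} requests zero copies")
        if gene not in copies_per_gene:
            raise ParameterError(f"planted target {gene!r} not in targets")
        copies_per_gene[gene].extend([mat] * int(copies))

    promoters: dict[str, str] = {}
    planted: list[tuple[str, str, int, str]] = []
    for gene in targets:
        seq = rng.choice(4, size=promoter_length, p=base_probs)
        occupied: list[tuple[int, int]] = []
        for mat in copies_per_gene[gene]:
            pwm = pwm_library[mat]
            w = pwm.length
            if w > promoter_length:
                raise ParameterError(
                    f"promoter of {promoter_length} bp too short for {mat}"
                )
            site = pwm.sample_site(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = site if strand == "+" else _revcomp(site)
            placed = False
            for _ in range(1000):
                start = int(rng.integers(0, promoter_length - w + 1))
                if all(start + w <= a or start >= b for a, b in occupied):
                    placed = True
                    break
            if not placed:
                raise ParameterError(
                    f"promoter of {gene} too short for requested copies"
                )
            occupied.append((start, start + w))
            seq[start:start + w] = [ALPHABET.index(b) for b in insert]
            planted.append((gene, mat, start, strand))
        promoters[gene] = "".join(ALPHABET[i] for i in seq)
    return promoters, planted


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    config: SyntheticConfig, seed: int | None = None,
    membership_prob: float = 0.3,
) -> dict[str, set[str]]:
    """Process annotations over the role-labelled genes.

    Each TSG/OCG/TF/common gene joins each of four processes independently
    with ``membership_prob``; empty sets are refilled with one random gene
    so every set is usable.
    """
    rng = np.random.default_rng(seed)
    names = gene_names(config)
    universe = [g for role in ROLES for g in names[role]]
    sets: dict[str, set[str]] = {}
    for process in PROCESS_NAMES:
        mask = rng.random(len(universe)) < membership_prob
        members = {g for g, m in zip(universe, mask) if m}
        if not members:
            members = {universe[int(rng.integers(len(universe)))]}
        sets[process] = members
    return sets


# ---------------------------------------------------------------------------
# The assembled world
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    ppi: nx.Graph
    expression: pd.DataFrame
    roles: pd.DataFrame
    pwms: dict[str, PWM]
    tf_to_matrix: dict[str, list[str]]
    promoters: dict[str, str]
    gene_sets: dict[str, set[str]]
    ground_truth: GroundTruth

    @property
    def modulators(self) -> list[str]:
        sel = self.roles["role"].isin(["TSG", "OCG"])
        return list(self.roles.loc[sel, "gene"])

    @property
    def tfs(self) -> list[str]:
        return list(self.roles.loc[self.roles["role"] == "TF", "gene"])

    @property
    def candidate_targets(self) -> list[str]:
        return list(self.roles.loc[self.roles["role"] == "common", "gene"])


def generate_world(config: SyntheticConfig | None = None) -> SyntheticWorld:
    """Generate every pipeline input from one seed, deterministically."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(6) % (2**31)]
    names = gene_names(config)

    ppi = generate_ppi(
        config.n_genes, config.ppi_edges_per_node, seed=seeds[0],
        names=[g for role in (*ROLES, "extra") for g in names[role]],
    )
    triplets = plant_triplets(config, np.random.default_rng(seeds[1]))
    expression, truth = generate_expression(config, triplets, seed=seeds[2])

    consensus_rng = np.random.default_rng(seeds[3])
    pwms: dict[str, PWM] = {}
    tf_to_matrix: dict[str, list[str]] = {}
    for tf in names["TF"]:
        mat = generate_pwm(
            random_consensus(config.motif_length, consensus_rng),
            concentration=config.pwm_concentration,
            name=f"V${tf}",
        )
        pwms[mat.name] = mat
        tf_to_matrix[tf] = [mat.name]

    planted_map = {
        (tf_to_matrix[t][0], g): config.motif_copies
        for _, t, g in triplets
    }
    promoters, tfbs = generate_promoters(
        names["common"],
        pwms,
        planted_map,
        promoter_length=config.promoter_length,
        seed=seeds[4],
        gc_content=config.gc_content,
    )
    truth.planted_tfbs = tfbs
    gene_sets = generate_gene_sets(config, seed=seeds[5])
    return SyntheticWorld(
        config=config,
        ppi=ppi,
        expression=expression,
        roles=role_table(config),
        pwms=pwms,
        tf_to_matrix=tf_to_matrix,
        promoters=promoters,
        gene_sets=gene_sets,
        ground_truth=truth,
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    if math.isinf(d["pwm_concentration"]):
        d["pwm_concentration"] = "inf"
    return d


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    if d.get("pwm_concentration") == "inf":
        d["pwm_concentration"] = math.inf
    return SyntheticConfig(**d)
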