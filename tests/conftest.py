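import numpy as np
import pytest

from trireg import assembly, modulators, synthetic


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic world for cheap unit tests."""
    return synthetic.SyntheticConfig(
        n_genes=40,
        n_samples=120,
        n_tsg=4,
        n_ocg=3,
        n_tf=2,
        n_common=12,
        n_planted_triplets=6,
        promoter_length=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return synthetic.generate_world(small_config)


@pytest.fixture(scope="session")
def bench_world():
    """The reference benchmark world (defaults, one fixed seed)."""
    return synthetic.generate_world(synthetic.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def bench_inference(bench_world):
    """Full inference table on the benchmark world (computed once)."""
    candidates = modulators.CandidateSets(
        bench_world.modulators, bench_world.tfs, bench_world.candidate_targets
    )
    config = modulators.InferenceConfig(seed=101)
    table = modulators.infer_modulations(
        bench_world.expression, candidates, config, return_all=True
    )
    return table


def toy_network(triplets, role_map=None):
    """Assemble a network from triplets with roles inferred by prefix."""
    if role_map is None:
        role_map = {}
        for m, t, g in triplets:
            role_map.setdefault(m, "TSG" if m.startswith("TSG") else "OCG")
            role_map.setdefault(t, "TF")
            role_map.setdefault(g, role_map.get(g, "common"))
    return assembly.build_network(triplets, role_map)


def random_regulatory_network(rng, n_mod=4, n_tf=3, n_target=6, p_edge=0.4):
    """Random three-layer network over a shared gene pool.

    Some modulators/TFs double as targets so dual roles and feedback loops
    occur with useful frequency.
    """
    mods = [f"M{i}" for i in range(n_mod)]
    tfs = [f"F{i}" for i in range(n_tf)]
    pure = [f"G{i}" for i in range(n_target)]
    targets = pure + list(rng.choice(mods, size=min(2, n_mod), replace=False))
    role_map = (
        {m: ("TSG" if i % 2 == 0 else "OCG") for i, m in enumerate(mods)}
        | {t: "TF" for t in tfs}
        | {g: "common" for g in pure}
    )
    triplets = []
    for m in mods:
        for t in tfs:
            for g in targets:
                if g in (m, t):
                    continue
                if rng.random() < p_edge:
                    triplets.append((m, t, g))
    if not triplets:
        triplets = [(mods[0], tfs[0], pure[0])]
    return assembly.build_network(triplets, role_map), role_map
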