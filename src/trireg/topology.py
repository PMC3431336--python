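"""Topology statistics of gene sets in a protein-protein interaction network.

Degree, betweenness and closeness centrality per node; two-sample KS
comparisons between gene lists; empirical resampling p-values for the mean
metric of a gene set against same-size random draws; and seed-neighborhood
subnetwork extraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ParseError

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "closeness")


def load_ppi(path, strict: bool = True) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected simple graph.

    Self-pairs are dropped and duplicate records (either orientation)
    collapsed; the number of discarded records is logged.  An optional
    single header line is tolerated.  In strict mode a malformed line
    raises :class:`ParseError` naming the line; otherwise it is skipped.
    """
    g = nx.Graph()
    dropped_self = dropped_dup = 0
    n_records = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                if lineno == 1 and len(fields) >= 2:
                    continue  # header
                if strict:
                    raise ParseError(f"malformed edge record {line!r}", lineno)
                logger.warning("skipping malformed line %d: %r", lineno, line)
                continue
            a, b = fields
            n_records += 1
            if a == b:
                dropped_self += 1
                continue
            if g.has_edge(a, b):
                dropped_dup += 1
                continue
            g.add_edge(a, b)
    if n_records == 0:
        logger.warning("edge list %s contained no edges", path)
    if dropped_self or dropped_dup:
        logger.info(
            "dropped %d self-interactions and %d duplicate records",
            dropped_self, dropped_dup,
        )
    return g


def topology_stats(
    network: nx.Graph, normalized_betweenness: bool = True
) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality for every node.

    Betweenness follows the standard convention of normalising by the
    number of ordered pairs excluding the node (``normalized_betweenness``
    exposes the raw pair counts instead).  Closeness is computed within a
    node's connected component and scaled by (reachable-1)/(n-1); an
    isolated node has closeness 0.
    """
    if network.number_of_nodes() == 0:
        raise ParameterError("network is empty")
    degree = dict(network.degree())
    betweenness = nx.betweenness_centrality(
        network, normalized=normalized_betweenness
    )
    closeness = nx.closeness_centrality(network, wf_improved=True)
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    )
    df.index.name = "gene"
    return df.sort_index()


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float


def ks_compare(values_a: Sequence[float], values_b: Sequence[float]) -> KSResult:
    """Two-tailed two-sample Kolmogorov-Smirnov comparison."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("both samples must have at least 2 values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


@dataclass(frozen=True)
class ResamplingResult:
    """Empirical p-value report: p = (#draws with mean metric strictly
    greater than observed) / R.  A zero count is reported with the caveat
    that only p < 1/R can be claimed."""

    metric: str
    observed_mean: float
    n_exceed: int
    n_resamples: int
    seed: int | None

    @property
    def pvalue(self) -> float:
        return self.n_exceed / self.n_resamples

    @property
    def note(self) -> str:
        if self.n_exceed == 0:
            return f"no exceedances; p < {1.0 / self.n_resamples:g}"
        return ""

    def to_json(self, path) -> None:
        payload = {
            "metric": self.metric,
            "observed_mean": self.observed_mean,
            "n_exceed": self.n_exceed,
            "n_resamples": self.n_resamples,
            "p": self.pvalue,
            "seed": self.seed,
            "note": self.note,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def resampling_pvalue(
    stats_table: pd.DataFrame,
    gene_set: Iterable[str],
    background_pool: Iterable[str],
    metric: str,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> ResamplingResult:
    """Empirical significance of a gene set's mean topology metric.

    Draws ``n_resamples`` same-size sets without replacement from the
    background pool and counts draws whose mean metric strictly exceeds
    the observed mean.  Invariant to pool ordering; deterministic given
    the seed.
    """
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    genes = sorted(set(gene_set))
    pool = sorted(set(background_pool))
    missing = [g for g in genes if g not in stats_table.index]
    if missing:
        raise ParameterError(f"gene set members missing from stats: {missing}")
    if len(genes) > len(pool):
        raise ParameterError("gene set larger than background pool")
    values = stats_table.loc[pool, metric].to_numpy()
    observed = float(stats_table.loc[genes, metric].mean())

    rng = np.random.default_rng(seed)
    s = len(genes)
    # Random subsets via partial argsort of uniform keys: one row per draw.
    keys = rng.random((n_resamples, len(pool)))
    idx = np.argpartition(keys, s - 1, axis=1)[:, :s]
    means = values[idx].mean(axis=1)
    n_exceed = int(np.sum(means > observed))
    return ResamplingResult(
        metric=metric,
        observed_mean=observed,
        n_exceed=n_exceed,
        n_resamples=n_resamples,
        seed=seed,
    )


def extract_neighborhood(network: nx.Graph, seed_genes: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the seeds plus their direct interactors.

    Seeds absent from the network are logged and ignored.
    """
    seeds = set(seed_genes)
    present = seeds & set(network.nodes)
    missing = seeds - present
    if missing:
        logger.warning(
            "%d seed genes absent from the network: %s",
            len(missing), sorted(missing)[:10],
        )
    nodes = set(present)
    for s in present:
        nodes.update(network.neighbors(s))
    return network.subgraph(nodes).copy()
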