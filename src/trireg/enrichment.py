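"""Gene-set over-representation analysis.

Hypergeometric upper-tail tests of a query gene list against GMT
collections, Benjamini-Hochberg adjustment, and a random-gene-list
comparison that contrasts the query's adjusted-p distribution with
same-size draws from a candidate pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .topology import KSResult, ks_compare

logger = logging.getLogger(__name__)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for overlap k of a size-n query with a
    size-K set in a size-N background."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ParameterError(f"invalid hypergeometric arguments {(k, K, n, N)}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: name <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParameterError(
                    f"GMT record needs name, description and genes (line {lineno})"
                )
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{genes}\n")


def enrich(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    The background defaults to the union of the collection's genes.  Query
    genes outside the background are logged and dropped; terms with no
    background members are dropped before testing (they would be untestable
    and would distort the BH correction).  ``ease`` applies the k-1
    penalised variant of the overlap count used by some annotation servers.
    """
    query = set(query)
    if not query:
        raise ParameterError("query gene list is empty")
    sets = {name: set(genes) for name, genes in collection.items()}
    if background is None:
        background = set().union(*sets.values()) if sets else set()
    background = set(background)
    stray = query - background
    if stray:
        logger.warning(
            "%d query genes outside the background were dropped: %s",
            len(stray), sorted(stray)[:10],
        )
    query &= background
    if not query:
        raise ParameterError("no query gene lies in the background")

    N = len(background)
    n = len(query)
    rows = []
    for term in sorted(sets):
        members = sets[term] & background
        K = len(members)
        if K == 0:
            logger.info("term %r has no background members; dropped", term)
            continue
        k = len(query & members)
        k_eff = max(k - 1, 0) if ease else k
        rows.append(
            {
                "term": term, "k": k, "K": K, "n": n, "N": N,
                "p": hypergeom_p(k_eff, K, n, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
        df = df.sort_values(["q", "p", "term"], ignore_index=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


@dataclass
class RandomListComparison:
    observed: pd.DataFrame
    random_results: list[pd.DataFrame]
    ks_results: list[KSResult]
    seed: int | None

    def observed_q(self, truncate_at: float | None = 0.05) -> np.ndarray:
        return _q_values(self.observed, truncate_at)

    def random_q(self, truncate_at: float | None = 0.05) -> list[np.ndarray]:
        return [_q_values(df, truncate_at) for df in self.random_results]


def _q_values(df: pd.DataFrame, truncate_at: float | None) -> np.ndarray:
    q = df["q"].to_numpy() if len(df) else np.array([])
    if truncate_at is not None:
        q = q[q <= truncate_at]
    return q


def random_list_comparison(
    query: Iterable[str],
    candidate_pool: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    n_random: int = 10,
    seed: int | None = None,
    background: Iterable[str] | None = None,
) -> RandomListComparison:
    """Contrast the query's enrichment with same-size random gene lists.

    Draws ``n_random`` lists of the query's size from the candidate pool,
    enriches each, and KS-compares the observed adjusted-p distribution
    with each random list's.
    """
    query = sorted(set(query))
    pool = sorted(set(candidate_pool))
    if len(query) > len(pool):
        raise ParameterError("query larger than candidate pool")
    rng = np.random.default_rng(seed)
    observed = enrich(query, collection, background=background)
    random_results = []
    ks_results = []
    for _ in range(n_random):
        draw = rng.choice(pool, size=len(query), replace=False)
        res = enrich(draw, collection, background=background)
        random_results.append(res)
        if len(observed) >= 2 and len(res) >= 2:
            ks_results.append(
                ks_compare(observed["q"].to_numpy(), res["q"].to_numpy())
            )
    return RandomListComparison(
        observed=observed,
        random_results=random_results,
        ks_results=ks_results,
        seed=seed,
    )
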