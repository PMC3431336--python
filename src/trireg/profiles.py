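"""Binary regulatory profiles of modulators and their clustering.

Each modulator gets a 0/1 profile over the network's TFs (direct
modulation) or over its targets (two-hop regulation through any TF).
Hierarchical clustering of these profiles asks whether tumor-suppressor
and oncogene modulators use distinguishable regulatory repertoires; branch
purity at a cut quantifies the class separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .assembly import RegulatoryNetwork
from .errors import ParameterError

logger = logging.getLogger(__name__)

AXES = ("tf", "target")
DISTANCES = ("euclidean", "jaccard")
LINKAGES = ("complete", "average", "single")


def build_profiles(network: RegulatoryNetwork, axis: str = "tf") -> pd.DataFrame:
    """Binary modulator x (TF | target) incidence matrix.

    ``tf`` axis: entry 1 iff the modulator has a modulation edge to the TF.
    ``target`` axis: entry 1 iff some TF links the modulator to the target
    (a two-hop modulator -> TF -> target chain).
    Columns span every TF (resp. target) in the network; rows are sorted.
    """
    if axis not in AXES:
        raise ParameterError(f"axis must be one of {AXES}")
    mods = sorted(network.modulators)
    mod_edges = set(network.modulation_edges)
    if axis == "tf":
        cols = sorted(network.tfs)
        data = [
            [1 if (m, t) in mod_edges else 0 for t in cols] for m in mods
        ]
    else:
        cols = sorted(network.targets)
        reg_by_tf: dict[str, set[str]] = {}
        for t, g in network.regulation_edges:
            reg_by_tf.setdefault(t, set()).add(g)
        reach = {
            m: set().union(
                *(reg_by_tf.get(t, set()) for mm, t in mod_edges if mm == m)
            )
            if any(mm == m for mm, _ in mod_edges)
            else set()
            for m in mods
        }
        data = [[1 if g in reach[m] else 0 for g in cols] for m in mods]
    return pd.DataFrame(data, index=pd.Index(mods, name="modulator"), columns=cols)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: list[str]
    distance: str
    linkage: str
    zero_rows: list[str] = field(default_factory=list)

    def cut(self, k: int) -> dict[str, int]:
        """Branch index (1..k) per row label at a k-branch cut."""
        assignment = hierarchy.fcluster(
            self.linkage_matrix, t=k, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(a) for a in assignment)))


def hcluster(
    profile: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of profile rows (deterministic).

    Defaults (euclidean distance, complete linkage) match the stock
    settings of the usual statistical environments; jaccard/average are
    exposed because binary profiles often warrant them.  All-zero rows are
    kept — they simply co-cluster at maximal distance — and flagged.
    """
    if distance not in DISTANCES:
        raise ParameterError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}")
    if profile.shape[0] < 2:
        raise ParameterError("need at least 2 rows to cluster")
    values = profile.to_numpy(dtype=float)
    zero_rows = [
        str(lbl) for lbl, row in zip(profile.index, values) if not row.any()
    ]
    if zero_rows:
        logger.info("all-zero profile rows: %s", zero_rows)
    if distance == "jaccard":
        # Jaccard distance of two all-zero rows is defined as 0 here.
        dmat = pdist(values.astype(bool), metric="jaccard")
        dmat = np.nan_to_num(dmat, nan=0.0)
    else:
        dmat = pdist(values, metric="euclidean")
    Z = hierarchy.linkage(dmat, method=linkage)
    return ClusterResult(
        linkage_matrix=Z,
        labels=[str(lbl) for lbl in profile.index],
        distance=distance,
        linkage=linkage,
        zero_rows=zero_rows,
    )


def branch_purity(
    result: ClusterResult, k: int, class_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Majority-class purity of each branch at a k-branch cut."""
    if k < 2:
        raise ParameterError("k must be at least 2")
    missing = [lbl for lbl in result.labels if lbl not in class_labels]
    if missing:
        raise ParameterError(f"class labels missing for rows: {missing}")
    assignment = result.cut(k)
    rows = []
    for branch in sorted(set(assignment.values())):
        members = [lbl for lbl, b in assignment.items() if b == branch]
        classes = pd.Series([class_labels[m] for m in members])
        counts = classes.value_counts()
        rows.append(
            {
                "branch": branch,
                "size": len(members),
                "majority_class": counts.index[0],
                "purity": counts.iloc[0] / len(members),
            }
        )
    return pd.DataFrame(rows).set_index("branch")


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(result.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def write_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t")


def read_profile(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
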