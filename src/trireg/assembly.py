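"""Assembly and description of the three-layer regulatory network.

The network has modulators (tumor suppressors and oncogenes) on top,
transcription factors in the middle and target genes at the bottom.
Modulation edges (modulator -> TF) and regulation edges (TF -> target)
both derive from inferred triplets whose (TF, target) pair survived PWM
confirmation; edge multiplicity is collapsed, with supporting triplet
counts kept as edge attributes.

A gene may occupy several layers at once (e.g. an oncogene that is itself
a regulated target); such dual-role genes, and the modulator<->TF feedback
loops they can create, are first-class outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, RoleError

logger = logging.getLogger(__name__)

MODULATOR_CLASSES = ("TSG", "OCG")


def intersect_edges(
    cmi_triplets: pd.DataFrame | Iterable[tuple[str, str, str]],
    pwm_edges: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Keep triplets whose (TF, target) pair is PWM-confirmed."""
    if not isinstance(cmi_triplets, pd.DataFrame):
        cmi_triplets = pd.DataFrame(
            list(cmi_triplets), columns=["modulator", "tf", "target"]
        )
    confirmed = set(map(tuple, pwm_edges))
    keep = [
        (t, g) in confirmed
        for t, g in zip(cmi_triplets["tf"], cmi_triplets["target"])
    ]
    return cmi_triplets.loc[keep].reset_index(drop=True)


class RegulatoryNetwork:
    """Directed three-layer network with per-gene layer roles.

    Layer membership is structural: a gene is a modulator if it sources a
    modulation edge, a TF if it sources a regulation edge, and a target if
    it receives one.  A candidate TF that never regulates anything in the
    final network therefore holds no TF role — if it is itself regulated it
    is a plain target (the demotion the construction implies).
    """

    def __init__(self) -> None:
        # Keyed by edge kind: the same ordered gene pair may carry both a
        # modulation and a regulation edge (dual-role genes).
        self.graph = nx.MultiDiGraph()
        self.base_class: dict[str, str] = {}

    # -- construction ---------------------------------------------------
    def add_triplet(self, modulator: str, tf: str, target: str) -> None:
        for kind, u, v in (
            ("modulation", modulator, tf),
            ("regulation", tf, target),
        ):
            if self.graph.has_edge(u, v, key=kind):
                self.graph[u][v][kind]["n_support"] += 1
            else:
                self.graph.add_edge(u, v, key=kind, kind=kind, n_support=1)

    # -- layers ---------------------------------------------------------
    def _edges(self, kind: str):
        return (
            (u, v)
            for u, v, k in self.graph.edges(keys=True)
            if k == kind
        )

    @property
    def modulation_edges(self) -> list[tuple[str, str]]:
        return sorted(self._edges("modulation"))

    @property
    def regulation_edges(self) -> list[tuple[str, str]]:
        return sorted(self._edges("regulation"))

    @property
    def modulators(self) -> set[str]:
        return {u for u, _ in self._edges("modulation")}

    @property
    def tfs(self) -> set[str]:
        return {u for u, _ in self._edges("regulation")}

    @property
    def targets(self) -> set[str]:
        return {v for _, v in self._edges("regulation")}

    def roles(self, gene: str) -> set[str]:
        """Layer roles of a gene; modulators are labelled by their class."""
        out: set[str] = set()
        if gene in self.modulators:
            out.add(self.base_class.get(gene, "modulator"))
        if gene in self.tfs:
            out.add("TF")
        if gene in self.targets:
            out.add("target")
        return out

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def summary(self) -> dict:
        mods = self.modulators
        return {
            "n_genes": len(self.genes),
            "n_tsg": sum(1 for m in mods if self.base_class.get(m) == "TSG"),
            "n_ocg": sum(1 for m in mods if self.base_class.get(m) == "OCG"),
            "n_tf": len(self.tfs),
            "n_target": len(self.targets),
            "n_modulation_edges": len(self.modulation_edges),
            "n_regulation_edges": len(self.regulation_edges),
            "n_links": self.graph.number_of_edges(),
        }


def build_network(
    confirmed_triplets: pd.DataFrame | Iterable[tuple[str, str, str]],
    role_map: Mapping[str, str],
) -> RegulatoryNetwork:
    """Assemble the three-layer network from confirmed triplets.

    Every modulator must be classed TSG or OCG and every TF classed TF in
    ``role_map``; a triplet violating this raises :class:`RoleError`
    naming the gene.
    """
    if isinstance(confirmed_triplets, pd.DataFrame):
        triplets = list(
            zip(
                confirmed_triplets["modulator"],
                confirmed_triplets["tf"],
                confirmed_triplets["target"],
            )
        )
    else:
        triplets = list(confirmed_triplets)
    net = RegulatoryNetwork()
    for m, t, g in triplets:
        m_class = role_map.get(m)
        if m_class not in MODULATOR_CLASSES:
            raise RoleError(
                f"modulator {m!r} has role {m_class!r}, expected TSG or OCG"
            )
        if role_map.get(t) != "TF":
            raise RoleError(f"gene {t!r} used as TF but classed {role_map.get(t)!r}")
        net.add_triplet(m, t, g)
        net.base_class[m] = m_class
    for gene in net.genes:
        if gene in role_map and gene not in net.base_class:
            net.base_class[gene] = role_map[gene]
    return net


@dataclass(frozen=True)
class DegreeSummary:
    per_tf: pd.DataFrame  # columns in_degree, out_degree, indexed by TF
    pearson_r: float | None
    r_pvalue: float | None


def degree_summary(network: RegulatoryNetwork) -> DegreeSummary:
    """TF in-degree (modulators) vs out-degree (targets), with Pearson r.

    The correlation is not computable when either degree vector has zero
    variance or there are fewer than 3 TFs; it is then reported as None.
    """
    tfs = sorted(network.tfs)
    mod_edges = set(network.modulation_edges)
    reg_edges = set(network.regulation_edges)
    rows = [
        {
            "tf": t,
            "in_degree": sum(1 for u, v in mod_edges if v == t),
            "out_degree": sum(1 for u, v in reg_edges if u == t),
        }
        for t in tfs
    ]
    per_tf = pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame(
        columns=["in_degree", "out_degree"]
    )
    r = p = None
    if len(tfs) >= 3:
        x = per_tf["in_degree"].to_numpy(dtype=float)
        y = per_tf["out_degree"].to_numpy(dtype=float)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        else:
            logger.warning("degree correlation not computable: zero variance")
    return DegreeSummary(per_tf=per_tf, pearson_r=r, r_pvalue=p)


@dataclass(frozen=True, order=True)
class FeedbackLoop:
    """A mutual pair: ``partner`` modulates ``tf`` and ``tf`` regulates
    ``partner`` back as a target."""

    tf: str
    partner: str


def detect_feedback_loops(network: RegulatoryNetwork) -> list[FeedbackLoop]:
    mod_edges = set(network.modulation_edges)
    reg_edges = set(network.regulation_edges)
    loops = {
        FeedbackLoop(tf=t, partner=p)
        for p, t in mod_edges
        if (t, p) in reg_edges
    }
    return sorted(loops)


def dual_role_genes(network: RegulatoryNetwork) -> dict[str, set[str]]:
    """Genes occupying more than one layer, with their role sets."""
    return {
        g: roles
        for g in sorted(network.genes)
        if len(roles := network.roles(g)) >= 2
    }


# ---------------------------------------------------------------------------
# Serialisation: SIF, node attributes, node-link JSON
# ---------------------------------------------------------------------------

_INTERACTION = {"modulation": "modulates", "regulation": "regulates"}
_INTERACTION_INV = {v: k for k, v in _INTERACTION.items()}


def write_sif(network: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        for kind in ("modulation", "regulation"):
            for u, v in sorted(network._edges(kind)):
                fh.write(f"{u}\t{_INTERACTION[kind]}\t{v}\n")


def write_node_attributes(network: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\troles\tbase_class\n")
        for g in sorted(network.genes):
            roles = ",".join(sorted(network.roles(g)))
            fh.write(f"{g}\t{roles}\t{network.base_class.get(g, '')}\n")


def to_json(network: RegulatoryNetwork, path=None) -> str:
    payload = {
        "directed": True,
        "base_class": dict(sorted(network.base_class.items())),
        "edges": [
            {"source": u, "target": v, "kind": k, "n_support": d["n_support"]}
            for u, v, k, d in sorted(network.graph.edges(keys=True, data=True))
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_json(source) -> RegulatoryNetwork:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    net = RegulatoryNetwork()
    for e in payload["edges"]:
        net.graph.add_edge(
            e["source"], e["target"], key=e["kind"],
            kind=e["kind"], n_support=e["n_support"],
        )
    net.base_class = dict(payload["base_class"])
    return net


def read_sif(path) -> RegulatoryNetwork:
    """Reload a SIF export (roles beyond layer structure are not recovered)."""
    net = RegulatoryNetwork()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3 or fields[1] not in _INTERACTION_INV:
                raise ParameterError(f"malformed SIF record at line {lineno}")
            u, rel, v = fields
            kind = _INTERACTION_INV[rel]
            net.graph.add_edge(u, v, key=kind, kind=kind, n_support=1)
    return net
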