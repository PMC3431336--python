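"""Process-specific regulatory subnetworks.

A biological process (apoptosis, cell cycle, ...) is supplied as a gene
set; its subnetwork is built bottom-up in three passes: map the process
genes to the target layer, recruit every TF regulating those targets
(flagging TFs that are not themselves process-annotated as *added*), and
finally recruit process-annotated modulators with modulation edges to
those TFs.  Cross-process overlaps are reported per role with the first
subnetwork's role set as denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .assembly import RegulatoryNetwork
from .errors import ParameterError

logger = logging.getLogger(__name__)

OVERLAP_ROLES = ("TSG", "OCG", "TF", "target")


@dataclass
class ProcessSubnetwork:
    name: str
    targets: set[str]
    tfs: set[str]
    added_tfs: set[str]
    modulators: set[str]
    edges: list[tuple[str, str, str]] = field(default_factory=list)  # (kind, u, v)

    @property
    def members(self) -> set[str]:
        return self.targets | self.tfs | self.modulators

    def role_members(self, role: str, base_class: dict[str, str]) -> set[str]:
        if role == "TF":
            return set(self.tfs)
        if role == "target":
            return set(self.targets)
        if role in ("TSG", "OCG"):
            return {m for m in self.modulators if base_class.get(m) == role}
        raise ParameterError(f"unknown role {role!r}")

    @property
    def is_empty(self) -> bool:
        return not self.members


def extract_process_subnetwork(
    network: RegulatoryNetwork,
    process_gene_set,
    name: str = "process",
) -> ProcessSubnetwork:
    process = set(process_gene_set)
    if not process:
        raise ParameterError("process gene set is empty")
    reg_edges = set(network.regulation_edges)
    mod_edges = set(network.modulation_edges)

    targets = network.targets & process
    tfs = {t for t, g in reg_edges if g in targets}
    added = {t for t in tfs if t not in process}
    modulators = {
        m for m, t in mod_edges if t in tfs and m in process
    }
    edges = sorted(
        [("regulation", t, g) for t, g in reg_edges if t in tfs and g in targets]
        + [("modulation", m, t) for m, t in mod_edges if m in modulators and t in tfs]
    )
    sub = ProcessSubnetwork(
        name=name, targets=targets, tfs=tfs, added_tfs=added,
        modulators=modulators, edges=edges,
    )
    if sub.is_empty:
        logger.warning("process %r maps to no layer of the network", name)
    return sub


@dataclass(frozen=True)
class OverlapResult:
    role: str
    shared: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.shared / self.denominator if self.denominator else 0.0


def subnetwork_overlap(
    subnet_a: ProcessSubnetwork,
    subnet_b: ProcessSubnetwork,
    role: str,
    base_class: dict[str, str] | None = None,
) -> OverlapResult:
    """Shared role members of two subnetworks, as a fraction of A's.

    The denominator is the first argument's role set; an empty role set is
    logged and yields fraction 0.
    """
    if role not in OVERLAP_ROLES:
        raise ParameterError(f"role must be one of {OVERLAP_ROLES}")
    base_class = base_class or {}
    a = subnet_a.role_members(role, base_class)
    b = subnet_b.role_members(role, base_class)
    if not a:
        logger.warning(
            "subnetwork %r has no %s members; overlap fraction reported as 0",
            subnet_a.name, role,
        )
    return OverlapResult(role=role, shared=len(a & b), denominator=len(a))


def to_graph(subnet: ProcessSubnetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(subnet.members)
    for kind, u, v in subnet.edges:
        g.add_edge(u, v, key=kind, kind=kind)
    return g


def write_sif(subnet: ProcessSubnetwork, path) -> None:
    rel = {"modulation": "modulates", "regulation": "regulates"}
    with open(path, "w") as fh:
        for kind, u, v in subnet.edges:
            fh.write(f"{u}\t{rel[kind]}\t{v}\n")


def write_membership(subnet: ProcessSubnetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlayer\tadded_tf\n")
        for g in sorted(subnet.members):
            layers = []
            if g in subnet.modulators:
                layers.append("modulator")
            if g in subnet.tfs:
                layers.append("TF")
            if g in subnet.targets:
                layers.append("target")
            added = "yes" if g in subnet.added_tfs else "no"
            fh.write(f"{g}\t{','.join(layers)}\t{added}\n")
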