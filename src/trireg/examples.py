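"""Worked example: an ovarian-cancer-shaped three-layer network.

Reconstructs the size and role structure of a published ovarian-cancer
regulatory map: 29 tumor-suppressor and 13 oncogene modulators, 15
transcription factors and 65 target genes, of which 10 targets also hold
an upper-layer role (3 TSGs, 3 OCGs, 4 TFs) so that 112 unique genes
remain, and exactly six modulator<->TF feedback loops are present:

    E2F3 <-> CHEK2,  ETS1 <-> EGFR,  ETS1 <-> ERBB2,
    ETS1 <-> SPARC,  HMGA2 <-> MYC,  HNF1B <-> MYC.

Gene symbols appearing in those loops are real; every other symbol
(TSG..., OCG..., TF..., TG..., and the placeholder TSG_SYN3 standing in
for a third dual-role tumor suppressor whose identity is not derivable
from the loop list) is synthetic.  All remaining edges are one-way decoy
fillers that give every layer member at least one edge without creating
additional loops.
"""

from __future__ import annotations

from .assembly import RegulatoryNetwork, build_network

LOOP_PAIRS = (
    ("E2F3", "CHEK2"),
    ("ETS1", "EGFR"),
    ("ETS1", "ERBB2"),
    ("ETS1", "SPARC"),
    ("HMGA2", "MYC"),
    ("HNF1B", "MYC"),
)

_DUAL_TSG = ("CHEK2", "SPARC", "TSG_SYN3")
_DUAL_OCG = ("EGFR", "ERBB2", "MYC")
_DUAL_TF = ("TF05", "TF06", "TF07", "TF08")


def ovarian_example_network() -> RegulatoryNetwork:
    """Build the example network from triplets, as the pipeline would."""
    tsgs = list(_DUAL_TSG) + [f"TSG{i:02d}" for i in range(4, 30)]  # 29
    ocgs = list(_DUAL_OCG) + [f"OCG{i:02d}" for i in range(4, 14)]  # 13
    tfs = ["E2F3", "ETS1", "HMGA2", "HNF1B"] + [
        f"TF{i:02d}" for i in range(5, 16)
    ]  # 15
    pure_targets = [f"TG{i:02d}" for i in range(1, 56)]  # 55

    role_map = (
        {g: "TSG" for g in tsgs}
        | {g: "OCG" for g in ocgs}
        | {g: "TF" for g in tfs}
        | {g: "common" for g in pure_targets}
    )

    triplets: list[tuple[str, str, str]] = [
        # Feedback loops: the dual gene modulates the TF in one triplet and
        # is regulated back by the same TF in another.
        ("CHEK2", "E2F3", "TG01"), ("TSG04", "E2F3", "CHEK2"),
        ("EGFR", "ETS1", "TG02"), ("TSG05", "ETS1", "EGFR"),
        ("ERBB2", "ETS1", "TG02"), ("TSG05", "ETS1", "ERBB2"),
        ("SPARC", "ETS1", "TG03"), ("TSG06", "ETS1", "SPARC"),
        ("MYC", "HMGA2", "TG04"), ("OCG04", "HMGA2", "MYC"),
        ("MYC", "HNF1B", "TG05"), ("OCG05", "HNF1B", "MYC"),
        # Dual-role genes without loops: modulator and target roles are
        # mediated by different TFs.
        ("TSG_SYN3", "TF09", "TG06"), ("TSG07", "TF10", "TSG_SYN3"),
        # Dual-role TFs: each regulates targets and is itself regulated by
        # a different TF.
        ("TSG08", "TF05", "TG07"), ("TSG08", "TF09", "TF05"),
        ("TSG09", "TF06", "TG08"), ("TSG09", "TF10", "TF06"),
        ("OCG06", "TF07", "TG09"), ("OCG06", "TF11", "TF07"),
        ("OCG07", "TF08", "TG10"), ("OCG07", "TF12", "TF08"),
    ]

    # Decoy one-way fillers: every remaining modulator modulates some TF,
    # every TF regulates some pure target, every pure target is regulated.
    # Dual-role genes are deliberately excluded so no extra loop can form.
    filler_mods = [m for m in tsgs + ocgs if m not in _DUAL_TSG + _DUAL_OCG]
    remaining_targets = [
        g for g in pure_targets
        if g not in {t for _, _, t in triplets}
    ]
    for i, g in enumerate(remaining_targets):
        m = filler_mods[i % len(filler_mods)]
        t = tfs[i % len(tfs)]
        triplets.append((m, t, g))
    for j, m in enumerate(filler_mods):
        triplets.append((m, tfs[j % len(tfs)], pure_targets[j % len(pure_targets)]))

    return build_network(triplets, role_map)
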