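"""Readers and writers for the tabular and sequence inputs.

Expression matrices travel as TSV (first column gene symbol, remaining
columns sample IDs), role lists as two-column TSV, promoters as FASTA
(one record per target gene, header = gene symbol).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"expression matrix {path} has no samples")
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    # Full repr so a reload is bit-identical (rank-based statistics must
    # not change across a checkpoint round trip).
    expr.to_csv(path, sep="\t")


def read_roles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "role"}.issubset(df.columns):
        raise ParseError(f"role file {path} must have 'gene' and 'role' columns")
    return df[["gene", "role"]]


def write_roles(roles: pd.DataFrame, path) -> None:
    roles.to_csv(path, sep="\t", index=False)


def role_map(roles: pd.DataFrame) -> dict[str, str]:
    return dict(zip(roles["gene"], roles["role"]))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(edges):
            fh.write(f"{u}\t{v}\n")
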