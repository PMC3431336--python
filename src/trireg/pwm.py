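"""MATCH-style position-weight-matrix scanning.

A transcription-factor binding preference is represented as a position
frequency matrix ``f(i, b)`` (base ``b`` at motif position ``i``).  Each
position is weighted by its information content

    I(i) = sum_b f(i, b) * ln(4 * f(i, b)),        with 0 * ln 0 := 0,

which ranges from 0 (uniform column) to ln 4 (point mass).  A sequence
window ``b_1 .. b_L`` is scored by the min-max normalised weighted sum

    score = (Current - Min) / (Max - Min)
    Current = sum_i I(i) * f(i, b_i)
    Min     = sum_i I(i) * min_b f(i, b)
    Max     = sum_i I(i) * max_b f(i, b)

over either all L positions (*matrix score*) or the 5 consecutive most
informative positions (*core score*).  A window is reported as a hit when
both scores reach their thresholds; the conventional stringent setting is
core 1.00 (the core must be consensus) and matrix 0.95.

Natural logarithms are used throughout so scores are reproducible
bit-for-bit against the definitions above.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, UndefinedScoreError

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_ORDER = [3, 2, 1, 0]  # A<->T, C<->G row swap
CORE_LENGTH = 5


@dataclass(frozen=True)
class ScanConfig:
    """Hit-calling thresholds and scanning policy.

    ``core_threshold`` of 1.00 demands that the 5-position core achieve the
    maximum attainable weighted sum, i.e. the core must spell the consensus.
    Windows containing ``N`` are skipped under the default ambiguity policy;
    the ``"min-frequency"`` policy instead scores ``N`` with the position's
    minimum base frequency (the most pessimistic defined score).
    """

    core_threshold: float = 1.00
    matrix_threshold: float = 0.95
    both_strands: bool = True
    ambiguity_policy: str = "skip"

    def __post_init__(self) -> None:
        if self.ambiguity_policy not in ("skip", "min-frequency"):
            raise ParameterError(
                f"unknown ambiguity_policy {self.ambiguity_policy!r}"
            )


@dataclass(frozen=True)
class ScanHit:
    """A thresholded PWM match on a promoter sequence.

    ``position`` is the 0-based start of the half-open window on the
    forward strand; minus-strand hits are reported in forward coordinates.
    """

    seq_id: str
    position: int
    strand: str
    core_score: float
    matrix_score: float
    matrix: str


class PWM:
    """Position frequency matrix over A, C, G, T.

    Parameters
    ----------
    counts:
        Array-like of shape (4, L): rows A, C, G, T, one column per motif
        position.  Raw (possibly fractional) observation counts.
    name:
        Matrix identifier (e.g. a TRANSFAC accession).
    pseudocount:
        Added to every count before column normalisation so no frequency is
        exactly zero (keeps ln f finite).
    """

    def __init__(self, counts, name: str = "PWM", pseudocount: float = 1e-3):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ParameterError("counts must have shape (4, L)")
        if counts.shape[1] < 1:
            raise ParameterError("PWM must have at least one column")
        if np.any(counts < 0) or np.any(~np.isfinite(counts)):
            raise ParameterError("counts must be finite and non-negative")
        if np.any(counts.sum(axis=0) == 0) and pseudocount == 0:
            raise ParameterError("empty column with zero pseudocount")
        self.name = name
        self.pseudocount = float(pseudocount)
        self.counts = counts
        padded = counts + self.pseudocount
        self.matrix = padded / padded.sum(axis=0, keepdims=True)

    # -- basic geometry -------------------------------------------------
    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def __len__(self) -> int:
        return self.length

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.matrix, axis=0))

    @property
    def information(self) -> np.ndarray:
        return information_vector(self)

    @property
    def core_offset(self) -> int:
        return find_core(self)

    def reverse_complement(self) -> "PWM":
        rc = self.counts[_COMPLEMENT_ORDER, ::-1]
        return PWM(rc, name=self.name, pseudocount=self.pseudocount)

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site column-wise from the raw count distribution.

        Sampling uses the counts *without* pseudocount, so a one-hot matrix
        always yields the consensus.
        """
        sums = self.counts.sum(axis=0)
        if np.any(sums == 0):
            raise ParameterError("cannot sample from an empty column")
        probs = self.counts / sums
        cols = [rng.choice(4, p=probs[:, i]) for i in range(self.length)]
        return "".join(ALPHABET[i] for i in cols)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PWM({self.name!r}, L={self.length}, core@{self.core_offset})"


def information_vector(pwm: PWM) -> np.ndarray:
    """Per-position information content I(i) = sum_b f ln(4 f), in nats."""
    f = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=0)


def find_core(pwm: PWM) -> int:
    """Start of the 5 consecutive positions maximising summed information.

    Ties resolve to the leftmost window.
    """
    if pwm.length < CORE_LENGTH:
        raise ParameterError(
            f"PWM of length {pwm.length} has no {CORE_LENGTH}-position core"
        )
    info = information_vector(pwm)
    window_sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
    return int(np.argmax(window_sums))  # argmax returns the first maximum


def _score_components(pwm: PWM, positions: np.ndarray):
    info = information_vector(pwm)[positions]
    f = pwm.matrix[:, positions]
    current_weights = info * f  # (4, len(positions))
    lo = (info * f.min(axis=0)).sum()
    hi = (info * f.max(axis=0)).sum()
    return current_weights, lo, hi


def score_window(
    pwm: PWM,
    window: str,
    positions: Sequence[int] | None = None,
) -> float:
    """Min-max normalised similarity of ``window`` to the PWM.

    ``positions`` restricts scoring to a subset of motif positions (the core
    score passes the 5 core positions); the window must supply exactly the
    bases at those positions, i.e. always the full L-length window.
    """
    if len(window) != pwm.length:
        raise ParameterError("window length must equal PWM length")
    pos = (
        np.arange(pwm.length)
        if positions is None
        else np.asarray(list(positions), dtype=int)
    )
    weights, lo, hi = _score_components(pwm, pos)
    if hi == lo:
        raise UndefinedScoreError(
            f"PWM {pwm.name!r}: max and min attainable sums coincide"
        )
    try:
        rows = np.array([_BASE_INDEX[window[i]] for i in pos])
    except KeyError as exc:
        raise ParameterError(f"non-ACGT base {exc} in window") from None
    current = weights[rows, np.arange(len(pos))].sum()
    return float((current - lo) / (hi - lo))


def _scan_one_strand(
    codes: np.ndarray, pwm: PWM, policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Score every window on the coded sequence for one PWM orientation.

    Returns (core_scores, matrix_scores) arrays of length n_windows; windows
    invalidated by the ambiguity policy score NaN.
    """
    L = pwm.length
    info = information_vector(pwm)
    f = pwm.matrix
    # Row 4 handles 'N': NaN under "skip", the per-position minimum under
    # "min-frequency" (the most pessimistic defined value).
    fill = np.full(L, np.nan) if policy == "skip" else f.min(axis=0)
    lookup = np.vstack([f, fill[None, :]])  # (5, L)

    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (W, L)
    fvals = lookup[windows, np.arange(L)]  # base frequency at each position

    def _norm(pos_slice: slice) -> np.ndarray:
        w = info[pos_slice]
        lo = (w * f[:, pos_slice].min(axis=0)).sum()
        hi = (w * f[:, pos_slice].max(axis=0)).sum()
        if hi == lo:
            raise UndefinedScoreError(
                f"PWM {pwm.name!r}: max and min attainable sums coincide"
            )
        # Summing (w * fvals) rowwise uses the same pairwise reduction as
        # the scalar hi/lo sums, so a consensus window scores exactly 1.0.
        current = (w * fvals[:, pos_slice]).sum(axis=1)
        return (current - lo) / (hi - lo)

    core = pwm.core_offset
    core_scores = _norm(slice(core, core + CORE_LENGTH))
    matrix_scores = _norm(slice(0, L))
    return core_scores, matrix_scores


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    if re.search(r"[^ACGTN]", seq):
        bad = re.search(r"[^ACGTN]", seq).group()
        raise ParameterError(f"sequence contains unsupported base {bad!r}")
    table = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
    table[ord("N")] = 4
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.intp)


def scan_sequence(
    sequence: str,
    pwm: PWM,
    config: ScanConfig | None = None,
    seq_id: str = "",
) -> list[ScanHit]:
    """Thresholded scan of one sequence, both strands by default.

    Minus-strand windows are scored against the reverse-complemented PWM at
    the same forward coordinates.  Hits are sorted by position, then strand
    ('+' before '-').
    """
    config = config or ScanConfig()
    codes = _encode(sequence)
    if len(codes) < pwm.length:
        return []
    hits: list[ScanHit] = []
    strands = [("+", pwm)]
    if config.both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat in strands:
        core_scores, matrix_scores = _scan_one_strand(
            codes, mat, config.ambiguity_policy
        )
        ok = (
            ~np.isnan(core_scores)
            & ~np.isnan(matrix_scores)
            & (core_scores >= config.core_threshold)
            & (matrix_scores >= config.matrix_threshold)
        )
        for pos in np.nonzero(ok)[0]:
            hits.append(
                ScanHit(
                    seq_id=seq_id,
                    position=int(pos),
                    strand=strand,
                    core_score=float(core_scores[pos]),
                    matrix_score=float(matrix_scores[pos]),
                    matrix=pwm.name,
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))  # '+' < '-' in ASCII
    return hits


def predict_tf_targets(
    promoters: Mapping[str, str],
    pwm_library: Mapping[str, PWM],
    tf_to_matrix: Mapping[str, Sequence[str]],
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Predict TF -> gene regulation edges from promoter scans.

    An edge (TF, gene) is emitted when any PWM mapped to the TF produces at
    least one hit in the gene's promoter; ``n_hits`` counts all supporting
    hits across the TF's matrices.
    """
    config = config or ScanConfig()
    rows = []
    for tf, matrix_names in tf_to_matrix.items():
        if not matrix_names:
            raise ParameterError(f"TF {tf!r} maps to no PWM")
        for gene, seq in promoters.items():
            n_hits = 0
            for mname in matrix_names:
                pwm = pwm_library[mname]
                n_hits += len(scan_sequence(seq, pwm, config, seq_id=gene))
            if n_hits:
                rows.append({"tf": tf, "target": gene, "n_hits": n_hits})
    df = pd.DataFrame(rows, columns=["tf", "target", "n_hits"])
    return df.sort_values(["tf", "target"], ignore_index=True)


def edge_set(predictions: pd.DataFrame) -> set[tuple[str, str]]:
    """Collapse a prediction table to the bare (TF, target) edge set."""
    return set(zip(predictions["tf"], predictions["target"]))


# ---------------------------------------------------------------------------
# Matrix file I/O
# ---------------------------------------------------------------------------

def read_transfac(path) -> dict[str, PWM]:
    """Read a TRANSFAC-style flat file of count matrices.

    Recognised records: ``ID <name>``, a ``P0``/``PO`` header line, numbered
    rows of four counts, ``//`` terminators.  Other annotation lines are
    ignored.  Returns matrices keyed by their ID.
    """
    pwms: dict[str, PWM] = {}
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag == "ID":
                name = line[2:].strip()
                rows = []
            elif tag in ("P0", "PO"):
                continue
            elif tag == "//":
                if name is None or not rows:
                    raise ParseError("matrix terminator without data", lineno)
                counts = np.array(rows, dtype=float).T  # rows -> (4, L)
                pwms[name] = PWM(counts, name=name)
                name, rows = None, []
            elif line[:1].isdigit():
                fields = line.split()
                try:
                    values = [float(v) for v in fields[1:5]]
                except (ValueError, IndexError):
                    raise ParseError("malformed count row", lineno) from None
                if len(values) != 4:
                    raise ParseError("expected four counts", lineno)
                rows.append(values)
    if name is not None:
        raise ParseError("unterminated matrix record")
    return pwms


def write_transfac(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.name}\n")
            fh.write("P0      A      C      G      T\n")
            for i in range(pwm.length):
                a, c, g, t = pwm.counts[:, i]
                fh.write(f"{i + 1:02d} {a:10.4f} {c:10.4f} {g:10.4f} {t:10.4f}\n")
            fh.write("//\n")


def read_matrix_tsv(path) -> dict[str, PWM]:
    """Read the minimal 4-column dialect: name, position, then A C G T counts.

    Columns: matrix, position (1-based), A, C, G, T; tab-separated, header
    row required.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"matrix", "position", "A", "C", "G", "T"}
    if not required.issubset(df.columns):
        raise ParseError(f"matrix TSV must have columns {sorted(required)}")
    pwms = {}
    for name, grp in df.groupby("matrix", sort=False):
        grp = grp.sort_values("position")
        counts = grp[["A", "C", "G", "T"]].to_numpy().T
        pwms[str(name)] = PWM(counts, name=str(name))
    return pwms


def hits_to_frame(hits: Iterable[ScanHit], pwm_lengths: Mapping[str, int]) -> pd.DataFrame:
    rows = [
        {
            "seq": h.seq_id,
            "start": h.position,
            "end": h.position + pwm_lengths[h.matrix],
            "strand": h.strand,
            "core_score": h.core_score,
            "matrix_score": h.matrix_score,
            "matrix": h.matrix,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["seq", "start", "end", "strand", "core_score", "matrix_score", "matrix"],
    )
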