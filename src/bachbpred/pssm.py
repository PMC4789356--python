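"""Position-specific scoring matrices: parsing, normalization, composition.

A PSSM assigns every sequence position a row of 20 integer log-odds
substitution scores.  Scores span a wide range, so each row is rescaled
to [0, 1] by the min–max map

    X = (n − l) / (m − l)

where n is the raw score and l, m are the row minimum and maximum.  The
normalized matrix is then pooled into a fixed 400-dimensional
"PSSM composition": a 20×20 accumulator whose cell (a, b) sums the
normalized scores toward residue b over all positions whose query
residue is a, divided by the sequence length L.

The ASCII dialect read and written here follows the PSI-BLAST text PSSM
layout: header lines, then one row per position holding the position
index, the query residue, 20 integer log-odds, 20 integer percentages
and two trailing statistics.  Only the log-odds block is used; column
order is taken from the header line so both the classic PSI-BLAST
ordering and alphabetical ordering parse correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_ALPHABET, AA_INDEX, PSIBLAST_COLUMN_ORDER
from .encoders import FeatureVector
from .errors import ParseError, ValidationError

_AA_SET = frozenset(AA_ALPHABET)


@dataclass(frozen=True)
class PSSMatrix:
    """Raw per-sequence L×20 integer score matrix.

    ``scores[i, j]`` is the substitution score at position i toward the
    j-th residue in alphabetical order, regardless of the column order
    of the file the matrix came from.
    """

    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=int)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(f"PSSM must be L x 20, got shape {scores.shape}")
        if scores.shape[0] != len(self.sequence):
            raise ValidationError(
                f"PSSM has {scores.shape[0]} rows but sequence length is "
                f"{len(self.sequence)}"
            )
        if not self.sequence:
            raise ValidationError("PSSM for an empty sequence")
        bad = sorted(set(self.sequence) - _AA_SET)
        if bad:
            raise ValidationError(f"non-standard residues in PSSM sequence: {bad}")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NormalizedPSSM:
    """Row-wise min–max normalized PSSM with all values in [0, 1]."""

    sequence: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sequence), 20):
            raise ValidationError(
                f"normalized PSSM shape {values.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValidationError("normalized PSSM values outside [0, 1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_row(row: np.ndarray) -> np.ndarray:
    """Min–max normalize one 20-score row to [0, 1].

    The row minimum maps to 0 and the maximum to 1.  A constant row,
    where the map would divide by zero, returns all zeros — a documented
    convention chosen to keep sparse behaviour deterministic.
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (20,):
        raise ValidationError(f"expected 20 scores per row, got shape {row.shape}")
    lo, hi = row.min(), row.max()
    if hi == lo:
        return np.zeros(20)
    return (row - lo) / (hi - lo)


def normalize_pssm(pssm: PSSMatrix) -> NormalizedPSSM:
    """Apply :func:`normalize_row` to every position of a PSSM."""
    values = np.apply_along_axis(normalize_row, 1, pssm.scores.astype(float))
    return NormalizedPSSM(sequence=pssm.sequence, values=values)


def truncate4(value: float) -> float:
    """Truncate (floor) a non-negative value to 4 decimal places.

    Compatibility formatter: printed normalized scores are conventionally
    truncated, not rounded (236/1433 = 0.16468… prints as 0.1646).  Full
    precision is always kept internally.
    """
    return math.floor(value * 10000) / 10000


def pssm_composition(npssm: NormalizedPSSM) -> FeatureVector:
    """Pool a normalized PSSM into the 400-dimensional composition.

    Cell (a, b) of a 20×20 accumulator receives the sum of normalized
    scores toward residue b over positions whose query residue is a;
    every cell is divided by the sequence length, and the accumulator is
    flattened row-major (query residue outer, substitution column inner).
    """
    length = len(npssm)
    if length < 1:
        raise ValidationError("PSSM composition of an empty matrix")
    acc = np.zeros((20, 20))
    codes = np.array([AA_INDEX[c] for c in npssm.sequence], dtype=np.intp)
    np.add.at(acc, codes, npssm.values)
    return FeatureVector("PSSM", (acc / length).ravel())


def parse_pssm_ascii(path: str | Path) -> PSSMatrix:
    """Parse a PSI-BLAST style ASCII PSSM file.

    Rows must carry exactly 40 numeric score fields (20 log-odds +
    20 percentages); only the log-odds block is kept.  The sequence is
    reconstructed from the residue column.  Trailing statistics sections
    are ignored.
    """
    path = Path(path)
    column_order: str | None = None
    residues: list[str] = []
    rows: list[list[int]] = []
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                if in_body:
                    break  # blank line ends the score table
                continue
            if column_order is None:
                if all(len(t) == 1 and t in _AA_SET for t in tokens) and len(tokens) in (20, 40):
                    order = "".join(tokens[:20])
                    if sorted(order) != sorted(AA_ALPHABET):
                        raise ParseError(
                            f"{path}:{lineno}: header does not list the 20 amino acids"
                        )
                    column_order = order
                continue
            if not tokens[0].lstrip("-").isdigit():
                if in_body:
                    break  # footer (lambda/K statistics)
                continue
            in_body = True
            if len(tokens) < 2 or tokens[1] not in _AA_SET:
                raise ParseError(
                    f"{path}:{lineno}: residue column {tokens[1] if len(tokens) > 1 else '?'!r} "
                    "is not a standard amino acid"
                )
            numeric = tokens[2:]
            scores = []
            for tok in numeric[:40]:
                try:
                    scores.append(int(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer score field {tok!r}"
                    ) from None
            if len(scores) != 40:
                raise ParseError(
                    f"{path}:{lineno}: expected 40 numeric score fields, found {len(scores)}"
                )
            residues.append(tokens[1])
            rows.append(scores[:20])
    if column_order is None:
        raise ParseError(f"{path}: no column-order header line found")
    if not rows:
        raise ParseError(f"{path}: no score rows found")
    # Re-index file columns into alphabetical order.
    perm = np.array([column_order.index(aa) for aa in AA_ALPHABET])
    scores = np.asarray(rows, dtype=int)[:, perm]
    return PSSMatrix(sequence="".join(residues), scores=scores)


def write_pssm_ascii(pssm: PSSMatrix, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect read by the parser.

    Columns use the classic PSI-BLAST residue ordering.  The percentage
    block is filled with zeros: it is not consumed anywhere, only the
    field count matters for format validity.
    """
    perm = np.array([AA_INDEX[aa] for aa in PSIBLAST_COLUMN_ORDER])
    out = pssm.scores[:, perm]
    letters = "   ".join(PSIBLAST_COLUMN_ORDER)
    with open(path, "w") as fh:
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(" " * 12 + letters + "   " + letters + "\n")
        for i, (res, row) in enumerate(zip(pssm.sequence, out), start=1):
            scores = "".join(f"{v:6d}" for v in row)
            percents = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i:5d} {res} {scores} {percents}  0.00 0.00\n")
        fh.write("\n")
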