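"""Composition-based feature encodings of protein sequences.

Four sequence-only encodings are provided:

AC
    amino-acid composition — the fraction of each of the 20 residues,
    indexed alphabetically (dimension 20);
DC
    dipeptide composition — the fraction of each ordered residue pair
    among the L−1 overlapping windows, row-major by first then second
    residue (dimension 400);
MM
    the AC fractions re-indexed from most to least abundant residue in
    the average HbL protein, the fixed order ``ALEKIVGDPNFQRTMYSHWC``
    (dimension 20);
HYBRID
    AC followed by DC (dimension 420).

All values are fractions in [0, 1]; AC, MM and DC each sum to one.  The
PSSM scheme (dimension 400) is computed in :mod:`bachbpred.pssm` but
shares the :class:`FeatureVector` container defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.datasets import dump_svmlight_file

from .alphabet import AA_ALPHABET, AA_INDEX, DIPEPTIDES, MM_ORDER
from .errors import ValidationError

#: Fixed dimensionality of each encoding scheme.
SCHEME_DIMS = {"AC": 20, "DC": 400, "MM": 20, "HYBRID": 420, "PSSM": 400}

#: Component labels per scheme, for TSV headers.
SCHEME_LABELS = {
    "AC": tuple(AA_ALPHABET),
    "MM": tuple(MM_ORDER),
    "DC": DIPEPTIDES,
    "HYBRID": tuple(AA_ALPHABET) + DIPEPTIDES,
    "PSSM": tuple(a + b for a in AA_ALPHABET for b in AA_ALPHABET),
}

_MM_PERMUTATION = np.array([AA_INDEX[aa] for aa in MM_ORDER])


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-dimension real vector tagged with its encoding scheme."""

    scheme: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_DIMS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (SCHEME_DIMS[self.scheme],):
            raise ValidationError(
                f"scheme {self.scheme} expects dimension {SCHEME_DIMS[self.scheme]}, "
                f"got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def dimension(self) -> int:
        return SCHEME_DIMS[self.scheme]


def _codes(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(
            f"non-standard residue {exc.args[0]!r}; validate the sequence first"
        ) from None


def aa_composition(sequence: str) -> FeatureVector:
    """Fraction of each amino acid, alphabetical order (dimension 20)."""
    if not sequence:
        raise ValidationError("amino-acid composition of an empty sequence")
    counts = np.bincount(_codes(sequence), minlength=20)
    return FeatureVector("AC", counts / len(sequence))


def dipeptide_composition(sequence: str) -> FeatureVector:
    """Fraction of each ordered residue pair over overlapping windows.

    The denominator is L−1, the number of dipeptide windows actually
    present in the sequence.
    """
    if len(sequence) < 2:
        raise ValidationError("dipeptide composition needs length >= 2")
    codes = _codes(sequence)
    pair_idx = codes[:-1] * 20 + codes[1:]
    counts = np.bincount(pair_idx, minlength=400)
    return FeatureVector("DC", counts / (len(sequence) - 1))


def mm_profile(sequence: str) -> FeatureVector:
    """AC fractions re-indexed by the fixed most-to-least-abundant order."""
    ac = aa_composition(sequence)
    return FeatureVector("MM", ac.values[_MM_PERMUTATION])


def hybrid_composition(sequence: str) -> FeatureVector:
    """Concatenation of AC (20) and DC (400) into one 420-vector."""
    ac = aa_composition(sequence)
    dc = dipeptide_composition(sequence)
    return FeatureVector("HYBRID", np.concatenate([ac.values, dc.values]))


_SEQUENCE_ENCODERS = {
    "AC": aa_composition,
    "DC": dipeptide_composition,
    "MM": mm_profile,
    "HYBRID": hybrid_composition,
}


def encode_sequence(sequence: str, scheme: str) -> FeatureVector:
    """Encode one sequence under a sequence-only scheme (not PSSM)."""
    try:
        encoder = _SEQUENCE_ENCODERS[scheme]
    except KeyError:
        raise ValueError(
            f"scheme {scheme!r} is not sequence-only; valid: {sorted(_SEQUENCE_ENCODERS)}"
        ) from None
    return encoder(sequence)


def feature_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    """Stack same-scheme feature vectors into an (n, d) array."""
    if not features:
        raise ValidationError("no feature vectors to stack")
    scheme = features[0].scheme
    if any(f.scheme != scheme for f in features):
        raise ValidationError("mixed encoding schemes in one matrix")
    return np.vstack([f.values for f in features])


def write_feature_tsv(
    ids: Sequence[str], features: Sequence[FeatureVector], path: str | Path
) -> None:
    """Write features as TSV: id column then one column per component."""
    matrix = feature_matrix(features)
    labels = SCHEME_LABELS[features[0].scheme]
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *labels]) + "\n")
        for rec_id, row in zip(ids, matrix):
            fh.write(rec_id + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def write_svmlight(
    features: Sequence[FeatureVector],
    labels: Iterable[int],
    path: str | Path,
) -> None:
    """Write features in SVMlight sparse format with 1-based indices.

    Labels follow the positive/negative convention: +1 for the positive
    class, −1 for the negative class.
    """
    X = feature_matrix(features)
    y = np.asarray(list(labels), dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("label count does not match feature count")
    with open(path, "wb") as fh:
        dump_svmlight_file(X, y, fh, zero_based=False)
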