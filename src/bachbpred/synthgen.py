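"""Synthetic labeled datasets with the compositional structure the
classifier assumes.

Real bacterial hemoglobin-like (HbL) proteins differ from background
proteins only subtly in bulk composition: alanine, glutamate and
histidine are each about 0.5 percentage points more frequent in HbL,
while serine and threonine are correspondingly enriched in non-HbL.
Within HbL, single-domain hemoglobins (sHb) are lysine-rich (K above
8%), with isoleucine and asparagine elevated; truncated hemoglobins
(trHb) are arginine-enriched and depleted in D/F/P/W; flavohemoglobins
(flavoHb) are mildly depleted in A/G/Q/S/T/V.  The generator encodes
exactly these directional biases as deviations from a uniform 5%
baseline, drawn i.i.d. per residue, with class-specific length ranges
(flavoHb 300–500 aa; sHb 110–160 and trHb 100–140 as plausible globin
lengths).

A single ``separation`` knob scales every profile's deviation from the
uniform baseline: 0 collapses all classes onto the same composition
(downstream accuracy falls to chance), 1 reproduces the real-data-scale
biases above, and larger values give cleanly separable classes for
end-to-end pipeline checks.

Because every encoder in this package is composition-based, i.i.d.
sampling is sufficient; no positional motif structure is simulated.
Synthetic PSSM fixtures place a high signal-scaled score in each
position's own-residue column against a noisy background, which is
enough to exercise the full PSSM path (parse → normalize → compose).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .alphabet import AA_ALPHABET, AA_INDEX
from .errors import ValidationError
from .pssm import PSSMatrix
from .seqio import LabeledDataset, ProteinRecord

_UNIFORM = np.full(20, 0.05)

#: Per-class deviations (at separation 1) from the uniform baseline and
#: sequence length ranges.  HbL classes share the A/E/H enrichment.
_HBL_DELTA = {"A": 0.005, "E": 0.005, "H": 0.005}
_CLASS_SPECS: dict[str, tuple[dict[str, float], tuple[int, int]]] = {
    "nonHbL": ({"S": 0.005, "T": 0.005}, (100, 500)),
    "sHb": ({**_HBL_DELTA, "K": 0.04, "I": 0.01, "N": 0.01}, (110, 160)),
    "flavoHb": (
        {**_HBL_DELTA, "G": -0.004, "Q": -0.004, "S": -0.004, "T": -0.004, "V": -0.004},
        (300, 500),
    ),
    "trHb": (
        {**_HBL_DELTA, "R": 0.02, "D": -0.004, "F": -0.004, "P": -0.004, "W": -0.004},
        (100, 140),
    ),
}

#: Synthetic flavoHb domain-subgroup biases (added on top of the flavoHb
#: deltas).  Real data carries no published compositional signature for
#: these subgroups; disjoint marker residues are a synthetic construct
#: that merely makes the stage-3 task learnable.
_DOMAIN_SPECS: dict[str, dict[str, float]] = {
    "fg_FAD_insig": {"C": 0.02},
    "fg_cyto_FAD_NAD": {"M": 0.02},
    "fg_FAD": {"W": 0.02},
}

#: Per-class sizes of the curated study collections: 333 HbL proteins
#: (217 flavoHb + 87 trHb + 29 sHb) against 337 non-HbL controls.
STUDY_COUNTS: dict[str, int] = {"nonHbL": 337, "sHb": 29, "flavoHb": 217, "trHb": 87}

#: Class name -> (binary, subfamily, domain) label triple.
CLASS_LABELS: dict[str, tuple[str, str | None, str | None]] = {
    "nonHbL": ("nonHbL", None, None),
    "sHb": ("HbL", "sHb", "single_domain"),
    "flavoHb": ("HbL", "flavoHb", None),
    "trHb": ("HbL", "trHb", "trunc_domain"),
    "fg_FAD_insig": ("HbL", "flavoHb", "fg_FAD_insig"),
    "fg_cyto_FAD_NAD": ("HbL", "flavoHb", "fg_cyto_FAD_NAD"),
    "fg_FAD": ("HbL", "flavoHb", "fg_FAD"),
}


@dataclass(frozen=True)
class ClassProfile:
    """Residue sampling distribution and length range for one class."""

    name: str
    aa_probs: np.ndarray
    length_range: tuple[int, int]

    def __post_init__(self) -> None:
        probs = np.asarray(self.aa_probs, dtype=float)
        if probs.shape != (20,):
            raise ValidationError("profile needs 20 residue probabilities")
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-12:
            raise ValidationError("profile probabilities must be >=0 and sum to 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValidationError("length range must satisfy 2 <= min <= max")
        object.__setattr__(self, "aa_probs", probs)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: profiles, size per class, seed, separation.

    ``n_per_class`` is either one count for every class or a mapping
    from profile name to count, which lets a dataset mirror the study's
    unequal subfamily sizes (217 flavoHb : 87 trHb : 29 sHb against 337
    non-HbL).
    """

    profiles: tuple[ClassProfile, ...]
    n_per_class: int | Mapping[str, int] = 100
    seed: int = 0
    separation: float = 1.0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValidationError("separation must be non-negative")
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if isinstance(self.n_per_class, Mapping):
            missing = [p.name for p in self.profiles if p.name not in self.n_per_class]
            if missing:
                raise ValidationError(f"n_per_class missing classes: {missing}")
            counts = dict(self.n_per_class)
        else:
            counts = {p.name: self.n_per_class for p in self.profiles}
        if min(counts.values()) < 1:
            raise ValidationError("every class count must be at least 1")
        object.__setattr__(self, "_counts", counts)

    def count(self, name: str) -> int:
        return self._counts[name]


def _profile_from_deltas(
    name: str, deltas: dict[str, float], length_range: tuple[int, int]
) -> ClassProfile:
    probs = _UNIFORM.copy()
    for aa, delta in deltas.items():
        probs[AA_INDEX[aa]] += delta
    probs = np.clip(probs, 0.0, None)
    return ClassProfile(name=name, aa_probs=probs / probs.sum(), length_range=length_range)


def default_profiles(include_domains: bool = False) -> list[ClassProfile]:
    """The four study classes (plus, optionally, flavoHb domain subgroups).

    With ``include_domains`` the undivided flavoHb profile is replaced by
    its three domain-subgroup variants so the stage-3 task has labels.
    """
    profiles = [
        _profile_from_deltas(name, deltas, lengths)
        for name, (deltas, lengths) in _CLASS_SPECS.items()
    ]
    if include_domains:
        flavo_deltas, flavo_lengths = _CLASS_SPECS["flavoHb"]
        domain_profiles = [
            _profile_from_deltas(name, {**flavo_deltas, **extra}, flavo_lengths)
            for name, extra in _DOMAIN_SPECS.items()
        ]
        profiles = [p for p in profiles if p.name != "flavoHb"] + domain_profiles
    return profiles


def scale_separation(profile: ClassProfile, separation: float) -> ClassProfile:
    """Rescale a profile's deviation from the uniform baseline."""
    probs = np.clip(_UNIFORM + separation * (profile.aa_probs - _UNIFORM), 0.0, None)
    return ClassProfile(
        name=profile.name, aa_probs=probs / probs.sum(), length_range=profile.length_range
    )


def generate_dataset(config: SynthConfig) -> LabeledDataset:
    """Draw ``n_per_class`` i.i.d. sequences per class profile.

    Sequence lengths are uniform in each class's range; residues are
    drawn independently from the (separation-scaled) class composition.
    Output is byte-deterministic under the seed.  Label maps are built
    for every task the profile names support (binary always; subfamily
    and domain where defined in :data:`CLASS_LABELS`).
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(AA_ALPHABET))
    records: list[ProteinRecord] = []
    labels: dict[str, dict[str, str]] = {"binary": {}, "subfamily": {}, "domain": {}}
    for profile in config.profiles:
        scaled = scale_separation(profile, config.separation)
        try:
            binary, subfamily, domain = CLASS_LABELS[profile.name]
        except KeyError:
            binary, subfamily, domain = profile.name, None, None
        lo, hi = scaled.length_range
        for i in range(config.count(profile.name)):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=scaled.aa_probs))
            rec_id = f"{profile.name}_{i:04d}"
            records.append(
                ProteinRecord(
                    id=rec_id,
                    description=f"synthetic {profile.name} sequence",
                    sequence=seq,
                )
            )
            labels["binary"][rec_id] = binary
            if subfamily:
                labels["subfamily"][rec_id] = subfamily
            if domain:
                labels["domain"][rec_id] = domain
    # Emit the domain task only when it covers every HbL record; a partial
    # table (e.g. flavoHb generated without its subgroups) is unusable for
    # training the five-way stage-3 models.
    hbl_ids = {i for i, lbl in labels["binary"].items() if lbl == "HbL"}
    if set(labels["domain"]) != hbl_ids:
        labels["domain"] = {}
    labels = {task: table for task, table in labels.items() if table}
    return LabeledDataset(records=records, labels=labels)


def generate_pssm(record: ProteinRecord, signal: float = 0.9, seed: int = 0) -> PSSMatrix:
    """Synthetic integer PSSM for one record.

    The column matching each position's residue scores around
    ``300 + 600*signal`` with integer noise of amplitude scaled by
    (1 − signal); all other columns draw from a low background in
    [−500, −100).  At signal 1 the own-residue column is exactly the row
    maximum, so the normalized row peaks at 1 there.
    """
    if not 0.0 <= signal <= 1.0:
        raise ValidationError("signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    length = len(record.sequence)
    scores = rng.integers(-500, -100, size=(length, 20))
    noise_amp = int(round(200 * (1.0 - signal)))
    peak = int(round(300 + 600 * signal))
    codes = [AA_INDEX[c] for c in record.sequence]
    for i, j in enumerate(codes):
        noise = int(rng.integers(-noise_amp, noise_amp + 1)) if noise_amp else 0
        scores[i, j] = peak + noise
    return PSSMatrix(sequence=record.sequence, scores=scores)
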