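"""FASTA input/output, sequence validation, and dataset curation.

The curation steps mirror how the HbL training set was assembled from a
raw UniProt keyword search: entries whose annotation marks them as
fragments, isoforms or otherwise uncertain are dropped, and a greedy
redundancy filter removes sequences more than 90% identical to one
already retained.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .alphabet import AA_ALPHABET
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_AA_SET = frozenset(AA_ALPHABET)

#: Annotation keywords whose presence flags an entry for removal.
#: Singular forms so that plurals also match as substrings.
DEFAULT_EXCLUDE_KEYWORDS = ("fragment", "isoform", "potential", "similarity", "probable")

#: Remapping of ambiguous residue codes onto their most common standard
#: counterpart (B = Asx -> D, Z = Glx -> E, U = selenocysteine -> C).
AMBIGUOUS_REMAP = {"B": "D", "Z": "E", "U": "C"}


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its FASTA header split in two."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered protein records plus one id -> label map per labeling task.

    ``labels`` is keyed by task name ("binary", "subfamily", "domain");
    each task maps record ids to a single class label.  Records without a
    label for a task (e.g. non-HbL records in the subfamily task) are
    simply absent from that task's map.
    """

    records: list[ProteinRecord]
    labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {', '.join(dup)}")

    def record_map(self) -> dict[str, ProteinRecord]:
        return {r.id: r for r in self.records}

    def task_labels(self, task: str) -> dict[str, str]:
        try:
            return self.labels[task]
        except KeyError:
            raise ValidationError(
                f"no labels for task {task!r}; available: {sorted(self.labels)}"
            ) from None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header is split into an id (first whitespace-delimited token) and a
    free-text description (the remainder).  Sequences are uppercased with
    internal whitespace removed.  Duplicate ids raise a
    :class:`ValidationError`.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.description
            parts = header.split(None, 1)
            rec_id = parts[0] if parts else rec.id
            description = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise ValidationError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            seq = "".join(str(rec.seq).split()).upper()
            records.append(ProteinRecord(id=rec_id, description=description, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def validate_sequence(record: ProteinRecord, policy: str = "reject") -> ProteinRecord:
    """Enforce the 20-letter alphabet on a record's sequence.

    policy
        ``reject`` — raise on any non-standard character, listing the
        offending positions (the default: silent data corruption is
        impossible unless explicitly requested);
        ``strip`` — drop non-standard characters;
        ``remap`` — map B→D, Z→E, U→C, strip everything else.
    """
    if policy not in ("reject", "strip", "remap"):
        raise ValueError(f"unknown validation policy {policy!r}")
    seq = record.sequence
    bad = [(i, c) for i, c in enumerate(seq) if c not in _AA_SET]
    if not bad:
        if not seq:
            raise ValidationError(f"record {record.id!r}: empty sequence")
        return record
    if policy == "reject":
        detail = ", ".join(f"{c!r}@{i}" for i, c in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValidationError(
            f"record {record.id!r}: non-standard residues {detail}{more}"
        )
    if policy == "strip":
        cleaned = "".join(c for c in seq if c in _AA_SET)
    else:  # remap
        cleaned = "".join(
            c if c in _AA_SET else AMBIGUOUS_REMAP.get(c, "") for c in seq
        )
    if not cleaned:
        raise ValidationError(
            f"record {record.id!r}: sequence empty after {policy} cleaning"
        )
    return ProteinRecord(id=record.id, description=record.description, sequence=cleaned)


def filter_annotations(
    records: list[ProteinRecord],
    keywords: Iterable[str] = DEFAULT_EXCLUDE_KEYWORDS,
) -> list[ProteinRecord]:
    """Drop records whose description contains any keyword.

    Matching is case-insensitive substring search on the description only
    (never the id).  An empty keyword list retains everything.
    """
    kws = [k.lower() for k in keywords]
    kept = [
        r for r in records if not any(k in r.description.lower() for k in kws)
    ]
    logger.info(
        "filter_annotations: %d removed, %d retained", len(records) - len(kept), len(kept)
    )
    return kept


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity between two sequences.

    Needleman–Wunsch with match 1, mismatch 0, linear gap −1; identity is
    the number of identical aligned positions divided by the shorter
    sequence's length.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def reduce_redundancy(
    records: list[ProteinRecord], identity_cutoff: float = 0.9
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy reduction.

    Records are sorted by length descending (ties by id); each record is
    retained iff its identity to every already-retained record is at or
    below ``identity_cutoff``.  This is the deterministic, desk-scale
    equivalent of a CD-HIT style 90% clustering.
    """
    if not records:
        raise ValidationError("reduce_redundancy requires at least one record")
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity_cutoff must be in (0, 1]")
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    retained: list[ProteinRecord] = []
    for rec in ordered:
        if all(
            pairwise_identity(rec.sequence, kept.sequence, aligner) <= identity_cutoff
            for kept in retained
        ):
            retained.append(rec)
    logger.info(
        "reduce_redundancy: cutoff %.2f, %d removed, %d retained",
        identity_cutoff,
        len(records) - len(retained),
        len(retained),
    )
    order = {r.id: i for i, r in enumerate(records)}
    return sorted(retained, key=lambda r: order[r.id])


def read_labels(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a label table (TSV with an ``id`` column plus one column per task).

    Empty cells mean "no label for this task".  A headerless two-column
    file is read as a single task named ``binary``.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty label table")
    header = lines[0].split("\t")
    if header[0] != "id":
        header = ["id", "binary"]
        body = lines
    else:
        body = lines[1:]
    tasks: dict[str, dict[str, str]] = {t: {} for t in header[1:]}
    for lineno, line in enumerate(body, start=1):
        fields = line.split("\t")
        if len(fields) > len(header):
            raise ParseError(f"{path}:{lineno}: expected <= {len(header)} columns")
        rec_id = fields[0]
        for task, value in zip(header[1:], fields[1:]):
            if value:
                tasks[task][rec_id] = value
    return tasks


def write_labels(labels: dict[str, dict[str, str]], path: str | Path) -> None:
    """Write a label table as TSV (one column per task, empty = unlabeled)."""
    tasks = sorted(labels)
    ids: list[str] = []
    seen: set[str] = set()
    for task in tasks:
        for rec_id in labels[task]:
            if rec_id not in seen:
                seen.add(rec_id)
                ids.append(rec_id)
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *tasks]) + "\n")
        for rec_id in ids:
            row = [rec_id] + [labels[task].get(rec_id, "") for task in tasks]
            fh.write("\t".join(row) + "\n")


def _main_check() -> None:  # pragma: no cover
    for p in sys.argv[1:]:
        recs = read_fasta(p)
        print(f"{p}: {len(recs)} records")


if __name__ == "__main__":  # pragma: no cover
    _main_check()
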