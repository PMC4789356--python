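"""Three-stage hierarchical prediction of bacterial hemoglobin-like proteins.

Stage 1 decides HbL vs non-HbL with a single binary RBF-SVM at decision
threshold 0.0.  For sequences called HbL, stage 2 assigns one of the
three subfamilies — single-domain hemoglobin (sHb), flavohemoglobin
(flavoHb), truncated hemoglobin (trHb) — by the argmax of three
one-vs-rest decision scores; if all three scores are negative the
sequence is left an unclassified HbL.  Stage 3 assigns one of five
domain-architecture subgroups the same way: three flavoHb subgroups
(FAD-insignificant flavoglobin, globin-cyto-FAD/NAD, globin-FAD) plus
the single-domain and truncated-globin tasks.  The single-domain and
truncated-domain tasks coincide with the sHb and trHb subfamily tasks
(identical positive sets within HbL), so those two models are shared
rather than retrained.

Argmax ties break deterministically by fixed task order (sHb < flavoHb
< trHb; domain tasks in registry order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import svm
from .encoders import FeatureVector, encode_sequence
from .errors import ModelError, ValidationError
from .pssm import PSSMatrix, NormalizedPSSM, normalize_pssm, pssm_composition
from .seqio import LabeledDataset, ProteinRecord
from .svm import SVMParams, TrainedModel

SCHEMES = ("AC", "DC", "MM", "HYBRID", "PSSM")

BINARY_TASK = "HbL_vs_non"
SUBFAMILY_TASKS = ("sHb", "flavoHb", "trHb")
DOMAIN_TASKS = (
    "fg_FAD_insig",
    "fg_cyto_FAD_NAD",
    "fg_FAD",
    "single_domain",
    "trunc_domain",
)
ALL_TASKS = (BINARY_TASK, *SUBFAMILY_TASKS, *DOMAIN_TASKS)

#: Domain tasks whose positive set equals a subfamily task's; the model
#: is shared, not retrained, to avoid silent divergence.
SHARED_DOMAIN_TASKS = {"single_domain": "sHb", "trunc_domain": "trHb"}

#: Per-task, per-scheme (gamma, C) defaults for the RBF-SVM, as tuned on
#: the original curated HbL/non-HbL training collections.
_DEFAULT_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    (BINARY_TASK, "AC"): (25, 400),
    (BINARY_TASK, "DC"): (1, 375),
    (BINARY_TASK, "PSSM"): (1, 300),
    (BINARY_TASK, "MM"): (25, 450),
    (BINARY_TASK, "HYBRID"): (0.1, 375),
    ("sHb", "AC"): (15, 9),
    ("sHb", "DC"): (0.2, 250),
    ("sHb", "PSSM"): (5, 7),
    ("sHb", "MM"): (1, 150),
    ("sHb", "HYBRID"): (0.1, 350),
    ("flavoHb", "AC"): (10, 300),
    ("flavoHb", "DC"): (1, 350),
    ("flavoHb", "PSSM"): (1, 350),
    ("flavoHb", "MM"): (10, 300),
    ("flavoHb", "HYBRID"): (1, 150),
    ("trHb", "AC"): (5, 350),
    ("trHb", "DC"): (1, 275),
    ("trHb", "PSSM"): (1, 400),
    ("trHb", "MM"): (4, 500),
    ("trHb", "HYBRID"): (1, 150),
    ("fg_FAD_insig", "AC"): (50, 200),
    ("fg_FAD_insig", "DC"): (2, 250),
    ("fg_FAD_insig", "PSSM"): (2, 400),
    ("fg_FAD_insig", "MM"): (25, 450),
    ("fg_FAD_insig", "HYBRID"): (1, 450),
    ("fg_cyto_FAD_NAD", "AC"): (10, 200),
    ("fg_cyto_FAD_NAD", "DC"): (5, 200),
    ("fg_cyto_FAD_NAD", "PSSM"): (2, 500),
    ("fg_cyto_FAD_NAD", "MM"): (25, 400),
    ("fg_cyto_FAD_NAD", "HYBRID"): (3, 350),
    ("fg_FAD", "AC"): (10, 275),
    ("fg_FAD", "DC"): (1, 275),
    ("fg_FAD", "PSSM"): (1, 500),
    ("fg_FAD", "MM"): (15, 500),
    ("fg_FAD", "HYBRID"): (1, 200),
}
# Shared domain tasks inherit their subfamily task's parameters.
for _dom, _sub in SHARED_DOMAIN_TASKS.items():
    for _scheme in SCHEMES:
        _DEFAULT_PARAMS[(_dom, _scheme)] = _DEFAULT_PARAMS[(_sub, _scheme)]


def default_params(task: str, scheme: str) -> SVMParams:
    """Return the default (gamma, C) pair for a task/scheme combination."""
    try:
        gamma, cost = _DEFAULT_PARAMS[(task, scheme)]
    except KeyError:
        valid_tasks = sorted({t for t, _ in _DEFAULT_PARAMS})
        raise ValidationError(
            f"no default parameters for ({task!r}, {scheme!r}); "
            f"tasks: {valid_tasks}, schemes: {sorted(SCHEMES)}"
        ) from None
    return SVMParams(gamma=gamma, cost=cost)


def encode_record(
    record: ProteinRecord,
    scheme: str,
    pssm: PSSMatrix | NormalizedPSSM | None = None,
) -> FeatureVector:
    """Encode one record under any scheme, including PSSM."""
    if scheme == "PSSM":
        if pssm is None:
            raise ValidationError(
                f"record {record.id!r}: PSSM scheme requires a scoring matrix"
            )
        if pssm.sequence != record.sequence:
            raise ValidationError(
                f"record {record.id!r}: PSSM sequence does not match record sequence"
            )
        npssm = pssm if isinstance(pssm, NormalizedPSSM) else normalize_pssm(pssm)
        return pssm_composition(npssm)
    return encode_sequence(record.sequence, scheme)


@dataclass
class ModelRegistry:
    """One trained binary model (and its parameters) per hierarchy task."""

    scheme: str
    models: dict[str, TrainedModel] = field(default_factory=dict)
    params: dict[str, SVMParams] = field(default_factory=dict)
    seed: int = 0

    def model(self, task: str) -> TrainedModel:
        try:
            return self.models[task]
        except KeyError:
            raise ModelError(
                f"no model for task {task!r}; available: {sorted(self.models)}"
            ) from None


@dataclass
class HierarchicalPrediction:
    """Scores and calls from the three prediction stages for one record.

    ``subfamily``/``domain`` are None either because stage 1 called the
    record non-HbL (the score dicts are then empty) or because every
    one-vs-rest score was negative (an unclassified HbL).
    """

    record_id: str
    stage1_score: float
    stage1_label: str  # "HbL" or "nonHbL"
    subfamily_scores: dict[str, float] = field(default_factory=dict)
    subfamily: str | None = None
    domain_scores: dict[str, float] = field(default_factory=dict)
    domain: str | None = None


def _labels_for_task(
    dataset: LabeledDataset, task: str
) -> tuple[list[str], np.ndarray]:
    """Ids and ±1 labels for one binary task of the hierarchy."""
    if task == BINARY_TASK:
        table = dataset.task_labels("binary")
        ids = [r.id for r in dataset.records if r.id in table]
        y = np.array([1 if table[i] == "HbL" else -1 for i in ids])
    elif task in SUBFAMILY_TASKS:
        binary = dataset.task_labels("binary")
        table = dataset.task_labels("subfamily")
        ids = [r.id for r in dataset.records if binary.get(r.id) == "HbL"]
        missing = [i for i in ids if i not in table]
        if missing:
            raise ValidationError(f"HbL records without subfamily label: {missing[:5]}")
        y = np.array([1 if table[i] == task else -1 for i in ids])
    elif task in DOMAIN_TASKS:
        binary = dataset.task_labels("binary")
        table = dataset.task_labels("domain")
        ids = [r.id for r in dataset.records if binary.get(r.id) == "HbL"]
        missing = [i for i in ids if i not in table]
        if missing:
            raise ValidationError(f"HbL records without domain label: {missing[:5]}")
        y = np.array([1 if table[i] == task else -1 for i in ids])
    else:
        raise ValidationError(f"unknown task {task!r}")
    return ids, y


def train_hierarchy(
    dataset: LabeledDataset,
    scheme: str,
    registry_params: Mapping[str, SVMParams] | None = None,
    seed: int = 0,
    pssms: Mapping[str, PSSMatrix] | None = None,
) -> ModelRegistry:
    """Train one binary model per hierarchy task (one-vs-rest within HbL).

    ``registry_params`` overrides the per-task defaults; the shared
    single-domain/truncated-domain models are aliased to their subfamily
    counterparts.  Every task needs both a positive and a negative
    training example.  If the dataset carries no domain-level labels the
    non-shared domain models are skipped and stage 3 is unavailable.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    features: dict[str, FeatureVector] = {}
    for rec in dataset.records:
        pssm = pssms.get(rec.id) if pssms else None
        features[rec.id] = encode_record(rec, scheme, pssm=pssm)
    registry = ModelRegistry(scheme=scheme, seed=seed)
    have_domain_labels = "domain" in dataset.labels
    for task in ALL_TASKS:
        if task in DOMAIN_TASKS and task not in SHARED_DOMAIN_TASKS and not have_domain_labels:
            continue
        params = (
            registry_params[task]
            if registry_params and task in registry_params
            else default_params(task, scheme)
        )
        registry.params[task] = params
        if task in SHARED_DOMAIN_TASKS:
            registry.models[task] = registry.models[SHARED_DOMAIN_TASKS[task]]
            continue
        ids, y = _labels_for_task(dataset, task)
        if len(set(y.tolist())) < 2:
            raise ValidationError(
                f"task {task!r} has a single class in the training data"
            )
        X = np.vstack([features[i].values for i in ids])
        registry.models[task] = svm.train(X, y, params, seed=seed, scheme=scheme)
    return registry


def _argmax_call(scores: dict[str, float], order: tuple[str, ...]) -> str | None:
    """Highest-scoring task, ties broken by fixed order; None if all < 0."""
    best: str | None = None
    best_score = -np.inf
    for task in order:
        if scores[task] > best_score:
            best, best_score = task, scores[task]
    return best if best_score >= 0.0 else None


def predict_full(
    record: ProteinRecord,
    registry: ModelRegistry,
    pssm: PSSMatrix | NormalizedPSSM | None = None,
) -> HierarchicalPrediction:
    """Run all three stages on one record.

    Stage 1 calls HbL iff the binary score is at or above the threshold;
    stages 2 and 3 run only on HbL-positive records.
    """
    feature = encode_record(record, registry.scheme, pssm=pssm)
    binary_model = registry.model(BINARY_TASK)
    score1 = svm.decision_score(binary_model, feature)
    prediction = HierarchicalPrediction(
        record_id=record.id,
        stage1_score=score1,
        stage1_label="HbL" if score1 >= binary_model.threshold else "nonHbL",
    )
    if prediction.stage1_label != "HbL":
        return prediction
    prediction.subfamily_scores = {
        task: svm.decision_score(registry.model(task), feature)
        for task in SUBFAMILY_TASKS
    }
    prediction.subfamily = _argmax_call(prediction.subfamily_scores, SUBFAMILY_TASKS)
    if all(task in registry.models for task in DOMAIN_TASKS):
        prediction.domain_scores = {
            task: svm.decision_score(registry.model(task), feature)
            for task in DOMAIN_TASKS
        }
        prediction.domain = _argmax_call(prediction.domain_scores, DOMAIN_TASKS)
    return prediction


def save_registry(registry: ModelRegistry, directory: str | Path) -> None:
    """Save every model plus a manifest into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "bachbpred-registry",
        "version": 1,
        "scheme": registry.scheme,
        "seed": registry.seed,
        "tasks": {},
        "shared": dict(SHARED_DOMAIN_TASKS),
    }
    for task, model in registry.models.items():
        if task in SHARED_DOMAIN_TASKS:
            continue
        filename = f"{task}.json"
        svm.save_model(model, directory / filename)
        manifest["tasks"][task] = filename
    for task in registry.params:
        manifest.setdefault("params", {})[task] = {
            "gamma": registry.params[task].gamma,
            "cost": registry.params[task].cost,
        }
    with open(directory / "registry.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def load_registry(directory: str | Path) -> ModelRegistry:
    """Load a registry written by :func:`save_registry`."""
    directory = Path(directory)
    manifest_path = directory / "registry.json"
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise ModelError(f"{directory}: no registry.json manifest") from None
    except json.JSONDecodeError as exc:
        raise ModelError(f"{manifest_path}: corrupted manifest ({exc})") from None
    if manifest.get("format") != "bachbpred-registry" or manifest.get("version") != 1:
        raise ModelError(f"{manifest_path}: unsupported registry format/version")
    registry = ModelRegistry(scheme=manifest["scheme"], seed=int(manifest.get("seed", 0)))
    for task, filename in manifest["tasks"].items():
        registry.models[task] = svm.load_model(directory / filename)
    for task, alias in manifest.get("shared", {}).items():
        registry.models[task] = registry.models[alias]
    for task, p in manifest.get("params", {}).items():
        registry.params[task] = SVMParams(gamma=p["gamma"], cost=p["cost"])
    return registry
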