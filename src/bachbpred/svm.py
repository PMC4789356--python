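"""Soft-margin RBF-kernel SVM binary classifiers.

The decision function is the standard kernel expansion

    f(x) = sum_i alpha_i y_i K(x_i, x) + b,      K(x, y) = exp(-gamma ||x - y||^2)

with box constraint C on the dual coefficients.  The dual problem is
solved by libsvm (through scikit-learn); the fitted expansion — support
vectors, signed dual coefficients, bias — is extracted into a plain
:class:`TrainedModel` so that scoring, serialization and reloading are
exact and independent of the fitting backend.

Classification uses a decision threshold (default 0.0): a score at or
above the threshold is called positive.  Scores exactly at the threshold
classify positive by convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .encoders import SCHEME_DIMS, FeatureVector
from .errors import ModelError, ValidationError

MODEL_FORMAT = "bachbpred-svm"
MODEL_VERSION = 1


@dataclass(frozen=True)
class SVMParams:
    """RBF kernel width gamma and regularization cost C, both positive."""

    gamma: float
    cost: float

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.cost > 0):
            raise ValueError("gamma and cost must both be positive")


@dataclass
class TrainedModel:
    """A fitted RBF-SVM decision function with its decision threshold."""

    scheme: str
    params: SVMParams
    support_vectors: np.ndarray  # (n_sv, d)
    dual_coef: np.ndarray  # (n_sv,), alpha_i * y_i, signed
    bias: float
    threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sv = np.asarray(self.support_vectors, dtype=float)
        dc = np.asarray(self.dual_coef, dtype=float)
        if sv.ndim != 2 or sv.shape[0] != dc.shape[0]:
            raise ModelError("support vector / dual coefficient shape mismatch")
        if self.scheme in SCHEME_DIMS and sv.shape[1] != SCHEME_DIMS[self.scheme]:
            raise ModelError(
                f"scheme {self.scheme} expects dimension {SCHEME_DIMS[self.scheme]}, "
                f"support vectors have {sv.shape[1]}"
            )
        if not (np.any(dc > 0) and np.any(dc < 0)):
            raise ModelError("model must have support vectors of both class signs")
        self.support_vectors = sv
        self.dual_coef = dc

    @property
    def dimension(self) -> int:
        return self.support_vectors.shape[1]


def _as_matrix(features: Sequence[FeatureVector] | np.ndarray) -> tuple[np.ndarray, str | None]:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float), None
    scheme = features[0].scheme
    if any(f.scheme != scheme for f in features):
        raise ValidationError("mixed encoding schemes in training data")
    return np.vstack([f.values for f in features]), scheme


def train(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[int],
    params: SVMParams,
    seed: int = 0,
    scheme: str | None = None,
    threshold: float = 0.0,
    tol: float = 1e-3,
) -> TrainedModel:
    """Fit an RBF-SVM on ±1-labeled feature vectors.

    Deterministic given the seed and the input order; both classes must
    be present.  ``scheme`` is inferred from FeatureVector inputs and
    must be supplied for raw arrays.
    """
    X, inferred = _as_matrix(features)
    scheme = scheme or inferred
    if scheme is None:
        raise ValidationError("scheme must be given when training on raw arrays")
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("label count does not match feature count")
    if set(np.unique(y)) != {-1, 1}:
        raise ValidationError("labels must contain both +1 and -1")
    clf = SVC(
        kernel="rbf",
        gamma=params.gamma,
        C=params.cost,
        tol=tol,
        random_state=seed,
        cache_size=200,
    )
    clf.fit(X, y)
    # classes_ is [-1, 1]; decision_function > 0 corresponds to class +1,
    # and dual_coef_ already carries the alpha_i * y_i signs.
    return TrainedModel(
        scheme=scheme,
        params=params,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        threshold=threshold,
        seed=seed,
    )


def _check_input(model: TrainedModel, x: FeatureVector | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureVector):
        if x.scheme != model.scheme:
            raise ModelError(
                f"feature scheme {x.scheme} does not match model scheme {model.scheme}"
            )
        vec = x.values
    else:
        vec = np.asarray(x, dtype=float)
    if vec.shape != (model.dimension,):
        raise ModelError(
            f"feature dimension {vec.shape} does not match model dimension "
            f"{model.dimension}"
        )
    return vec


def decision_score(model: TrainedModel, x: FeatureVector | np.ndarray) -> float:
    """Evaluate the kernel expansion f(x) at one point."""
    vec = _check_input(model, x)
    diff = model.support_vectors - vec
    kernel = np.exp(-model.params.gamma * np.einsum("ij,ij->i", diff, diff))
    return float(model.dual_coef @ kernel + model.bias)


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decision_score` over the rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.dimension:
        raise ModelError(f"expected (n, {model.dimension}) array, got {X.shape}")
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(model.support_vectors**2, axis=1)[None, :]
        - 2.0 * X @ model.support_vectors.T
    )
    kernel = np.exp(-model.params.gamma * np.maximum(sq, 0.0))
    return kernel @ model.dual_coef + model.bias


def classify(model: TrainedModel, x: FeatureVector | np.ndarray) -> int:
    """+1 iff the decision score is at or above the model threshold."""
    return 1 if decision_score(model, x) >= model.threshold else -1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model losslessly as versioned JSON text.

    Floats are stored via ``repr`` round-tripping (JSON numbers), so a
    reloaded model produces bit-identical decision scores.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "scheme": model.scheme,
        "gamma": model.params.gamma,
        "cost": model.params.cost,
        "bias": model.bias,
        "threshold": model.threshold,
        "seed": model.seed,
        "dual_coef": model.dual_coef.tolist(),
        "support_vectors": model.support_vectors.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model(path: str | Path) -> TrainedModel:
    """Load a model written by :func:`save_model`; explicit on corruption."""
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelError(f"{path}: corrupted model file ({exc})") from None
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelError(f"{path}: not a {MODEL_FORMAT} model file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelError(
            f"{path}: unsupported model version {payload.get('version')!r} "
            f"(expected {MODEL_VERSION})"
        )
    try:
        return TrainedModel(
            scheme=payload["scheme"],
            params=SVMParams(gamma=payload["gamma"], cost=payload["cost"]),
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            bias=float(payload["bias"]),
            threshold=float(payload["threshold"]),
            seed=int(payload.get("seed", 0)),
        )
    except KeyError as exc:
        raise ModelError(f"{path}: missing field {exc.args[0]!r}") from None
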