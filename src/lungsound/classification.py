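"""Binary classifiers: RBF extreme learning machine and RBF-kernel SVM.

The **ELM** is a single-hidden-layer feedforward network whose hidden
parameters (RBF centers and widths) are drawn at random and never
trained; the output weights are the minimum-norm least-squares solution
``beta = pinv(M) @ D`` via the Moore-Penrose pseudoinverse of the hidden
activation matrix M. Ten hidden nodes are the default.

The **SVM** is the standard soft-margin RBF-kernel machine: the dual
problem max ``sum(a) - 0.5 * a' Q a`` subject to ``0 <= a_j <= C`` and
``sum(a_j d_j) = 0`` is solved by libsvm (through scikit-learn), and the
decision function is ``sign(sum_j a_j d_j K(y, y_j) + b)``.

Labels are encoded +1 = abnormal, -1 = normal throughout; a zero
score/margin is broken toward the positive (abnormal) class. Features
should be standardised (zero mean, unit variance, statistics from the
training folds only) before either classifier — RBF distances are not
meaningful across heterogeneous units otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

__all__ = [
    "ELMModel",
    "SVMModel",
    "FeatureScaler",
    "elm_train",
    "elm_predict",
    "svm_train",
    "svm_predict",
    "encode_labels",
    "save_model",
    "load_model",
]

POSITIVE_LABEL = "abnormal"
NEGATIVE_LABEL = "normal"

DEFAULT_N_HIDDEN = 10
PINV_RCOND = 1e-10


def encode_labels(labels) -> np.ndarray:
    """Map class tags to the +/-1 targets (+1 = abnormal)."""
    out = np.empty(len(labels), dtype=np.float64)
    for i, lab in enumerate(labels):
        if lab == POSITIVE_LABEL:
            out[i] = 1.0
        elif lab == NEGATIVE_LABEL:
            out[i] = -1.0
        else:
            raise ValueError(f"unknown label {lab!r}")
    return out


@dataclass(frozen=True)
class FeatureScaler:
    """Zero-mean unit-variance standardisation, fit on training data only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=np.float64)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=X.mean(axis=0), scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale


# ---------------------------------------------------------------------------
# Extreme learning machine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ELMModel:
    """Trained ELM: random RBF hidden layer plus solved output weights.

    ``hidden(X)[p, j] = exp(-widths[j] * ||X_p - centers_j||**2)`` and the
    score is ``hidden(X) @ output_weights``.
    """

    centers: np.ndarray  # (n_hidden, n_features)
    widths: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)
    rng_seed: int
    activation: str = "rbf"

    @property
    def n_hidden(self) -> int:
        return self.centers.shape[0]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.centers.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension "
                f"{self.centers.shape[1]}"
            )
        sq = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.widths[None, :] * sq)


def elm_train(
    X,
    targets,
    n_hidden: int = DEFAULT_N_HIDDEN,
    rng_seed: int = 0,
) -> ELMModel:
    """Fit an RBF-activation extreme learning machine.

    Centers are drawn uniformly over the training bounding box and widths
    uniformly from (0, 1] scaled by the inverse squared median pairwise
    sample distance, so activations stay non-degenerate at the data's own
    scale. The hidden parameters depend only on the seed and on
    order-invariant data statistics (bounding box, median distance), so
    reordering the training set does not change the model. Output weights
    are the minimum-norm least-squares solution via SVD pseudoinverse.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    d = np.asarray(targets, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.all(d > 0) or np.all(d < 0):
        raise ValueError("training data contain a single class")

    rng = np.random.default_rng(rng_seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    centers = lo + span * rng.random((n_hidden, X.shape[1]))
    u = 1.0 - rng.random(n_hidden)  # uniform on (0, 1]
    dists = pdist(X)
    med = float(np.median(dists[dists > 0])) if np.any(dists > 0) else 1.0
    widths = u / med**2

    model = ELMModel(
        centers=centers, widths=widths, output_weights=np.zeros(n_hidden),
        rng_seed=int(rng_seed),
    )
    M = model.hidden(X)
    beta = np.linalg.pinv(M, rcond=PINV_RCOND) @ d
    return ELMModel(
        centers=centers, widths=widths, output_weights=beta, rng_seed=int(rng_seed)
    )


def elm_predict(model: ELMModel, X):
    """Signed scores and +/-1 labels; zero score goes to the positive class."""
    scores = model.hidden(X) @ model.output_weights
    labels = np.where(scores >= 0, 1.0, -1.0)
    return labels, scores


# ---------------------------------------------------------------------------
# Support vector machine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVMModel:
    """Trained soft-margin RBF SVM in dual form.

    ``dual_coefs[j] = alpha_j * d_j`` for each support vector; the margin
    of a point y is ``sum_j dual_coefs[j] * K(y, sv_j) + bias``. ``slack``
    holds the training hinge losses ``max(0, 1 - d_j * margin_j)``.
    """

    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    bias: float
    gamma: float
    C: float
    slack: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def kernel(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension "
                f"{self.support_vectors.shape[1]}"
            )
        sq = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * sq)


def _resolve_gamma(X: np.ndarray, gamma) -> float:
    if gamma == "scale" or gamma is None:
        var = X.var()
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return float(gamma)


def svm_train(X, targets, C: float = 1.0, gamma="scale") -> SVMModel:
    """Solve the soft-margin RBF-kernel dual problem.

    ``gamma="scale"`` resolves to ``1 / (n_features * var(X))``. The
    returned model satisfies the dual box constraint ``0 <= alpha_j <= C``
    and the equality constraint ``sum alpha_j d_j = 0``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    d = np.asarray(targets, dtype=np.float64)
    if np.all(d > 0) or np.all(d < 0):
        raise ValueError("training data contain a single class")
    if not C > 0:
        raise ValueError("C must be positive")
    g = _resolve_gamma(X, gamma)
    svc = SVC(C=C, kernel="rbf", gamma=g, tol=1e-6)
    svc.fit(X, d)
    if svc.fit_status_ != 0:
        raise RuntimeError(
            f"SVM solver did not converge (libsvm fit_status={svc.fit_status_})"
        )
    model = SVMModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coefs=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        gamma=g,
        C=float(C),
    )
    _, margins = svm_predict(model, X)
    slack = np.maximum(0.0, 1.0 - d * margins)
    return SVMModel(
        support_vectors=model.support_vectors,
        dual_coefs=model.dual_coefs,
        bias=model.bias,
        gamma=g,
        C=float(C),
        slack=slack,
    )


def svm_predict(model: SVMModel, X):
    """Signed margins and +/-1 labels; zero margin goes to abnormal (+1)."""
    margins = model.kernel(X) @ model.dual_coefs + model.bias
    labels = np.where(margins >= 0, 1.0, -1.0)
    return labels, margins


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_model(model, path) -> None:
    """Serialise a trained model to JSON for exact reload."""
    if isinstance(model, ELMModel):
        doc = {
            "schema_version": _SCHEMA_VERSION,
            "kind": "elm",
            "centers": model.centers.tolist(),
            "widths": model.widths.tolist(),
            "output_weights": model.output_weights.tolist(),
            "rng_seed": model.rng_seed,
            "activation": model.activation,
        }
    elif isinstance(model, SVMModel):
        doc = {
            "schema_version": _SCHEMA_VERSION,
            "kind": "svm",
            "support_vectors": model.support_vectors.tolist(),
            "dual_coefs": model.dual_coefs.tolist(),
            "bias": model.bias,
            "gamma": model.gamma,
            "C": model.C,
            "slack": model.slack.tolist(),
        }
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    Path(path).write_text(json.dumps(doc))


def load_model(path):
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('schema_version')}")
    if doc["kind"] == "elm":
        return ELMModel(
            centers=np.asarray(doc["centers"], dtype=np.float64),
            widths=np.asarray(doc["widths"], dtype=np.float64),
            output_weights=np.asarray(doc["output_weights"], dtype=np.float64),
            rng_seed=int(doc["rng_seed"]),
            activation=doc["activation"],
        )
    if doc["kind"] == "svm":
        return SVMModel(
            support_vectors=np.asarray(doc["support_vectors"], dtype=np.float64),
            dual_coefs=np.asarray(doc["dual_coefs"], dtype=np.float64),
            bias=float(doc["bias"]),
            gamma=float(doc["gamma"]),
            C=float(doc["C"]),
            slack=np.asarray(doc["slack"], dtype=np.float64),
        )
    raise ValueError(f"unknown model kind {doc['kind']!r}")
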