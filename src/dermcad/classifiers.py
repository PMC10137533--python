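"""Supervised models for melanoma (+1) vs nevus (-1) classification.

All three models share the same contract: ``fit`` on an (n_samples,
n_features) matrix with labels in {-1, +1} and ``predict`` returning labels in
{-1, +1}.  A decision score of exactly zero is resolved to +1 (melanoma), the
safety-first direction for a diagnostic tool.

* **Gentle AdaBoost** is implemented in full: the weak learner is a
  single-feature threshold stump fitted by weighted least squares (region
  responses are the weighted mean of the labels, i.e. the weighted class
  probability difference P_w(y=1|region) - P_w(y=-1|region)), weights are
  updated multiplicatively by exp(-y f(x)) and renormalized each round, and
  the final classifier is the sign of the summed stump responses.
* **kNN** stores the training matrix and votes over the k nearest neighbors
  by Euclidean distance, with explicit deterministic tie rules.
* **SVM** is a soft-margin RBF machine; the quadratic program is delegated to
  scikit-learn's SVC, exposed behind the shared sign-decision contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# Gentle AdaBoost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stump:
    """Threshold stump: response ``left_value`` where feature < threshold,
    ``right_value`` where feature >= threshold; responses lie in [-1, 1]."""

    feature_index: int
    threshold: float
    left_value: float
    right_value: float

    def __post_init__(self) -> None:
        for v in (self.left_value, self.right_value):
            if not np.isfinite(v) or abs(v) > 1.0 + 1e-12:
                raise ValueError("stump responses must be finite and in [-1, 1]")

    def respond(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.feature_index]
        return np.where(col < self.threshold, self.left_value, self.right_value)


@dataclass(frozen=True)
class GABEnsemble:
    """Ordered list of stumps; prediction = sign of summed responses."""

    stumps: tuple[Stump, ...]

    @property
    def M(self) -> int:
        return len(self.stumps)


def _check_Xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match the number of rows of X")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be -1 or +1")
    return X, y


def fit_stump_wls(
    X,
    y,
    w,
    sort_idx: np.ndarray | None = None,
) -> Stump:
    """Exhaustive weighted-least-squares stump fit.

    Scans every (feature, threshold between consecutive distinct sorted
    values) candidate and returns the stump minimizing the weighted squared
    error ``sum_i w_i (y_i - f(x_i))^2``; each region's response is the
    weighted mean of its labels.  Ties break toward the lowest feature index,
    then the lowest threshold.  ``sort_idx`` may carry per-column argsort
    indices precomputed by the boosting loop.
    """
    X, y = _check_Xy(X, y)
    w = np.asarray(w, dtype=float)
    if w.shape != y.shape or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per sample")
    total = w.sum()
    if not np.isclose(total, 1.0):
        raise ValueError("weights must sum to 1")
    n, d = X.shape
    if n < 1:
        raise ValueError("need at least one sample")
    overall_mean = float(np.clip(np.dot(w, y), -1.0, 1.0))

    if sort_idx is None:
        sort_idx = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, sort_idx, axis=0)  # (n, d) sorted per column
    ws = w[sort_idx]
    wys = (w * y)[sort_idx]
    cw = np.cumsum(ws, axis=0)
    cwy = np.cumsum(wys, axis=0)

    if n < 2:
        return Stump(0, float(X[0, 0]), overall_mean, overall_mean)

    # candidate split after sorted position i (left = first i+1 samples)
    wl = cw[:-1]
    wr = total - wl
    sl = cwy[:-1]
    sr = cwy[-1] - sl
    valid = (Xs[:-1] < Xs[1:]) & (wl > 0) & (wr > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(valid, sl**2 / wl + sr**2 / wr, -np.inf)

    if not valid.any():
        # every column is constant: degenerate stump, both responses the mean
        return Stump(0, float(X[0, 0]), overall_mean, overall_mean)

    best_per_feature = gain.max(axis=0)
    j = int(np.argmax(best_per_feature))  # first max -> lowest feature index
    i = int(np.argmax(gain[:, j]))  # first max -> lowest threshold (sorted)
    threshold = 0.5 * (Xs[i, j] + Xs[i + 1, j])
    left = float(np.clip(sl[i, j] / wl[i, j], -1.0, 1.0))
    right = float(np.clip(sr[i, j] / wr[i, j], -1.0, 1.0))
    return Stump(j, float(threshold), left, right)


def gab_train(X, y, M: int = 100, return_history: bool = False):
    """Gentle AdaBoost: M rounds of WLS stump fitting with multiplicative
    weight updates ``w_i <- w_i exp(-y_i f_m(x_i))`` renormalized to sum 1.

    With ``return_history=True`` also returns the per-round normalized weight
    vectors (after each update) for diagnostics.
    """
    X, y = _check_Xy(X, y)
    if M < 1:
        raise ValueError("M must be >= 1")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if len(np.unique(y)) == 1:
        warnings.warn(
            "single-class training labels: returning a constant ensemble",
            stacklevel=2,
        )
        c = float(y[0])
        model = GABEnsemble((Stump(0, float(X[0, 0]), c, c),))
        return (model, [np.full(n, 1.0 / n)]) if return_history else model
    sort_idx = np.argsort(X, axis=0, kind="stable")
    w = np.full(n, 1.0 / n)
    stumps: list[Stump] = []
    history: list[np.ndarray] = []
    for _ in range(M):
        stump = fit_stump_wls(X, y, w, sort_idx=sort_idx)
        stumps.append(stump)
        f = stump.respond(X)
        w = w * np.exp(-y * f)
        w = w / w.sum()
        if return_history:
            history.append(w.copy())
    model = GABEnsemble(tuple(stumps))
    return (model, history) if return_history else model


def gab_predict(model: GABEnsemble, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels (sign of the summed responses, 0 -> +1) and real scores."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    needed = max(s.feature_index for s in model.stumps) + 1
    if X.shape[1] < needed:
        raise ValueError(
            f"feature count {X.shape[1]} smaller than model requirement {needed}"
        )
    scores = np.zeros(X.shape[0])
    for stump in model.stumps:
        scores += stump.respond(X)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


# ---------------------------------------------------------------------------
# k-nearest neighbors
# ---------------------------------------------------------------------------

def euclidean_distance(x, y) -> float:
    """Plain Euclidean distance sqrt(sum (x_i - y_i)^2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.sum((x - y) ** 2)))


@dataclass(frozen=True)
class KNNModel:
    """Lazy learner: the stored training set plus the neighbor count k.

    ``z_scale`` optionally standardizes features with statistics computed on
    the stored (training) rows only.
    """

    train_matrix: np.ndarray
    train_labels: np.ndarray
    k: int = 5
    z_scale: bool = False
    _mean: np.ndarray = field(init=False, repr=False, default=None)
    _sd: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        X, y = _check_Xy(self.train_matrix, self.train_labels)
        if not np.all(np.isfinite(X)):
            raise ValueError("missing or non-numeric entries are not allowed")
        if not (1 <= self.k <= X.shape[0]):
            raise ValueError("k must satisfy 1 <= k <= number of samples")
        object.__setattr__(self, "train_matrix", X)
        object.__setattr__(self, "train_labels", y.astype(int))
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        object.__setattr__(self, "_mean", mean)
        object.__setattr__(self, "_sd", sd)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mean) / self._sd if self.z_scale else X


def knn_fit(X, y, k: int = 5, z_scale: bool = False) -> KNNModel:
    return KNNModel(np.asarray(X, dtype=float), np.asarray(y), k=k, z_scale=z_scale)


def knn_predict(model: KNNModel, x) -> int | np.ndarray:
    """Majority vote over the k nearest stored samples.

    Distance ties at the k-th position break toward the lower training index;
    vote ties break toward the label of the single nearest neighbor.  Accepts
    one query vector or a matrix of queries.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    queries = x[None, :] if single else x
    if queries.shape[1] != model.train_matrix.shape[1]:
        raise ValueError("query dimension does not match the training matrix")
    train = model._transform(model.train_matrix)
    queries = model._transform(queries)
    out = np.empty(queries.shape[0], dtype=int)
    for i, q in enumerate(queries):
        dist = np.sqrt(np.sum((train - q) ** 2, axis=1))
        order = np.argsort(dist, kind="stable")  # stable -> lower index first
        nearest = order[: model.k]
        votes = model.train_labels[nearest]
        pos = int(np.sum(votes == 1))
        neg = model.k - pos
        if pos > neg:
            out[i] = 1
        elif neg > pos:
            out[i] = -1
        else:
            out[i] = int(model.train_labels[order[0]])
    return int(out[0]) if single else out


# ---------------------------------------------------------------------------
# Support vector machine (RBF)
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """Fitted soft-margin RBF SVM; decision f(x) = sum_i a_i y_i k(x_i, x) + b."""

    svc: SVC
    gamma: float

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_weights(self) -> np.ndarray:
        return self.svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])


def svm_train(X, y, C: float = 1.0, gamma: float | None = None) -> SVMModel:
    """Train a soft-margin RBF SVM.

    ``gamma`` defaults to 1 / (d * mean feature variance) (the 'scale'
    heuristic).  The quadratic program is solved by scikit-learn's SVC; the
    contract kept here is the sign-of-decision-function prediction and
    reproducibility for fixed inputs.
    """
    X, y = _check_Xy(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if gamma is None:
        mean_var = X.var()
        gamma = 1.0 / (X.shape[1] * mean_var) if mean_var > 0 else 1.0
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(X, y.astype(int))
    return SVMModel(svc=svc, gamma=float(gamma))


def svm_decision(model: SVMModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("query dimension does not match the training matrix")
    return model.svc.decision_function(X)


def svm_predict(model: SVMModel, x) -> int | np.ndarray:
    """Label = sign of the decision value; exactly zero resolves to +1."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    scores = svm_decision(model, x)
    labels = np.where(scores >= 0, 1, -1)
    return int(labels[0]) if single else labels


# ---------------------------------------------------------------------------
# Unified fit/predict surface + JSON serialization
# ---------------------------------------------------------------------------

def fit_classifier(kind: str, X, y, **hyper):
    if kind == "gab":
        return gab_train(X, y, M=int(hyper.get("M", 100)))
    if kind == "knn":
        return knn_fit(
            X, y, k=int(hyper.get("k", 5)), z_scale=bool(hyper.get("z_scale", False))
        )
    if kind == "svm":
        return svm_train(X, y, C=float(hyper.get("C", 1.0)), gamma=hyper.get("gamma"))
    raise ValueError(f"unknown classifier kind: {kind}")


def predict_classifier(model, X) -> np.ndarray:
    if isinstance(model, GABEnsemble):
        return gab_predict(model, X)[0]
    if isinstance(model, KNNModel):
        return np.atleast_1d(knn_predict(model, np.asarray(X, dtype=float)))
    if isinstance(model, SVMModel):
        return np.atleast_1d(svm_predict(model, np.asarray(X, dtype=float)))
    raise TypeError(f"unsupported model type: {type(model)!r}")


_FORMAT_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Serialize any of the three models to a documented JSON container."""
    if isinstance(model, GABEnsemble):
        payload = {
            "kind": "gab",
            "stumps": [
                [s.feature_index, s.threshold, s.left_value, s.right_value]
                for s in model.stumps
            ],
        }
    elif isinstance(model, KNNModel):
        payload = {
            "kind": "knn",
            "k": model.k,
            "z_scale": model.z_scale,
            "train_matrix": model.train_matrix.tolist(),
            "train_labels": model.train_labels.tolist(),
        }
    elif isinstance(model, SVMModel):
        svc = model.svc
        payload = {
            "kind": "svm",
            "gamma": model.gamma,
            "C": svc.C,
            "support_vectors": svc.support_vectors_.tolist(),
            # the private coefficients are libsvm's own sign convention, the
            # ones decision_function computes with
            "dual_coef": svc._dual_coef_.tolist(),
            "intercept": svc._intercept_.tolist(),
            "classes": svc.classes_.tolist(),
            "n_support": svc.n_support_.tolist(),
        }
    else:
        raise TypeError(f"unsupported model type: {type(model)!r}")
    payload["format_version"] = _FORMAT_VERSION
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    kind = payload["kind"]
    if kind == "gab":
        return GABEnsemble(tuple(Stump(int(f), t, l, r) for f, t, l, r in payload["stumps"]))
    if kind == "knn":
        return KNNModel(
            np.asarray(payload["train_matrix"], dtype=float),
            np.asarray(payload["train_labels"]),
            k=int(payload["k"]),
            z_scale=bool(payload["z_scale"]),
        )
    if kind == "svm":
        sv = np.asarray(payload["support_vectors"], dtype=float)
        dual = np.asarray(payload["dual_coef"], dtype=float)
        svc = SVC(C=payload["C"], kernel="rbf", gamma=payload["gamma"])
        # rebuild the fitted state sklearn needs for decision_function; the
        # public binary-class attributes carry the opposite sign convention
        svc.support_vectors_ = sv
        svc._dual_coef_ = dual
        svc.dual_coef_ = -dual
        svc._intercept_ = np.asarray(payload["intercept"], dtype=float)
        svc.intercept_ = -svc._intercept_
        svc.classes_ = np.asarray(payload["classes"])
        svc.support_ = np.arange(sv.shape[0], dtype=np.int32)
        svc._n_support = np.asarray(payload["n_support"], dtype=np.int32)
        svc.fit_status_ = 0
        svc._sparse = False
        svc.shape_fit_ = (sv.shape[0], sv.shape[1])
        svc._gamma = payload["gamma"]
        svc._probA = np.empty(0)
        svc._probB = np.empty(0)
        return SVMModel(svc=svc, gamma=float(payload["gamma"]))
    raise ValueError(f"unknown model kind in file: {kind}")
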