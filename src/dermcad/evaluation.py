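"""Class balancing, k-fold cross-validation, and diagnostic statistics.

Melanoma is the positive class (+1).  The five reported statistics are the
usual diagnostic ratios, each as a percentage:

    AC  = (TP + TN) / (TP + TN + FP + FN)   accuracy
    SE  = TP / (TP + FN)                    sensitivity (recall on melanoma)
    SP  = TN / (TN + FP)                    specificity
    PPV = TP / (TP + FP)                    positive predictive value
    NPV = TN / (TN + FN)                    negative predictive value

Zero-denominator ratios are reported as NaN, never silently as 0 or 100.

Cross-validation is stratified 10-fold by default.  Random over-sampling of
the minority class is applied inside the training folds only, so replicated
rows can never leak into their own test fold; ``paper_mode=True`` instead
reproduces the oversample-before-split order some studies describe, which
does allow such leakage and typically inflates the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from dermcad import classifiers, descriptors, preprocessing
from dermcad.synthetic import LabeledSample


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsReport:
    AC: float
    SE: float
    SP: float
    PPV: float
    NPV: float
    confusion: ConfusionMatrix

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("AC", "SE", "SP", "PPV", "NPV")}
        d["confusion"] = asdict(self.confusion)
        return d


@dataclass(frozen=True)
class FoldAssignment:
    """fold_of[i] = fold id of sample i, ids in [0, k)."""

    fold_of: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    return y


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    y_true = _check_labels(y_true)
    y_pred = _check_labels(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def diagnostic_metrics(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        AC=_ratio(cm.TP + cm.TN, cm.total),
        SE=_ratio(cm.TP, cm.TP + cm.FN),
        SP=_ratio(cm.TN, cm.TN + cm.FP),
        PPV=_ratio(cm.TP, cm.TP + cm.FP),
        NPV=_ratio(cm.TN, cm.TN + cm.FN),
        confusion=cm,
    )


def random_oversample(features, labels, seed: int = 0):
    """Append seeded with-replacement copies of minority rows until the two
    class counts are equal; majority rows are untouched."""
    labels = _check_labels(labels)
    dense = not sp.issparse(features)
    X = np.asarray(features, dtype=float) if dense else features.tocsr()
    if X.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if n_pos == n_neg:
        return (X.copy() if dense else X.copy()), labels.copy()
    minority = 1 if n_pos < n_neg else -1
    deficit = abs(n_pos - n_neg)
    pool = np.flatnonzero(labels == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(pool, size=deficit, replace=True)
    new_labels = np.concatenate([labels, labels[extra]])
    if dense:
        return np.vstack([X, X[extra]]), new_labels
    return sp.vstack([X, X[extra]]).tocsr(), new_labels


def kfold_split(
    labels, k: int = 10, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Seeded k-fold assignment by round-robin over a shuffled order.

    Stratified mode (default) shuffles within each class and keeps a single
    round-robin cursor running across classes, so overall fold sizes differ
    by at most one and per-class fold counts differ by at most one.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= number of samples")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    cursor = 0
    if stratified:
        for cls in np.unique(labels):  # sorted class order, then shuffle within
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for i in idx:
                fold_of[i] = cursor % k
                cursor += 1
    else:
        idx = rng.permutation(n)
        for i in idx:
            fold_of[i] = cursor % k
            cursor += 1
    return FoldAssignment(fold_of=fold_of, k=k)


# ---------------------------------------------------------------------------
# Descriptor extraction for cross-validation
# ---------------------------------------------------------------------------

DESCRIPTOR_KINDS = ("lbp", "nlbp", "hog", "cshog")


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 10
    stratified: bool = True
    oversample: bool = True
    paper_mode: bool = False  # oversample the whole set before splitting
    preprocess: bool = True  # median filter + hair removal before extraction
    masked: bool = False  # zero out non-lesion pixels before extraction
    select_k: int | None = None  # None -> 4096 for nlbp, no selection otherwise
    classifier_params: dict = field(default_factory=dict)

    def effective_select_k(self, descriptor_kind: str) -> int | None:
        if self.select_k is not None:
            return self.select_k
        return 4096 if descriptor_kind == "nlbp" else None


def extract_feature_matrix(
    samples: Sequence[LabeledSample],
    descriptor_kind: str,
    config: CVConfig | None = None,
):
    """Per-sample descriptor extraction; returns (matrix, labels).

    The matrix is dense for lbp/hog/cshog and a CSR sparse matrix over the
    union of observed codes for nlbp (columns sorted by code).  Extraction is
    per-image and deterministic, so it is shared across folds.
    """
    if descriptor_kind not in DESCRIPTOR_KINDS:
        raise ValueError(f"unknown descriptor kind: {descriptor_kind}")
    if config is None:
        config = CVConfig()
    labels = np.array([s.label for s in samples], dtype=int)
    grays = []
    for s in samples:
        if config.preprocess:
            _, gray = preprocessing.preprocess_rgb(s.image)
        else:
            gray = preprocessing.to_grayscale(s.image)
        if config.masked:
            gray = np.where(s.mask, gray, 0).astype(gray.dtype)
        grays.append(gray)

    if descriptor_kind == "lbp":
        X = np.stack([descriptors.lbp_histogram(g).astype(float) for g in grays])
    elif descriptor_kind == "hog":
        X = np.stack([descriptors.hog_descriptor(g) for g in grays])
    elif descriptor_kind == "cshog":
        X = np.stack([descriptors.cs_hog_descriptor(g) for g in grays])
    else:  # nlbp: sparse matrix over the union of observed codes
        hists = [descriptors.nlbp_histogram(g) for g in grays]
        all_codes = np.unique(
            np.concatenate([h.to_arrays()[0] for h in hists])
            if hists
            else np.empty(0, dtype=np.int64)
        )
        col_of = {int(c): i for i, c in enumerate(all_codes)}
        rows, cols, vals = [], [], []
        for i, h in enumerate(hists):
            codes, counts = h.to_arrays()
            rows.extend([i] * len(codes))
            cols.extend(col_of[int(c)] for c in codes)
            vals.extend(counts.tolist())
        X = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(samples), len(all_codes)), dtype=float
        )
    return X, labels


def _slice_rows(X, idx):
    return X[idx] if sp.issparse(X) else X[idx, :]


def _densify(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def fold_matrices(
    X,
    labels: np.ndarray,
    folds: FoldAssignment,
    fold: int,
    config: CVConfig,
    seed: int,
    select_k: int | None,
):
    """Assemble dense (X_tr, y_tr, X_te, y_te) for one fold: feature
    selection fitted on the training rows, then (sound mode) over-sampling of
    the training rows only.  Test rows are always untouched originals."""
    tr = folds.train_indices(fold)
    te = folds.test_indices(fold)
    X_tr, y_tr = _slice_rows(X, tr), labels[tr]
    X_te, y_te = _slice_rows(X, te), labels[te]
    if select_k is not None:
        sel = descriptors.select_features(X_tr, select_k)
        X_tr = X_tr[:, sel]
        X_te = X_te[:, sel]
    X_tr, X_te = _densify(X_tr), _densify(X_te)
    if config.oversample and not config.paper_mode:
        X_tr, y_tr = random_oversample(X_tr, y_tr, seed=seed + 1000 + fold)
    return X_tr, y_tr, X_te, y_te


def cross_validate_features(
    X,
    labels,
    classifier_kind: str,
    config: CVConfig | None = None,
    seed: int = 0,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold CV over a precomputed feature matrix.

    Per fold: variance-based feature selection fitted on the training rows,
    over-sampling of the training rows (unless ``paper_mode``), classifier
    training, prediction of the held-out fold.  Metrics are pooled over folds
    (micro-average); per-fold reports are also returned.
    """
    if config is None:
        config = CVConfig()
    labels = _check_labels(labels)
    select_k = config.effective_select_k("nlbp" if sp.issparse(X) else "dense")
    if config.paper_mode and config.oversample:
        X, labels = random_oversample(X, labels, seed=seed)
    folds = kfold_split(labels, k=config.k_folds, seed=seed, stratified=config.stratified)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    per_fold: list[MetricsReport] = []
    for fold in range(folds.k):
        X_tr, y_tr, X_te, y_te = fold_matrices(
            X, labels, folds, fold, config, seed, select_k
        )
        model = classifiers.fit_classifier(
            classifier_kind, X_tr, y_tr, **config.classifier_params
        )
        y_pred = classifiers.predict_classifier(model, X_te)
        cm = confusion_matrix(y_te, y_pred)
        per_fold.append(diagnostic_metrics(cm))
        pooled = pooled + cm
    return diagnostic_metrics(pooled), per_fold


def cross_validate(
    samples: Sequence[LabeledSample],
    descriptor_kind: str,
    classifier_kind: str,
    config: CVConfig | None = None,
    seed: int = 0,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """End-to-end k-fold CV on labeled images: preprocessing + descriptor
    extraction per image, then :func:`cross_validate_features`."""
    if config is None:
        config = CVConfig()
    X, labels = extract_feature_matrix(samples, descriptor_kind, config)
    return cross_validate_features(X, labels, classifier_kind, config, seed=seed)
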