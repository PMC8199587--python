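"""PCA-CA-kNN metabolomic fingerprint classifier.

The chain: mean-center the PQN-normalized binned matrix, project onto the
principal components explaining 99.9% of the variance, rotate the scores onto
the canonical (Fisher discriminant) axis maximizing between- over within-class
scatter, and classify by k-nearest neighbours (k = 9, Euclidean, majority
vote) in that canonical space.  Performance is assessed by leave-one-out
cross-validation in which the entire chain -- PQN reference, centering, PCA
basis and canonical axis -- is refit on each fold, so the held-out sample
never influences the model that classifies it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocess import PQNNormalizer

EARLY, METASTATIC = "early", "metastatic"


def fit_pca(X: np.ndarray, var_threshold: float = 0.999):
    """Covariance PCA keeping the smallest basis explaining ``var_threshold``.

    Returns (center, basis, retained_m, explained_variance_ratio); the basis
    rows are orthonormal components in descending-variance order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with n >= 2")
    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance; PCA undefined")
    ratio = var / total
    m = int(np.searchsorted(np.cumsum(ratio), var_threshold - 1e-12) + 1)
    m = min(m, len(s))
    return center, Vt[:m], m, ratio


def fit_ca(scores: np.ndarray, labels: np.ndarray, positive_label: str = METASTATIC) -> np.ndarray:
    """Canonical (Fisher) axis in PCA-score space for two classes.

    The axis is the leading eigenvector of W^-1 B (W pooled within-class
    scatter, B between-class scatter); for two classes B has rank one and the
    axis is proportional to W^-1 (mu_pos - mu_neg).  It is scaled to unit
    pooled within-class variance and oriented so the positive (metastatic)
    class mean is positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"canonical analysis needs exactly 2 classes, got {len(classes)}")
    pos = positive_label if positive_label in classes else classes[1]
    neg = classes[classes != pos][0]
    Xp, Xn = scores[labels == pos], scores[labels == neg]
    if len(Xp) < 2 or len(Xn) < 2:
        raise ValueError("each class needs at least 2 samples for within-class scatter")
    d = Xp.mean(axis=0) - Xn.mean(axis=0)
    W = np.zeros((scores.shape[1], scores.shape[1]))
    for block in (Xp, Xn):
        c = block - block.mean(axis=0)
        W += c.T @ c
    try:
        a = np.linalg.solve(W, d)
    except np.linalg.LinAlgError:
        raise ValueError(
            "within-class scatter is singular in the PCA subspace; "
            "lower var_threshold to retain fewer components"
        ) from None
    wvar = float(a @ W @ a) / (len(scores) - 2)
    if not np.isfinite(wvar) or wvar <= 0:
        raise ValueError(
            "within-class scatter is numerically singular; lower var_threshold"
        )
    a = a / np.sqrt(wvar)
    if (Xp.mean(axis=0) - Xn.mean(axis=0)) @ a < 0:
        a = -a
    return a


def knn_vote(
    train_scores: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    k: int,
    positive_label: str = METASTATIC,
) -> np.ndarray:
    """Majority vote among the k nearest training points (Euclidean, 1-D CA
    space); distance ties broken by the smaller training index."""
    train_scores = np.asarray(train_scores, dtype=float).ravel()
    queries = np.atleast_1d(np.asarray(queries, dtype=float)).ravel()
    n = train_scores.size
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} training samples")
    out = []
    is_pos = np.asarray(train_labels) == positive_label
    neg_label = np.asarray(train_labels)[~is_pos][0] if (~is_pos).any() else positive_label
    for q in queries:
        dist = np.abs(train_scores - q)
        order = np.argsort(dist, kind="stable")[:k]
        pos_votes = int(is_pos[order].sum())
        out.append(positive_label if pos_votes * 2 > k else neg_label)
    return np.asarray(out, dtype=object)


class PCACAKNN(ClassifierMixin, BaseEstimator):
    """PCA -> canonical analysis -> kNN classifier (two classes).

    Parameters
    ----------
    k : int
        Neighbourhood size (odd; default 9).
    var_threshold : float
        Cumulative explained-variance fraction retained by the PCA step.
    positive_class : str
        Label treated as positive (metastatic) for axis orientation and
        sensitivity/specificity bookkeeping.
    """

    def __init__(self, k: int = 9, var_threshold: float = 0.999, positive_class: str = METASTATIC):
        self.k = k
        self.var_threshold = var_threshold
        self.positive_class = positive_class

    def fit(self, X, y) -> "PCACAKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be an odd positive integer")
        if self.k > len(y) - 1:
            raise ValueError(f"k = {self.k} too large for n = {len(y)} training samples")
        self.classes_ = np.unique(y)
        self.center_, self.components_, self.n_components_, self.explained_variance_ratio_ = (
            fit_pca(X, self.var_threshold)
        )
        T = (X - self.center_) @ self.components_.T
        self.ca_axis_ = fit_ca(T, y, self.positive_class)
        self.train_scores_ = T @ self.ca_axis_
        self.y_train_ = y.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Canonical scores of new samples (distance along CA1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"bin-grid mismatch: model has {self.n_features_in_} bins, data has {X.shape[1]}"
            )
        return ((X - self.center_) @ self.components_.T) @ self.ca_axis_

    def decision_function(self, X) -> np.ndarray:
        return self.transform(X)

    def predict(self, X) -> np.ndarray:
        scores = self.transform(X)
        if scores.size == 0:
            return np.asarray([], dtype=object)
        return knn_vote(self.train_scores_, self.y_train_, scores, self.k, self.positive_class)


@dataclass
class FingerprintModel:
    """Fitted chain: PQN reference + PCA-CA-kNN classifier."""

    pqn: PQNNormalizer | None
    clf: PCACAKNN
    pulse_seq: str = "NOESY"

    @property
    def n_bins(self) -> int:
        return self.clf.n_features_in_

    def save(self, path: str | Path) -> None:
        """Persist as JSON (metadata + numeric arrays)."""
        payload = {
            "pulse_seq": self.pulse_seq,
            "k": self.clf.k,
            "var_threshold": self.clf.var_threshold,
            "positive_class": self.clf.positive_class,
            "center": self.clf.center_.tolist(),
            "components": self.clf.components_.tolist(),
            "ca_axis": self.clf.ca_axis_.tolist(),
            "train_scores": self.clf.train_scores_.tolist(),
            "train_labels": self.clf.y_train_.tolist(),
            "pqn_reference": None if self.pqn is None else self.pqn.reference_.tolist(),
            "pqn_area_scale": None if self.pqn is None else self.pqn.area_scale_,
            "pqn_total_area": None if self.pqn is None else self.pqn.total_area,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FingerprintModel":
        p = json.loads(Path(path).read_text())
        clf = PCACAKNN(k=p["k"], var_threshold=p["var_threshold"], positive_class=p["positive_class"])
        clf.center_ = np.asarray(p["center"])
        clf.components_ = np.asarray(p["components"])
        clf.n_components_ = clf.components_.shape[0]
        clf.ca_axis_ = np.asarray(p["ca_axis"])
        clf.train_scores_ = np.asarray(p["train_scores"])
        clf.y_train_ = np.asarray(p["train_labels"], dtype=object)
        clf.classes_ = np.unique(clf.y_train_)
        clf.n_features_in_ = clf.center_.size
        clf.explained_variance_ratio_ = np.asarray([])
        pqn = None
        if p["pqn_reference"] is not None:
            pqn = PQNNormalizer(total_area=p["pqn_total_area"])
            pqn.reference_ = np.asarray(p["pqn_reference"])
            pqn.area_scale_ = p["pqn_area_scale"]
        return cls(pqn=pqn, clf=clf, pulse_seq=p["pulse_seq"])


def fit_fingerprint(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 9,
    var_threshold: float = 0.999,
    use_pqn: bool = True,
    pulse_seq: str = "NOESY",
) -> FingerprintModel:
    """Fit the full chain (PQN reference from the training matrix)."""
    X = np.asarray(X, dtype=float)
    pqn = None
    if use_pqn:
        pqn = PQNNormalizer().fit(X)
        X = pqn.transform(X)
    clf = PCACAKNN(k=k, var_threshold=var_threshold).fit(X, y)
    return FingerprintModel(pqn=pqn, clf=clf, pulse_seq=pulse_seq)


@dataclass
class ClassificationResult:
    """Predictions plus the confusion-matrix summary (positive = metastatic)."""

    sample_ids: list[str]
    y_true: np.ndarray | None
    y_pred: np.ndarray
    ca_scores: np.ndarray
    positive_label: str = METASTATIC
    negative_label: str = EARLY
    confusion: np.ndarray | None = field(default=None)  # [[TN, FP], [FN, TP]]
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.y_true is not None and self.confusion is None:
            t_pos = np.asarray(self.y_true) == self.positive_label
            p_pos = np.asarray(self.y_pred) == self.positive_label
            tp = int(np.sum(t_pos & p_pos))
            tn = int(np.sum(~t_pos & ~p_pos))
            fp = int(np.sum(~t_pos & p_pos))
            fn = int(np.sum(t_pos & ~p_pos))
            self.confusion = np.array([[tn, fp], [fn, tp]])
            n_pos, n_neg = tp + fn, tn + fp
            self.sensitivity = tp / n_pos if n_pos else float("nan")
            self.specificity = tn / n_neg if n_neg else float("nan")
            self.accuracy = (tp + tn) / len(self.y_pred)

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.sample_ids, "ca_score": self.ca_scores, "predicted": self.y_pred}
        if self.y_true is not None:
            data["true"] = self.y_true
        return pd.DataFrame(data)


def _loocv_fold_pca_scores(X: np.ndarray, var_threshold: float, use_pqn: bool):
    """Per-fold, label-independent part of LOOCV: PQN + centering + PCA.

    Returns, for each held-out index, the training PCA scores and the
    projected held-out sample.  Shared by the evaluation and the permutation
    null (labels only enter the canonical/kNN stage).
    """
    n = X.shape[0]
    folds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Xte = X[mask], X[i : i + 1]
        if use_pqn:
            pqn = PQNNormalizer().fit(Xtr)
            Xtr, Xte = pqn.transform(Xtr), pqn.transform(Xte)
        center, basis, _, _ = fit_pca(Xtr, var_threshold)
        folds.append(((Xtr - center) @ basis.T, ((Xte - center) @ basis.T)[0]))
    return folds


def _predict_fold(T_tr, t_te, y_tr, k: int, positive_label: str):
    a = fit_ca(T_tr, y_tr, positive_label)
    s_tr = T_tr @ a
    s_te = float(t_te @ a)
    label = knn_vote(s_tr, y_tr, [s_te], k, positive_label)[0]
    return label, s_te


def loocv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list[str] | None = None,
    k: int = 9,
    var_threshold: float = 0.999,
    use_pqn: bool = True,
    positive_label: str = METASTATIC,
) -> ClassificationResult:
    """Leave-one-out evaluation with the full chain refit on every fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("LOOCV evaluation needs exactly 2 classes")
    if counts.min() < 2:
        lost = classes[np.argmin(counts)]
        raise ValueError(f"a fold would lose class {lost!r} entirely")
    if n - 1 < k:
        raise ValueError(f"n - 1 = {n - 1} < k = {k}")
    neg_label = classes[classes != positive_label][0] if positive_label in classes else classes[0]
    folds = _loocv_fold_pca_scores(X, var_threshold, use_pqn)
    preds, scores = [], []
    for i, (T_tr, t_te) in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        label, s = _predict_fold(T_tr, t_te, y[mask], k, positive_label)
        preds.append(label)
        scores.append(s)
    return ClassificationResult(
        sample_ids=list(sample_ids),
        y_true=y,
        y_pred=np.asarray(preds, dtype=object),
        ca_scores=np.asarray(scores),
        positive_label=positive_label,
        negative_label=str(neg_label),
    )


def permutation_null_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    k: int = 9,
    var_threshold: float = 0.999,
    use_pqn: bool = True,
    positive_label: str = METASTATIC,
) -> np.ndarray:
    """LOOCV accuracies under label permutation.

    The label-independent per-fold PCA scores are computed once and reused,
    so only the canonical axis and the kNN vote are refit per permutation --
    numerically identical to rerunning the full LOOCV on permuted labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    folds = _loocv_fold_pca_scores(X, var_threshold, use_pqn)
    accs = np.empty(n_permutations)
    for p in range(n_permutations):
        yp = y[rng.permutation(n)]
        correct = 0
        for i, (T_tr, t_te) in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            label, _ = _predict_fold(T_tr, t_te, yp[mask], k, positive_label)
            correct += label == yp[i]
        accs[p] = correct / n
    return accs


def project(model: FingerprintModel, X_new: np.ndarray, sample_ids: list[str] | None = None):
    """Classify new samples with a fitted chain (never refits anything)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[0] == 0:
        return ClassificationResult(sample_ids=[], y_true=None, y_pred=np.asarray([], dtype=object),
                                    ca_scores=np.asarray([]))
    if X_new.shape[1] != model.n_bins:
        raise ValueError(
            f"bin-grid mismatch: model has {model.n_bins} bins, data has {X_new.shape[1]}"
        )
    Xn = model.pqn.transform(X_new) if model.pqn is not None else X_new
    preds = model.clf.predict(Xn)
    scores = model.clf.transform(Xn)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X_new.shape[0])]
    return ClassificationResult(
        sample_ids=list(sample_ids), y_true=None, y_pred=preds, ca_scores=scores
    )


def stratify_risk(
    loocv_result: ClassificationResult,
    projected_result: ClassificationResult,
    positive_label: str = METASTATIC,
) -> pd.Series:
    """Merge LOOCV predictions (training members) and projections (held-out
    relapsed patients) into one high/low metabolomic-risk label per patient.

    Predicted-metastatic maps to "high", predicted-early to "low"; duplicate
    ids across the two sources raise.
    """
    pairs: list[tuple[str, str]] = []
    for res in (loocv_result, projected_result):
        pairs.extend(zip(res.sample_ids, res.y_pred))
    ids = [p[0] for p in pairs]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValueError(f"duplicate patient id(s) in risk stratification: {dup}")
    if not pairs:
        raise ValueError("no predictions to stratify")
    risk = {pid: ("high" if pred == positive_label else "low") for pid, pred in pairs}
    return pd.Series(risk, name="metabolomic_risk")
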