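"""Partial least squares regression (NIPALS) and the PLSDA classifier.

The classifier regresses a class-indicator (dummy) matrix on the spectra
and assigns each sample to the class with the maximal predicted indicator
element.  The latent-variable count is chosen by cross-validation
(leave-one-out for n <= 100, otherwise 10-fold venetian blinds),
minimizing the misclassification count (classification mode) or PRESS
(regression mode), with ties resolved toward the smaller count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PLSModel:
    """Fitted PLS decomposition with per-latent-variable quantities.

    ``weights`` (p x a), ``x_loadings`` (p x a) and ``y_loadings`` (m x a)
    hold one column per latent variable; ``coefficients`` (p x m) is the
    equivalent X -> Y regression matrix on centered data.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    coefficients: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} variables, got matrix of shape {X.shape}"
            )
        return (X - self.x_mean) @ self.coefficients + self.y_mean

    def predict_per_lv(self, X: np.ndarray) -> np.ndarray:
        """Predictions using 1..n_lv latent variables; shape (a, n, m)."""
        X = np.asarray(X, dtype=float)
        Xc = X - self.x_mean
        n, m = X.shape[0], self.y_mean.size
        out = np.empty((self.n_lv, n, m))
        acc = np.tile(self.y_mean, (n, 1)).astype(float)
        for a in range(self.n_lv):
            t = Xc @ self.weights[:, a]
            Xc = Xc - np.outer(t, self.x_loadings[:, a])
            acc = acc + np.outer(t, self.y_loadings[:, a])
            out[a] = acc
        return out


@dataclass
class DummyCoding:
    """Class-indicator coding: one column per class, in class_order."""

    class_order: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.class_order):
            raise ValueError("matrix column count must equal the number of classes")
        rows_ok = np.all(self.matrix.sum(axis=1) == 1) and np.all(
            ((self.matrix == 0) | (self.matrix == 1))
        )
        if not rows_ok:
            raise ValueError("each row must contain exactly one 1 and zeros elsewhere")


def dummy_code(labels: np.ndarray, n_classes: int | None = None) -> DummyCoding:
    """Indicator matrix for 1-based integer class labels."""
    labels = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(labels.max())
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError("labels must lie in 1..n_classes")
    matrix = np.zeros((labels.size, n_classes))
    matrix[np.arange(labels.size), labels - 1] = 1.0
    return DummyCoding(class_order=[f"G{k:02d}" for k in range(1, n_classes + 1)], matrix=matrix)


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-10,
    strict: bool = True,
) -> PLSModel:
    """NIPALS PLS of `Y` on `X` with `n_lv` latent variables.

    Both matrices are column-centered internally.  With ``strict=False``
    the fit stops silently when the X residual rank is exhausted and the
    returned model carries the achieved number of latent variables
    (used by the cross-validation loop); with ``strict=True`` rank
    exhaustion raises.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} outside the feasible range 1..{min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    x_scale = np.linalg.norm(Xc) or 1.0

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    achieved = 0
    for a in range(n_lv):
        if np.linalg.norm(Xc) <= 1e-12 * x_scale or np.linalg.norm(Yc) == 0:
            if strict:
                raise ValueError(f"rank exhausted after {a} latent variables")
            break
        if m == 1:
            w = Xc.T @ Yc[:, 0]
            nw = np.linalg.norm(w)
            if nw == 0:
                if strict:
                    raise ValueError("response is orthogonal to X; no latent variable")
                break
            w = w / nw
            t = Xc @ w
        else:
            u = Yc[:, int(np.argmax((Yc**2).sum(axis=0)))]
            t_old = None
            for _ in range(max_iter):
                w = Xc.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w = w / nw
                t = Xc @ w
                tt = t @ t
                if tt == 0:
                    break
                q = Yc.T @ t / tt
                qq = q @ q
                if qq == 0:
                    break
                u = Yc @ q / qq
                if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                    break
                t_old = t
            if nw == 0:
                if strict:
                    raise ValueError("response is orthogonal to X; no latent variable")
                break
        tt = t @ t
        if tt <= (1e-12 * x_scale) ** 2:
            if strict:
                raise ValueError(f"rank exhausted after {a} latent variables")
            break
        p_a = Xc.T @ t / tt
        q_a = Yc.T @ t / tt
        Xc -= np.outer(t, p_a)
        Yc -= np.outer(t, q_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
        achieved = a + 1

    if achieved == 0:
        raise ValueError("could not extract any latent variable")
    W, P, Q, T = W[:, :achieved], P[:, :achieved], Q[:, :achieved], T[:, :achieved]
    coefficients = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        n_lv=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        coefficients=coefficients,
    )


def _cv_folds(n: int) -> list[np.ndarray]:
    if n <= 100:
        return [np.array([i]) for i in range(n)]
    return [np.arange(n)[k::10] for k in range(10)]


def select_n_lv(
    X: np.ndarray, Y: np.ndarray, max_lv: int, mode: str = "regression"
) -> int:
    """Cross-validated latent-variable count (ties -> smallest).

    In ``"classification"`` mode `Y` must be a dummy matrix and the CV
    criterion is the misclassification count of the argmax rule; in
    ``"regression"`` mode it is PRESS.  Internally the predictors are
    compressed to their row space (exact for PLS, which only uses sample
    inner products), so wide spectral matrices cross-validate quickly.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if mode not in ("regression", "classification"):
        raise ValueError("mode must be 'regression' or 'classification'")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]

    mu = X.mean(axis=0)
    Xc = X - mu
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = max(int((s > (s[0] if s.size else 0.0) * 1e-12).sum()), 1)
    Z = Xc @ Vt[:rank].T

    folds = _cv_folds(n)
    min_train = min(n - f.size for f in folds)
    a_cap = max(1, min(max_lv, min_train - 1, rank))

    truth = np.argmax(Y, axis=1) if mode == "classification" else None
    err = np.zeros(a_cap)
    idx = np.arange(n)
    for f in folds:
        tr = np.setdiff1d(idx, f, assume_unique=True)
        model = pls_fit(Z[tr], Y[tr], a_cap, strict=False)
        preds = model.predict_per_lv(Z[f])  # (achieved, |f|, m)
        if model.n_lv < a_cap:  # rank dropped within the fold: carry last prediction
            pad = np.repeat(preds[-1:], a_cap - model.n_lv, axis=0)
            preds = np.concatenate([preds, pad], axis=0)
        if mode == "classification":
            err += (preds.argmax(axis=2) != truth[f]).sum(axis=1)
        else:
            err += ((preds - Y[f]) ** 2).sum(axis=(1, 2))
    return int(np.argmin(err)) + 1


def fit_plsda(X: np.ndarray, labels: np.ndarray, n_lv: int, n_classes: int | None = None):
    """Fit a PLSDA model: PLS of the dummy matrix on `X`.

    Returns ``(model, coding)``.
    """
    coding = dummy_code(labels, n_classes)
    model = pls_fit(X, coding.matrix, n_lv)
    return model, coding


def classify(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Assign 1-based class indices by argmax of the predicted indicators.

    Exact ties go to the lowest class index, with a warning.
    """
    pred = model.predict(X_new)
    maxima = pred.max(axis=1, keepdims=True)
    tie_rows = np.flatnonzero((pred == maxima).sum(axis=1) > 1)
    if tie_rows.size:
        warnings.warn(
            f"tied class scores for sample rows {tie_rows.tolist()}; "
            "assigning the lowest class index",
            stacklevel=2,
        )
    return pred.argmax(axis=1) + 1


@dataclass
class ClassificationReport:
    """Per-class sensitivity/selectivity and the confusion matrix.

    ``confusion[i, j]`` counts samples of true class i+1 assigned to class
    j+1.  SEN = TP/(TP+FN), SEL = TN/(TN+FP); classes absent from the
    truth get SEN = NaN.
    """

    confusion: np.ndarray
    sensitivity: np.ndarray
    selectivity: np.ndarray
    accuracy: float

    @property
    def n_classes(self) -> int:
        return self.confusion.shape[0]


def figures_of_merit(
    truth: np.ndarray, predicted: np.ndarray, n_classes: int
) -> ClassificationReport:
    """Confusion matrix, per-class SEN/SEL and overall accuracy."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.size != predicted.size:
        raise ValueError("truth and predicted must have equal lengths")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(truth, predicted):
        confusion[t - 1, p - 1] += 1
    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    tn = truth.size - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sen = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        sel = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    return ClassificationReport(
        confusion=confusion,
        sensitivity=sen,
        selectivity=sel,
        accuracy=float(tp.sum() / truth.size),
    )
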