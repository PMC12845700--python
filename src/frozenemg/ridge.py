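"""Closed-form ridge readout, multiclass metrics, and paired tests.

The only trainable component of the pipeline is a linear map W fitted to
one-hot class indicators Y by L2-regularised least squares,

    W = (D^T D + alpha I)^{-1} D^T Y,

predicting by the argmax of the class scores.  Features are z-scored on
the training set by default (GAP and PPV live on different scales and the
default alpha = 0.039 is small, so scaling materially affects
conditioning); centering doubles as the intercept.  When the sample count
is below the feature dimension the mathematically identical dual form
W = D^T (D D^T + alpha I)^{-1} Y is solved instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class RidgeModel:
    W: np.ndarray                       # d x n_classes
    alpha: float
    classes: np.ndarray                 # class labels, column order of W
    center: np.ndarray | None = None    # per-feature mean (None: no scaling)
    scale: np.ndarray | None = None     # per-feature SD


@dataclass
class EvalReport:
    """Confusion matrix and the five summary metrics (percent scale)."""

    confusion: np.ndarray
    classes: np.ndarray
    acc: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict:
        return {"acc": self.acc, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "mcc": self.mcc}


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, labels)
    Y = np.zeros((labels.size, classes.size))
    Y[np.arange(labels.size), idx] = 1.0
    return Y


def fit_ridge(features: np.ndarray, labels: np.ndarray,
              alpha: float = 0.039, standardize: bool = True) -> RidgeModel:
    """Fit the closed-form multiclass ridge readout.

    With ``alpha = 0`` and a singular Gram matrix the minimum-norm
    pseudoinverse solution is used (logged).
    """
    D = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).ravel()
    if D.shape[0] != y.size or D.shape[0] < 1:
        raise ValueError("features and labels disagree in length")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    center = scale = None
    if standardize:
        center = D.mean(axis=0)
        scale = D.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        D = (D - center) / scale
    Y = _one_hot(y, classes)
    n, d = D.shape
    if alpha == 0.0:
        G = D.T @ D
        if np.linalg.matrix_rank(G) < d:
            log.warning("singular Gram matrix at alpha=0; "
                        "using pseudoinverse solution")
            W = np.linalg.pinv(D) @ Y
        else:
            W = np.linalg.solve(G, D.T @ Y)
    elif n < d:
        W = D.T @ np.linalg.solve(D @ D.T + alpha * np.eye(n), Y)
    else:
        W = np.linalg.solve(D.T @ D + alpha * np.eye(d), D.T @ Y)
    return RidgeModel(W=W, alpha=float(alpha), classes=classes,
                      center=center, scale=scale)


def predict(model: RidgeModel, features: np.ndarray) -> np.ndarray:
    """Argmax class scores; ties resolve to the lowest class index."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.W.shape[0]})"
        )
    if model.center is not None:
        X = (X - model.center) / model.scale
    scores = X @ model.W
    return model.classes[np.argmax(scores, axis=1)]


def evaluate(pred: np.ndarray, true: np.ndarray,
             classes: np.ndarray | None = None) -> EvalReport:
    """Confusion matrix and ACC / macro PRE / REC / F1 / multiclass MCC.

    Metrics are reported on the percent scale (MCC included).  Classes
    absent from the predictions score precision 0; classes absent from
    the truth score recall 0.
    """
    p = np.asarray(pred).ravel()
    t = np.asarray(true).ravel()
    if p.size != t.size:
        raise ValueError("prediction and truth lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([t, p]))
    else:
        classes = np.asarray(classes)
        if not (np.isin(p, classes).all() and np.isin(t, classes).all()):
            raise ValueError("label outside the declared class set")
    k = classes.size
    ti = np.searchsorted(classes, t)
    pi = np.searchsorted(classes, p)
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (ti, pi), 1)

    diag = np.diag(conf).astype(float)
    col = conf.sum(axis=0).astype(float)    # predicted counts
    row = conf.sum(axis=1).astype(float)    # true counts
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col > 0, diag / col, 0.0)
        rec = np.where(row > 0, diag / row, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    n = conf.sum()
    acc = 100.0 * diag.sum() / n

    # Multiclass MCC from the confusion matrix.
    s = float(n)
    c = diag.sum()
    num = c * s - float(row @ col)
    den = np.sqrt((s * s - float(col @ col)) * (s * s - float(row @ row)))
    mcc = num / den if den > 0 else 0.0

    return EvalReport(confusion=conf, classes=classes, acc=float(acc),
                      precision=float(100.0 * prec.mean()),
                      recall=float(100.0 * rec.mean()),
                      f1=float(100.0 * f1.mean()),
                      mcc=float(100.0 * mcc))


def mcnemar_exact(pred_a: np.ndarray, pred_b: np.ndarray,
                  true: np.ndarray) -> float:
    """Exact two-sided McNemar p-value from discordant pairs.

    b counts samples classifier A gets right and B wrong, c the converse;
    p = min(1, 2 P(X <= min(b, c))) for X ~ Binomial(b + c, 1/2), and
    p = 1 when there are no discordant pairs.
    """
    a = np.asarray(pred_a).ravel()
    bb = np.asarray(pred_b).ravel()
    t = np.asarray(true).ravel()
    if not (a.size == bb.size == t.size):
        raise ValueError("prediction and truth lengths differ")
    right_a = a == t
    right_b = bb == t
    b = int(np.count_nonzero(right_a & ~right_b))
    c = int(np.count_nonzero(~right_a & right_b))
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment, monotone and capped at 1, input order."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
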