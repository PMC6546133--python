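"""NMF-based binary classifiers.

Spectra are mapped to features by correlation with the pseudo spectra,
``f = y X^T``.  Two constructions are supported:

* *optimized* — a fresh classifier (Fisher LDA or maximum-likelihood
  logistic regression) is trained on the features ``F = Y X^T``, ignoring
  any regression weights the NMF may have produced;
* *integrated* — the supervised NMF's own weight vector ``beta`` is used
  directly: the Flda family scores ``Y X^T beta`` against a threshold
  chosen to maximize training balanced accuracy, while Flog thresholds
  the logistic probabilities ``sigmoid([1 | Y X^T] beta)`` at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .nmf_unsupervised import NMFFactors

__all__ = [
    "ClassifierModel",
    "feature_map",
    "fit_lda",
    "fit_logreg",
    "integrated_threshold",
    "build_classifier",
    "predict",
    "discriminatory_pattern",
]

_KINDS = ("lda", "logreg", "integrated_lda", "integrated_log")


@dataclass
class ClassifierModel:
    """A fitted decision rule over the feature map ``y -> y X^T``.

    ``weights`` holds the LDA direction, the logistic coefficients
    (intercept first), or the NMF's beta for the integrated variants;
    ``threshold`` is the decision cut (fixed at 0.5 on the probability
    scale for logistic kinds).
    """

    kind: str
    pattern_matrix: np.ndarray
    weights: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        self.pattern_matrix = np.asarray(self.pattern_matrix, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if (self.pattern_matrix < 0).any():
            raise ValueError("pattern matrix must be non-negative")
        if self.kind == "integrated_lda" and (self.weights < 0).any():
            raise ValueError("integrated_lda weights must be non-negative")


def feature_map(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Correlation features ``F = Y X^T`` (n x p, non-negative)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    if Y.shape[1] != X.shape[1]:
        raise ValueError(
            f"channel mismatch: Y has {Y.shape[1]} columns, X has {X.shape[1]}"
        )
    return Y @ X.T


def _check_two_classes(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=int).ravel()
    if len(np.unique(u)) < 2:
        raise ValueError("both classes must be present")
    return u


def fit_lda(F: np.ndarray, u: np.ndarray,
            pattern_matrix: Optional[np.ndarray] = None) -> ClassifierModel:
    """Fisher's linear discriminant with pooled covariance and equal priors.

    ``weights = S_w^{-1} (m1 - m0)`` with a small ridge on the pooled
    within-class scatter; the threshold is the midpoint of the projected
    class means.  If the class means coincide the direction is undefined
    and a majority-class rule (zero weights) is returned.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    u = _check_two_classes(u)
    F0, F1 = F[u == 0], F[u == 1]
    m0, m1 = F0.mean(axis=0), F1.mean(axis=0)
    d = F.shape[1]
    Sw = np.zeros((d, d))
    for Fc, mc in ((F0, m0), (F1, m1)):
        C = Fc - mc
        Sw += C.T @ C
    Sw /= max(len(u) - 2, 1)
    if np.linalg.norm(m1 - m0) < 1e-12:
        # equal class means: direction undefined; fall back to majority class
        w = np.zeros(d)
        majority = 1 if (u == 1).sum() > (u == 0).sum() else 0
        t = 0.0 if majority == 1 else np.inf
    else:
        w = np.linalg.solve(Sw + 1e-8 * np.eye(d), m1 - m0)
        t = 0.5 * (w @ m0 + w @ m1)
    if pattern_matrix is None:
        pattern_matrix = np.zeros((0, 0))
    return ClassifierModel("lda", pattern_matrix, w, float(t))


def fit_logreg(F: np.ndarray, u: np.ndarray,
               pattern_matrix: Optional[np.ndarray] = None,
               max_iter: int = 200, tol: float = 1e-10) -> ClassifierModel:
    """Unregularized binary logistic regression with intercept.

    Fitted by Newton iterations (iteratively reweighted least squares)
    with a tiny Hessian ridge for numerical safety; on separable data the
    iteration simply stops at ``max_iter``.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    u = _check_two_classes(u).astype(float)
    n, d = F.shape
    Z = np.hstack([np.ones((n, 1)), F])
    w = np.zeros(d + 1)
    for _ in range(max_iter):
        s = expit(Z @ w)
        grad = Z.T @ (s - u)
        R = s * (1 - s)
        H = (Z * R[:, None]).T @ Z + 1e-10 * np.eye(d + 1)
        step = np.linalg.solve(H, grad)
        w_new = w - step
        if not np.all(np.isfinite(w_new)):
            break
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    if pattern_matrix is None:
        pattern_matrix = np.zeros((0, 0))
    return ClassifierModel("logreg", pattern_matrix, w, 0.5)


def _balanced_accuracy_at(scores: np.ndarray, u: np.ndarray,
                          t: float) -> float:
    pred = scores >= t
    pos, neg = u == 1, u == 0
    return 0.5 * (pred[pos].mean() + (~pred[neg]).mean())


def integrated_threshold(scores: np.ndarray, u: np.ndarray) -> float:
    """Decision cut maximizing training balanced accuracy.

    Balanced accuracy is piecewise constant in the threshold, so the exact
    optimum lies among the midpoints of consecutive sorted unique scores
    (plus sentinels below and above all scores).  Ties are broken toward
    the smallest optimal threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    u = _check_two_classes(u)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], 0.5 * (uniq[:-1] + uniq[1:]), [np.inf]]
    )
    best_t, best_ba = -np.inf, -1.0
    for t in candidates:
        ba = _balanced_accuracy_at(scores, u, t)
        if ba > best_ba + 1e-15:
            best_ba, best_t = ba, t
    return float(best_t)


def build_classifier(scheme: str, factors: NMFFactors, Y: np.ndarray,
                     u: np.ndarray) -> ClassifierModel:
    """Construct the classifier named by a scheme id such as ``FR_lda``.

    The suffix selects the construction: ``_lda``/``_log`` refit an
    optimized classifier on ``F = Y X^T``; ``_int`` wraps the supervised
    NMF's beta (requires ``factors.beta``) — the Flda family with a
    balanced-accuracy-optimal threshold on ``Y X^T beta``, Flog with the
    fixed probability threshold 0.5.
    """
    model, _, suffix = scheme.rpartition("_")
    if suffix not in ("lda", "log", "int"):
        raise ValueError(f"scheme {scheme!r} must end in _lda, _log or _int")
    X = factors.X
    if suffix == "lda":
        return fit_lda(feature_map(Y, X), u, pattern_matrix=X)
    if suffix == "log":
        return fit_logreg(feature_map(Y, X), u, pattern_matrix=X)
    if factors.beta is None:
        raise ValueError(
            f"scheme {scheme!r} needs the supervised NMF's beta; "
            "fit a supervised model first"
        )
    beta = factors.beta
    if beta.size == X.shape[0] + 1:  # logistic family: intercept first
        return ClassifierModel("integrated_log", X, beta, 0.5)
    scores = feature_map(Y, X) @ beta
    t = integrated_threshold(scores, u)
    return ClassifierModel("integrated_lda", X, beta, t)


def predict(model: ClassifierModel, Y_new: np.ndarray) -> np.ndarray:
    """Apply the feature map and decision rule; returns labels in {0, 1}."""
    Y_new = np.atleast_2d(np.asarray(Y_new, dtype=float))
    X = model.pattern_matrix
    if X.size and Y_new.shape[1] != X.shape[1]:
        raise ValueError(
            f"channel mismatch: data has {Y_new.shape[1]} columns, "
            f"patterns have {X.shape[1]}"
        )
    if model.kind == "lda":
        F = feature_map(Y_new, X) if X.size else Y_new
        return (F @ model.weights >= model.threshold).astype(int)
    if model.kind == "logreg":
        F = feature_map(Y_new, X) if X.size else Y_new
        p = expit(model.weights[0] + F @ model.weights[1:])
        return (p >= model.threshold).astype(int)
    if model.kind == "integrated_lda":
        scores = feature_map(Y_new, X) @ model.weights
        return (scores >= model.threshold).astype(int)
    # integrated_log
    p = expit(model.weights[0] + feature_map(Y_new, X) @ model.weights[1:])
    return (p >= model.threshold).astype(int)


def discriminatory_pattern(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """The beta-weighted combination of pseudo spectra, ``x_beta = X^T beta``.

    For a logistic beta of length p+1 the intercept is dropped first.  The
    result (length m) is the spectral pattern that drives the integrated
    classifier's decision.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    p = X.shape[0]
    if beta.size == p + 1:
        beta = beta[1:]
    elif beta.size != p:
        raise ValueError(
            f"beta length {beta.size} matches neither p={p} nor p+1"
        )
    return X.T @ beta
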