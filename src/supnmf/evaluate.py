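"""Group-level cross-validation, balanced accuracy and diagnostics.

Cross-validation is leave-one-group-out: with spectra grouped by their
measurement unit (e.g. the TMA slide of origin), each fold trains the
*entire* pipeline — NMF decomposition and classifier — on all other
groups and predicts the held-out group, so the reported accuracy reflects
robustness to between-measurement variation.  The union of the per-fold
predictions covers every spectrum exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import build_classifier, fit_lda, fit_logreg, feature_map, predict
from .dataio import SpectraDataset
from .nmf_supervised import fit_supervised
from .nmf_unsupervised import (
    NMFConfig,
    SUPERVISED_MODELS,
    UNSUPERVISED_MODELS,
    fit_nmf,
)

__all__ = [
    "CVResult",
    "balanced_accuracy",
    "group_kfold",
    "run_cv",
    "fold_variation",
    "active_weights",
    "active_weight_curve",
    "parse_scheme",
]


def parse_scheme(scheme: str) -> tuple[str, str]:
    """Split a scheme id like ``Flog_int`` into (NMF model, classifier suffix)."""
    model, _, suffix = scheme.rpartition("_")
    if suffix not in ("lda", "log", "int") or not model:
        raise ValueError(
            f"scheme {scheme!r} must be '<model>_lda', '<model>_log' or "
            "'<model>_int'"
        )
    if model not in UNSUPERVISED_MODELS + SUPERVISED_MODELS:
        raise ValueError(f"unknown NMF model {model!r} in scheme {scheme!r}")
    if suffix == "int" and model not in SUPERVISED_MODELS:
        raise ValueError(
            f"scheme {scheme!r}: the integrated classifier requires a "
            "supervised NMF model"
        )
    return model, suffix


@dataclass
class CVResult:
    """Outcome of a leave-one-group-out cross-validation run."""

    fold_assignments: Dict[object, int]
    per_fold_balanced_accuracy: np.ndarray
    pooled_predictions: np.ndarray
    scheme: str
    p: int
    labels: np.ndarray

    @property
    def pooled_balanced_accuracy(self) -> float:
        """Balanced accuracy of the union of all fold predictions."""
        return balanced_accuracy(self.labels, self.pooled_predictions)

    @property
    def mean_fold_balanced_accuracy(self) -> float:
        return float(np.nanmean(self.per_fold_balanced_accuracy))

    def to_table(self) -> pd.DataFrame:
        """Per-fold summary (fold, group, n_test, balanced_accuracy)."""
        groups = sorted(self.fold_assignments, key=self.fold_assignments.get)
        return pd.DataFrame(
            {
                "fold": [self.fold_assignments[g] for g in groups],
                "group": groups,
                "balanced_accuracy": self.per_fold_balanced_accuracy,
            }
        )


def balanced_accuracy(u_true: np.ndarray, u_pred: np.ndarray) -> float:
    """Mean of the two class sensitivities, ``(TPR + TNR) / 2``.

    Insensitive to class proportions; requires both classes in ``u_true``.
    """
    u_true = np.asarray(u_true, dtype=int).ravel()
    u_pred = np.asarray(u_pred, dtype=int).ravel()
    if u_true.shape != u_pred.shape:
        raise ValueError("prediction length does not match truth")
    pos, neg = u_true == 1, u_true == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy undefined: truth is single-class")
    tpr = (u_pred[pos] == 1).mean()
    tnr = (u_pred[neg] == 0).mean()
    return float(0.5 * (tpr + tnr))


def group_kfold(groups: Sequence) -> list[tuple[object, np.ndarray, np.ndarray]]:
    """Leave-one-group-out folds: one per distinct group id.

    Returns ``(group_id, train_index, test_index)`` triples; the test sets
    partition the spectra and no spectrum is in its own training set.
    """
    groups = np.asarray(groups)
    uniq = sorted(np.unique(groups).tolist())
    if len(uniq) < 2:
        raise ValueError("group-level CV needs at least 2 distinct groups")
    folds = []
    for g in uniq:
        test = np.flatnonzero(groups == g)
        train = np.flatnonzero(groups != g)
        folds.append((g, train, test))
    return folds


def _fit_for_scheme(model: str, Y: np.ndarray, u: np.ndarray,
                    config: NMFConfig):
    config = replace(config, model=model)
    if model in SUPERVISED_MODELS:
        factors, _ = fit_supervised(Y, u, config)
    else:
        factors, _ = fit_nmf(Y, config)
    return factors


def run_cv(ds: SpectraDataset, scheme: str, config: NMFConfig) -> CVResult:
    """Leave-one-group-out CV of a full NMF + classifier pipeline.

    Per fold, the NMF decomposition is computed on the training groups
    only, the classifier is built on the training features, and the
    held-out group is predicted.  Per-fold balanced accuracies (NaN when a
    test group is single-class) and the pooled prediction are returned.
    """
    if ds.labels is None or ds.groups is None:
        raise ValueError("run_cv requires labels and groups on the dataset")
    model, _ = parse_scheme(scheme)
    folds = group_kfold(ds.groups)
    pooled = np.full(ds.n_spectra, -1, dtype=int)
    fold_assignments: Dict[object, int] = {}
    per_fold = []
    for k, (g, train, test) in enumerate(folds):
        u_train = ds.labels[train]
        if len(np.unique(u_train)) < 2:
            raise ValueError(
                f"fold {k} (test group {g!r}): training labels are "
                "single-class"
            )
        Y_train = ds.intensities[train]
        factors = _fit_for_scheme(model, Y_train, u_train, config)
        clf = build_classifier(scheme, factors, Y_train, u_train)
        pred = predict(clf, ds.intensities[test])
        pooled[test] = pred
        fold_assignments[g] = k
        u_test = ds.labels[test]
        if len(np.unique(u_test)) < 2:
            per_fold.append(np.nan)
        else:
            per_fold.append(balanced_accuracy(u_test, pred))
    assert (pooled >= 0).all(), "every spectrum must be predicted exactly once"
    return CVResult(
        fold_assignments=fold_assignments,
        per_fold_balanced_accuracy=np.array(per_fold),
        pooled_predictions=pooled,
        scheme=scheme,
        p=config.p,
        labels=ds.labels.copy(),
    )


def fold_variation(cv: CVResult) -> tuple[float, float]:
    """Minimum and maximum per-fold balanced accuracy."""
    ba = cv.per_fold_balanced_accuracy
    if ba.size == 0:
        raise ValueError("no folds")
    return float(np.nanmin(ba)), float(np.nanmax(ba))


def active_weights(beta: np.ndarray, frac: float = 0.10,
                   has_intercept: bool = False) -> int:
    """Count regression weights exceeding ``frac`` of the maximum |weight|.

    A weight is *active* when its absolute value is greater than
    ``frac * max|beta|`` (default: 10%).  For logistic weight vectors the
    leading intercept is excluded from both the maximum and the count
    (it shifts the decision boundary rather than weighting a pseudo
    spectrum).  An all-zero vector has no active weights.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size == 0:
        raise ValueError("beta is empty")
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    if has_intercept:
        beta = beta[1:]
    mx = np.abs(beta).max(initial=0.0)
    if mx == 0:
        return 0
    return int((np.abs(beta) > frac * mx).sum())


def active_weight_curve(ds: SpectraDataset, schemes: Iterable[str],
                        p_grid: Sequence[int],
                        config: NMFConfig) -> pd.DataFrame:
    """Active-weight counts as a function of the feature count ``p``.

    For a bare supervised model name (e.g. ``Flog``) the NMF's own beta is
    counted; for a two-step scheme (e.g. ``FR_log``) the refit
    classifier's weight vector is counted instead.  Intercepts are always
    excluded.  Deterministic given ``config.seed``.
    """
    if ds.labels is None:
        raise ValueError("active_weight_curve requires labels")
    Y, u = ds.intensities, ds.labels
    rows = []
    for scheme in schemes:
        for p in p_grid:
            cfg = replace(config, p=int(p))
            if "_" in scheme:
                model, suffix = parse_scheme(scheme)
                factors = _fit_for_scheme(model, Y, u, cfg)
                if suffix == "int":
                    beta, intercept = factors.beta, factors.beta.size == p + 1
                else:
                    F = feature_map(Y, factors.X)
                    clf = fit_logreg(F, u) if suffix == "log" else fit_lda(F, u)
                    beta = clf.weights
                    intercept = suffix == "log"
            else:
                if scheme not in SUPERVISED_MODELS:
                    raise ValueError(
                        f"bare scheme {scheme!r} must be a supervised model"
                    )
                factors = _fit_for_scheme(scheme, Y, u, cfg)
                beta = factors.beta
                intercept = scheme == "Flog"
            rows.append(
                {
                    "scheme": scheme,
                    "p": int(p),
                    "active_weights": active_weights(
                        beta, has_intercept=intercept
                    ),
                }
            )
    return pd.DataFrame(rows)
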