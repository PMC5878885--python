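"""The search objective: 5-fold cross-validated AUC of a logistic model.

Logistic regression is used as the classification estimator because it is
deterministic — repeated fitness evaluations of the same mask return the
same value — and cheap enough to evaluate thousands of candidate
specifications.  Fold assignment is stratified by outcome (the critical
outcome is rare, ~3%) and fixed by a single ``fold_seed`` so that fitness
differences between masks reflect the masks, not fold noise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_model import Cohort, SpecificationMask
from .design import DesignMatrix, build_design
from .errors import (
    ConvergenceError,
    FitError,
    StratificationError,
    UndefinedAUCError,
    ValidationError,
)

_PROB_EPS = 1e-12


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2.

    Computed from midranks, which is algebraically (and in floating point,
    for realistic sizes, bitwise) identical to the all-pairs count
    ``(#{pos > neg} + 0.5 * #{pos == neg}) / (m * n)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-D vectors")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be 0/1")
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise UndefinedAUCError("AUC is undefined with a single outcome class")
    r = rankdata(s)
    return float((r[y == 1].sum() - m * (m + 1) / 2) / (m * n))


@dataclass
class FittedModel:
    """Logistic coefficients aligned with a design's columns.

    Dropped reference-level columns carry coefficient 0 so that the linear
    predictor can be formed against the full indicator matrix.
    """

    coefficients: np.ndarray
    intercept: float
    column_names: list[str]

    def predict_proba(self, design: DesignMatrix | sp.spmatrix | np.ndarray) -> np.ndarray:
        X = design.values if isinstance(design, DesignMatrix) else design
        eta = np.asarray(X @ self.coefficients).ravel() + self.intercept
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)


def _fit_raw(
    X: sp.spmatrix,
    y: np.ndarray,
    ridge: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float]:
    """Fit and return (coefficients, intercept).

    A zero-column design has the closed-form intercept-only solution
    logit(prevalence).
    """
    if ridge < 0:
        raise ValidationError("ridge must be non-negative")
    if len(np.unique(y)) < 2:
        raise ValidationError("logistic fit needs both outcome classes")
    if X.shape[1] == 0:
        prev = float(np.mean(y))
        return np.empty(0), float(np.log(prev / (1 - prev)))
    C = np.inf if ridge == 0 else 1.0 / ridge
    clf = LogisticRegression(
        C=C, l1_ratio=0.0, solver="lbfgs", tol=tol, max_iter=max_iter
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    if clf.n_iter_[0] >= max_iter:
        biggest = float(np.abs(clf.coef_).max())
        hint = (
            " (possible complete separation; refit with ridge > 0)"
            if ridge == 0 and biggest > 15
            else ""
        )
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations; "
            f"max|coef| = {biggest:.3g}{hint}"
        )
    if ridge == 0 and float(np.abs(clf.coef_).max()) > 30:
        raise FitError(
            "complete separation suspected (a coefficient diverged); "
            "refit with ridge > 0"
        )
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def fit_logistic(
    design: DesignMatrix,
    ridge: float = 0.0,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FittedModel:
    """Maximum-likelihood (ridge-penalized if ridge > 0) logistic fit.

    The design's exclusive blocks each have their reference column dropped
    before fitting (full rank with an intercept); the returned coefficient
    vector is re-expanded to the full column set with zeros at references.
    """
    X, _, kept = design.for_fitting()
    w, b = _fit_raw(X, design.outcome, ridge, tol, max_iter)
    coef = np.zeros(len(design.column_names))
    coef[kept] = w
    return FittedModel(coef, b, list(design.column_names))


@dataclass
class CVResult:
    """Pooled out-of-fold predictions from k-fold cross-validation."""

    oof_probabilities: np.ndarray
    fold_assignment: np.ndarray
    auc: float
    fold_aucs: tuple[float, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "record": np.arange(len(self.oof_probabilities)),
            "fold": self.fold_assignment,
            "oof_probability": self.oof_probabilities,
        })


def stratified_folds(cohort: Cohort, k: int, fold_seed: int) -> list:
    """Outcome-stratified fold index pairs, cached per cohort."""
    key = ("folds", k, fold_seed)
    if key not in cohort._cache:
        y = cohort.outcome
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise StratificationError(
                f"cannot form {k} stratified folds: rarest class has "
                f"{counts.min()} records"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        cohort._cache[key] = list(skf.split(np.zeros(len(y)), y))
    return cohort._cache[key]


def cv_fitness(
    cohort: Cohort,
    mask: SpecificationMask | None,
    mode: str,
    k: int = 5,
    fold_seed: int = 0,
    ridge: float = 1e-6,
    *,
    tol: float = 1e-4,
    max_iter: int = 500,
    fold_average: bool = False,
) -> CVResult:
    """k-fold cross-validated AUC for a specification mask under ``mode``.

    Each record's probability comes from the fold model that did not train
    on it; the headline ``auc`` pools all out-of-fold probabilities (set
    ``fold_average=True`` for the mean of per-fold AUCs instead).  The
    default ridge (1e-6) is effectively unpenalized but guards against
    complete separation by rare complaint indicators.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    design = build_design(cohort, mask, mode)
    X, _, _ = design.for_fitting()
    y = np.asarray(design.outcome, dtype=np.int8)
    folds = stratified_folds(cohort, k, fold_seed)

    oof = np.empty(len(y))
    assign = np.empty(len(y), dtype=np.intp)
    fold_aucs = []
    for i, (train, test) in enumerate(folds):
        if len(np.unique(y[train])) < 2:
            raise StratificationError(f"fold {i}: training split is single-class")
        try:
            w, b = _fit_raw(X[train], y[train], ridge, tol, max_iter)
        except FitError as exc:
            raise FitError(f"fold {i}: {exc}") from exc
        eta = np.asarray(X[test] @ w).ravel() + b
        oof[test] = np.clip(
            1.0 / (1.0 + np.exp(-eta)), _PROB_EPS, 1.0 - _PROB_EPS
        )
        assign[test] = i
        fold_aucs.append(auc(oof[test], y[test]))

    pooled = auc(oof, y)
    value = float(np.mean(fold_aucs)) if fold_average else pooled
    return CVResult(oof, assign, value, tuple(fold_aucs))
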