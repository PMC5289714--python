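"""Logistic-regression classification under repeated stratified 10-fold CV.

The classifier is the logistic model F(z) = 1 / (1 + e^-z) with
z = alpha + sum_k beta_k X_k; a subject is called positive (responder) when
F(z) exceeds the 0.5 threshold.  Feature standardization and selection are
re-fit inside every training fold so the test fold never informs them, and
the whole procedure is repeated (100 x 10-fold by default) to obtain
mean +/- SD distributions of accuracy, sensitivity, specificity and
F-measure from the pooled per-repeat confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .selection import (FeatureMatrix, auc_rank, mrmr_select, prune_correlated,
                        take_top)

#: subset sizes swept when probing for over-fitting
DEFAULT_SUBSET_SIZES: tuple[int, ...] = (1, 2, 3, 4, 5, 10, 15, 20, 25, 30, 35, 50)


@dataclass
class LogisticModel:
    alpha: float
    beta: np.ndarray
    threshold: float = 0.5
    feature_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class ConfusionMatrix:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass
class CVReport:
    """Per-repeat pooled confusion matrices and derived metric distributions."""

    confusions: list[ConfusionMatrix]
    folds: int
    repeats: int
    subset_size: int
    selected_indices: list[list[np.ndarray]] = field(default_factory=list)

    def metric(self, name: str) -> np.ndarray:
        return np.array([confusion_metrics(cm)[name] for cm in self.confusions],
                        dtype=float)

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "f_measure"):
            vals = self.metric(name)
            out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out


# ---------------------------------------------------------------------------
# model fit / predict / metrics
# ---------------------------------------------------------------------------

def fit_logistic(X: np.ndarray, y: np.ndarray,
                 ridge: float = 1e-6,
                 feature_indices: np.ndarray | None = None) -> LogisticModel:
    """Maximum-likelihood logistic fit.

    ``ridge`` is a vanishing L2 strength that only guards the optimiser
    against perfect separability; it is not meant as regularization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValueError("NaN in design matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    clf.fit(X, (y == np.max(y)).astype(int))
    return LogisticModel(float(clf.intercept_[0]), clf.coef_[0],
                         feature_indices=feature_indices)


def predict(model: LogisticModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (F(z), labels); positive iff F(z) strictly exceeds the threshold."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(model.beta):
        raise ValueError(
            f"{X.shape[1]} columns do not match the model's {len(model.beta)}")
    z = model.alpha + X @ model.beta
    proba = expit(z)
    return proba, proba > model.threshold


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, F-measure from confusion counts.

    Metrics with empty denominators are reported as NaN (undefined), not 0.
    """
    sens = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN > 0 else float("nan")
    spec = cm.TN / (cm.TN + cm.FP) if cm.TN + cm.FP > 0 else float("nan")
    acc = (cm.TP + cm.TN) / cm.total if cm.total > 0 else float("nan")
    denom = 2 * cm.TP + cm.FP + cm.FN
    f = 2 * cm.TP / denom if denom > 0 else float("nan")
    return dict(sensitivity=sens, specificity=spec, accuracy=acc, f_measure=f)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    dead = sd == 0
    sd = np.where(dead, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd, dead


def cross_validate(features: FeatureMatrix, k_features: int,
                   folds: int = 10, repeats: int = 100, seed: int = 0,
                   selector: str = "roc", r_max: float | None = 0.9,
                   positive_class: str = "R", y: np.ndarray | None = None,
                   group_by_subject: bool = True, permute_labels: bool = False,
                   record_selection: bool = False) -> CVReport:
    """Repeated stratified k-fold CV with in-fold selection and fitting.

    Within every training fold the features are standardized, ranked
    (ROC-based by default, correlation-pruned when ``r_max`` is set, or
    mRMR-selected), the top ``k_features`` are kept, and a logistic model is
    fit; the untouched test fold is then standardized and selected with the
    train-derived statistics and indices.  EC and EO instances of the same
    subject share a fold when ``group_by_subject`` (identity-leakage guard).

    ``permute_labels`` draws a fresh subject-level label permutation for every
    repeat, giving the permutation-null distribution of the metrics.
    """
    X = features.values
    if y is None:
        y01 = (features.labels(positive_class) == 1).astype(int)
    else:
        y = np.asarray(y)
        y01 = (y == np.max(y)).astype(int)
    counts = np.bincount(y01, minlength=2)
    if counts.min() < folds and not group_by_subject:
        raise ValueError(
            f"class sizes {counts.tolist()} too small for {folds} stratified folds")
    groups = features.instance_meta["subject_id"].to_numpy()
    rng = np.random.default_rng(seed)

    confusions: list[ConfusionMatrix] = []
    all_selected: list[list[np.ndarray]] = []
    base_y01 = y01
    for _rep in range(repeats):
        rs = int(rng.integers(0, 2 ** 31 - 1))
        if permute_labels:
            # permute the subject -> label map, keeping a subject's instances consistent
            subj, first = np.unique(groups, return_index=True)
            perm = rng.permutation(base_y01[first])
            lut = dict(zip(subj, perm))
            y01 = np.array([lut[g] for g in groups])
        if group_by_subject:
            splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                            random_state=rs)
            split_iter = splitter.split(X, y01, groups)
        else:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(X, y01)
        pooled = ConfusionMatrix()
        rep_selected: list[np.ndarray] = []
        for tr, te in split_iter:
            ztr, zte, dead = _fold_standardize(X[tr], X[te])
            ytr = np.where(y01[tr] == 1, 1, -1)
            if selector == "roc":
                ranked = auc_rank(ztr, ytr)
                ranked.auc[dead] = 0.0
                ranked.order = ranked.order[~dead[ranked.order]]
                if r_max is not None:
                    ranked = prune_correlated(ranked, ztr, r_max=r_max,
                                              max_keep=k_features)
                else:
                    ranked.retained = ranked.order
                idx = take_top(ranked, min(k_features, ranked.N_r))
            elif selector == "mrmr":
                idx = mrmr_select(ztr, ytr, k=k_features)
            else:
                raise ValueError(f"unknown selector {selector!r}")
            rep_selected.append(idx)
            model = fit_logistic(ztr[:, idx], ytr, feature_indices=idx)
            _, pred = predict(model, zte[:, idx])
            yte = y01[te] == 1
            pooled = pooled + ConfusionMatrix(
                TP=int(np.sum(pred & yte)), FP=int(np.sum(pred & ~yte)),
                TN=int(np.sum(~pred & ~yte)), FN=int(np.sum(~pred & yte)))
        confusions.append(pooled)
        if record_selection:
            all_selected.append(rep_selected)
    return CVReport(confusions, folds, repeats, k_features, all_selected)


def subset_sweep(features: FeatureMatrix,
                 sizes=DEFAULT_SUBSET_SIZES, **cv_kwargs) -> dict[int, CVReport]:
    """One :func:`cross_validate` run per subset size."""
    if max(sizes) > features.n_features:
        raise ValueError("largest subset size exceeds the available features")
    return {int(k): cross_validate(features, k_features=int(k), **cv_kwargs)
            for k in sizes}


def combine_features(matrices: list[FeatureMatrix],
                     index_lists: list[np.ndarray] | None = None,
                     k_each: int = 15) -> FeatureMatrix:
    """Column-wise concatenation of the top features of several methods.

    With three 15-feature lists this yields the combined 45-column matrix.
    ``index_lists`` give the per-method selected columns (defaults to the
    first ``k_each`` of each matrix).
    """
    if not matrices:
        raise ValueError("no feature matrices given")
    base = matrices[0].instance_meta[["subject_id", "condition"]]
    for m in matrices[1:]:
        if not base.equals(m.instance_meta[["subject_id", "condition"]]):
            raise ValueError("instance metadata mismatch between methods")
    if index_lists is None:
        index_lists = [np.arange(min(k_each, m.n_features)) for m in matrices]
    vals, metas = [], []
    for m, idx in zip(matrices, index_lists):
        idx = np.asarray(idx)[:k_each]
        vals.append(m.values[:, idx])
        metas.append(m.feature_meta.iloc[idx])
    return FeatureMatrix(np.hstack(vals),
                         pd.concat(metas, ignore_index=True),
                         matrices[0].instance_meta.copy())
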