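"""Control-referenced standardization and rank-based feature selection.

Features are z-scored against the healthy-control sample
(z_l = (x_l - mu_l) / sigma_l) and then ranked by the area between each
feature's empirical ROC curve and the chance diagonal (the signed "z-value"
in [-0.5, 0.5]); ranking is by absolute value.  Redundant features are
removed by greedy correlation pruning, and an mRMR selector is provided as
the comparison method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score


@dataclass
class FeatureMatrix:
    """Instances x features with per-column and per-row metadata."""

    values: np.ndarray
    feature_meta: pd.DataFrame      # columns: channel, band, method, index (at least)
    instance_meta: pd.DataFrame     # columns: subject_id, condition, group (at least)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (instances x features)")
        if len(self.feature_meta) != self.values.shape[1]:
            raise ValueError("feature_meta rows must equal the number of columns")
        if len(self.instance_meta) != self.values.shape[0]:
            raise ValueError("instance_meta rows must equal the number of rows")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels(self, positive_class: str) -> np.ndarray:
        """+1/-1 encoding of the binary group label."""
        groups = self.instance_meta["group"].to_numpy()
        classes = set(groups)
        if positive_class not in classes or len(classes) != 2:
            raise ValueError(
                f"need exactly two groups including {positive_class!r}, got {sorted(classes)}")
        return np.where(groups == positive_class, 1, -1)

    def subset(self, rows=None, cols=None) -> "FeatureMatrix":
        rows = slice(None) if rows is None else np.asarray(rows)
        cols = slice(None) if cols is None else np.asarray(cols)
        return FeatureMatrix(
            self.values[rows][:, cols],
            self.feature_meta.iloc[cols].reset_index(drop=True),
            self.instance_meta.iloc[rows].reset_index(drop=True),
        )


@dataclass
class NormalizationReference:
    """Per-feature mean/SD estimated on the healthy-control sample."""

    mu: np.ndarray
    sigma: np.ndarray
    n_reference: int
    valid: np.ndarray = field(default=None)  # columns with sigma > 0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.mu), dtype=bool)


@dataclass
class RankedFeatureList:
    """Feature ordering by descending |auc| plus the retained subset."""

    order: np.ndarray               # permutation of column indices
    auc: np.ndarray                 # signed area-minus-half per feature
    retained: np.ndarray            # indices surviving correlation pruning

    @property
    def N_r(self) -> int:
        return len(self.retained)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def fit_reference(controls) -> NormalizationReference:
    """Per-feature mu_l, sigma_l (n-1 denominator) over the reference sample."""
    x = controls.values if isinstance(controls, FeatureMatrix) else np.asarray(controls, float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 reference instances")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    valid = sigma > 0
    if not valid.all():
        warnings.warn(
            f"dropping {int((~valid).sum())} zero-variance feature(s) from the reference")
    return NormalizationReference(mu, sigma, x.shape[0], valid)


def standardize(patients, ref: NormalizationReference):
    """Column-wise z_l = (x_l - mu_l) / sigma_l; zero-variance columns dropped.

    Accepts and returns either a plain array or a :class:`FeatureMatrix`.
    """
    is_fm = isinstance(patients, FeatureMatrix)
    x = patients.values if is_fm else np.asarray(patients, float)
    if x.shape[1] != len(ref.mu):
        raise ValueError(
            f"feature columns ({x.shape[1]}) do not align with the reference "
            f"({len(ref.mu)})")
    z = (x[:, ref.valid] - ref.mu[ref.valid]) / ref.sigma[ref.valid]
    if not is_fm:
        return z
    return FeatureMatrix(
        z,
        patients.feature_meta.loc[ref.valid].reset_index(drop=True),
        patients.instance_meta.copy(),
    )


# ---------------------------------------------------------------------------
# ROC rank-based selection
# ---------------------------------------------------------------------------

def roc_trace(x: np.ndarray, y: np.ndarray) -> dict:
    """Single-feature ROC staircase, step by step.

    Sort the feature values in descending order (stable, so ties keep their
    original order), accumulate the true/false positive fractions, and sum
    trapezoids: Y = midpoints of consecutive tp, X = increments of fp,
    auc = sum(Y * X) - 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, encoded as +1/-1")
    order = np.argsort(-x, kind="stable")
    ys = y[order]
    p = np.cumsum(ys == 1)
    n = np.cumsum(ys == -1)
    tp = p / p[-1]
    fp = n / n[-1]
    Y = (tp[1:] + tp[:-1]) / 2
    X = fp[1:] - fp[:-1]
    auc = float(np.sum(Y * X) - 0.5)
    return dict(sorted_values=x[order], sorted_labels=ys, p=p, n=n,
                tp=tp, fp=fp, Y=Y, X=X, auc=auc)


def _auc_columns(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed ROC area-minus-half for every column (vectorised staircase)."""
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-values, axis=0, kind="stable")
    ys = y[order]                                    # instances x features
    tp = np.cumsum(ys == 1, axis=0) / n_pos
    fp = np.cumsum(ys == -1, axis=0) / n_neg
    Y = (tp[1:] + tp[:-1]) / 2
    X = fp[1:] - fp[:-1]
    return np.sum(Y * X, axis=0) - 0.5


def auc_rank(features, y: np.ndarray | None = None,
             positive_class: str = "R") -> RankedFeatureList:
    """Rank every feature by the absolute signed ROC area ("z-value").

    Ties in |auc| are broken by column index, making the ordering
    deterministic.
    """
    if isinstance(features, FeatureMatrix):
        values = features.values
        if y is None:
            y = features.labels(positive_class)
    else:
        values = np.asarray(features, float)
        if y is None:
            raise ValueError("labels required for a plain array")
    auc = _auc_columns(values, np.asarray(y))
    order = np.argsort(-np.abs(auc), kind="stable")
    return RankedFeatureList(order=order, auc=auc, retained=order.copy())


def prune_correlated(ranked: RankedFeatureList, features, r_max: float = 0.9,
                     max_keep: int | None = None) -> RankedFeatureList:
    """Greedy top-down redundancy removal.

    Walking the ranking from the top, a feature is retained only if its
    absolute Pearson correlation with every already-retained feature stays
    below ``r_max``.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    z = values - values.mean(axis=0)
    norms = np.sqrt((z * z).sum(axis=0))
    norms[norms == 0] = np.inf                      # constant columns correlate with nothing
    z = z / norms
    kept: list[int] = []
    kept_cols: list[np.ndarray] = []
    for idx in ranked.order:
        col = z[:, idx]
        if all(abs(float(col @ other)) < r_max for other in kept_cols):
            kept.append(int(idx))
            kept_cols.append(col)
            if max_keep is not None and len(kept) >= max_keep:
                break
    return RankedFeatureList(order=ranked.order, auc=ranked.auc,
                             retained=np.asarray(kept, dtype=int))


def take_top(ranked: RankedFeatureList, k: int) -> np.ndarray:
    """First ``k`` retained indices (the subset a test fold must reuse)."""
    if k > ranked.N_r:
        raise ValueError(f"k={k} exceeds the {ranked.N_r} retained features")
    return ranked.retained[:k]


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning per column."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1], axis=0)
    out = np.zeros(values.shape, dtype=int)
    for j in range(values.shape[1]):
        out[:, j] = np.searchsorted(np.unique(qs[:, j]), values[:, j], side="right")
    return out


def mrmr_select(features, y: np.ndarray | None = None, k: int = 15,
                n_bins: int = 3, positive_class: str = "R") -> np.ndarray:
    """Greedy minimum-redundancy maximum-relevance selection (MID criterion).

    Features are discretised into ``n_bins`` equal-frequency bins; the first
    pick maximises I(feature; label) and each subsequent pick maximises
    relevance minus the mean mutual information with the already-selected set.
    """
    if isinstance(features, FeatureMatrix):
        values = features.values
        if y is None:
            y = features.labels(positive_class)
    else:
        values = np.asarray(features, float)
    y = np.asarray(y)
    if k > values.shape[1]:
        raise ValueError(f"k={k} exceeds the {values.shape[1]} available features")
    binned = _discretize(values, n_bins)
    relevance = np.array([mutual_info_score(binned[:, j], y)
                          for j in range(binned.shape[1])])
    selected: list[int] = [int(np.argmax(relevance))]
    redundancy = np.zeros(binned.shape[1])
    while len(selected) < k:
        last = selected[-1]
        redundancy += np.array([mutual_info_score(binned[:, j], binned[:, last])
                                for j in range(binned.shape[1])])
        score = relevance - redundancy / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return np.asarray(selected, dtype=int)
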