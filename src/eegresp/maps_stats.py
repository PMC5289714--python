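"""Per-channel group statistics and 2-D scalp maps.

Because the wavelet features are not normally distributed (checked with a
Kolmogorov-Smirnov gate), between-group differences per electrode are tested
with the two-sided Wilcoxon rank-sum test at the 5 % level; each of the 19
10-20 locations receives a binary decision H (1 = reject equal medians),
which is interpolated over the head disc for display.  A linear PCA scatter
of the reduced feature set gives the 2-D view of the two classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .montage import CHANNELS_1020, MONTAGE_XY
from .selection import FeatureMatrix, auc_rank


@dataclass
class TopoMap:
    channel_labels: tuple[str, ...]
    H: np.ndarray                   # per-channel {0,1}
    p_values: np.ndarray
    montage_xy: dict[str, tuple[float, float]]
    stratum: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(channel=list(self.channel_labels),
                                 p=self.p_values, H=self.H))


def ks_normality(x: np.ndarray, alpha: float = 0.05) -> int:
    """One-sample KS test of the standardized data against N(0, 1).

    Returns 1 when normality is rejected at level ``alpha`` (so a 1 routes
    the downstream group comparison to the rank-sum test).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant input; trivially non-normal")
        return 1
    z = (x - x.mean()) / sd
    return int(stats.kstest(z, "norm").pvalue < alpha)


def rank_sum_test(a: np.ndarray, b: np.ndarray,
                  alpha: float = 0.05) -> tuple[int, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) equal-medians test."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return int(res.pvalue < alpha), float(res.pvalue)


def channel_aggregate(features: FeatureMatrix, top_n: int = 100,
                      positive_class: str = "R") -> tuple[np.ndarray, list[str]]:
    """Per-instance scalar per channel: mean of the channel's top-ranked features.

    Channels absent from the ``top_n`` highest-|auc| features fall back to the
    mean over all of their features.
    """
    ranked = auc_rank(features, positive_class=positive_class)
    top = set(ranked.order[:top_n].tolist())
    channels = [c for c in CHANNELS_1020
                if (features.feature_meta["channel"] == c).any()]
    cols = features.feature_meta["channel"].to_numpy()
    agg = np.empty((features.n_instances, len(channels)))
    for j, ch in enumerate(channels):
        idx = [i for i in range(features.n_features) if cols[i] == ch and i in top]
        if not idx:
            idx = list(np.where(cols == ch)[0])
        agg[:, j] = features.values[:, idx].mean(axis=1)
    return agg, channels


def wilcoxon_channel_map(features: FeatureMatrix, positive_class: str = "R",
                         alpha: float = 0.05, top_n: int = 100,
                         sex: str | None = None, condition: str | None = None,
                         fdr: bool = False) -> TopoMap:
    """Binary topographic map of R-vs-NR differences per electrode.

    Instances may be restricted to one sex and/or recording condition
    (gender-stratified maps).  No multiple-testing correction is applied
    across the 19 channels unless ``fdr`` (Benjamini-Hochberg) is requested.
    """
    mask = np.ones(features.n_instances, dtype=bool)
    stratum = []
    if sex is not None:
        mask &= features.instance_meta["sex"].to_numpy() == sex
        stratum.append({"F": "female", "M": "male"}[sex])
    if condition is not None:
        mask &= features.instance_meta["condition"].to_numpy() == condition
        stratum.append(condition)
    sub = features.subset(rows=np.where(mask)[0])
    y = sub.labels(positive_class)
    if min(np.sum(y == 1), np.sum(y == -1)) < 2:
        raise ValueError("need >= 2 instances per group in the stratum")
    agg, channels = channel_aggregate(sub, top_n=top_n, positive_class=positive_class)
    p = np.array([rank_sum_test(agg[y == 1, j], agg[y == -1, j], alpha)[1]
                  for j in range(len(channels))])
    if fdr:
        from statsmodels.stats.multitest import multipletests
        H = multipletests(p, alpha=alpha, method="fdr_bh")[0].astype(int)
    else:
        H = (p < alpha).astype(int)
    xy = {c: MONTAGE_XY[c] for c in channels}
    return TopoMap(tuple(channels), H, p, xy, stratum=" ".join(stratum) or "all")


def topomaps_by_stratum(features: FeatureMatrix, condition_values=("EC", "EO"),
                        stratify_sex: bool = True, **kwargs) -> list[TopoMap]:
    """The paper-style panel: one map per (sex x condition) stratum."""
    sexes = ("F", "M") if stratify_sex else (None,)
    out = []
    for s in sexes:
        for cond in condition_values:
            try:
                out.append(wilcoxon_channel_map(features, sex=s, condition=cond,
                                                **kwargs))
            except ValueError as err:
                warnings.warn(f"stratum sex={s} condition={cond} skipped: {err}")
    return out


def interpolate_topomap(tm: TopoMap, grid_n: int = 64, power: float = 2.0,
                        n_neighbors: int = 2):
    """Inverse-distance interpolation of H onto the head disc.

    Each grid point takes the distance-weighted mean of its ``n_neighbors``
    nearest electrodes; a grid point on an electrode reproduces that
    electrode's H exactly.  Points outside the disc are masked.
    """
    pts = np.array([tm.montage_xy[c] for c in tm.channel_labels])
    radius = 1.05 * np.sqrt((pts ** 2).sum(axis=1)).max()
    axis = np.linspace(-radius, radius, grid_n)
    xx, yy = np.meshgrid(axis, axis)
    grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
    d = np.sqrt(((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    field = np.empty(len(grid))
    for g in range(len(grid)):
        nearest = np.argsort(d[g])[:n_neighbors]
        if d[g, nearest[0]] < 1e-9:
            field[g] = tm.H[nearest[0]]
        else:
            w = 1.0 / d[g, nearest] ** power
            field[g] = float(np.dot(w, tm.H[nearest]) / w.sum())
    field = field.reshape(grid_n, grid_n)
    outside = xx ** 2 + yy ** 2 > radius ** 2
    return xx, yy, np.ma.masked_array(field, mask=outside)


def plot_topomap(tm: TopoMap, ax=None, **interp_kwargs):
    """Red/blue head-disc rendering of a binary map (1 = red, 0 = blue)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xx, yy, field = interpolate_topomap(tm, **interp_kwargs)
    ax.pcolormesh(xx, yy, field, cmap="bwr", vmin=0, vmax=1, shading="auto")
    for c in tm.channel_labels:
        x, y = tm.montage_xy[c]
        ax.plot(x, y, "k.", ms=3)
        ax.annotate(c, (x, y), fontsize=6, ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(tm.stratum)
    return ax


def pca_scatter(features, n_components: int = 2):
    """Scores on the first two principal components plus variance fractions."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise ValueError("need >= 3 instances and >= 2 features")
    centered = values - values.mean(axis=0)
    if np.linalg.matrix_rank(centered) < n_components:
        raise ValueError("data rank below the requested number of components")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(values)
    return scores, pca.explained_variance_ratio_
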