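"""Evaluation-metric suite for the toolkit's benchmarks.

Implements the exact metric definitions used throughout: Calinski-Harabasz
clustering validity, Pearson and Kendall tau-b correlations, base-2
Jensen-Shannon divergence (bounded in [0, 1]), a global (windowless) SSIM for
spatial cell-type maps, per-gene MSE, weighted F1, and the cross-method
impact score that averages z-scored SSIM with inverted z-scored JS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("loki")

__all__ = [
    "MethodResult",
    "SSIMParams",
    "calinski_harabasz",
    "pearson",
    "kendall_tau",
    "js_divergence",
    "ssim_global",
    "impact_scores",
    "weighted_f1",
    "mse_per_gene",
    "rasterize_spots",
]


@dataclass
class MethodResult:
    """Per-cell-type JS and SSIM values of one decomposition method."""

    name: str
    js_values: np.ndarray
    ssim_values: np.ndarray

    def __post_init__(self) -> None:
        self.js_values = np.asarray(self.js_values, dtype=float)
        self.ssim_values = np.asarray(self.ssim_values, dtype=float)


@dataclass
class SSIMParams:
    """Stabilizers for the SSIM ratio: C1 = (k1 L)^2, C2 = (k2 L)^2."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None  # default: max range of the input pair


def calinski_harabasz(X: np.ndarray, labels) -> float:
    """Variance-ratio criterion: (BCSS/(k-1)) / (WCSS/(n-k)).

    BCSS is the size-weighted squared distance of cluster centroids to the
    overall centroid; WCSS the total squared distance of points to their
    cluster centroid. Coincident within-cluster points (WCSS = 0) return an
    infinity sentinel rather than raising, so batch sweeps keep running.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(X), len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    overall = X.mean(axis=0)
    bcss = wcss = 0.0
    for u in uniq:
        members = X[labels == u]
        if len(members) == 0:
            raise ValueError(f"empty cluster {u!r}")
        c = members.mean(axis=0)
        bcss += len(members) * float(np.sum((c - overall) ** 2))
        wcss += float(np.sum((members - c) ** 2))
    if wcss == 0.0:
        logger.warning("calinski_harabasz: zero within-cluster dispersion; returning inf")
        return math.inf
    return (bcss / (k - 1)) / (wcss / (n - k))


def pearson(x, y) -> float:
    """Pearson correlation coefficient; NaN (with a logged flag) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must share length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson: zero variance input; result undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(x, y) -> float:
    """Kendall tau-b: (P-Q)/sqrt((P+Q+T)(P+Q+U)) with tie corrections T, U."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must share length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("kendall_tau: zero variance input; result undefined")
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence with base-2 logarithm, bounded in [0, 1].

    Inputs are nonnegative weight vectors, renormalized to sum 1;
    0*log(0) := 0 by convention.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share shape")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be nonnegative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("distributions must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def ssim_global(x, y, params: SSIMParams | None = None) -> float:
    """Single global SSIM of two maps: whole-map means/variances/covariance, no window."""
    params = params or SSIMParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("maps must share shape")
    L = params.dynamic_range
    if L is None:
        L = max(x.max() - x.min(), y.max() - y.min())
        if L == 0:
            L = 1.0
    c1 = (params.k1 * L) ** 2
    c2 = (params.k2 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def rasterize_spots(coords: np.ndarray, values: np.ndarray, pitch: float) -> np.ndarray:
    """Nearest-spot rasterization of spot-level values onto a pitch-resolution grid.

    Grid cells whose center has no spot within one pitch are left at 0.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    nx = max(int(round((xmax - xmin) / pitch)) + 1, 1)
    ny = max(int(round((ymax - ymin) / pitch)) + 1, 1)
    gx, gy = np.meshgrid(xmin + np.arange(nx) * pitch, ymin + np.arange(ny) * pitch)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(coords)
    dist, idx = tree.query(centers)
    img = np.where(dist <= pitch, values[idx], 0.0)
    return img.reshape(ny, nx)


def impact_scores(results) -> dict:
    """Cross-method impact score: mean of z-scored SSIM and inverted z-scored JS.

    Per method, JS and SSIM are first averaged over cell types; z-scores are
    taken across methods (population sd); the JS z-score is sign-inverted so
    higher is better for both components. Zero cross-method variance yields a
    zero z-score with a logged flag.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("impact scores need >= 2 methods")
    n_types = {len(r.js_values) for r in results} | {len(r.ssim_values) for r in results}
    if len(n_types) != 1:
        raise ValueError("methods must share the cell-type set")
    mean_js = np.array([r.js_values.mean() for r in results])
    mean_ssim = np.array([r.ssim_values.mean() for r in results])

    def zscore(v):
        sd = v.std()
        if sd == 0:
            logger.warning("impact_scores: zero cross-method variance; z set to 0")
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    z_ssim = zscore(mean_ssim)
    z_js = -zscore(mean_js)
    impact = (z_ssim + z_js) / 2.0
    return {
        r.name: {"z_ssim": float(z_ssim[i]), "z_js": float(z_js[i]), "impact": float(impact[i])}
        for i, r in enumerate(results)
    }


def weighted_f1(y_true, y_pred) -> float:
    """Class-frequency-weighted mean of per-class F1 = 2TP/(2TP+FP+FN)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    from sklearn.metrics import f1_score

    labels = np.unique(y_true)  # zero-support classes carry no weight
    return float(f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0))


def mse_per_gene(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Mean squared prediction error across spots, one value per gene."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share shape")
    return ((pred - truth) ** 2).mean(axis=0)
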