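"""Cell-type decomposition by probabilistic mapping of reference cells to spots.

A row-stochastic mapping matrix M (cells-or-clusters x spots) is optimized so
that the projected reference embeddings M^T S match the spot embeddings G
column-by-column in cosine distance — the embedding-space analogue of
Tangram-style cell mapping. Spot-level cell-type probabilities follow by
summing mapped mass per type, and an optional non-maximum-suppression step
keeps only the top type per spot.

M is parameterized as the row-softmax of a free matrix so row-stochasticity
holds at every optimization checkpoint; optimization is Adam on the cosine
loss plus an optional KL-to-uniform spot-density prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import encoder as enc
from .stbank_io import SpotSlide, build_slide_sentences

logger = logging.getLogger("loki")

__all__ = [
    "MappingMatrix",
    "CellTypeMap",
    "DecomposeConfig",
    "fit_mapping",
    "cluster_aggregate",
    "celltype_probabilities",
    "nms_refine",
    "decompose_slide",
]


@dataclass
class MappingMatrix:
    """Cells (or clusters) x spots probability matrix; rows are distributions."""

    weights: np.ndarray
    cell_ids: np.ndarray
    spot_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.cell_ids), len(self.spot_ids)):
            raise ValueError("weights must be cells x spots")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows must sum to 1")


@dataclass
class CellTypeMap:
    """Spots x cell-types probability map."""

    probabilities: np.ndarray
    spot_ids: np.ndarray
    type_labels: np.ndarray
    refined: bool = False

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.spot_ids), len(self.type_labels)):
            raise ValueError("probabilities must be spots x types")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")


@dataclass
class DecomposeConfig:
    max_iter: int = 1000
    learning_rate: float = 0.1
    density_prior_weight: float = 0.0
    cluster_level: bool = False
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_prior_weight < 0:
            raise ValueError("density_prior_weight must be >= 0")


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grad(M, S, G, prior_weight):
    """Cosine-distance column loss (+ optional density prior) and gradient wrt M."""
    A = M.T @ S  # spots x d projections
    a_norm = np.linalg.norm(A, axis=0)
    g_norm = np.linalg.norm(G, axis=0)
    # zero columns carry no directional signal: skip them entirely
    live = (a_norm > 1e-12) & (g_norm > 1e-12)
    a_safe = np.where(live, a_norm, 1.0)
    g_safe = np.where(live, g_norm, 1.0)
    dots = np.where(live, (A * G).sum(axis=0), 0.0)
    cos = dots / (a_safe * g_safe)
    loss = float(np.sum(live) - cos.sum())
    # d(1 - cos_k)/dA_k = -(G_k/(|A_k||G_k|) - dot_k * A_k / (|A_k|^3 |G_k|))
    dA = -(G / (a_safe * g_safe) - A * (dots / (a_safe**3 * g_safe)))
    dA[:, ~live] = 0.0
    grad = S @ dA.T  # cells x spots

    if prior_weight > 0:
        n_cells, n_spots = M.shape
        density = M.sum(axis=0) / n_cells
        d_safe = np.where(density > 1e-300, density, 1e-300)
        loss += prior_weight * float(np.sum(d_safe * np.log(d_safe * n_spots)))
        grad += prior_weight * (np.log(d_safe * n_spots) + 1.0)[None, :] / n_cells
    return loss, grad


def fit_mapping(
    S: enc.EmbeddingMatrix | np.ndarray,
    G: enc.EmbeddingMatrix | np.ndarray,
    cfg: DecomposeConfig | None = None,
    spot_ids=None,
    cell_ids=None,
) -> MappingMatrix:
    """Optimize the cell -> spot probabilistic mapping against spot embeddings.

    Minimizes sum_k cos-distance((M^T S)_:,k, G_:,k) over the embedding
    columns k, plus density_prior_weight * KL(spot density || uniform), with
    M the row-softmax of a free matrix (Adam, fixed seed). The logged loss
    trajectory is checked to be non-increasing between checkpoints.
    """
    cfg = cfg or DecomposeConfig()
    S_ids = getattr(S, "ids", None)
    G_ids = getattr(G, "ids", None)
    S = np.asarray(getattr(S, "vectors", S), dtype=float)
    G = np.asarray(getattr(G, "vectors", G), dtype=float)
    if S.shape[1] != G.shape[1]:
        raise ValueError("reference and target embedding dimensions differ")
    if len(S) < 1 or len(G) < 1:
        raise ValueError("need at least one cell and one spot")
    n_cells, n_spots = len(S), len(G)
    rng = np.random.default_rng(cfg.seed)
    Z = rng.normal(0.0, 0.01, (n_cells, n_spots))

    opt = enc._Adam([Z.shape], cfg.learning_rate)
    prev_loss = np.inf
    checkpoints = []
    for it in range(cfg.max_iter):
        M = _softmax_rows(Z)
        loss, gM = _loss_and_grad(M, S, G, cfg.density_prior_weight)
        if not np.isfinite(loss):
            raise RuntimeError("decomposition diverged; try a smaller learning_rate")
        # backprop through row-softmax
        gZ = M * (gM - (gM * M).sum(axis=1, keepdims=True))
        opt.step([Z], [gZ])
        if it % 50 == 0:
            checkpoints.append(loss)
        if abs(prev_loss - loss) / max(abs(prev_loss), 1e-300) < cfg.tol:
            break
        prev_loss = loss
    if any(b > a + 1e-9 for a, b in zip(checkpoints, checkpoints[1:])):
        logger.warning("fit_mapping: loss trajectory not non-increasing at checkpoints")
    M = _softmax_rows(Z)
    if cell_ids is None:
        cell_ids = S_ids if S_ids is not None else np.array([f"cell{i}" for i in range(n_cells)], dtype=object)
    if spot_ids is None:
        spot_ids = G_ids if G_ids is not None else np.array([f"spot{i}" for i in range(n_spots)], dtype=object)
    return MappingMatrix(weights=M, cell_ids=np.asarray(cell_ids, dtype=object),
                         spot_ids=np.asarray(spot_ids, dtype=object))


def cluster_aggregate(cell_emb: enc.EmbeddingMatrix, cluster_labels):
    """Average member embeddings per cluster (re-normalized); returns (embeddings, sizes)."""
    labels = np.asarray(cluster_labels)
    if len(labels) != len(cell_emb):
        raise ValueError("one label per cell required")
    uniq = np.unique(labels)
    if len(uniq) == 0:
        raise ValueError("empty cluster label set")
    means = np.stack([cell_emb.vectors[labels == u].mean(axis=0) for u in uniq])
    norms = np.linalg.norm(means, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    sizes = np.array([(labels == u).sum() for u in uniq])
    emb = enc.EmbeddingMatrix(vectors=means / norms, ids=uniq.astype(object), modality=cell_emb.modality)
    return emb, sizes


def celltype_probabilities(
    M: MappingMatrix, type_labels, sizes=None
) -> CellTypeMap:
    """Per-spot cell-type probabilities from the mapping.

    P[spot, type] = sum over rows of that type of size * M, normalized per
    spot. A spot receiving zero total mass gets a uniform row with a warning.
    """
    labels = np.asarray(type_labels)
    if len(labels) != M.weights.shape[0]:
        raise ValueError("one type label per mapping row required")
    sizes = np.ones(len(labels)) if sizes is None else np.asarray(sizes, dtype=float)
    uniq = np.unique(labels)
    weighted = sizes[:, None] * M.weights
    P = np.stack([weighted[labels == u].sum(axis=0) for u in uniq], axis=1)
    totals = P.sum(axis=1, keepdims=True)
    zero = (totals == 0).ravel()
    if zero.any():
        logger.warning("celltype_probabilities: %d spot(s) with zero mass set uniform", int(zero.sum()))
        P[zero] = 1.0 / len(uniq)
        totals = P.sum(axis=1, keepdims=True)
    return CellTypeMap(probabilities=P / totals, spot_ids=M.spot_ids,
                       type_labels=uniq.astype(object))


def nms_refine(P: CellTypeMap) -> CellTypeMap:
    """Keep only each spot's most probable type at its original probability.

    All other entries are zeroed; the retained value is not renormalized.
    Argmax ties go to the first type in label order and are logged.
    """
    probs = P.probabilities
    best = probs.argmax(axis=1)
    ties = int(sum((row == row.max()).sum() > 1 for row in probs))
    if ties:
        logger.info("nms_refine: %d spot(s) had tied top probabilities", ties)
    refined = np.zeros_like(probs)
    rows = np.arange(probs.shape[0])
    refined[rows, best] = probs[rows, best]
    return CellTypeMap(probabilities=refined, spot_ids=P.spot_ids,
                       type_labels=P.type_labels, refined=True)


def decompose_slide(
    cell_emb: enc.EmbeddingMatrix,
    cell_type_labels,
    target: SpotSlide,
    backend,
    mode: str = "st",
    cfg: DecomposeConfig | None = None,
    nms: bool = False,
) -> CellTypeMap:
    """Full decomposition pipeline on a slide.

    ``st`` mode embeds the target's gene sentences with the text encoder;
    ``image`` mode embeds its patches with the image encoder. With
    cfg.cluster_level the reference is first collapsed to per-type cluster
    embeddings (size-weighted downstream). Deterministic at fixed cfg.seed.
    """
    cfg = cfg or DecomposeConfig()
    if mode not in ("st", "image"):
        raise ValueError("mode must be 'st' or 'image'")
    if mode == "st":
        G = enc.encode_text(backend, build_slide_sentences(target))
    else:
        if target.patches is None:
            raise ValueError("image mode requires per-spot patches")
        G = enc.encode_image(backend, target.patches, ids=target.spot_ids)

    labels = np.asarray(cell_type_labels)
    sizes = None
    ref = cell_emb
    if cfg.cluster_level:
        ref, sizes = cluster_aggregate(cell_emb, labels)
        labels = np.asarray(ref.ids)
    M = fit_mapping(ref, G, cfg, spot_ids=target.spot_ids)
    P = celltype_probabilities(M, labels, sizes)
    return nms_refine(P) if nms else P
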