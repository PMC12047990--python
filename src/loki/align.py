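"""Tissue alignment by embedding-augmented non-rigid coherent point drift.

Spots of the source and target slides become points in an augmented space
[x, y, g*pc1, g*pc2], where pc1/pc2 are the leading principal components of
the dual-encoder embeddings, rescaled relative to the normalized
coordinates. CPD treats the source set as a Gaussian-mixture model fitted to
the target by EM; the adaptation here computes correspondences (E-step) in
the full augmented space while the M-step displacement is applied to the
coordinate columns only, so embedding similarity identifies matching tissue
but geometry alone moves. The coupling weights W are clipped to [0, 1]
after each solve (meaningful because points are pre-normalized), and a rigid
(rotation + translation) fit between pre- and post-alignment positions
screens the non-rigid result for excessive distortion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import encoder as enc
from .stbank_io import SpotSlide, build_slide_sentences

logger = logging.getLogger("loki")

__all__ = [
    "CPDParams",
    "AlignmentResult",
    "augment_points",
    "cpd_em_step",
    "cpd_align",
    "rigid_regularize",
    "align_slides",
    "evaluate_alignment",
]


@dataclass
class CPDParams:
    """Non-rigid CPD knobs.

    beta: Gaussian kernel width of the coupling matrix G (transformation
    stiffness); lam: regularization weight trading data fidelity for
    smoothness; w: uniform-outlier mixture weight in [0, 1); gamma: scale of
    the embedding-PC columns relative to the normalized coordinates
    (gamma = 0 recovers pure-coordinate CPD).

    clip_W clamps the coupling weights elementwise to [0, 1] after each
    M-step solve. It is off by default: with a nonnegative kernel G the
    clipped displacement field G @ W is elementwise nonnegative, which rules
    out rotations and any displacement with a negative component.
    """

    beta: float = 2.0
    lam: float = 2.0
    w: float = 0.1
    max_iter: int = 100
    tol: float = 1e-5
    clip_W: bool = False
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.w < 1:
            raise ValueError("w must be in [0, 1)")
        if min(self.beta, self.lam, self.tol) <= 0:
            raise ValueError("beta, lam, tol must be positive")


@dataclass
class AlignmentResult:
    """Output of one alignment: displaced coordinates plus the CPD state."""

    aligned_coords: np.ndarray
    W: np.ndarray
    sigma2_final: float
    n_iter: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rigid_coords: np.ndarray | None = None
    displacement_per_spot: np.ndarray | None = None
    distortion_residuals: np.ndarray | None = None
    used_rigid_fallback: bool = False

    @property
    def rotation_deg(self) -> float:
        return math.degrees(math.atan2(self.rotation[1, 0], self.rotation[0, 0]))


def _normalize_coords(coords, center, scale):
    return (np.asarray(coords, dtype=float) - center) / scale


def _pc_columns(embeddings: np.ndarray, n: int = 2) -> np.ndarray:
    """First n principal-component scores of the embedding rows (deterministic SVD)."""
    X = embeddings - embeddings.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    # zero-variance directions (within numerical rank) carry no signal
    tol = max(X.shape) * np.finfo(float).eps * max(np.linalg.norm(embeddings), 1.0)
    s = np.where(s > tol, s, 0.0)
    # deterministic sign: largest-magnitude loading of each PC made positive
    pcs = u[:, :n] * s[:n]
    for j in range(pcs.shape[1]):
        col = pcs[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            pcs[:, j] = -col
    return pcs


def _scale_pcs(pcs: np.ndarray, gamma: float, coord_std: float) -> np.ndarray:
    out = np.zeros_like(pcs)
    for j in range(pcs.shape[1]):
        sd = pcs[:, j].std()
        if sd > 0:
            out[:, j] = (pcs[:, j] - pcs[:, j].mean()) / sd * gamma * coord_std
    return out


def augment_points(coords: np.ndarray, embeddings, gamma: float) -> np.ndarray:
    """Augment 2D points with the first two embedding PCs: [x, y, g*pc1, g*pc2].

    Coordinates are normalized (zero mean, unit max-abs); each PC column is
    standardized then rescaled so its standard deviation equals gamma times
    the pooled standard deviation of the normalized coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("PCA augmentation needs at least 3 points")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    vectors = getattr(embeddings, "vectors", embeddings)
    center = coords.mean(axis=0)
    scale = np.abs(coords - center).max()
    scale = scale if scale > 0 else 1.0
    nc = _normalize_coords(coords, center, scale)
    pcs = _scale_pcs(_pc_columns(np.asarray(vectors, dtype=float)), gamma, nc.std())
    return np.column_stack([nc, pcs])


def cpd_em_step(X: np.ndarray, T: np.ndarray, Y: np.ndarray, G: np.ndarray,
                sigma2: float, params: CPDParams):
    """One EM iteration of coordinate-only non-rigid CPD on prepared point sets.

    X: target points (N x D_aug); Y: original source points; T: current
    transformed source (feature columns identical to Y's); G: M x M Gaussian
    coupling of Y. Returns (P, W, T_new, sigma2_new). Posteriors use the full
    augmented dimension; the displacement GW is applied to the first two
    (coordinate) columns only.
    """
    M, D = T.shape
    N = X.shape[0]
    d2 = ((X[None, :, :] - T[:, None, :]) ** 2).sum(axis=2)  # M x N
    num = np.exp(-d2 / (2.0 * sigma2))
    c = (params.w / (1.0 - params.w)) * ((2.0 * math.pi * sigma2) ** (D / 2.0)) * M / N
    P = num / (num.sum(axis=0, keepdims=True) + c)

    p1 = P.sum(axis=1)
    p1_safe = np.where(p1 > 1e-300, p1, 1e-300)
    dP1_inv = 1.0 / p1_safe
    A = G + params.lam * sigma2 * np.diag(dP1_inv)
    rhs = dP1_inv[:, None] * (P @ X[:, :2]) - Y[:, :2]
    try:
        W = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        logger.warning("cpd: singular M-step system; retrying with ridge")
        try:
            W = np.linalg.solve(A + 1e-8 * np.trace(A) / M * np.eye(M), rhs)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("cpd: M-step solve failed to converge") from err
    if params.clip_W:
        W = np.clip(W, 0.0, 1.0)

    T_new = Y.copy()
    T_new[:, :2] = Y[:, :2] + G @ W

    Np = p1.sum()
    pt1 = P.sum(axis=0)
    sigma2_new = (
        float(np.sum(pt1 * (X * X).sum(axis=1)))
        - 2.0 * float(np.sum((P @ X) * T_new))
        + float(np.sum(p1 * (T_new * T_new).sum(axis=1)))
    ) / (Np * D)
    if sigma2_new < 1e-12:
        logger.warning("cpd: sigma^2 underflow; clamped at 1e-12")
        sigma2_new = 1e-12
    return P, W, T_new, sigma2_new


def cpd_align(source: np.ndarray, target: np.ndarray, params: CPDParams | None = None,
              normalize: bool = True) -> AlignmentResult:
    """Non-rigid CPD of a source point set onto a target set.

    Points may be augmented (first two columns are coordinates; any further
    columns are matching features held fixed). When ``normalize`` is set, the
    coordinate columns of each set are centered on their own mean and both
    divided by a shared max-abs scale; aligned coordinates are returned in
    the target frame (de-normalized with the target center).
    """
    params = params or CPDParams()
    Y = np.asarray(source, dtype=float).copy()
    X = np.asarray(target, dtype=float).copy()
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[1] != X.shape[1]:
        raise ValueError("source and target must be 2D arrays of equal width")
    if len(Y) < 3 or len(X) < 3:
        raise ValueError("need at least 3 points per set")

    if normalize:
        y_center = Y[:, :2].mean(axis=0)
        x_center = X[:, :2].mean(axis=0)
        scale = max(np.abs(Y[:, :2] - y_center).max(), np.abs(X[:, :2] - x_center).max())
        scale = scale if scale > 0 else 1.0
        Y[:, :2] = (Y[:, :2] - y_center) / scale
        X[:, :2] = (X[:, :2] - x_center) / scale
    else:
        x_center = np.zeros(2)
        scale = 1.0

    M, D = Y.shape
    N = X.shape[0]
    G = np.exp(-((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2) / (2.0 * params.beta**2))
    sigma2 = float(((X[None, :, :] - Y[:, None, :]) ** 2).sum()) / (D * M * N)
    sigma2 = max(sigma2, 1e-12)
    T = Y.copy()
    W = np.zeros((M, 2))
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        prev = sigma2
        _, W, T, sigma2 = cpd_em_step(X, T, Y, G, sigma2, params)
        if abs(prev - sigma2) / max(prev, 1e-300) < params.tol:
            break

    aligned = T[:, :2] * scale + x_center
    return AlignmentResult(aligned_coords=aligned, W=W, sigma2_final=sigma2, n_iter=n_iter)


def rigid_regularize(original_coords: np.ndarray, cpd_coords: np.ndarray):
    """Least-squares rigid (proper rotation + translation) fit original -> aligned.

    Solved by orthogonal Procrustes with the determinant forced to +1 (no
    scaling, no reflection). Returns (rotation 2x2, translation 2-vector,
    rigidly transformed coordinates). Degenerate (collinear) inputs fall back
    to the identity rotation with a warning.
    """
    A = np.asarray(original_coords, dtype=float)
    B = np.asarray(cpd_coords, dtype=float)
    if A.shape != B.shape or len(A) < 2:
        raise ValueError("point sets must share shape with >= 2 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-12 * max(S[0], 1e-300):
        logger.warning("rigid_regularize: degenerate (collinear) input; identity rotation")
        R = np.eye(2)
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cb - R @ ca
    rigid = A @ R.T + t
    return R, t, rigid


def _slide_embeddings(slide: SpotSlide, backend, mode_text: bool) -> np.ndarray:
    if mode_text:
        return enc.encode_text(backend, build_slide_sentences(slide)).vectors
    if slide.patches is None:
        raise ValueError("image mode requires per-spot patches")
    return enc.encode_image(backend, slide.patches, ids=slide.spot_ids).vectors


def align_slides(
    source: SpotSlide,
    target: SpotSlide,
    backend,
    params: CPDParams | None = None,
    mode: str = "st_to_st",
    distortion_threshold: float | None = None,
) -> AlignmentResult:
    """Align a source slide onto a target slide in embedding-augmented space.

    ``st_to_st`` embeds both slides' gene sentences with the text encoder;
    ``image_to_st`` embeds source patches with the image encoder against the
    target's text embeddings. The PCA augmentation is fit jointly on both
    embedding sets so the PC axes are shared. The non-rigid result is the
    default output; when the 95th-percentile residual between non-rigid and
    rigid-fit coordinates exceeds ``distortion_threshold`` (default 2x the
    target pitch) the rigid projection is returned instead.
    """
    params = params or CPDParams()
    if mode not in ("st_to_st", "image_to_st"):
        raise ValueError("mode must be 'st_to_st' or 'image_to_st'")
    src_emb = _slide_embeddings(source, backend, mode_text=(mode == "st_to_st"))
    tgt_emb = _slide_embeddings(target, backend, mode_text=True)

    # joint normalization: own centers, shared scale
    s_center = source.coords.mean(axis=0)
    t_center = target.coords.mean(axis=0)
    scale = max(
        np.abs(source.coords - s_center).max(), np.abs(target.coords - t_center).max()
    )
    scale = scale if scale > 0 else 1.0
    s_nc = _normalize_coords(source.coords, s_center, scale)
    t_nc = _normalize_coords(target.coords, t_center, scale)

    coord_std = np.vstack([s_nc, t_nc]).std()
    if mode == "st_to_st":
        # same encoder on both slides: fit the PC axes jointly
        pcs = _scale_pcs(_pc_columns(np.vstack([src_emb, tgt_emb])), params.gamma, coord_std)
        s_pcs, t_pcs = pcs[: len(src_emb)], pcs[len(src_emb):]
    else:
        # different modalities need not share axes: fit PCA per set, then
        # rotate the source PC basis onto the target's (orthogonal Procrustes
        # under the rough spatial overlap; a PC basis is only defined up to
        # rotation/sign within its plane)
        s_pcs = _scale_pcs(_pc_columns(src_emb), params.gamma, coord_std)
        t_pcs = _scale_pcs(_pc_columns(tgt_emb), params.gamma, coord_std)
        from scipy.spatial import cKDTree

        _, nn = cKDTree(t_nc).query(s_nc)
        U, _, Vt = np.linalg.svd(s_pcs.T @ t_pcs[nn])
        s_pcs = s_pcs @ (U @ Vt)
        # keep only PC columns that transfer across the modalities: a match
        # feature that disagrees between the sets distorts the registration
        for j in range(s_pcs.shape[1]):
            if s_pcs[:, j].std() == 0 or t_pcs[nn, j].std() == 0 or \
                    np.corrcoef(s_pcs[:, j], t_pcs[nn, j])[0, 1] < 0.5:
                s_pcs[:, j] = 0.0
                t_pcs[:, j] = 0.0
                logger.info("align_slides: dropped cross-modal PC column %d (unreliable)", j)
    Y = np.column_stack([s_nc, s_pcs])
    X = np.column_stack([t_nc, t_pcs])

    res = cpd_align(Y, X, params, normalize=False)
    n_iter = res.n_iter
    aligned_nc = res.aligned_coords
    if params.gamma > 0:
        # coarse-to-fine: the feature-guided stage finds the global pose but
        # any persistent cross-set feature residual floors sigma^2 and with
        # it the attainable precision, and feature mismatch can distort the
        # field non-rigidly. Distill the coarse stage to its rigid pose,
        # then refine with pure-coordinate CPD.
        _, _, posed = rigid_regularize(s_nc, aligned_nc)
        refine = cpd_align(posed, t_nc, params, normalize=False)
        aligned_nc = refine.aligned_coords
        n_iter += refine.n_iter
        res = refine
    aligned = aligned_nc * scale + t_center

    R, t, rigid = rigid_regularize(source.coords, aligned)
    residuals = np.linalg.norm(aligned - rigid, axis=1)
    threshold = 2.0 * target.pitch_um if distortion_threshold is None else distortion_threshold
    fallback = bool(np.percentile(residuals, 95) > threshold)
    if fallback:
        logger.warning("align_slides: distortion above threshold; using rigid projection")
    out = rigid if fallback else aligned
    return AlignmentResult(
        aligned_coords=out,
        W=res.W,
        sigma2_final=res.sigma2_final,
        n_iter=n_iter,
        rotation=R,
        translation=t,
        rigid_coords=rigid,
        displacement_per_spot=np.linalg.norm(out - source.coords, axis=1),
        distortion_residuals=residuals,
        used_rigid_fallback=fallback,
    )


def evaluate_alignment(
    aligned_coords: np.ndarray,
    source: SpotSlide,
    target: SpotSlide,
    n_hvg: int = 50,
    match_radius: float | None = None,
):
    """Per-gene PCC and Kendall tau between matched source/target spots.

    Each aligned source spot is matched to its nearest target spot within
    ``match_radius`` (default half the target pitch; unmatched spots are
    dropped); correlations are computed across matched pairs for the
    ``n_hvg`` most variable target genes. Returns a dict with per-gene
    arrays, the matched index pairs, and the median PCC / tau.
    """
    from scipy.spatial import cKDTree

    from .metrics import kendall_tau, pearson

    radius = target.pitch_um / 2.0 if match_radius is None else match_radius
    tree = cKDTree(target.coords)
    dist, idx = tree.query(np.asarray(aligned_coords, dtype=float))
    matched = dist <= radius
    if not matched.any():
        raise ValueError("no aligned spot matches a target spot within the radius")
    src_rows = np.where(matched)[0]
    tgt_rows = idx[matched]

    tgt_expr = target.normalized if target.normalized is not None else target.counts.astype(float)
    src_expr = source.normalized if source.normalized is not None else source.counts.astype(float)
    hvg = np.argsort(tgt_expr.var(axis=0))[::-1][:n_hvg]

    pccs, taus = [], []
    for gidx in hvg:
        x = src_expr[src_rows, gidx]
        y = tgt_expr[tgt_rows, gidx]
        pccs.append(pearson(x, y) if np.std(x) > 0 and np.std(y) > 0 else np.nan)
        taus.append(kendall_tau(x, y) if np.std(x) > 0 and np.std(y) > 0 else np.nan)
    pccs = np.asarray(pccs)
    taus = np.asarray(taus)
    return {
        "genes": target.gene_symbols[hvg],
        "pcc": pccs,
        "tau": taus,
        "median_pcc": float(np.nanmedian(pccs)),
        "median_tau": float(np.nanmedian(taus)),
        "matched_source": src_rows,
        "matched_target": tgt_rows,
    }
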