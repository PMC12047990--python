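"""Synthetic paired spatial-transcriptomics data with known ground truth.

Every downstream tool in the toolkit is exercised on data from this module:
hex-grid slides whose spots carry a planted domain structure, cell-type
composition, Poisson counts, and image patches rendered deterministically
from the same program mixture that generates the expression — so image
features and expression correlate through a shared latent, the property that
dual-encoder alignment, annotation, decomposition, retrieval, and prediction
all rely on.

Perturbation utilities emulate the robustness experiments: coordinate and
expression perturbation for alignment benchmarks, binomial UMI downsampling
to fixed depth tiers, and additive Gaussian image noise.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stbank_io import SpotSlide, hex_grid

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "make_slide",
    "make_paired_embeddings",
    "perturb_alignment",
    "downsample_depth",
    "add_image_noise",
]

# base colors of up to 8 domain programs (distinct hues, 8-bit RGB)
_PALETTE = np.array(
    [
        [200, 60, 60],
        [60, 170, 90],
        [70, 90, 200],
        [210, 190, 60],
        [170, 70, 190],
        [60, 190, 190],
        [230, 140, 50],
        [120, 120, 120],
    ],
    dtype=float,
)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    ``n_spots`` spots on a 100-um-pitch hex grid are partitioned into
    ``n_types`` quadrant-style domains. Each cell type owns a disjoint block
    of program genes expressed at ``program_strength``-fold over a uniform
    background; a spot's expected profile mixes the programs with weight
    ``purity`` on its domain's type. Counts are Poisson at expected library
    size ``depth``. Patches blend the domain base colors by the same mixture
    plus seeded texture of sd ``texture_sd``.
    """

    n_spots: int = 200
    n_genes: int = 200
    n_types: int = 4
    program_strength: float = 50.0
    depth: float = 5000.0
    purity: float = 0.85
    latent_dim: int = 8
    image_noise_sd: float = 0.0
    expr_noise_sd: float = 0.0
    coord_noise_sd: float = 0.0
    rotation_deg: float = 0.0
    patch_size: int = 16
    texture_sd: float = 5.0
    pitch_um: float = 100.0
    n_cells_per_type: int = 50
    cell_depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_spots, self.n_genes, self.n_types, self.patch_size) < 1:
            raise ValueError("counts must be positive")
        if self.n_types > self.n_genes / 10:
            raise ValueError("each type program needs >= 10 genes: reduce n_types or add genes")
        if self.n_types > len(_PALETTE):
            raise ValueError(f"at most {len(_PALETTE)} domain types supported")
        if min(self.image_noise_sd, self.expr_noise_sd, self.coord_noise_sd) < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


@dataclass
class SynthTruth:
    """Ground truth of one synthetic slide."""

    domain_labels: np.ndarray          # per-spot domain/type index
    fractions: np.ndarray              # spots x types, rows sum to 1
    type_names: np.ndarray
    cell_counts: np.ndarray            # reference cells x genes
    cell_labels: np.ndarray            # per-cell type name
    true_coords: np.ndarray            # pre-perturbation spot coordinates
    programs: np.ndarray = field(default=None)  # types x genes expected profiles (sum 1)
    membership: np.ndarray | None = None        # cell -> spot table when applicable


def _type_programs(cfg: SynthConfig) -> np.ndarray:
    """Expected expression profile per type: disjoint program blocks over background 1."""
    programs = np.ones((cfg.n_types, cfg.n_genes))
    block = cfg.n_genes // cfg.n_types
    for t in range(cfg.n_types):
        programs[t, t * block : (t + 1) * block] = cfg.program_strength
    return programs / programs.sum(axis=1, keepdims=True)


def make_slide(cfg: SynthConfig) -> tuple[SpotSlide, SynthTruth]:
    """Generate a paired slide (counts + patches) and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    side = math.ceil(math.sqrt(cfg.n_spots))
    extent = side * cfg.pitch_um
    centers = hex_grid(0.0, extent, 0.0, extent, cfg.pitch_um)
    coords = centers[: cfg.n_spots].copy()
    if len(coords) < cfg.n_spots:
        raise ValueError("hex grid smaller than requested n_spots")

    # quadrant-style domain layout: g x g grid of labeled regions
    g = math.ceil(math.sqrt(cfg.n_types))
    cx = np.clip(((coords[:, 0] / (extent + 1e-9)) * g).astype(int), 0, g - 1)
    cy = np.clip(((coords[:, 1] / (extent + 1e-9)) * g).astype(int), 0, g - 1)
    domains = (cy * g + cx) % cfg.n_types

    fractions = np.full((cfg.n_spots, cfg.n_types), (1.0 - cfg.purity) / max(cfg.n_types - 1, 1))
    if cfg.n_types == 1:
        fractions[:] = 0.0
    fractions[np.arange(cfg.n_spots), domains] = cfg.purity

    programs = _type_programs(cfg)
    expected = fractions @ programs * cfg.depth
    counts = rng.poisson(expected).astype(np.int64)

    # patches: domain-color mixture + seeded texture, shared latent with expression
    base = fractions @ _PALETTE[: cfg.n_types]
    patches = np.empty((cfg.n_spots, cfg.patch_size, cfg.patch_size, 3), dtype=np.uint8)
    for i in range(cfg.n_spots):
        img = base[i][None, None, :] + rng.normal(0.0, cfg.texture_sd, (cfg.patch_size, cfg.patch_size, 3))
        patches[i] = np.clip(img, 0, 255).astype(np.uint8)
    if cfg.image_noise_sd > 0:
        patches = add_image_noise(patches, cfg.image_noise_sd, seed=int(rng.integers(2**31)))

    gene_symbols = np.array([f"GENE{j:04d}" for j in range(cfg.n_genes)], dtype=object)
    spot_ids = np.array([f"spot_{i:04d}" for i in range(cfg.n_spots)], dtype=object)
    slide = SpotSlide(
        spot_ids=spot_ids,
        coords=coords,
        counts=counts,
        gene_symbols=gene_symbols,
        patches=patches,
        pitch_um=cfg.pitch_um,
    )

    # single-cell reference drawn from the same programs (pure-type cells)
    n_cells = cfg.n_cells_per_type * cfg.n_types
    cell_labels = np.repeat([f"type{t}" for t in range(cfg.n_types)], cfg.n_cells_per_type)
    cell_expected = np.repeat(programs, cfg.n_cells_per_type, axis=0) * cfg.cell_depth
    cell_counts = rng.poisson(cell_expected).astype(np.int64)

    truth = SynthTruth(
        domain_labels=domains,
        fractions=fractions,
        type_names=np.array([f"type{t}" for t in range(cfg.n_types)], dtype=object),
        cell_counts=cell_counts,
        cell_labels=np.asarray(cell_labels, dtype=object),
        true_coords=coords.copy(),
        programs=programs,
    )
    assert n_cells == len(cell_labels)
    return slide, truth


def make_paired_embeddings(n: int, d: int = 64, latent_noise_sd: float = 0.0, seed: int = 0):
    """Paired cross-modal embeddings sharing a latent: ideal-encoder stand-in.

    Both matrices are independent unit-normalized perturbations of the same
    latent vectors, emulating a dual encoder whose two branches agree up to
    per-modality noise of sd ``latent_noise_sd``. At zero noise the pair is
    identical. Returns ``(query EmbeddingMatrix, bank EmbeddingMatrix)`` with
    matching ids.
    """
    from .encoder import EmbeddingMatrix

    if latent_noise_sd < 0:
        raise ValueError("latent_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, d))

    def unit(m):
        return m / np.linalg.norm(m, axis=1, keepdims=True)

    ids = np.array([f"pair_{i}" for i in range(n)], dtype=object)
    q = unit(z + rng.normal(0.0, latent_noise_sd, (n, d)))
    b = unit(z + rng.normal(0.0, latent_noise_sd, (n, d)))
    return (
        EmbeddingMatrix(vectors=q, ids=ids, modality="image"),
        EmbeddingMatrix(vectors=b, ids=ids.copy(), modality="text"),
    )


def perturb_alignment(
    slide: SpotSlide,
    expr_noise_sd: float = 0.0,
    coord_noise_sd: float = 0.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
):
    """Simulate a new experiment of the same tissue: noisy counts + moved coordinates.

    Counts get log-normal multiplicative noise (sd ``expr_noise_sd`` on the
    log scale, re-rounded to integers); coordinates are rotated by
    ``rotation_deg`` about the centroid then jittered with Gaussian sd
    ``coord_noise_sd``. Returns the perturbed slide and a ground-truth record
    with the original coordinates and applied displacement field.
    """
    if expr_noise_sd < 0 or coord_noise_sd < 0:
        raise ValueError("noise sds must be >= 0")
    rng = np.random.default_rng(seed)
    counts = slide.counts.astype(float)
    if expr_noise_sd > 0:
        counts = counts * rng.lognormal(0.0, expr_noise_sd, counts.shape)
    counts = np.asarray(np.round(counts), dtype=np.int64)

    if rotation_deg == 0.0:
        coords = slide.coords.copy()
    else:
        theta = math.radians(rotation_deg)
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        centroid = slide.coords.mean(axis=0)
        coords = (slide.coords - centroid) @ rot.T + centroid
    if coord_noise_sd > 0:
        coords = coords + rng.normal(0.0, coord_noise_sd, coords.shape)

    from dataclasses import replace

    perturbed = replace(slide, counts=counts, coords=coords, normalized=None, zero_library=None)
    truth = {
        "true_coords": slide.coords.copy(),
        "rotation_deg": rotation_deg,
        "displacement": coords - slide.coords,
    }
    return perturbed, truth


def downsample_depth(counts: np.ndarray, target_umi: int, seed: int = 0) -> np.ndarray:
    """Binomially thin each spot's counts to an expected total of ``target_umi`` UMIs.

    Per spot, every count is thinned with p = target_umi / spot_total
    (spots already at or below target are left unchanged), matching
    depth-tier downsampling of sequencing experiments.
    """
    if target_umi <= 0:
        raise ValueError("target_umi must be positive")
    counts = np.asarray(counts)
    rng = np.random.default_rng(seed)
    out = counts.copy()
    totals = counts.sum(axis=1)
    for i, tot in enumerate(totals):
        if tot > target_umi:
            out[i] = rng.binomial(counts[i], target_umi / tot)
    return out


def add_image_noise(patches: np.ndarray, sd: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. Gaussian pixel noise (clipped to 8-bit) to simulate low-quality images."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    patches = np.asarray(patches)
    if sd == 0:
        return patches.copy()
    rng = np.random.default_rng(seed)
    noisy = patches.astype(float) + rng.normal(0.0, sd, patches.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8)
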