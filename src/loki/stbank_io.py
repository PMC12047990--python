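"""Spot-level spatial transcriptomics data model and standard-format I/O.

This module owns the universal containers of the toolkit — :class:`SpotSlide`
(spots with coordinates, gene counts and optional image patches) and
:class:`GeneSentence` (the rank-ordered top-expressed-gene text representation
of one expression profile) — together with the plumbing every downstream tool
needs: MatrixMarket/TSV/CSV readers and writers, QC filtering, library-size
normalization, gene-sentence construction, pseudo-spot binning of single-cell
resolution data, and patch extraction from a whole-slide image.

Conventions: coordinates are stored in micrometres, 0-based, with x growing
to the right and y growing down (image pixel convention). Counts are oriented
spots x genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("loki")

__all__ = [
    "SpotSlide",
    "GeneSentence",
    "GeneMaps",
    "FormatError",
    "read_slide",
    "write_slide",
    "qc_filter_spots",
    "build_gene_sentence",
    "build_slide_sentences",
    "normalize_counts",
    "bin_pseudo_spots",
    "extract_patches",
    "read_gene_maps",
    "write_sentences",
    "read_sentences",
]


class FormatError(ValueError):
    """A standard-format file does not satisfy the expected layout."""


@dataclass
class SpotSlide:
    """Spots with coordinates, gene counts and optional per-spot image patches.

    Attributes
    ----------
    spot_ids : array of str, shape (n_spots,)
    coords : float array, shape (n_spots, 2)
        Positions in micrometres (x right, y down).
    counts : int array, shape (n_spots, n_genes)
        Raw nonnegative counts.
    gene_symbols : array of str, shape (n_genes,)
    patches : optional uint8 array, shape (n_spots, H, W, 3)
    normalized : optional float array, shape (n_spots, n_genes)
        log1p library-size-normalized layer (see :func:`normalize_counts`).
    zero_library : optional bool array flagging spots with zero total count.
    """

    spot_ids: np.ndarray
    coords: np.ndarray
    counts: np.ndarray
    gene_symbols: np.ndarray
    patches: np.ndarray | None = None
    spot_diameter_um: float = 55.0
    pitch_um: float = 100.0
    normalized: np.ndarray | None = None
    zero_library: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.counts = np.asarray(self.counts)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        n = len(self.spot_ids)
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 2)")
        if self.counts.shape[0] != n:
            raise ValueError("counts rows must match number of spots")
        if self.counts.shape[1] != len(self.gene_symbols):
            raise ValueError("counts columns must match number of gene symbols")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("gene_symbols must be unique")
        if self.patches is not None:
            self.patches = np.asarray(self.patches)
            if self.patches.shape[0] != n:
                raise ValueError("one patch per spot required")
        if self.spot_diameter_um <= 0 or self.pitch_um <= 0:
            raise ValueError("spot_diameter_um and pitch_um must be positive")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def subset(self, mask: np.ndarray) -> "SpotSlide":
        """Return a new slide restricted to the spots selected by ``mask``."""
        mask = np.asarray(mask)
        return replace(
            self,
            spot_ids=self.spot_ids[mask],
            coords=self.coords[mask],
            counts=self.counts[mask],
            patches=None if self.patches is None else self.patches[mask],
            normalized=None if self.normalized is None else self.normalized[mask],
            zero_library=None if self.zero_library is None else self.zero_library[mask],
        )


@dataclass(frozen=True)
class GeneSentence:
    """Rank-ordered top-expressed gene symbols of one expression profile."""

    tokens: tuple
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("sentence tokens must be unique")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class GeneMaps:
    """Ensembl-to-symbol conversion table plus a housekeeping-gene blocklist."""

    ensembl_to_symbol: dict = field(default_factory=dict)
    housekeeping: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for k, v in self.ensembl_to_symbol.items():
            if not v:
                raise ValueError(f"empty symbol mapped from {k!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_single_column_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).to_numpy(dtype=object)


def read_slide(
    matrix_path,
    features_path,
    barcodes_path,
    positions_path,
    patches_dir=None,
    spot_diameter_um: float = 55.0,
    pitch_um: float = 100.0,
) -> SpotSlide:
    """Read a Visium-style slide: MTX counts + feature/barcode tables + positions CSV.

    The count matrix orientation (spots x genes vs genes x spots) is
    auto-detected from the barcode count and logged. Spots missing from the
    positions table are dropped with a logged count. The positions CSV must
    have columns ``barcode,x_um,y_um``.
    """
    mat = spio.mmread(str(matrix_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    features = pd.read_csv(features_path, sep="\t", header=None)
    symbols = features.iloc[:, min(1, features.shape[1] - 1)].astype(str).to_numpy(dtype=object)
    barcodes = _read_single_column_tsv(barcodes_path)

    n_bc, n_ft = len(barcodes), len(symbols)
    if mat.shape == (n_bc, n_ft):
        counts = mat
    elif mat.shape == (n_ft, n_bc):
        counts = mat.T
        logger.info("read_slide: matrix stored genes x spots; transposed to spots x genes")
    else:
        raise FormatError(
            f"matrix {matrix_path} has shape {mat.shape}, which matches neither "
            f"(barcodes={n_bc}, features={n_ft}) orientation"
        )
    if not np.allclose(counts, np.round(counts)):
        raise ValueError(f"matrix {matrix_path} contains non-integer counts")
    counts = np.asarray(np.round(counts), dtype=np.int64)

    pos = pd.read_csv(positions_path)
    required = {"barcode", "x_um", "y_um"}
    if not required.issubset(pos.columns):
        raise FormatError(f"positions file {positions_path} lacks columns {sorted(required - set(pos.columns))}")
    pos = pos.set_index(pos["barcode"].astype(str))
    have = np.array([b in pos.index for b in barcodes])
    n_dropped = int((~have).sum())
    if n_dropped:
        logger.info("read_slide: dropped %d spot(s) lacking positions", n_dropped)
    barcodes = barcodes[have]
    counts = counts[have]
    coords = np.column_stack(
        [pos.loc[barcodes, "x_um"].to_numpy(float), pos.loc[barcodes, "y_um"].to_numpy(float)]
    )

    patches = None
    if patches_dir is not None:
        from PIL import Image

        patches = np.stack(
            [np.asarray(Image.open(Path(patches_dir) / f"{b}.png").convert("RGB")) for b in barcodes]
        )
    return SpotSlide(
        spot_ids=barcodes,
        coords=coords,
        counts=counts,
        gene_symbols=symbols,
        patches=patches,
        spot_diameter_um=spot_diameter_um,
        pitch_um=pitch_um,
    )


def write_slide(slide: SpotSlide, out_dir) -> None:
    """Write a slide in the same layout :func:`read_slide` consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(slide.counts))
    pd.DataFrame({0: slide.gene_symbols, 1: slide.gene_symbols}).to_csv(
        out / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({0: slide.spot_ids}).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        {"barcode": slide.spot_ids, "x_um": slide.coords[:, 0], "y_um": slide.coords[:, 1]}
    ).to_csv(out / "positions.csv", index=False)
    if slide.patches is not None:
        from PIL import Image

        pdir = out / "patches"
        pdir.mkdir(exist_ok=True)
        for b, p in zip(slide.spot_ids, slide.patches):
            Image.fromarray(p).save(pdir / f"{b}.png")


def read_gene_maps(mapping_path=None, housekeeping_path=None) -> GeneMaps:
    """Load an Ensembl->symbol TSV (two columns) and/or a housekeeping list (one symbol per line)."""
    mapping = {}
    if mapping_path is not None:
        df = pd.read_csv(mapping_path, sep="\t", header=None)
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    hk: set = set()
    if housekeeping_path is not None:
        hk = set(_read_single_column_tsv(housekeeping_path))
    return GeneMaps(ensembl_to_symbol=mapping, housekeeping=hk)


def write_sentences(sentences, path) -> None:
    pd.DataFrame(
        {"id": [s.source_id for s in sentences], "sentence": [s.text for s in sentences]}
    ).to_csv(path, sep="\t", index=False)


def read_sentences(path):
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [GeneSentence(tokens=tuple(t.split()), source_id=i) for i, t in zip(df["id"], df["sentence"])]


# ---------------------------------------------------------------------------
# QC, normalization, sentences
# ---------------------------------------------------------------------------


def qc_filter_spots(slide: SpotSlide, min_genes: int = 200) -> SpotSlide:
    """Retain spots expressing strictly more than ``min_genes`` genes.

    The threshold is strict ("over" ``min_genes`` genes with nonzero count);
    spot order is preserved and the operation is idempotent.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    expressed = (slide.counts > 0).sum(axis=1)
    keep = expressed > min_genes
    if not keep.any():
        logger.warning("qc_filter_spots: all %d spots removed", slide.n_spots)
    return slide.subset(keep)


def build_gene_sentence(
    expression: np.ndarray,
    gene_symbols,
    maps: GeneMaps | None = None,
    top_n: int = 50,
    source_id: str = "",
) -> GeneSentence:
    """Build the gene sentence of one profile: top ``top_n`` expressed genes, rank order.

    Ensembl IDs are converted to symbols, housekeeping genes dropped, genes
    with zero expression excluded; remaining genes are ranked by descending
    expression with ties broken by ascending symbol, and the first ``top_n``
    kept. Ranking uses the values as given (raw counts by default) — rank
    order is library-size invariant within a spot.
    """
    maps = maps or GeneMaps()
    expression = np.asarray(expression, dtype=float)
    if expression.shape[0] != len(gene_symbols):
        raise ValueError("expression length must equal gene symbol list length")
    seen: dict = {}
    for sym, val in zip(gene_symbols, expression):
        sym = maps.ensembl_to_symbol.get(sym, sym)
        if sym in maps.housekeeping or val <= 0:
            continue
        # duplicate symbols after ID conversion: keep the larger value
        if sym not in seen or val > seen[sym]:
            seen[sym] = val
    if not seen:
        raise ValueError(f"profile {source_id!r} has no nonzero non-housekeeping gene")
    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))
    return GeneSentence(tokens=tuple(sym for sym, _ in ranked[:top_n]), source_id=source_id)


def build_slide_sentences(slide: SpotSlide, maps: GeneMaps | None = None, top_n: int = 50):
    """Gene sentences of every spot of a slide (raw-count ranking)."""
    return [
        build_gene_sentence(slide.counts[i], slide.gene_symbols, maps, top_n, source_id=str(slide.spot_ids[i]))
        for i in range(slide.n_spots)
    ]


def normalize_counts(slide: SpotSlide, target_sum: float = 1e4) -> SpotSlide:
    """Attach a log1p CP-``target_sum`` layer: log(1 + count/libsize * target_sum).

    Raw counts are retained; spots with zero library size get an all-zero
    normalized row and are flagged in ``zero_library``.
    """
    lib = slide.counts.sum(axis=1).astype(float)
    zero = lib == 0
    safe = np.where(zero, 1.0, lib)
    layer = np.log1p(slide.counts / safe[:, None] * target_sum)
    layer[zero] = 0.0
    if zero.any():
        logger.warning("normalize_counts: %d spot(s) have zero library size", int(zero.sum()))
    return replace(slide, normalized=layer, zero_library=zero)


# ---------------------------------------------------------------------------
# pseudo-spot binning and patch geometry
# ---------------------------------------------------------------------------


def hex_grid(xmin: float, xmax: float, ymin: float, ymax: float, pitch: float) -> np.ndarray:
    """Hexagonal-offset grid centers covering a bounding box (row pitch = pitch*sqrt(3)/2)."""
    row_pitch = pitch * math.sqrt(3.0) / 2.0
    centers = []
    j = 0
    y = ymin
    while y <= ymax + 1e-9:
        x0 = xmin + (pitch / 2.0 if j % 2 else 0.0)
        x = x0
        while x <= xmax + 1e-9:
            centers.append((x, y))
            x += pitch
        y += row_pitch
        j += 1
    return np.asarray(centers, dtype=float)


def bin_pseudo_spots(
    cell_coords: np.ndarray,
    cell_counts: np.ndarray,
    pitch_um: float = 100.0,
    diameter_um: float = 55.0,
    gene_symbols=None,
    aggregate: str = "mean",
):
    """Bin single-cell-resolution data into Visium-geometry pseudo-spots.

    A hexagonal-offset grid of circular pseudo-spots (circle boundary
    inclusive) covers the cell bounding box; each pseudo-spot profile is the
    arithmetic mean (or sum) of the profiles of cells whose centers fall
    inside its circle. Empty pseudo-spots are dropped. Returns
    ``(SpotSlide, membership)`` where membership maps cell index -> spot index
    (-1 for unassigned cells).
    """
    cell_coords = np.asarray(cell_coords, dtype=float)
    cell_counts = np.asarray(cell_counts, dtype=float)
    if len(cell_coords) < 1:
        raise ValueError("at least one cell required")
    if not (pitch_um >= diameter_um > 0):
        raise ValueError("require pitch >= diameter > 0")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    centers = hex_grid(
        cell_coords[:, 0].min(), cell_coords[:, 0].max(),
        cell_coords[:, 1].min(), cell_coords[:, 1].max(), pitch_um,
    )
    r = diameter_um / 2.0
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    dist, idx = tree.query(cell_coords)
    membership = np.where(dist <= r + 1e-9, idx, -1)
    if (membership < 0).all():
        raise ValueError("no cell falls inside any pseudo-spot circle")
    used = np.unique(membership[membership >= 0])
    remap = {old: new for new, old in enumerate(used)}
    profiles = np.zeros((len(used), cell_counts.shape[1]))
    sizes = np.zeros(len(used))
    for ci, m in enumerate(membership):
        if m >= 0:
            profiles[remap[m]] += cell_counts[ci]
            sizes[remap[m]] += 1
    if aggregate == "mean":
        profiles /= sizes[:, None]
    membership = np.array([remap.get(m, -1) if m >= 0 else -1 for m in membership])
    if gene_symbols is None:
        gene_symbols = np.array([f"g{k}" for k in range(cell_counts.shape[1])], dtype=object)
    slide = SpotSlide(
        spot_ids=np.array([f"pseudo_{k}" for k in range(len(used))], dtype=object),
        coords=centers[used],
        counts=np.asarray(np.round(profiles), dtype=np.int64),
        gene_symbols=gene_symbols,
        spot_diameter_um=diameter_um,
        pitch_um=pitch_um,
    )
    return slide, membership


def extract_patches(
    image: np.ndarray,
    coords: np.ndarray,
    microns_per_pixel: float,
    diameter_um: float,
):
    """Crop a square patch centered on each spot from a whole-slide image.

    Side length is ceil(diameter_um / microns_per_pixel) pixels; crops that
    run past the image border are zero-padded and flagged. Returns
    ``(patches, padded_flags)``.
    """
    if microns_per_pixel <= 0 or diameter_um <= 0:
        raise ValueError("microns_per_pixel and diameter_um must be positive")
    image = np.asarray(image)
    side = int(math.ceil(diameter_um / microns_per_pixel))
    half = side // 2
    n = len(coords)
    patches = np.zeros((n, side, side, image.shape[2]), dtype=image.dtype)
    padded = np.zeros(n, dtype=bool)
    H, W = image.shape[:2]
    for i, (x_um, y_um) in enumerate(np.asarray(coords, dtype=float)):
        cx, cy = int(round(x_um / microns_per_pixel)), int(round(y_um / microns_per_pixel))
        x0, y0 = cx - half, cy - half
        x1, y1 = x0 + side, y0 + side
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x1, W), min(y1, H)
        if sx0 != x0 or sy0 != y0 or sx1 != x1 or sy1 != y1:
            padded[i] = True
        if sx1 > sx0 and sy1 > sy0:
            patches[i, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return patches, padded
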