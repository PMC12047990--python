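"""Zero-shot tissue annotation of image patches against transcriptomic references.

A reference is either a bulk expression profile (turned into a gene sentence
by rank) or an ordered marker-gene list (used verbatim as the sentence).
Patches are scored by cosine similarity between their image embeddings and
the reference's text embedding; classification picks the best-scoring
candidate; scores from two models can be fused by per-query min-max
normalization and summation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encoder as enc
from .stbank_io import GeneMaps, GeneSentence, build_gene_sentence

logger = logging.getLogger("loki")

__all__ = [
    "ReferenceProfile",
    "SimilarityMap",
    "ScoreTable",
    "reference_from_bulk",
    "reference_from_markers",
    "load_marker_references",
    "annotate_with_reference",
    "zero_shot_classify",
    "fuse_scores",
    "region_enrichment_test",
]


@dataclass
class ReferenceProfile:
    """One annotation candidate: a named gene sentence with its provenance kind."""

    name: str
    kind: str  # "bulk" or "markers"
    sentence: GeneSentence
    source_expression: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bulk", "markers"):
            raise ValueError("kind must be 'bulk' or 'markers'")
        if len(self.sentence.tokens) == 0:
            raise ValueError(f"reference {self.name!r} has an empty sentence")


@dataclass
class SimilarityMap:
    """Per-spot similarity of patches to one reference."""

    spot_ids: np.ndarray
    scores: np.ndarray
    reference_name: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.spot_ids):
            raise ValueError("one score per spot required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"spot_id": self.spot_ids, "score": self.scores})


@dataclass
class ScoreTable:
    """Queries x candidates score matrix (internal or produced by an external model)."""

    scores: np.ndarray
    query_ids: np.ndarray
    candidate_labels: np.ndarray
    provenance: str = "internal"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.query_ids = np.asarray(self.query_ids, dtype=object)
        self.candidate_labels = np.asarray(self.candidate_labels, dtype=object)
        if self.scores.shape != (len(self.query_ids), len(self.candidate_labels)):
            raise ValueError("scores must be queries x candidates")
        if len(set(self.candidate_labels)) != len(self.candidate_labels):
            raise ValueError("candidate labels must be unique")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(self.candidate_labels))
        df.insert(0, "query_id", self.query_ids)
        return df

    @classmethod
    def from_tsv(cls, path, provenance: str = "external-file") -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            scores=df.iloc[:, 1:].to_numpy(float),
            query_ids=df.iloc[:, 0].astype(str).to_numpy(dtype=object),
            candidate_labels=np.asarray(df.columns[1:], dtype=object),
            provenance=provenance,
        )


def reference_from_bulk(
    expression: np.ndarray,
    gene_symbols,
    name: str,
    maps: GeneMaps | None = None,
    top_n: int = 50,
) -> ReferenceProfile:
    """Bulk reference: multi-sample profiles are averaged, then sentence-built by rank."""
    expression = np.asarray(expression, dtype=float)
    if expression.ndim == 2:  # genes x samples cohort -> mean profile
        expression = expression.mean(axis=1)
    sentence = build_gene_sentence(expression, gene_symbols, maps, top_n, source_id=name)
    return ReferenceProfile(name=name, kind="bulk", sentence=sentence, source_expression=expression)


def reference_from_markers(markers, name: str) -> ReferenceProfile:
    """Marker reference: the user's ordered marker list IS the sentence (no re-ranking)."""
    return ReferenceProfile(
        name=name, kind="markers", sentence=GeneSentence(tokens=tuple(markers), source_id=name)
    )


def load_marker_references(path):
    """Load marker references from JSON {label: [gene, ...]} preserving order."""
    with open(path) as fh:
        spec = json.load(fh)
    return [reference_from_markers(genes, label) for label, genes in spec.items()]


def annotate_with_reference(
    patch_emb: enc.EmbeddingMatrix, ref: ReferenceProfile, backend
) -> SimilarityMap:
    """Score every patch by cosine similarity to the reference's text embedding."""
    text = enc.encode_text(backend, [ref.sentence])
    scores = enc.cosine_similarity(patch_emb, text)[:, 0]
    return SimilarityMap(spot_ids=patch_emb.ids, scores=scores, reference_name=ref.name)


def zero_shot_classify(image_emb: enc.EmbeddingMatrix, candidates, backend):
    """Label each image with the candidate of highest cosine similarity.

    Ties are broken by candidate list order and logged. Returns
    (labels, ScoreTable).
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate references")
    names = [c.name for c in candidates]
    if len(set(names)) != len(names):
        raise ValueError("duplicate candidate names")
    text = enc.encode_text(backend, [c.sentence for c in candidates])
    scores = enc.cosine_similarity(image_emb, text)
    best = scores.argmax(axis=1)  # argmax takes the first max: candidate-order tie-break
    n_ties = int(sum((row == row.max()).sum() > 1 for row in scores))
    if n_ties:
        logger.info("zero_shot_classify: %d query(ies) had tied top scores", n_ties)
    labels = np.asarray([names[j] for j in best], dtype=object)
    table = ScoreTable(
        scores=scores,
        query_ids=image_emb.ids,
        candidate_labels=np.asarray(names, dtype=object),
    )
    return labels, table


def _minmax_rows(scores: np.ndarray) -> np.ndarray:
    lo = scores.min(axis=1, keepdims=True)
    hi = scores.max(axis=1, keepdims=True)
    rng = hi - lo
    const = (rng == 0).ravel()
    if const.any():
        logger.warning("fuse_scores: %d constant score row(s) normalized to zeros", int(const.sum()))
    rng[rng == 0] = 1.0
    out = (scores - lo) / rng
    out[const] = 0.0
    return out


def fuse_scores(a: ScoreTable, b: ScoreTable):
    """Fuse two models' score tables: per-query min-max normalize, sum, argmax.

    Candidate columns are reconciled by label; rows by query order of ``a``.
    Returns (fused labels, fused ScoreTable).
    """
    if set(a.candidate_labels) != set(b.candidate_labels):
        missing = set(a.candidate_labels) ^ set(b.candidate_labels)
        raise ValueError(f"candidate label sets differ: {sorted(map(str, missing))}")
    order = [list(b.candidate_labels).index(lbl) for lbl in a.candidate_labels]
    fused = _minmax_rows(a.scores) + _minmax_rows(b.scores[:, order])
    labels = np.asarray([a.candidate_labels[j] for j in fused.argmax(axis=1)], dtype=object)
    table = ScoreTable(
        scores=fused, query_ids=a.query_ids, candidate_labels=a.candidate_labels,
        provenance="fused",
    )
    return labels, table


def region_enrichment_test(sim_map: SimilarityMap, region_mask):
    """Two-sided Wilcoxon rank-sum of in-region vs out-of-region similarity scores.

    Returns a dict with the statistic, p-value and both medians.
    """
    from scipy import stats

    mask = np.asarray(region_mask, dtype=bool)
    if mask.shape != sim_map.scores.shape:
        raise ValueError("mask must have one entry per spot")
    if mask.all() or not mask.any():
        raise ValueError("both mask classes must be non-empty")
    inside = sim_map.scores[mask]
    outside = sim_map.scores[~mask]
    res = stats.ranksums(inside, outside)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_in": float(np.median(inside)),
        "median_out": float(np.median(outside)),
    }
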