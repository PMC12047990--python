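"""Cross-modal retrieval and similarity-weighted spot-expression prediction.

Retrieval ranks a bank of transcriptomic embeddings by cosine similarity to
each image query and is scored by Recall@K over rank quantiles (ties take
the worst rank, the conservative convention). Expression prediction
reconstructs a query spot's profile as the similarity-weighted average of
reference-spot profiles; the cross-validation protocol fine-tunes the
trainable encoder per fold and evaluates the fold's top expressed genes by
MSE and per-gene Pearson correlation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import encoder as enc
from .stbank_io import SpotSlide, build_slide_sentences, normalize_counts

logger = logging.getLogger("loki")

__all__ = [
    "RetrievalResult",
    "PredExConfig",
    "retrieve",
    "recall_at_k",
    "predict_expression",
    "crossval_predex",
]


@dataclass
class RetrievalResult:
    """Batch retrieval output: per-query ranked candidates and ground-truth ranks."""

    query_ids: np.ndarray
    candidate_ids: np.ndarray       # n_queries x k, descending similarity
    similarities: np.ndarray        # n_queries x k
    n_bank: int
    gt_rank: np.ndarray | None = None       # 1-based worst-tie rank of the true candidate
    gt_quantile: np.ndarray | None = None   # rank / n_bank, in (0, 1]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.similarities, axis=1) > 1e-12):
            raise ValueError("similarities must be non-increasing along each ranking")


@dataclass
class PredExConfig:
    n_folds: int = 10
    top_genes: int = 300
    fine_tune_epochs: int = 10
    weight_floor: str = "clip_zero"  # or "softmax"
    softmax_temperature: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.top_genes < 1:
            raise ValueError("top_genes must be >= 1")
        if self.weight_floor not in ("clip_zero", "softmax"):
            raise ValueError("weight_floor must be 'clip_zero' or 'softmax'")


def retrieve(
    query_emb: enc.EmbeddingMatrix,
    bank_emb: enc.EmbeddingMatrix,
    k: int,
    ground_truth=None,
) -> RetrievalResult:
    """Rank bank candidates by descending cosine similarity to each query.

    Ties are ordered by candidate id (deterministic). When ``ground_truth``
    gives the true bank id per query, each query's rank and rank quantile are
    recorded with ties assigned the worst (largest) rank among
    equal-similarity candidates.
    """
    n_bank = len(bank_emb)
    if k > n_bank:
        raise ValueError(f"k={k} exceeds bank size {n_bank}")
    sims = enc.cosine_similarity(query_emb, bank_emb)
    bank_ids = np.asarray(bank_emb.ids, dtype=object)
    id_order = np.argsort(bank_ids.astype(str), kind="stable")

    ranked_ids = np.empty((len(query_emb), k), dtype=object)
    ranked_sims = np.empty((len(query_emb), k))
    gt_rank = gt_quantile = None
    if ground_truth is not None:
        ground_truth = np.asarray(ground_truth, dtype=object)
        gt_rank = np.empty(len(query_emb), dtype=int)
        gt_quantile = np.empty(len(query_emb))

    for qi in range(len(query_emb)):
        row = sims[qi]
        order = id_order[np.argsort(-row[id_order], kind="stable")]
        ranked_ids[qi] = bank_ids[order][:k]
        ranked_sims[qi] = row[order][:k]
        if ground_truth is not None:
            matches = np.where(bank_ids == ground_truth[qi])[0]
            if len(matches) == 0:
                raise ValueError(f"query {query_emb.ids[qi]!r}: ground truth {ground_truth[qi]!r} not in bank")
            s_gt = row[matches[0]]
            rank = int((row > s_gt).sum() + (row == s_gt).sum())  # worst tie rank
            gt_rank[qi] = rank
            gt_quantile[qi] = rank / n_bank
    return RetrievalResult(
        query_ids=np.asarray(query_emb.ids, dtype=object),
        candidate_ids=ranked_ids,
        similarities=ranked_sims,
        n_bank=n_bank,
        gt_rank=gt_rank,
        gt_quantile=gt_quantile,
    )


def recall_at_k(result: RetrievalResult, K_quantiles=(0.05, 0.10)) -> dict:
    """Fraction of queries whose true candidate falls within each rank quantile K."""
    if result.gt_quantile is None:
        raise ValueError("retrieval result lacks ground-truth ranks")
    return {float(K): float(np.mean(result.gt_quantile <= K)) for K in K_quantiles}


def predict_expression(
    query_emb: enc.EmbeddingMatrix,
    ref_emb: enc.EmbeddingMatrix,
    ref_expr: np.ndarray,
    cfg: PredExConfig | None = None,
) -> np.ndarray:
    """Similarity-weighted average of reference profiles for each query spot.

    Weights are the cosine similarities between query and reference
    embeddings, floored per cfg.weight_floor (clip_zero keeps the prediction
    a convex combination of reference rows); queries whose processed weights
    all vanish fall back to the unweighted reference mean with a flag.
    """
    cfg = cfg or PredExConfig()
    ref_expr = np.asarray(ref_expr, dtype=float)
    if len(ref_emb) == 0 or ref_expr.shape[0] != len(ref_emb):
        raise ValueError("reference embeddings and expression must align and be non-empty")
    w = enc.cosine_similarity(query_emb, ref_emb)
    if cfg.weight_floor == "clip_zero":
        w = np.clip(w, 0.0, None)
    else:
        w = np.exp(w / cfg.softmax_temperature)
    totals = w.sum(axis=1)
    dead = totals <= 1e-12
    if dead.any():
        logger.warning("predict_expression: %d query(ies) fell back to the unweighted mean", int(dead.sum()))
        w[dead] = 1.0
        totals = w.sum(axis=1)
    return (w @ ref_expr) / totals[:, None]


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % n_folds
    rng.shuffle(folds)
    return folds


def crossval_predex(
    slide: SpotSlide,
    backend,
    cfg: PredExConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated expression prediction from histology patches.

    Spots are split into cfg.n_folds (seeded). Per fold, a trainable backend
    is fine-tuned on the training pairs, training sentences are text-encoded,
    validation patches image-encoded, expression predicted by
    :func:`predict_expression`, and the fold's top expressed genes (by summed
    raw validation counts) scored with MSE and per-gene PCC on the log-
    normalized layer. Returns a tidy report (fold, gene, mse, pcc).
    """
    from .metrics import mse_per_gene, pearson

    cfg = cfg or PredExConfig()
    if slide.patches is None:
        raise ValueError("crossval_predex requires per-spot patches")
    slide = normalize_counts(slide) if slide.normalized is None else slide
    folds = _fold_assignment(slide.n_spots, cfg.n_folds, cfg.seed)
    sentences = build_slide_sentences(slide)
    rows = []
    for fold in range(cfg.n_folds):
        val = folds == fold
        train = ~val
        if val.sum() < 2 or train.sum() < 2:
            raise ValueError(f"fold {fold} smaller than 2 spots")
        fold_backend = backend
        if getattr(backend, "trainable", False):
            fold_backend = copy.deepcopy(backend)
            enc.fine_tune(
                fold_backend,
                (slide.patches[train], [s for s, t in zip(sentences, train) if t]),
                enc.TrainConfig(epochs=cfg.fine_tune_epochs, seed=cfg.seed + fold),
            )
        ref = enc.encode_text(fold_backend, [s for s, t in zip(sentences, train) if t])
        qry = enc.encode_image(fold_backend, slide.patches[val], ids=slide.spot_ids[val])
        pred = predict_expression(qry, ref, slide.normalized[train], cfg)
        truth = slide.normalized[val]

        top = np.argsort(slide.counts[val].sum(axis=0))[::-1][: cfg.top_genes]
        mse = mse_per_gene(pred[:, top], truth[:, top])
        for j, g in enumerate(top):
            x, y = pred[:, g], truth[:, g]
            pcc = pearson(x, y) if np.std(x) > 0 and np.std(y) > 0 else np.nan
            rows.append({"fold": fold, "gene": slide.gene_symbols[g], "mse": float(mse[j]), "pcc": pcc})
    return pd.DataFrame(rows)
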