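"""Dual-encoder contract: unit-norm embeddings for gene sentences and image patches.

Two backends ship with the toolkit. :class:`HashEncoder` is a deterministic
stand-in for a pretrained visual-omics foundation model: every gene symbol is
hashed (seeded) to a pseudo-random direction and a sentence embeds as the
rank-weighted sum of its gene directions, so the embedding is sensitive to
the rank order that defines a gene sentence; patches embed through a fixed
random projection of simple color statistics. :class:`ToyDualEncoder` is a
small trainable pair of linear maps optimized with the symmetric InfoNCE
contrastive objective (:func:`contrastive_loss`), standing in for
fine-tuning at desk scale.

All embeddings are L2-normalized rows, default dimension 768, and
byte-reproducible at a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .stbank_io import GeneSentence

logger = logging.getLogger("loki")

MAX_TEXT_TOKENS = 76  # token budget of the text encoder contract

__all__ = [
    "EmbeddingMatrix",
    "EncoderBackend",
    "HashEncoder",
    "ToyDualEncoder",
    "TrainConfig",
    "encode_text",
    "encode_image",
    "cosine_similarity",
    "contrastive_loss",
    "fine_tune",
    "image_feature_vector",
    "save_embeddings",
    "load_embeddings",
]


@dataclass
class EmbeddingMatrix:
    """n x d matrix of unit-norm embedding rows with ids and a modality tag."""

    vectors: np.ndarray
    ids: np.ndarray
    modality: str  # "image" or "text"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be n x d with one id per row")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("embedding rows must be unit-norm")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def _stable_rng(*parts) -> np.random.Generator:
    """Generator seeded from a platform-independent hash of the parts."""
    h = hashlib.blake2b("\x1f".join(str(p) for p in parts).encode(), digest_size=8)
    return np.random.default_rng(int.from_bytes(h.digest(), "little"))


def image_feature_vector(patch: np.ndarray) -> np.ndarray:
    """Fixed 30-dim color-statistics features: per-channel mean/std + 8-bin histograms."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("patch must be H x W x 3")
    feats = []
    for c in range(3):
        ch = patch[:, :, c].ravel()
        feats.extend([ch.mean() / 255.0, ch.std() / 255.0])
        hist, _ = np.histogram(ch, bins=8, range=(0, 255.0001))
        feats.extend(hist / ch.size)
    return np.asarray(feats)


IMAGE_FEATURE_DIM = 30


class EncoderBackend:
    """Contract: deterministic unit-norm text and image encoders of shared dimension d."""

    d: int = 768
    trainable: bool = False
    seed: int = 0

    def encode_text_raw(self, sentences) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def encode_image_raw(self, patches) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class HashEncoder(EncoderBackend):
    """Deterministic stand-in dual encoder.

    Text: gene symbol -> seeded pseudo-random d-vector; sentence embedding is
    the sum over tokens of rank-weight(r) = 1/log2(r+2) times the token
    vector, L2-normalized. Image: 30-dim color statistics projected through a
    fixed seeded Gaussian matrix to d, L2-normalized.
    """

    def __init__(self, d: int = 768, seed: int = 0):
        if d < 1:
            raise ValueError("d must be positive")
        self.d = d
        self.seed = seed
        self.trainable = False
        self._gene_cache: dict = {}
        self._proj = _stable_rng("image-proj", seed, d).standard_normal((IMAGE_FEATURE_DIM, d))

    def _gene_vector(self, symbol: str) -> np.ndarray:
        v = self._gene_cache.get(symbol)
        if v is None:
            v = _stable_rng("gene", self.seed, symbol).standard_normal(self.d)
            self._gene_cache[symbol] = v
        return v

    def encode_text_raw(self, sentences) -> np.ndarray:
        out = np.zeros((len(sentences), self.d))
        for i, s in enumerate(sentences):
            tokens = s.tokens[:MAX_TEXT_TOKENS]
            for r, tok in enumerate(tokens):
                out[i] += self._gene_vector(tok) / np.log2(r + 2)
        return out

    def encode_image_raw(self, patches) -> np.ndarray:
        feats = np.stack([image_feature_vector(p) for p in patches])
        return feats @ self._proj


@dataclass
class TrainConfig:
    """Hyperparameters for contrastive fine-tuning of a trainable backend."""

    temperature: float = 0.07
    batch_size: int = 64
    epochs: int = 10
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class ToyDualEncoder(EncoderBackend):
    """Trainable linear dual encoder over a fixed gene vocabulary.

    Text branch: rank-weighted bag-of-genes -> linear map to d. Image branch:
    the 30-dim color-statistics features -> linear map to d. Both outputs are
    L2-normalized; trained with the symmetric contrastive loss.
    """

    def __init__(self, vocabulary, d: int = 64, seed: int = 0):
        self.vocab = {g: i for i, g in enumerate(vocabulary)}
        if not self.vocab:
            raise ValueError("vocabulary must be non-empty")
        self.d = d
        self.seed = seed
        self.trainable = True
        rng = _stable_rng("toy-init", seed, d, len(self.vocab))
        self.W_text = rng.standard_normal((len(self.vocab), d)) / np.sqrt(len(self.vocab))
        self.W_image = rng.standard_normal((IMAGE_FEATURE_DIM, d)) / np.sqrt(IMAGE_FEATURE_DIM)

    def text_features(self, sentences) -> np.ndarray:
        feats = np.zeros((len(sentences), len(self.vocab)))
        for i, s in enumerate(sentences):
            for r, tok in enumerate(s.tokens[:MAX_TEXT_TOKENS]):
                j = self.vocab.get(tok)
                if j is not None:
                    feats[i, j] = 1.0 / np.log2(r + 2)
        return feats

    def encode_text_raw(self, sentences) -> np.ndarray:
        return self.text_features(sentences) @ self.W_text

    def encode_image_raw(self, patches) -> np.ndarray:
        return np.stack([image_feature_vector(p) for p in patches]) @ self.W_image

    def save(self, path) -> None:
        vocab = sorted(self.vocab, key=self.vocab.get)
        np.savez_compressed(path, W_text=self.W_text, W_image=self.W_image,
                            vocab=np.asarray(vocab, dtype=str), seed=self.seed)

    @classmethod
    def load(cls, path) -> "ToyDualEncoder":
        with np.load(path, allow_pickle=False) as z:
            backend = cls(list(z["vocab"]), d=z["W_text"].shape[1], seed=int(z["seed"]))
            backend.W_text = z["W_text"]
            backend.W_image = z["W_image"]
        return backend


# ---------------------------------------------------------------------------
# encoding entry points
# ---------------------------------------------------------------------------


def encode_text(backend: EncoderBackend, sentences) -> EmbeddingMatrix:
    """Encode gene sentences into unit-norm embeddings (truncated to 76 tokens)."""
    if len(sentences) == 0:
        raise ValueError("no sentences to encode")
    for s in sentences:
        if len(s.tokens) == 0:
            raise ValueError(f"empty sentence for id {s.source_id!r}")
    raw = backend.encode_text_raw(sentences)
    return EmbeddingMatrix(
        vectors=_normalize_rows(raw),
        ids=np.array([s.source_id for s in sentences], dtype=object),
        modality="text",
    )


def encode_image(backend: EncoderBackend, patches, ids=None) -> EmbeddingMatrix:
    """Encode H x W x 3 image patches into unit-norm embeddings."""
    patches = np.asarray(patches)
    if patches.ndim != 4 or patches.shape[3] != 3:
        raise ValueError("patches must be n x H x W x 3")
    raw = backend.encode_image_raw(patches)
    # an all-zero raw embedding (e.g. blank patch under a rank-deficient map)
    # normalizes to a deterministic unit basis vector rather than NaN
    zero = np.linalg.norm(raw, axis=1) == 0
    raw[zero, 0] = 1.0
    if ids is None:
        ids = np.array([str(i) for i in range(len(patches))], dtype=object)
    return EmbeddingMatrix(vectors=_normalize_rows(raw), ids=np.asarray(ids, dtype=object), modality="image")


def cosine_similarity(a: EmbeddingMatrix, b: EmbeddingMatrix) -> np.ndarray:
    """Pairwise cosine similarity; for unit-norm rows this is the dot product."""
    if a.d != b.d:
        raise ValueError(f"embedding dimensions differ: {a.d} vs {b.d}")
    return np.clip(a.vectors @ b.vectors.T, -1.0, 1.0)


# ---------------------------------------------------------------------------
# contrastive loss and fine-tuning
# ---------------------------------------------------------------------------


def _logsumexp_rows(s: np.ndarray) -> np.ndarray:
    m = s.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(s - m).sum(axis=1, keepdims=True))).ravel()


def contrastive_loss(X: np.ndarray, Y: np.ndarray, temperature: float = 0.07) -> float:
    """Symmetric InfoNCE loss over a batch of paired unit-norm embeddings.

    L = -(1/N) [ sum_i log softmax_j(x_i.y_j / sigma)_i
               + sum_i log softmax_j(y_i.x_j / sigma)_i ],
    with the diagonal pairs as positives. Zero for N = 1.
    """
    X = getattr(X, "vectors", X)
    Y = getattr(Y, "vectors", Y)
    if X.shape != Y.shape:
        raise ValueError("paired embedding matrices must share shape")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = (X @ Y.T) / temperature
    diag = np.diag(s)
    n = s.shape[0]
    li = diag - _logsumexp_rows(s)       # image -> text direction
    lt = diag - _logsumexp_rows(s.T)     # text -> image direction
    return float(-(li.sum() + lt.sum()) / n)


def _contrastive_grad(X, Y, temperature):
    """Loss and gradients w.r.t. the (unit-norm) embeddings X, Y."""
    n = X.shape[0]
    s = (X @ Y.T) / temperature
    pr = np.exp(s - _logsumexp_rows(s)[:, None])          # row softmax
    pc = np.exp(s - _logsumexp_rows(s.T)[None, :])        # column softmax
    eye = np.eye(n)
    ds = (pr + pc - 2 * eye) / n
    loss = float(-(np.diag(s).sum() * 2 - _logsumexp_rows(s).sum() - _logsumexp_rows(s.T).sum()) / n)
    return loss, (ds @ Y) / temperature, (ds.T @ X) / temperature


def _norm_backprop(raw: np.ndarray, unit: np.ndarray, grad_unit: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (grad_unit - (grad_unit * unit).sum(axis=1, keepdims=True) * unit) / norms


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def fine_tune(backend: ToyDualEncoder, pairs, cfg: TrainConfig) -> ToyDualEncoder:
    """Fine-tune a trainable dual encoder on paired (patches, sentences) batches.

    Minimizes the symmetric contrastive loss with Adam; logs the per-epoch
    mean batch loss and warns if the final epoch's mean loss exceeds the
    first's. Deterministic at fixed cfg.seed.
    """
    if not getattr(backend, "trainable", False):
        raise TypeError("backend is not trainable")
    patches, sentences = pairs
    n = len(sentences)
    if n < 2 or len(patches) != n:
        raise ValueError("need >= 2 paired (patch, sentence) examples")
    tfeat = backend.text_features(sentences)
    ifeat = np.stack([image_feature_vector(p) for p in patches])
    opt = _Adam([backend.W_text.shape, backend.W_image.shape], cfg.learning_rate)
    rng = _stable_rng("finetune", cfg.seed)
    epoch_losses = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue
            t_raw = tfeat[idx] @ backend.W_text
            i_raw = ifeat[idx] @ backend.W_image
            x = _normalize_rows(i_raw)
            y = _normalize_rows(t_raw)
            loss, gx, gy = _contrastive_grad(x, y, cfg.temperature)
            g_iraw = _norm_backprop(i_raw, x, gx)
            g_traw = _norm_backprop(t_raw, y, gy)
            opt.step(
                [backend.W_text, backend.W_image],
                [tfeat[idx].T @ g_traw, ifeat[idx].T @ g_iraw],
            )
            losses.append(loss)
        mean_loss = float(np.mean(losses)) if losses else float("nan")
        epoch_losses.append(mean_loss)
        logger.info("fine_tune epoch %d/%d: mean batch loss %.6f", epoch + 1, cfg.epochs, mean_loss)
    if epoch_losses and epoch_losses[-1] > epoch_losses[0]:
        logger.warning("fine_tune: final-epoch loss %.6f exceeds first-epoch loss %.6f",
                       epoch_losses[-1], epoch_losses[0])
    backend.epoch_losses_ = epoch_losses
    return backend


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_embeddings(emb: EmbeddingMatrix, path) -> None:
    np.savez_compressed(path, vectors=emb.vectors,
                        ids=np.asarray(emb.ids, dtype=str), modality=emb.modality)


def load_embeddings(path) -> EmbeddingMatrix:
    with np.load(path, allow_pickle=False) as z:
        return EmbeddingMatrix(vectors=z["vectors"], ids=z["ids"].astype(object),
                               modality=str(z["modality"]))
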