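# loki-st

A toolkit for joint analysis of spatial transcriptomics (ST) and histology
images through a shared embedding space. Expression profiles are turned into
**gene sentences** — the spot's top-expressed gene symbols, rank-ordered and
space-joined — so that a dual encoder (one text branch for sentences, one
image branch for H&E patches) can place both modalities in a common unit-norm
vector space. Five downstream tools operate on that space:

- **Align** — non-rigid coherent point drift (CPD) registration of two
  slides, with spot points augmented by the leading principal components of
  their embeddings and a rigid (rotation + translation) screen against
  excessive distortion.
- **Annotate** — zero-shot labeling of image patches by cosine similarity to
  text references built from bulk RNA-seq profiles or ordered marker-gene
  lists, with min-max score fusion across models.
- **Decompose** — probabilistic mapping `M` (cells × spots, row-stochastic)
  of a single-cell reference onto spots by minimizing
  `L(S, M) = Σ_k cos-distance((MᵀS)·k, G·k)` over embedding dimensions `k`,
  yielding per-spot cell-type probabilities, optionally sharpened by
  non-maximum suppression.
- **Retrieve** — image → transcriptomics retrieval ranked by cosine
  similarity, scored by Recall@K over rank quantiles.
- **PredEx** — spot expression prediction as the similarity-weighted average
  `X̂_i = Σ_j w_ij X_j / Σ_j w_ij` of reference profiles, with a 10-fold
  cross-validation protocol.

The package ships two encoder backends: a deterministic hash encoder (a
cheap, reproducible stand-in for a pretrained visual-omics foundation model)
and a toy trainable dual encoder fit with the symmetric InfoNCE contrastive
loss

```
L = -(1/N) [ Σ_i log softmax_j(x_iᵀy_j/σ)_i + Σ_i log softmax_j(y_iᵀx_j/σ)_i ].
```

A synthetic-data module generates paired slides with planted domain
structure, cell-type fractions, and image patches driven by the same latent
as the expression, plus alignment perturbations, UMI downsampling and image
noise — so every tool is testable end-to-end with known ground truth. An
evaluation suite implements the exact metric definitions used throughout:
Calinski–Harabasz, Pearson/Kendall τ-b, base-2 Jensen–Shannon divergence,
global (windowless) SSIM, weighted F1, per-gene MSE, and the cross-method
impact score.

## Worked example

```python
import numpy as np
import loki

# a 200-spot synthetic slide with 4 domains, plus a perturbed copy
slide, truth = loki.make_slide(loki.SynthConfig(n_spots=200, n_genes=200, n_types=4, seed=2))
moved, info = loki.perturb_alignment(slide, expr_noise_sd=0.05,
                                     coord_noise_sd=5.0, rotation_deg=10, seed=3)

backend = loki.HashEncoder(d=128, seed=0)
res = loki.align_slides(moved, slide, backend, loki.CPDParams(), mode="st_to_st")

pre = np.linalg.norm(moved.coords - info["true_coords"], axis=1).mean()
post = np.linalg.norm(res.aligned_coords - info["true_coords"], axis=1).mean()
print(f"mean distance to truth: {pre:.1f} um before, {post:.1f} um after")
print(f"recovered rotation: {res.rotation_deg:.2f} deg")
```

prints

```
mean distance to truth: 89.6 um before, 6.1 um after
recovered rotation: -10.00 deg
```

i.e. alignment reduces the error to ~7% of the perturbation (the applied
rotation was +10°, so the recovered inverse is ≈ −10°). The same pipeline is
available from the shell:

```bash
loki simulate slide --seed 3 --out slide/
loki sentences --matrix slide/matrix.mtx --features slide/features.tsv \
     --barcodes slide/barcodes.tsv --positions slide/positions.csv --out sentences.tsv
loki embed --backend hash --modality text --in sentences.tsv --out emb.npz
loki align --mode st_to_st --source perturbed/ --target slide/ --out aligned.csv
```

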