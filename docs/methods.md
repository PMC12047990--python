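# Methods

This note documents the models and procedures implemented in `loki-st`, the
defaults chosen where the design was open, and what the synthetic benchmarks
do and do not demonstrate.

## Gene sentences

A spot's expression profile is represented as text: gene symbols ranked by
descending expression, ties broken by ascending symbol, housekeeping genes
removed, zero-expression genes excluded, truncated to the top 50 (text
encoders additionally truncate input to 76 tokens). Ranking uses **raw
counts**: within a spot, rank order is invariant to library size, so the
sentence is identical whether or not the slide has been normalized. The
alphabetical tie rule makes sentences deterministic across platforms. QC
retains spots expressing strictly more than 200 genes (`count > 0` per gene);
the strict inequality is deliberate and `qc_filter_spots` is idempotent.
Library-size normalization (`normalize_counts`) attaches a
`log(1 + count/libsize · 10⁴)` layer and never overwrites raw counts.

Pseudo-spots: single-cell-resolution data is binned onto a hexagonal-offset
grid of circles (defaults pitch 100 µm, diameter 55 µm, the Visium
geometry), boundary-inclusive, profile = arithmetic mean of member cells
(sum available). Cells outside every circle are unassigned; the membership
table is returned for ground-truth bookkeeping.

## Encoders

`HashEncoder` is the deterministic stand-in for a pretrained dual encoder.
Text: each gene symbol is hashed (BLAKE2, seeded) to a pseudo-random
direction in `R^d`; a sentence embeds as `Σ_r v_gene(r) / log2(r+2)`,
L2-normalized — rank-sensitive but training-free. Image: 30 color statistics
(per-channel mean/std + 8-bin histograms) through a fixed seeded Gaussian
projection. Both branches are byte-reproducible across runs and platforms.
**Limitation:** the two branches share no latent space, so raw hash
embeddings carry no *cross-modal* signal; they are suitable for
within-modality similarity (ST-to-ST alignment, text annotation) and as a
featurizer.

`ToyDualEncoder` provides the shared space at desk scale: linear maps from a
rank-weighted bag-of-genes and from the 30 color features into `R^d`,
L2-normalized, trained with the symmetric InfoNCE loss (temperature default
0.07, batch 64, Adam in numpy with manual backprop through the
normalization). Following the platform's protocol, cross-modal tasks
(image-to-expression retrieval, image-mode decomposition, expression
prediction from patches) fine-tune this encoder on the target sample's own
(patch, sentence) pairs before encoding — 10 epochs for alignment, 5 for
decomposition by default. On domain-structured data the contrastive loss
plateaus at its theoretical floor (same-domain spots are mutually
confusable), so embeddings resolve tissue domains, not individual spots;
tests are calibrated to that resolution.

Embedding dimension defaults to 768; tests and the acceptance script use
32–128 since the stand-in encoders gain nothing from width.

## Alignment (embedding-augmented CPD)

Spots of the source (Y) and target (X) slides become points
`[x, y, γ·pc1, γ·pc2]`: coordinates are centered per set and scaled by a
shared max-abs factor; the two leading principal components of the
embeddings are standardized and rescaled so each PC column's sd equals γ ×
the pooled sd of the normalized coordinates (γ default 1; γ=0 is pure
geometry). For same-encoder (ST-to-ST) alignment the PCA is fit jointly on
both embedding sets. For cross-modal alignment the PC axes are fit per set —
two different encoders need not share axes — then the source PC basis is
rotated onto the target's by orthogonal Procrustes under a nearest-neighbor
spatial prior, and any PC column whose cross-set correlation stays below 0.5
is dropped: a match feature that disagrees between the sets distorts the
registration more than it guides it.

CPD follows the standard non-rigid Gaussian-mixture EM: coupling
`G_ij = exp(-|y_i−y_j|²/2β²)`, posteriors with a uniform-outlier weight `w`,
M-step solve `(G + λσ² d(P1)^{-1}) W = d(P1)^{-1} P X − Y`, variance update
from the weighted traces, convergence on the relative σ² change. The
adaptation: posteriors are computed in the **full augmented space** while the
displacement `GW` is applied to the **coordinate columns only** — embedding
similarity identifies matching tissue, geometry alone moves. σ² is clamped at
1e-12; a singular M-step system is retried with a small ridge.

Defaults β=2, λ=2, w=0.1, max_iter=100, tol=1e-5 on the normalized scale.

**W-clipping.** An elementwise constraint `0 ≤ W ≤ 1` is available
(`clip_W`), applied after each M-step solve on the normalized scale, but is
**off by default**: since `G ≥ 0`, clipped weights make every displacement
component nonnegative, which provably cannot express a rotation (half the
points of any rotation field move in a negative direction). With clipping on,
rotational recovery fails by construction; the option is retained for
experimentation only.

**Coarse-to-fine.** When γ > 0 the feature-guided pass runs first; its
displacement is distilled to a rigid pose (Procrustes, det +1), and a pure-
coordinate CPD pass refines from that pose. Rationale: any persistent
cross-set feature residual floors σ² at the feature-noise scale and with it
the attainable coordinate precision, and feature mismatch can distort the
field non-rigidly; the rigid distillation keeps the global pose the features
found while discarding their local bias. A final rigid fit between original
and aligned spots provides a distortion report; if the 95th-percentile
residual exceeds 2 × pitch the rigid projection is returned instead of the
non-rigid field.

Alignment quality is evaluated by matching each aligned spot to its nearest
target spot within half a pitch and computing per-gene Pearson and Kendall
τ-b over the most variable target genes (median reported).

## Annotation

References are gene sentences: bulk profiles are averaged across cohort
samples (the aggregation is a package choice; per-sample embedding averaging
would be a reasonable alternative) then sentence-built by rank; marker lists
are used verbatim in the user's order. Scores are cosine similarities
between patch embeddings and the reference's text embedding.
Classification takes the argmax, ties to the first candidate (logged).
Fusion of two score tables min-max normalizes each query's row per table and
sums; constant rows normalize to zeros (not 0.5) so the informative table
drives the fused argmax. Region enrichment uses the two-sided Wilcoxon
rank-sum test.

## Decomposition

The mapping `M` (cells-or-clusters × spots) is the row-softmax of a free
matrix — row-stochasticity holds at every checkpoint by construction — and
is optimized with Adam (lr 0.1, ≤1000 iterations, relative-loss tolerance
1e-6) on `Σ_k cos-distance((MᵀS)·k, G·k)` over embedding columns, plus an
optional `density_prior_weight · KL(column-mass ‖ uniform)` term (default
weight 0). Zero embedding columns are skipped — they carry no direction.
`M` is oriented cells × spots so that `MᵀS` conforms; each row is the cell's
probability distribution over spots. Cluster-level mode collapses the
reference to per-type normalized mean embeddings and weights types by
cluster size downstream. Per-spot type probabilities are the
label-aggregated, size-weighted column masses, renormalized; spots with zero
mass get a uniform row with a warning. NMS refinement keeps only each spot's
argmax type at its original (un-renormalized) probability, ties to the first
label in order.

## Retrieval and expression prediction

Retrieval ranks bank candidates by descending cosine similarity, ties by
candidate id. The ground-truth rank takes the **worst** rank among
equal-similarity candidates (conservative Recall@K); `quantile = rank /
bank size` and `Recall@K` is the fraction of queries with quantile ≤ K
(defaults K = 5%, 10%).

Prediction weights are raw cosines floored by `clip_zero` (default;
negatives → 0, keeping predictions convex combinations of reference rows) or
`softmax` (`exp(w/τ)`, τ = 0.1). Queries whose processed weights all vanish
fall back to the unweighted mean, flagged. Cross-validation: seeded
modulo-n_folds assignment after shuffling; per fold the trainable backend is
fine-tuned on training pairs, training sentences and validation patches
encoded, expression predicted on the log-normalized layer, and the fold's
top genes (by summed raw validation counts; default 300) scored with MSE and
per-gene Pearson correlation.

## Metrics

Implemented exactly as defined: CH = (BCSS/(k−1))/(WCSS/(n−k)) with an
infinity sentinel when WCSS = 0 (keeps batch sweeps alive); Pearson and
Kendall τ-b via scipy (brute-force O(n²) oracles in the tests keep the dual
route); JS divergence with **log base 2**, forced by its [0,1] range, with
0·log0 = 0; SSIM as a single global statistic (no sliding window) with
C1=(0.01L)², C2=(0.03L)², L = the pair's max dynamic range, spot maps
rasterized nearest-spot at pitch resolution; weighted F1 over classes
present in the truth; impact score = mean of across-method z-scores of mean
SSIM and sign-inverted mean JS (population sd; zero variance → zero z,
flagged). Impact scores sum to zero across methods by construction.

## Synthetic data

`make_slide` places spots on a 100-µm-pitch hex grid split into quadrant
domains (default 4). Each type owns a disjoint block of program genes at
`program_strength` (default 50×) over background; a spot's expected profile
mixes programs with weight `purity` (default 0.85) on its domain's type, and
counts are Poisson at expected depth 5000 UMI. Patches blend per-type base
colors by the same mixture plus seeded texture (sd 5), so image features and
expression share the latent fraction vector. The cell reference is
pure-type Poisson draws (50 cells/type at 2000 UMI). Perturbations:
log-normal multiplicative expression noise, centroid rotation plus Gaussian
coordinate jitter (with the exact displacement field returned), binomial
thinning to a target UMI depth, and clipped Gaussian pixel noise. Every
generator is a pure function of (config, seed).

What the fixtures do **not** emulate: real histology texture, segmentation
artifacts, platform-specific count noise (over-dispersion, zero inflation),
batch effects, or partial tissue overlap between slides. Passing tests
demonstrate that the algorithms recover planted structure under their own
model assumptions at domain-level signal; they are not evidence about
performance on real tissue with a pretrained foundation model.

## Problem sizes and tolerances

Tests and the acceptance script use 60–500 spots, 100–200 genes, embedding
dimensions 32–128, 10 seeds for stochastic claims — sizes chosen so the full
suite runs in well under a minute of CPU per module while leaving the
statistical margins wide (e.g. alignment recovery is asserted at <10% of the
pre-alignment error where the measured value is ~7%). Oracle comparisons are
asserted at 1e-10; unit-norm invariants at 1e-6; stochastic claims use
seeded fixtures, never tolerance widening.
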