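# Methods

`epiguide` predicts the on-target activity of single guide RNAs (sgRNAs)
for dCas9-based epigenome-editing systems (CRISPRoff, CRISPRi, CRISPRa)
from the guide's sequence context plus four epigenetic feature groups at
the target site. This note records the model, the data conventions, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Score preprocessing

Growth-based silencing screens report a *phenotype score* per guide, with
more negative values meaning a stronger growth defect (stronger silencing).
Two transformations put all screens on a common activity scale:

1. **Sign flip** for silencing screens (`s -> -s`), so larger always means
   more active. This is a flip of the whole axis, not an absolute value: a
   guide with a strong *opposite-sign* phenotype must rank as inactive, which
   `|s|` would invert.
2. **Per-gene top-k normalization**: activity_i = s_i / |mean(top-k s)| with
   k = 3. Within every gene with at least 3 scored guides, the mean of the
   top-3 activity scores is exactly 1 — a useful invariant the tests assert.
   Genes with fewer than k scored guides are normalized by the mean of all
   available scores (least-surprise fallback); a gene whose top-k mean is
   exactly 0 cannot be normalized, so its guides are flagged undefined,
   excluded from model input, and counted in the preprocessing report.
   Genome-wide single-guide libraries skip gene-level normalization
   (`genewise_normalization=False`).

Binary labels use strict inequalities on the scale each rule names:
phenotype < −0.1 (applied to the *raw* phenotype, before the sign flip) or
activity > 0.75. Missing scores yield missing labels and are excluded from
classification training.

## Epigenetic annotation

Each guide receives seven scalars in four groups:

* **T — TSS distance (4 values)**: signed distances to the primary and
  secondary CAGE-defined TSS, from two anchors: the integer midpoint of the
  23-bp target window and the PAM-side end of the window (`end` for +
  guides, `start` for − guides). Positive = downstream of the TSS in the
  gene's transcriptional orientation. The composition of the four values is
  not uniquely determined by convention; 2 TSSs × 2 anchors is this
  package's choice. Distances are clipped to ±2500 bp before normalization
  because tiling libraries span ±2.5 kb of the TSS and unbounded outliers
  would compress the informative range under min–max scaling.
* **A — accessibility**: maximum ATAC signal over intervals overlapping the
  target window.
* **M — methylation**: coverage-weighted mean over a ±100 bp window. WGBS
  values are per-CpG; the window approximates a local methylation level.
* **R — expression**: unweighted mean of overlapping expression intervals
  (typically one per gene or locus).

All seven slots are min–max normalized to [0,1]. Statistics (median for
imputation, then min/max) are fit **on training data only** and reapplied
verbatim, with clipping, to validation/test/prediction inputs — refitting
on test data would leak. Missing values are imputed with the training
median before scaling; a slot that is constant in training maps to 0.5
everywhere; a slot with no observed training value at all is an error that
tells the user to disable the channel.

## Input encoding

The model input is a channels × positions matrix. The silencing default is
**11 × 40**: four one-hot base rows (fixed order A, C, G, T) over a 40-mer
context — 9 bp upstream, the 20-nt protospacer, the 3-nt NGG PAM, 8 bp
downstream — plus seven rows broadcasting the normalized epigenetic scalars
as constants across positions (the features are locus-level, not
base-resolved). The activation default is a 23-mer context (no flanks),
keeping the epigenetic channels (11 × 23). For other context lengths the
upstream flank is `(L−23)//2 + 1` and the downstream flank takes the rest,
reproducing the canonical 9/8 asymmetry at 40 and degenerating to 0/0 at
23. `N` bases one-hot to all-zero columns and flag the sample. Channel
subsets are first-class to support the ablation experiments (seq-only,
seq + one feature group, full).

## Network

A multi-kernel 1-D convolutional network, implemented directly in numpy
with hand-written backpropagation (forward convolutions are im2col + GEMM;
everything is float64 and deterministic given a seed, which enables the
finite-difference gradient checks and bit-identical checkpoint reloads in
the test suite):

* five parallel convolution branches over positions, kernel widths 1–5
  with 30 filters each (150 filters total), ReLU, no padding;
* **max pooling with non-overlapping windows of width 2** per branch, then
  flatten and concatenate. Global pooling was evaluated and rejected: it
  discards *where* a base occurs, and guide activity is driven by
  position-specific effects (measured on the planted-signal screen, a
  globally pooled network reached held-out AUC 0.69 while the
  position-aware linear oracle reached 0.97; width-2 local pooling closes
  the gap). Branches whose output is shorter than the pool width fall back
  to one window;
* one batch-normalization layer over the concatenated vector, then dropout
  with rate 0.4;
* three fully connected ReLU layers of 80, 60 and 40 units;
* one output unit — linear for regression on activity scores (MSE loss),
  logit/sigmoid for classification (binary cross-entropy with logits).

Training uses Adam (learning rate 1e-3, batch size 256 by default),
shuffled minibatches from a seeded generator, and early stopping on the
validation objective (AUC for classification, Spearman for regression) with
checkpoint restore of the best epoch. The optimizer and loss are standard
choices; both are exposed in `ModelConfig`.

## Splits

All splits are grouped by gene: every sgRNA of a gene lands on the same
side of every train/validation/test boundary. Guides of one gene share the
target and the per-gene normalization denominator, so ungrouped splits leak
label information across the boundary. The default evaluation split is
9:1; a validation slice (10% of the training side, also gene-grouped)
drives early stopping; K-fold cross-validation (10 folds for evaluation, 5
for hyperparameter search) uses gene-grouped folds with seeded shuffling.

## Baselines, oracle and hyperparameter search

Random Forest and Gradient Boosting baselines train on flattened input
matrices with the identical gene-grouped split (reports carry a split hash
so harnesses can assert the comparison is fair). The
**position-weight-matrix oracle** — a logistic (or ridge) model on the
one-hot sequence channels only — is near-Bayes for the synthetic generator,
whose sequence signal is linear in positional base indicators; it
calibrates what AUC is attainable.

Hyperparameter search is Bayesian optimization with a Matern-5/2 Gaussian
process surrogate and expected-improvement acquisition over seeded random
candidate pools, in a unit-cube encoding of the search space (real, integer
and categorical dimensions). Defaults: 30 initial random points, 300
acquisitions. The full trace is returned and is bit-reproducible under a
fixed seed.

## Interpretation

* **Tabular track**: engineered features over the 23-mer (PAM at positions
  21–23) — positional mono- and di-nucleotide indicators (`G_20`, `GG_17`),
  protospacer GC count and GC-dimer count, melting temperatures of the
  whole protospacer and three sub-segments (positions 3–7, 8–15, 16–20;
  nearest-neighbor thermodynamics by default, the Wallace 2+4 rule as a
  closed-form fallback), plus the seven epigenetic slots — fit with
  gradient-boosted trees; per-feature importance is the mean |SHAP| over
  samples, using the exact TreeSHAP implementation built into xgboost.
  Per-sample contributions plus the bias sum to the margin prediction
  (local accuracy) to float32 precision (~1e-5 absolute over ~450
  features).
* **Deep track**: expected gradients — integrated gradients averaged over a
  fixed background sample set — on the network. The network is piecewise
  linear (ReLU, max pooling, affine batch norm at inference), so midpoint
  integration converges as O(1/steps); the completeness axiom (per-sample
  attributions sum to prediction − mean background prediction) holds to
  1e-3 at 4096 steps, while the positional map uses 16 steps × 25–100
  background samples, which is ample for ranking. The reported map is the
  **presence-conditioned** mean: the average signed attribution of a
  (position, base) cell over guides that carry that base there. The
  unconditional mean cancels to ~0 for one-hot inputs (a favorable base
  contributes positively when present and its absence contributes
  negatively), so it carries no signal. Positive map values mean the base
  is favored at that position.

## Synthetic screens

The generator emits a toy genome, gene-grouped guides (random 23-mers
constrained to NGG, both strands, non-overlapping slots with 30 bp clear
flanks), a TSS table (secondary TSS 120 bp downstream of primary), and
per-gene epigenetic covariates written as bedGraph intervals spanning the
gene region — so the annotation stage must *recover* the planted values
rather than receive them. Latent activity is linear-Gaussian:
mean-centered positional base indicators, mean-centered per-gene
covariates, a squared-exponential TSS-proximity term (length scale 1 kb),
and Gaussian noise (sd 0.4 by default). Silencing screens report
phenotype = −activity.

Preset study conditions (fixed once):

* `planted-seq` — 2000 genes × 10 guides (n = 20,000); effects
  (+2.0 G@20, +0.8 A@16, −0.8 C@18, −0.6 T@5, +0.4 G@3), no epigenetic
  effects. Sized so the PWM oracle exceeds AUC 0.9 (measured ≈ 0.97) and
  labels split roughly 40/60.
* `planted-epi` — 100 genes × 12 guides; moderate sequence effects plus
  epigenetic weights (atac 0.6, methylation −0.4, expression 0.5,
  TSS-proximity 0.6) scaled by an effect level, used at levels 0.5/1.5/3.0
  for the ablation-monotonicity experiment.
* `null` — no effects, noise only; `smoke` — 12 genes × 6 guides for
  fast end-to-end runs.

What passing these experiments shows: the pipeline recovers planted
positional and epigenetic signal end-to-end through file round-trips,
annotation, encoding, training and attribution, at effect sizes where a
linear oracle says the signal is recoverable. What it does not show:
performance on real screens — real sgRNA activity has nonlinear sequence
dependence, position-resolved chromatin structure, measurement noise that
is not homoscedastic Gaussian, and covariate correlations the generator
deliberately omits (its epigenetic covariates are independent per gene).

## Problem sizes used by the test suite and acceptance script

Desk-scale choices, recorded here once: the planted-signal study trains at
its full n = 20,000 with max 20 epochs (early stopping typically triggers
near epoch 14); shuffled-label controls run on a 500-gene gene-grouped
subsample with 4 epochs (5 seeds in the tests, 3 in the acceptance script);
the ablation experiment runs 100 genes × 12 guides with 10 epochs (5 seeds
per level in the tests, 3 in the script); deep attribution explains 600
guides against 25 background samples at 16 integration steps.

## Known limitations

* Epigenetic channels are locus-constant; base-resolution methylation or
  accessibility profiles are not represented.
* Public screen corpora (hundreds of thousands of guides) and real
  GEO/ATACdb/FANTOM tracks are out of scope; readers supply their own
  tracks as bedGraph/TSV to run on real data.
* The CNN is CPU-bound numpy; it trains tens of thousands of guides in
  minutes but is not meant for million-guide corpora.
* Tm features use Biopython's nearest-neighbor model with its default
  parameter table; no salt/primer-concentration corrections are applied.
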