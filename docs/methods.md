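# Methods

`degsign` classifies genes as down-regulated (label 0), up-regulated
(label 1) or neutral (label 2) from a two-condition (normal vs tumor)
expression matrix, using a convolutional network trained in two levels
and transferable across datasets of any sample count. This note records
the model, the conventions the package chose where the protocol left them
open, and what the synthetic benchmark does and does not demonstrate.

## Labeling

A gene is *significant* when its Benjamini–Hochberg FDR is below 0.01
(strict inequality). Significant genes are labeled by the sign of their
log2 fold change (tumor over normal) relative to a threshold of 0: below
the threshold is down-regulated, above is up-regulated. Everything not
significant is neutral. A significant gene whose logFC equals the
threshold exactly is kept neutral, because the sign rule is strict; the
event is logged. Genes present in the expression matrix but absent from
the DE table are dropped with a logged count.

The recommended input is an externally computed DE table (e.g. from a
count-model package). For self-contained runs, `compute_de_standin`
provides a documented stand-in: logFC from condition means with a
pseudocount, Welch's unequal-variance t-test on log2(x + pseudocount),
and Benjamini–Hochberg correction across genes. It makes no claim of
equivalence to dispersion-modeling DE methods; on the package's own
negative-binomial simulations it recovers planted directions at well over
95% for |log2FC| = 2 with 20 + 20 samples.

A user-supplied list of disease-linked genes defines the biologically
validated partition Q: a gene is in Q when it is in the list *and*
significant (neutral genes are never bio-validated; list members that are
not significant are logged and excluded). Q splits 80:20 into fine-tune
data F1 and bio-test data T3; the remaining genes P (neutrals plus
unvalidated DEGs) split 80:20 into first-level training data T1 and
held-out data T2. Splits are stratified by label via largest-remainder
allocation, so every class is within one gene of its proportional share,
and are deterministic functions of their seed.

## Feature construction

Each gene's input to the network is its expression vector across the
dataset's samples, transformed as log2(x + 1) and standardized per gene
(zero mean, unit variance within the vector; constant genes map to
zeros). Two layout conventions matter and are deliberate:

* **Sample interleaving.** Samples are ordered by interleaving the two
  conditions by within-condition rank fraction (normal, tumor, normal,
  tumor, … for balanced designs). Samples within a condition are
  exchangeable, so any ordering is legitimate; interleaving makes the
  condition contrast a *local, repeating texture* that looks the same at
  every grid position and — critically — at every sample count. With a
  block layout (all normals, then all tumors) the condition boundary sits
  at a different spatial position for every n, and a model trained on
  60-sample datasets misreads 12-sample ones: on the transfer benchmark,
  block ordering scored 55% accuracy (with ROC-AUC 0.99 — a pure
  calibration shift), interleaving 96%+.

* **Edge padding in the 2D reshape.** The length-n vector is padded to
  the next perfect square m = ceil(sqrt(n))² and filled row-major into a
  √m × √m single-channel image. Padding repeats the last entry rather
  than injecting zeros: standardized features are centered at zero, so
  pad zeros would look like mid-range expression to the convolutions, and
  on small datasets padding can be a quarter of the grid.

## Architecture

Eight 3×3 convolutions (stride 1, padding 1, so the grid size is
preserved) with ReLU, one 2×2 max pool (after the eighth convolution;
skipped for 1×1 grids), an adaptive max pool to 1×1, then five dense
layers with ReLU between them and no activation after the last. The
adaptive pool makes the parameter count independent of n: the dense stack
always sees exactly `conv_channels[-1]` features, which is what allows a
single trained model to score datasets with different sample counts.

Defaults: conv channels (8, 8, 16, 16, 32, 32, 32, 32) and dense widths
(32, 16, 8, 8, head). These were sized so the full five-fold pipeline
trains in a few minutes on one CPU core; both are configurable, and wider
settings gave the same end-to-end quality on the reference benchmark at
proportionally higher cost. The output head has 3 units for first-level
training (softmax probabilities) or 2 units after `swap_head`
(raw scores for the logit-based binary loss). Argmax ties resolve to the
lower class index.

With a three-class head, class probabilities come from a softmax over the
logits; `predict` reports the raw scores as well, and binary ROC uses the
score difference z₁ − z₀ (monotone in the class-1 posterior).

### Numerical choices

* **Engine.** Layers, losses and the Adam update are implemented directly
  in NumPy (float32, channels-last, im2col + GEMM convolutions) with
  hand-derived backward passes, verified against central finite
  differences in float64.
* **Initialization.** He-uniform weights (bound √(6/fan_in)) and zero
  biases. A fan-in-only uniform bound (1/√fan_in) shrinks activation
  variance roughly six-fold per ReLU convolution; through eight layers
  that starves the gradients, and the fixed 50-epoch / lr 1e-4 budget
  cannot move the decision boundary at all.
* **Head replacement.** The swapped-in head starts at zero, not at a
  random draw. After first-level training the backbone emits large,
  confident features; a random head can start deep in sigmoid saturation,
  and 31 epochs at lr 1e-4 were observed to leave it there (training
  accuracy ~0.5 with ROC ~0.99). A zero head starts from unbiased scores
  and is the standard transfer-head choice. Backbone weights carry over
  bit-identically in either direction of the swap.

## Training protocol

First level: 3-class training on T1 with mean cross-entropy, 50 epochs,
batch 256, Adam (lr 1e-4, betas 0.9/0.999, eps 1e-8, no weight decay),
batches reshuffled each epoch, five-fold label-stratified
cross-validation; the best fold is the one with the highest validation
MCC (ties to the lower fold index). Second level: the head is swapped to
2 units and the whole network — no layer freezing — is fine-tuned on F1
with element-mean sigmoid cross-entropy on raw scores against one-hot
targets, 31 epochs, batch 64. Evaluation on T3 is binary.

Transfer: first-level training runs sequentially over each source
dataset's T1 (batch 256), carrying weights forward; the head is swapped
once; fine-tuning runs sequentially over each source's F1 (batch 64);
unseen datasets — consisting entirely of validated up/down genes — are
scored frozen, with the weights hash recorded before and asserted after
testing. Class imbalance is not reweighted (an extension point).

Every entry point is a deterministic function of (data, config, seed):
one master seed drives splits, folds, initialization, batch shuffling and
noise draws through independent derived streams, and repeated runs
reproduce metric files byte-identically.

## Evaluation

Reports carry accuracy, recall and precision as percentages, F-measure,
MCC, and ROC-AUC, with support-weighted averaging across classes.
Support-weighted recall is mathematically identical to accuracy (both
equal the confusion-matrix trace over its total); the implementation
asserts that identity on every report. MCC uses the generalized
multiclass correlation form, which reduces to the familiar binary
formula; multiclass ROC is one-vs-rest, support-weighted; a single-class
truth vector yields NaN ROC with a warning rather than an exception.

Noise robustness corrupts the *test* inputs with zero-mean Gaussian noise
at a percentage of each feature's training-set (T1 ∪ F1) standard
deviation, at levels 1, 10, 50, 100, 500, 1000, 1500 plus the clean
baseline; constant features pass through unchanged. Train-time
augmentation is not applied.

The five classical baselines (decision tree, k-nearest neighbors, random
forest, support-vector classifier, gradient-boosted trees) have no
head-swap analogue, so each is fit once on T1 ∪ F1 restricted to the
evaluation's label space — the up/down genes, the closest fair analogue
of the CNN's two-level scheme, whose final model is a two-class
classifier — and evaluated on the binary T3. Binary scores renormalize
the up/down class probabilities. All baselines use their library default
hyperparameters.

## Synthetic benchmark

The generator plants known directions: per-gene baseline means drawn
log2-uniformly over (3, 9), negative-binomial counts with variance
μ + φμ² (φ = 0.2 by default, the usual RNA-seq dispersion convention),
tumor means shifted by a known ±log2FC for a chosen fraction of genes,
and a random quarter of planted DEGs designated biologically validated —
inside the 4–47% range typical of disease-curated fractions of
significant DEGs. The reference conditions (2000 genes, 20% up, 20% down,
|log2FC| = 2, 20 + 20 samples) make the task strongly separable by
construction.

What passing the benchmark shows: the labeling rules, splits, training
mechanics, head swap, size-invariant transfer, and metric plumbing all
work, and the network can extract a planted mean-shift signal through the
full protocol. What it does not show: performance on real cohorts, where
library-size heterogeneity, batch effects, gene–gene correlation,
ambiguous effect sizes near the FDR boundary, and imperfect curation all
exist and are explicitly not simulated.

## Known limitations

* The DE stand-in is a t-test, not a count model; for real data, supply a
  DE table from a dedicated package.
* The quantile filter drops genes whose mean ties the cutoff exactly
  (strict inequality) and refuses to return an empty dataset.
* No GPU path; the NumPy engine targets small, CPU-sized problems.
* Fine-tuning updates the whole backbone; with very small F1 sets this
  can overfit — the protocol's fixed 31 epochs bound the exposure but do
  not eliminate it.
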