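# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic world the tests rely on, and the limits of
what a green test establishes.

## Model and assumptions

`pathfuse` fits a mid-fusion classifier to gene-level tri-omics profiles
(continuous expression, copy-number dosage, binary somatic mutation) for
one binary staging endpoint at a time. The central assumption is that
class-discriminative signal flows through curated gene → pathway →
super-pathway links: every encoder weight not supported by the prior is
held at zero by a binary Hadamard mask applied inside every forward pass.
The masks therefore act as a hard structural prior, not an initialization
trick — perturbing a masked-out weight can never change any output, and
the test suite asserts this exactly.

The prior is compiled from a GMT membership file and a child → parent
relation table forming a DAG (multiple parents allowed; a child
contributes a connection to every parent). Nodes are assigned to levels by
longest path to a root; roots form the top level. Nodes deeper than the
requested level count are dropped with a warning; nodes unreachable from
any gene are pruned (they would be untrainable dead units); leaf nodes
without member genes are flagged as orphans but kept in the hierarchy.
Node and gene ordering is lexicographic throughout, so mask construction
is deterministic. Two depth variants share the same prior: `3F` uses
genes → leaf level → top level with skipped levels collapsed by
reachability (any path ⇒ connected), and `5X` keeps every level; by
construction the boolean composition of the `5X` masks over the levels
`3F` skips reproduces the `3F` connectivity, which is tested on toy
hierarchies. `5X` requires at least three pathway levels — with two it
would coincide with `3F`.

## Fusion stage

The m per-modality pathway embeddings (dimension d = top-level pathway
count) are stacked and passed through single-head scaled dot-product
attention over the *modality* axis (sequence length m): the equation form
puts no axis on the attention, and modality-axis attention is the reading
that yields per-sample cross-omics interaction weights. z is the
concatenation of the m attended embeddings (length m·d); the two-layer
sigmoid gate has hidden width d; W_f maps the gated z back to d; the
residual term is the unweighted mean of the *raw* (pre-attention)
embeddings. The classifier head is a single linear map d → 1 with a
sigmoid cross-entropy loss and a 0.5 decision threshold. Per-sample
modality weights α_m(x) are the column means of the row-stochastic
attention matrix (average attention a modality receives), renormalized to
sum to one.

Two training-time regularizers operate beyond the fixed protocol:

* Standard dropout (rate 0.30) on hidden encoder layers.
* Modality dropout (rate 1/3): each sample independently has whole
  modalities zeroed at the input during training. This realizes the
  design goal of remaining modular when modalities are absent — external
  cohorts frequently supply only a subset of the omics layers — and it
  prevents the network from memorizing training labels through any single
  layer. Without it, a substantial fraction of random initializations on
  the synthetic world latched onto sample-unique mutation fingerprints
  (training accuracy ≈ 1, validation ≈ chance) instead of the planted
  pathway signal.

## Training protocol

Optimization is AdamW (decoupled weight decay 0.01) at initial learning
rate 0.01 with a 5-epoch linear warm-up, reduce-on-plateau scheduling
(factor 0.5, patience 5 epochs of no validation-loss improvement), global
gradient-norm clipping at L2 = 1.0, early stopping after 10 consecutive
non-improving epochs with the best-validation-loss weights restored,
batch size 128, and at most 200 epochs. Warm-up length, maximum epochs,
the weight-decay coefficient, the loss and the threshold are package
choices; the rest of the protocol is fixed a priori and no data-driven
hyperparameter search is performed.

Because the objective is non-convex and the networks are small, each fold
trains a few (default 3) independently initialized networks and keeps the
one with the best validation loss — the same signal early stopping already
consumes, so this adds no leakage channel. Kaiming-normal initialization
is used for all linear layers, with masked positions re-zeroed after
initialization. Per-fold seeds derive deterministically from the master
seed (master + fold index, + 100 per restart), making entire
cross-validation runs bit-reproducible at fixed thread count.

Cross-validation is stratified 5-fold. All fold statistics — per-gene
imputation means and z-scales for continuous modalities (mutation
matrices are imputed but never rescaled) — are fitted on the training
split only and applied to the validation split with the stored
parameters. Optional Borderline-SMOTE (k = 5) oversamples the minority
class inside the training split only, interpolating between borderline
minority points and their minority neighbors, capped at 15% of the
pre-augmentation training-fold size (the cap base is a package choice).

## Interpretation chain

Gene attributions are integrated gradients against a single baseline (the
training-fold feature-mean vector), 64 quadrature steps inside the CV
loop and 256 for the completeness audit. Integrated gradients satisfy the
completeness identity Σφ = logit(x) − logit(baseline) up to quadrature
error; with the network's smooth nonlinearities the residual stays well
below 10⁻³ of the observed logit range, which the acceptance suite
checks. A gradient-based Shapley approximation in the DeepSHAP family
would serve the same role; the quadrature form was chosen because its
completeness is controllable and it needs nothing beyond the package's
own autodiff.

Global gene importance is the mean *absolute* attribution (evidence
strength; the signed mean is available behind a flag). Per-sample pathway
scores stay signed, S_{m,p}(x) = Σ_g A_{g,p} φ_{m,g}(x), with A the
gene → top-pathway reachability of the mask stack; the integrated
importance I_p^int averages the α-weighted modality sum over the dataset.
Per fold, D is the held-out validation split — explanations are computed
where the model is being judged.

Stability is the average pairwise Spearman correlation (average ranks for
ties) of the K fold importance vectors. By default it is computed on the
absolute vectors, matching the ranking convention used everywhere else;
signed noise pathways carry no ranking meaning and at toy scale their
arbitrary signs dominate the correlation. Constant vectors contribute
correlation 0 with a warning.

Structural resolution metrics summarize the normalized attribution mass
p_i over the nodes of each masked layer: N≥τ counts nodes with
p_i ≥ τ = 0.001 and N_eff = exp(−Σ p_i log p_i) (0·log 0 := 0, so N_eff
is scale-invariant and bounded by the layer size). Node importances w_i
are mean |activation × ∂logit/∂activation| per node, aggregated over
samples and modalities.

The label-permutation test permutes the label assignment over the whole
cohort, re-runs the cross-validated fit per replicate, and reports the
mean null accuracy plus the mean (signed) Spearman correlation between
null and reference importance rankings.

## Synthetic world

The generator states one desk-scale world and the tests do not tune it:
400 patients, 500 genes in 20 disjoint leaf pathways of 25 genes, a
two-level hierarchy with fan-in 2 (10 top-level pathways), balanced
classes, one driver pathway whose genes carry effect size 3.0 (in units
of the noise SD 1.0) additively on log-scale expression; mutation odds
are modified multiplicatively (base rate 0.05) and a latent copy-number
dosage is discretized to GISTIC-style calls in {−2..2}. The fan-in of 2
keeps rank-based explanation metrics meaningful: with only five top
nodes, two independent rankings already agree at |ρ| ≈ 0.37 by chance,
which would swamp any rank-disruption readout.

What the generator does *not* emulate: correlation structure between
modalities beyond the shared drivers, gene–gene co-expression, batch
effects, missing values, or label noise. A green planted-recovery test
therefore establishes that the architecture, training harness and
interpretation chain are wired correctly and can recover a known
pathway-structured signal — not that the model attains any particular
performance on real cohorts.

## Numerical choices and degenerate inputs

Float64 throughout. Zero-variance genes get scale 1 with a warning;
all-zero importance vectors and empty baselines are errors; single-class
label vectors guard the F1 zero-division to 0 with a warning; a minority
class smaller than k + 1 skips SMOTE with a warning. Checkpoints embed a
SHA-256 fingerprint of the mask stack and refuse to load against
mismatched masks.

## Known limitations

* Attention axis, gate shapes, the classifier head and the 3F collapse
  rule are under-determined by the model equations; the choices above are
  documented but other readings exist.
* Fold-level explanations use validation splits of a single CV pass;
  stability across *re-randomized* CV partitions is not reported.
* The permutation test at toy scale uses few top-level pathways, so
  individual replicate correlations are coarse (granularity ≈ 0.1).
* No missing-modality *inference* path is provided; modality dropout
  regularizes training but prediction still expects all modalities.
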