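# pathfuse

Pathway-masked multi-omics mid-fusion models for binary tumor staging, with
an attention-integrated gene → pathway → modality interpretation chain.

## The problem

Tumors in the same pathologic stage can behave very differently, and deep
models that integrate multi-omics profiles (expression, copy number,
somatic mutations) often predict well but cannot be audited: a clinician
cannot see *which* genes, pathways and omics layers carry the signal.
`pathfuse` addresses this for binary TNM staging endpoints
(Tis/T1–2 vs T3–4; N0 vs N1–3; M0 vs M1) by constraining each modality's
encoder to a curated pathway hierarchy, fusing the modalities mid-network
with attention, and propagating signed gene attributions up the same
hierarchy the network was built from — so every prediction comes with a
pathway-resolved, fold-stable evidence chain.

It is aimed at computational oncology / systems-biology groups who want an
interpretable staging baseline that runs on a laptop CPU and is fully
testable on synthetic cohorts with planted signal — no data download
required.

## The model

Each modality *m* is encoded by masked linear layers whose connectivity is
fixed by the pathway prior (gene–pathway membership and pathway
parent–child relations):

    h_m^(ℓ+1) = LeakyReLU_α( (W_m^(ℓ) ⊙ M^(ℓ)) h_m^(ℓ) + b_m^(ℓ) ),  α = 0.01

where `M^(ℓ)` is a binary mask re-applied at every forward pass, so
prior-unsupported weights can never carry signal. Two depths share the
same priors: `3F` (genes → leaf pathways → top pathways, intermediate
levels collapsed by reachability) and `5X` (every hierarchy level kept as
its own masked layer, for deeper interpretive resolution).

The per-modality pathway embeddings h_m interact via scaled dot-product
attention over the modality axis, `Attn(Q,K,V) = softmax(QKᵀ/√d) V`; a
two-layer sigmoid gate `g = σ(W₂ GELU(W₁ z + b₁) + b₂)` softly selects the
attended stacked features z, and a residual mean preserves the raw
modality signal:

    h_fuse = W_f (g ⊙ z) + (1/m) Σ_m h_m

A linear head on h_fuse yields the staging logit.

Interpretation: integrated-gradient attributions φ_{m,g}(x) toward the
positive-class logit (single training-mean baseline; completeness
Σφ = logit(x) − logit(baseline) is audited by the tests) are aggregated
through the prior membership A_{g,p} into per-sample pathway scores
S_{m,p}(x) = Σ_g A_{g,p} φ_{m,g}(x), and integrated across modalities with
attention-derived per-sample weights α_m(x), Σ_m α_m(x) = 1:

    I_p^int = (1/|D|) Σ_x Σ_m α_m(x) S_{m,p}(x)

Reported alongside: fold-to-fold explanation stability (average pairwise
Spearman correlation of the fold importance vectors), per-layer structural
resolution metrics (N≥τ, the count of nodes holding ≥ τ = 0.001 of the
normalized attribution mass, and N_eff = exp of its Shannon entropy), and
a label-permutation sanity test.

Training follows a fixed protocol (no hyperparameter search): AdamW at
initial learning rate 0.01, linear warm-up, reduce-on-plateau (factor 0.5,
patience 5), global gradient-norm clipping at 1.0, early stopping after 10
non-improving epochs with best-weights restore, batch size 128, inside a
leakage-safe stratified 5-fold CV (fold-wise scaling/imputation fitted on
training splits only, optional capped Borderline-SMOTE in training folds
only).

## Worked example

```python
from pathfuse import SyntheticSpec, make_toy_hierarchy, simulate_cohort
from pathfuse.model import ModelConfig, StagingFusionModel

spec = SyntheticSpec(seed=1)                  # 400 samples, 500 genes, 20 leaf
hierarchy, _, _ = make_toy_hierarchy(spec)    # pathways, driver in expression
cohort = simulate_cohort(spec, hierarchy)
model = StagingFusionModel.from_cohort(cohort, hierarchy, ModelConfig(seed=1))
results = model.fit(k=5, smote=True, seed=1)
print(results.summary())
```

prints

```
Pathway-masked multi-omics staging model — cross-validated fit
==============================================================
variant: 3F   folds: 5   samples: 400   smote: True
pathway dim: 10   modalities: expression, cnv, snv

accuracy     : 0.960 ± 0.017
weighted F1  : 0.960 ± 0.017
stability    : 0.173 (avg pairwise Spearman over 10 fold pairs)

mean modality weights (attention-derived):
  expression   0.420
  cnv          0.292
  snv          0.288

top pathways by integrated importance:
   1. TP01       3.1116 ± 1.8503
   2. TP04       0.1403 ± 0.1429
   ...
```

Reading: the cross-validated accuracy and weighted F1 (mean ± SD over the
five folds) show the planted signal is recovered; the attention-derived
modality weights identify expression — the modality carrying the planted
driver — as the dominant layer; and `TP01`, the top-level ancestor of the
planted driver pathway `LP01`, ranks first by integrated importance with a
large margin over the noise pathways. `results.export(out_dir)` writes the
gene/pathway importance tables and Sankey-ready flow records;
`results.structural_metrics()` gives N≥τ and N_eff per masked layer.

The same pipeline runs from the shell:

```bash
pathfuse simulate --out-dir data/           # cohort + priors on disk
pathfuse masks build --gmt data/pathways.gmt --relations data/relations.tsv \
    --variant 3F --out masks/
pathfuse train --data-dir data/ --endpoint T --out-dir run/
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it generates the default synthetic cohort, compiles the masks,
runs the cross-validated fusion fit under the fixed protocol, computes the
interpretation chain (driver ranks, structural metrics) and a scaled-down
permutation null, prints the summary, and writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
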