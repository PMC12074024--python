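# Methods

## The model

`moeclock` estimates biological age from a normalized expression vector
x ∈ R^d with a mixture of experts (MoE).  Each expert F_i is a dense
network (hidden widths 640/256/128/64 by default, one output neuron) with
batch normalization, ReLU and dropout on the hidden layers; a gating
network with the same trunk ends in an E-way softmax head producing
per-sample simplex weights p(x).  The prediction is the gated convex
combination

    ŷ(x) = Σ_i p_i(x) · F_i(x),

so it always lies between the smallest and largest expert output.  Two
experts are the default; the gate lets the ensemble specialize across the
heterogeneous tissue/cohort structure of multi-cohort compilations.

## The training objective

Healthy subjects have, by assumption, biological age equal to chronological
age, and are scored with mean absolute error.  Unhealthy subjects carry
inexact labels — their biological age may deviate from the chronological
label — so they are scored with a *Hinge-MAE*: an absolute error below a
margin Δ (default 5 years) costs nothing, errors at or above the margin
cost their full absolute value.  Both branches share the same network; each
sample is routed by its health status.

A second term aligns the model's attention with prior knowledge.  The
saliency of expert i is S_i = ∂F_i/∂x; the model-level saliency is
Σ_i p_i·S_i with the gate weights treated as constants of the input
differentiation (the gate's own input-derivative is excluded; a flag
exposes the full product rule).  Per-gene importance is the mean absolute
saliency over the batch.  With G* a curated aging-gene pool and G_t the
top-k genes by importance, the alignment (AHK) loss is

    L_AHK = − (Σ_{g ∈ G_t ∩ G*} |S_g|) / (Σ_{g ∈ G_t} |S_g|)  ∈ [−1, 0],

−1 when all top-ranked mass sits on pool genes, 0 when none does.
Importance ranking uses |S| because a signed version of this ratio is
unbounded.  The total batch objective is

    L = λ · mean_s Σ_i p_si · err_si  +  γ · L_AHK,

with λ=30, γ=100 by default, err the status-routed per-sample error.  The
AHK term appears once per batch (the gate weights sum to one, so it factors
out of the per-expert sum).  Each epoch a fresh random 10% of the pool is
used in the AHK numerator-membership test; top-k defaults to 1000 (capped
at d).  The top-k selection and pool membership are piecewise constant and
carry no gradient; everything else does, which requires differentiating
through an input-gradient.  The package ships a small reverse-mode autodiff
engine (`moeclock.engine`) whose vector-Jacobian products are themselves
graph nodes, so this double differentiation is exact (finite-difference
checked in the test suite to relative 1e-3).

## Optimization

Adam with initial learning rate 5e-3, step-decayed by 0.8 every
`decay_every` epochs (default 20), batch size 512, 200 epochs by default.
Each training sample is augmented with 30 Gaussian-noise copies (sd 0.5 on
the standardized scale) by default; augmented copies never enter validation
or test folds.  Expert output biases are initialized at the mean training
age so early epochs fit the age signal rather than the global offset.  All
randomness (initialization, shuffling, augmentation, per-epoch pool
subsets, dropout) derives from one `random_state` through named
substreams; fits are bit-reproducible on the same build.

The engine is numpy-based and CPU-oriented.  The test suite and the worked
examples therefore run a *desk-scale profile* — hidden widths around
(128, 64) or smaller, a few augmentation copies, tens of epochs, cohorts of
a few hundred samples and d=2000 genes — chosen as the smallest sizes at
which every qualitative property of the method (margin routing, gate
behaviour, AHK descent, PAD separation) is still measurable.  The shipped
defaults remain the full-scale recipe above.

## Normalization

Counts-per-million on per-sample library size, log(1+CPM), then per-gene
z-scoring.  Gene filters (total count ≥ 10 and expressed in ≥ 2 samples,
both configurable) and all centers/scales are computed on training samples
only and frozen into a `NormalizationModel`; applying the model to new data
uses no statistic of that data, which is what makes the cross-validation
protocol leakage-free.  Genes with training sd < 1e-8 get scale 1 (they
standardize to 0 and carry no signal).  For data already on a continuous
scale (e.g. the synthetic cohorts) the CPM and log steps are switched off
and only the frozen z-scoring applies; count-based gene filters are skipped
in that mode.  Gene matching is exact-string; alias resolution is out of
scope.  CPM library sizes are computed over all genes present in the given
matrix, so train and test tables should share the same gene universe.

## The synthetic cohort generator

The generator emulates the structure of a multi-cohort bulk RNA-seq aging
compilation with known ground truth.  For each sample, chronological age is
uniform on (20, 90) years; biological age equals chronological age plus a
disease-group offset δ (0 for healthy).  A random subset of `n_causal`
(default 100 of d=2000) causal genes has expression
slope_g·(biological age) + cohort intercept + N(0, noise_sd²); slopes are
drawn N(0, effect_size²) with effect_size = 0.1 units/year, noise_sd = 1,
and per-cohort per-gene intercepts are N(0,1) across 3 cohorts.  Non-causal
genes are intercept + noise only.  The aging-gene pool (default 200 genes)
contains half of the causal genes plus non-causal padding
(`frac_causal_in_pool` = 0.5).  A quadratic age link is available behind a
flag for nonlinearity checks.

The effect size was set by a feasibility analysis: at n=600 samples an
oracle given the true slopes reaches MAE ≈ 1.2 years and a ridge reference
≈ 2.0, so a learned model has realistic headroom, while the per-gene
signal remains well below the noise floor of any single gene — the model
must pool hundreds of weak signals, as on real data.

What the generator deliberately does not emulate: count-level
(negative-binomial) noise — output is on the normalized scale the model
consumes; disease-specific expression signatures — unhealthy samples differ
from healthy *only* through the biological-age shift, so the gate cannot
separate them by condition and the margin branch is exercised in its
hardest regime; batch effects beyond additive cohort intercepts; and
realistic gene–gene correlation.  Passing tests therefore demonstrate the
mechanics and statistical behaviour of the method, not clinical accuracy on
real tissue.

## Evaluation protocol

Held-out accuracy on healthy samples is MAE and R².  For condition groups,
PAD = predicted − chronological age is compared between the condition and
healthy controls unseen in training, with Welch's unequal-variance t-test
(default) or a seeded 10,000-resample permutation test; the accelerated
verdict ("A.") requires significance at α=0.05 *and* a positive shift, a
significant negative shift is reported as decelerated ("D."), anything
else "N.".  No multiple-testing correction is applied across conditions
(verdicts are per-condition, as in the protocol this follows); that is a
documented limitation.  Age groups are young < 30, adult 30–70 (both ends
inclusive), old > 70 years.

Cross-validation is 10-fold, stratified by health status and age quartile,
with normalization refit inside every fold.

## Robustness models

Four perturbations: additive Gaussian noise on the (normalized) expression
matrix; dropout noise zeroing entries independently at a given rate; PCA
noise — coefficients on the principal components beyond the leading set
explaining 95% of training variance are rescaled by ρ, implemented
additively (x̃ = x + (ρ−1)·tail reconstruction) so ρ=1 is exactly the
identity for any sample; and Gaussian label noise.  The PCA basis is
always fitted on training samples only.  Default sweep magnitudes are
{0, 0.5, 1.5, 3, 5, 10} for Gaussian sd and {0, 1, 2, 5, 7, 10, 20} for ρ.
The sweep harness perturbs inputs at evaluation time; for label noise it
perturbs the evaluation labels as a cheap sensitivity proxy — the
training-label-noise experiment is run by refitting on annotations passed
through `inject_label_noise`.

## Numerical choices and edge cases

- Degenerate gene sd < 1e-8 → scale clamped to 1.0.
- All-zero saliency (e.g. a dead network) → L_AHK = 0 with a warning; 0 is
  the no-information value of the ratio.
- Ranking ties break by gene ID lexicographically (deterministic output).
- Pool subsampling size is round(fraction·N), at least 1.
- Batch-norm ε = 1e-5, momentum 0.1; eval mode uses running statistics, so
  eval-mode prediction and saliency are pure functions of parameters and
  input.
- Hinge boundary is inclusive: |error| = Δ is penalized.
- He-style uniform fan-in initialization; no sparsity (L1) penalty by
  design — the AHK term is the soft gene-selection mechanism.
- R² is reported as missing when the target is constant.

## Known limitations

- At desk-scale sample sizes (a few hundred training samples against
  d=2000 genes) the network's held-out predictions show regression-to-the-
  mean: the training-side calibration slope is ≈1 while the held-out slope
  settles around 0.8, which alone contributes several years of MAE when
  ages are spread uniformly over (20, 90).  A dense, weak, purely linear
  age signal is the least favourable case for a deep net relative to a
  ridge regression, and the synthetic generator produces exactly that
  case.  Held-out healthy MAE on the acceptance-scale fixture is ≈4.1
  years under the desk-scale profile (the test suite computes this
  number); group-level PAD verdicts and the type-I error rate are
  unaffected, because the attenuation shifts condition and control PADs
  alike.
- The reported trainable-parameter count depends on the input dimension d
  of the data at hand; `parameter_count` computes it per config.
- The autodiff engine implements exactly the primitives this model needs;
  it is not a general-purpose framework and runs on CPU only.
- The PAD test assumes exchangeable controls; with strong cohort imbalance
  between condition and control groups the verdict can reflect cohort
  effects rather than aging.
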