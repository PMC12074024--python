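# moeclock

A transcriptomic aging clock that trains on **both healthy and unhealthy
subjects**.  `moeclock` predicts biological age from bulk gene-expression
profiles with a mixture-of-experts regressor and is aimed at researchers
who work with heterogeneous multi-cohort RNA-seq compilations: multiple
tissues, sexes and disease conditions in one table, chronological age
labels that are only approximately equal to biological age for the
unhealthy subset.

## The model

Each expert F_i is a dense network (hidden widths 640/256/128/64, batch
normalization, ReLU, dropout); a gating network with the same trunk ends in
a softmax head and produces per-sample simplex weights p(x).  The predicted
age is the gated mixture ŷ(x) = Σ_i p_i(x)·F_i(x).  The training loss routes
every sample by health status:

- healthy → mean absolute error |ŷ − y_c| against chronological age y_c;
- unhealthy → **Hinge-MAE**: errors below a margin Δ (default 5 years) cost
  nothing, because an unhealthy subject's biological age may legitimately
  deviate from its chronological label by up to Δ;

plus an **alignment-to-human-knowledge (AHK)** term
L_AHK = −Σ_{g∈G_t∩G*}|S_g| / Σ_{g∈G_t}|S_g| ∈ [−1, 0], where S is the
gate-weighted input-gradient saliency, G_t the top-k genes by |S| and G* a
curated aging-gene pool.  The total objective is λ·(routed error) + γ·L_AHK
with λ=30, γ=100.  Training through L_AHK differentiates a gradient-derived
quantity; the package ships a small numpy autodiff engine whose backward
passes are themselves differentiable, so this double differentiation is
exact.

After fitting, per-gene importance (mean |saliency| across samples) yields
a ranked gene list — gene selection happens *after* model fitting, never
before it, so no label information leaks into a preselection step.

Accelerated aging in a condition group is judged by **PAD significance**:
PAD = predicted − chronological age, compared between the condition group
and healthy controls unseen in training (Welch's t-test or a seeded
permutation test); "A." requires significance *and* a positive shift.

## Worked example

Synthetic cohorts with a known age signal make every stage testable without
external data.  600 samples (400 healthy, 100 with a +10-year
biological-age offset, 100 with no offset) over 2000 genes, 100 of them
age-causal:

```python
import numpy as np
import moeclock as mc

spec = mc.CohortSpec(n_healthy=400,
                     disease_groups=[("acc", 100, 10.0), ("neu", 100, 0.0)],
                     d_genes=2000, n_causal=100, pool_size=200, seed=11)
expr, ann, truth = mc.generate_cohort(spec)
table = mc.align_annotations(expr, ann)
y, status = table["age"].to_numpy(float), table["status"].to_numpy(object)
cond = table["condition"].to_numpy(object)

rng = np.random.default_rng(5)                      # 25% held out per group
test = np.zeros(y.size, bool)
for lab in ("none", "acc", "neu"):
    idx = np.flatnonzero(cond == lab)
    test[rng.choice(idx, size=idx.size // 4, replace=False)] = True

sub = lambda m: mc.ExpressionMatrix(expr.values[m], expr.gene_ids,
                                    [s for s, t in zip(expr.sample_ids, m) if t])
norm = mc.CountNormalizer(library_size="none", log1p=False).fit(sub(~test))
Xtr, Xte = norm.transform(sub(~test)).values, norm.transform(sub(test)).values

est = mc.MoEAgeRegressor(hidden_widths=(128, 64), dropout_rate=0.3,
                         aug_copies=10, epochs=30, decay_every=2,
                         batch_size=256, random_state=0)     # desk-scale profile
est.fit(Xtr, y[~test], status=status[~test],
        pool_indices=truth.pool.indices_in(expr.gene_ids))

pred = est.predict(Xte)
pads = pred - y[test]
ctrl = pads[cond[test] == "none"]
print("healthy MAE", mc.mae(pred[cond[test] == "none"], y[test][cond[test] == "none"]))
for lab in ("acc", "neu"):
    v = mc.pad_significance(pads[cond[test] == lab], ctrl, condition=lab)
    print(lab, v.verdict, f"p={v.p_value:.2g}")
```

Output (≈70 s on one CPU):

```
healthy MAE 4.088753964561489
acc A. p=5.1e-08
neu N. p=0.19
```

The clock's held-out error on healthy samples is ~4.1 years; the group with
the built-in +10-year biological-age offset is flagged as accelerated aging
("A.", p≈5e-8) while the null disease group is not ("N.") — the verdict
pattern the joint healthy+unhealthy training is designed to produce.
Ranking genes by saliency on this model places 92 of the 100 true causal
genes in the top 200:

```python
agg = mc.aggregate_saliency(mc.total_saliency(est.model_, Xte[:50]))
top = mc.rank_genes(agg, expr.gene_ids, 200)
print(len(set(top.gene_ids) & truth.causal_gene_ids))   # -> 92
```

A command-line interface wraps the same pipeline:
`moeclock simulate | train | crossvalidate | saliency | robustness |
evaluate` (see `moeclock --help`).

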