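# parosal

Predicting radiation-induced salivary hypofunction from parotid-gland
dose-volume histograms (DVHs).

Head-and-neck radiotherapy frequently damages the parotid glands, and the
resulting hyposalivation drives dental disease, dysphagia and loss of quality
of life. Treatment plans are summarized by the cumulative DVH — a step
function `V(d)` giving the fraction of the gland receiving at least dose `d`
(Gy) — and the clinical question is how well a patient's one-year
post-therapy stimulated salivary flow can be predicted from it. A
*complication* is defined from the flow ratio: post-therapy flow below a
stated fraction of the pre-therapy baseline (0.25 for a severe reduction).

`parosal` implements, as statsmodels-style Model/Results pairs, three
predictors of that outcome plus the machinery to compare them:

1. **`LKBModel`** — the Lyman-Kutcher-Burman NTCP model. The DVH is reduced
   to an equivalent single-step irradiation by the effective-volume power law

   `v_eff = Σᵢ ΔVᵢ (Dᵢ / D_max)^(1/n)`,  `d_eff = D_max`,

   and the complication probability is a probit in the reduced dose:

   `NTCP = Φ(t)`, `t = (d_eff − TD50(v)) / (m · TD50(v))`, `TD50(1) = TD50(v) · v_eff^n`.

   The organ-specific triple `(TD50(1), m, n)` is estimated by maximum
   likelihood on binary complication labels. A literature parameterization
   (31 Gy, 0.54, 1) is available for reference scoring without fitting.
2. **`SplineLogisticModel`** — each DVH is compressed to six coefficients by
   least-squares fitting a cubic spline with 5 equally spaced knots to the
   cumulative curve; the coefficients feed a ridge-stabilized logistic
   regression, optionally with a natural-spline expansion of each coefficient.
3. **`DVHNeuralNet`** — the DVH sampled at 1-Gy intervals on [0, 70] Gy
   (71 inputs) feeds a single-hidden-layer network (12 logistic units,
   weight decay 0.8) trained by full-batch quasi-Newton minimization of the
   penalized cross-entropy.

`evaluation` provides the comparison protocol: a stratified 70/30 train/test
split, Mann-Whitney AUC, a correlated-ROC (DeLong-type) test for paired AUC
differences (with a permutation alternative), and `cutoff_auc_analysis`,
which scores the test set once per model and sweeps the complication cutoff
over a grid, reporting per-cutoff AUCs and pairwise p-values.

Because no patient-level data is distributed, `simulate` generates synthetic
cohorts whose DVHs are heterogeneous truncated-normal dose distributions and
whose complication probability at a reference cutoff follows the LKB model
*exactly* under a known parameter triple — so every stage of the pipeline is
testable against a known truth.

## Worked example

```python
from parosal import (GeneratorConfig, generate_cohort, LKBModel, SplitSpec,
                     split_cohort, cutoff_auc_analysis, EvaluationConfig)

cohort = generate_cohort(GeneratorConfig(n_patients=510, seed=42))
train, test = split_cohort(cohort, SplitSpec(seed=0))

print(LKBModel(train, cutoff=0.25).fit().summary())
```

```
LKB maximum-likelihood fit
==========================
patients              357
complication cutoff   0.25 x baseline flow
events                164
TD50(1)  [Gy]         42.559
m                     0.7803
n                     0.3458
neg. log-likelihood   227.5456
converged             True (5 starts)
```

The fitted `TD50(1)` of 42.6 Gy is the dose at which uniform whole-gland
irradiation would give this cohort a 50% chance of a severe (< 25% of
baseline) flow reduction; the generating truth was (39.2 Gy, 1.1, 1), and
the deviations illustrate the sampling spread of the maximum-likelihood fit
at this cohort size (the likelihood is nearly flat in `n`; see
`docs/methods.md`).

```python
result = cutoff_auc_analysis(train, test, cutoff_grid=(0.25, 0.5, 0.75),
                             config=EvaluationConfig())
print(result.to_frame().to_string(index=False))
```

```
 cutoff          model      auc  n_events
   0.25     lkb_fitted 0.614726        73
   0.25 lkb_literature 0.614212        73
   0.25         spline 0.621747        73
   0.25     neural_net 0.617123        73
   0.50     lkb_fitted 0.613878        82
   0.50 lkb_literature 0.609584        82
   0.50         spline 0.625043        82
   0.50     neural_net 0.612848        82
   0.75     lkb_fitted 0.610342       102
   0.75 lkb_literature 0.600154       102
   0.75         spline 0.606113       102
   0.75     neural_net 0.606498       102
```

Each row is a test-set AUC for one model when a complication is defined as a
flow ratio below that cutoff; `result.pairwise_frame()` holds the DeLong
p-values for the six model pairs at each cutoff, and `result.plot()` draws
the AUC-versus-cutoff figure. On these synthetic cohorts all four models
hover near the population ceiling implied by the shallow generating
dose-response (about 0.65 at the 0.25 cutoff), so their curves are close;
with real patient data the analysis is identical.

The same pipeline is scriptable:

```bash
parosal simulate --n 510 --seed 42 --out cohort.csv
parosal fit-lkb   --cohort cohort.csv --cutoff 0.25 --out lkb.json
parosal evaluate  --cohort cohort.csv --grid 0.25:0.75:0.05 --out results.json
```

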