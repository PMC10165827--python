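# Methods

## The problem and the data model

The package predicts radiation-induced salivary hypofunction of the parotid
gland from a cumulative dose-volume histogram (DVH). A DVH is stored as a
pair of arrays `(dose_edges, cum_volume)`: strictly increasing doses in Gy
starting at 0, and the fraction of organ volume receiving at least each
dose, starting at 1 and non-increasing. Differential bins are always
*derived*, never stored: the drop `ΔVᵢ = cum[i] − cum[i+1]` is assigned to
the dose edge at which the cumulative curve drops (`dose_edges[i+1]`), and
the residual volume at the last edge is assigned to that edge. This
"drop-edge" convention makes the mean dose of a DVH listing 50% at 20 Gy
and 50% at 60 Gy equal 40 Gy, as a step-function reading requires; a
"midpoint" alternative is available as a parameter and differs negligibly
on fine grids. Resampling uses right-continuous step interpolation (value
at `d` is `cum_volume` at the largest edge ≤ `d`; doses strictly beyond the
last edge map to 0), with linear interpolation as an option.

A patient record couples the ipsilateral DVH with pre- and one-year
post-therapy stimulated whole-mouth flow rates (g/min). The binary outcome
at cutoff `c` is `post/pre < c`, with strict inequality: a ratio exactly at
the cutoff is a non-complication. Only the one-year flow is modelled;
shorter-horizon measurements are out of scope.

## LKB model

The Lyman-Kutcher-Burman model reduces the DVH to an equivalent uniform
irradiation by the effective-volume power law
`v_eff = Σ ΔVᵢ (Dᵢ/D_max)^(1/n)` at `d_eff = D_max` (the largest dose
received by a nonzero volume), then applies a probit dose-response
`NTCP = Φ((d_eff − TD50(v)) / (m·TD50(v)))` with `TD50(v) = TD50(1)/v_eff^n`.
Φ is evaluated with the standard-normal CDF routine rather than by
quadrature of its integral representation — they are the same function.
Two algebraic identities anchor the implementation and its tests: uniform
whole-organ irradiation at `TD50(1)` yields NTCP = 1/2 for every `(m, n)`,
and at `n = 1` the model depends on the DVH only through its mean dose.

**Parameters.** `TD50(1)` (Gy): dose giving 50% complication probability at
uniform whole-organ irradiation; bounds [5, 150] Gy. `m` (unitless): slope;
`m·TD50(v)` is the standard deviation of the dose-response; bounds
[0.05, 5]. `n` (unitless): volume effect, bounded to (0.01, 1]; the cap at 1
reflects that published parotid fits report `n = 1` (a boundary value), and
is configurable.

**Fitting.** Maximum likelihood on Bernoulli labels at a configurable
cutoff (default 0.25). Probabilities are clipped to
`[1e-12, 1 − 1e-12]` inside the likelihood as a guard against `log(0)`;
the clip does not move any optimum encountered in testing. Optimization is
L-BFGS-B on transformed parameters — `log TD50(1)`, `log m`, and a logit
rescaling of `n` onto its bound interval — so positivity and bounds hold by
construction, from five deterministic starts (the profile likelihood in `n`
is nearly flat, and single-start fits can stop on the ridge); the best
final likelihood wins. Cohorts with a single outcome class raise an error,
as do DVHs with no positive dose. The model is fitted once at its training
cutoff by default; refitting per evaluation cutoff is available as a flag
in the evaluation layer, since scoring is cutoff-free either way.

## Spline-logistic model

**DVH featurization.** Each DVH is approximated by a cubic spline with 5
knots equally spaced across the fitting dose range (default: 0 to the
observed maximum dose for standalone use; a fixed [0, 70] Gy inside the
cohort-level model so features are comparable across patients). The fit is
ordinary least squares of the step-interpolated curve on a dense 0.5-Gy
grid, and the feature vector is the intercept plus the 5 basis weights —
six coefficients.

A note on the basis: a cubic spline that is natural (linear) beyond *both*
extreme knots spans only a 5-dimensional space on 5 knots, so no full-rank
6-coefficient two-sided-natural basis exists. We therefore use the
truncated-power basis `{1, u, (u−t₁)³₊, …, (u−t₄)³₊}` with `u` the dose
scaled by the top knot: a genuine cubic spline on the 5 stated knots whose
second derivative vanishes at the left boundary and whose last-knot basis
function is identically zero on the fitting range (and is therefore
omitted). The scaling of `u` to [0, 1] keeps the least-squares problem
well conditioned; rank deficiency (degenerate DVH support) raises an error
naming the gland. Straight lines are in the span exactly, which the tests
exploit.

**Classifier.** The six coefficients enter a logistic regression after an
optional additive natural-spline expansion of each coefficient
(knot count 0–4; knots at training quantiles; two or fewer knots reduce to
the plain linear term). The fit minimizes the *mean* Bernoulli negative
log-likelihood plus `0.5 · λ · ‖w‖²` with `λ = 1e-4` per observation and an
unpenalized intercept: the per-observation scaling makes the optimum
exactly invariant to replicating the dataset, and the ridge keeps the fit
finite under complete separation. Features are standardized internally
(training mean/sd). The expansion knot count can be tuned by stratified
10-fold cross-validated AUC at the 0.5×baseline cutoff
(`tune_expansion`); the default evaluation pipeline uses 3 knots per
coefficient without re-tuning, since tuning inside every evaluation run is
costly and the interface exposes it separately.

## Neural network

The network maps the DVH resampled at 1-Gy steps on [0, 70] Gy (71 inputs,
raw fractional volumes, no standardization — the inputs are already
commensurate in [0, 1]) through a single hidden layer of logistic units
(default 12) to a logistic output. Training minimizes the summed Bernoulli
negative log-likelihood plus `decay · Σw²` with biases excluded from the
penalty (a flag includes them); the default `decay = 0.8` matches the
classical weight-decay formulation in which that published value was
selected, where the penalized criterion is the entropy (half-deviance) —
using the full deviance would silently halve the effective decay.
Optimization is full-batch L-BFGS with analytic gradients (about 880 free
parameters at the defaults), capped at 500 iterations, from 5 seeded
uniform(−0.5, 0.5) initializations, keeping the best penalized loss; the
accepted-iterate loss trace is recorded and is non-increasing.
`tune_nn` grid-searches `(hidden_units, decay)` by stratified 10-fold CV
AUC at the 0.5 cutoff, retrying stratification once before erroring on a
single-class fold.

## Evaluation protocol

A seeded 70/30 split (training size `round(0.7·N)`; 510 → 357/153),
stratified on the label at a configurable cutoff (default 0.5) by
largest-remainder allocation; unstratified splitting is a flag. Four
models are scored on the test set: the fitted LKB (trained at 0.25), the
literature LKB (31 Gy, 0.54, 1; no fitting), the spline-logistic and the
network (both trained at 0.5). Scores are computed once and reused across
the cutoff grid (default 0.25–0.75 in 0.05 steps) — only the labels change.
AUC is the Mann-Whitney statistic with ties counted 1/2; paired AUC
differences are tested with the correlated-ROC (DeLong-type) variance
built from per-subject placement values, two-sided, with a
subject-level score-swap permutation test as an independent alternative.
Identical score vectors give p = 1 with a warning. P-values are reported
unadjusted; cutoffs at which the test set has a single class are reported
as missing rather than dropped.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
a portrait of any real cohort. Per patient: a mean dose
`μ ~ U(10, 65) Gy` and spread `σ ~ U(2, 15) Gy`; the differential dose
distribution is Normal(μ, σ) truncated to [0, 70] Gy and binned at 0.5 Gy,
and the cumulative DVH is its survival function. Baseline flow is
Normal(1.47, 0.864) g/min truncated above 0.1; the standard deviation is
back-computed from a reported 95% CI of the mean, (1.40, 1.55) g/min at
n = 510, as `half-width / 1.96 · √510`, and a test recomputes it. The flow
ratio is drawn from a mixture tied to the reference cutoff (default 0.25):
with probability `p = NTCP(dvh; truth)` — truth defaulting to
(39.2 Gy, 1.1, 1) — the ratio is U(0, cutoff), otherwise
`cutoff + (1.3 − cutoff)·Beta(2, 2)`. This makes
`P(ratio < cutoff | DVH) = p` hold *exactly* at the reference cutoff, so
parameter-recovery tests have a known truth; the induced probabilities at
other cutoffs are artifacts of the mixture, not modelling claims. Ratios
are continuous on [0, 1.3] and span every evaluation cutoff, and label
prevalence is non-decreasing in the cutoff.

What the generator does not emulate: demographics and tumor-site structure,
contralateral-gland correlation, realistic DVH shape families beyond the
truncated-normal choice, and any covariate effect on salivary recovery.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline, not clinical performance on real plans.

## Statistical behavior at the default conditions, and problem sizes

Two properties of the default generating truth matter when reading test
output. First, the dose-response is shallow: `m·TD50(1) = 43.1 Gy` keeps
per-patient NTCP within roughly [0.25, 0.72] over the generated dose range,
so scoring even with the *true* parameters yields a population AUC of about
0.65 at the reference cutoff — an intrinsic ceiling for every model on
these cohorts. Second, the likelihood is nearly flat in `n` when DVH shapes
co-vary with their means, so `n̂` has large sampling spread and `(TD50, m)`
estimates move along the ridge with it; at n = 2000 the observed sampling
spread is roughly 1.4 Gy in `TD50(1)` and 0.13 in `m`, with `n̂` ranging
over most of its interval. Unit tests therefore check recovery at
tolerances calibrated to that spread (±4 Gy, ±0.4) together with the
optimality property that the fitted likelihood is at least as high as the
truth's.

Test problem sizes are chosen to exercise every code path while keeping
the default suite around two minutes on one core: recovery fits at
n = 2000, end-to-end sweeps at n = 400–1000 with a reduced network
configuration where the property under test does not depend on network
capacity, and cross-validation properties at n = 120–500.

## Known limitations

- The LKB likelihood offers no confidence intervals or profile-likelihood
  machinery; the flat-`n` ridge makes Wald intervals misleading anyway.
- The spline and network models accept only DVH-derived inputs; clinical
  covariates (age, chemotherapy, site) have no interface.
- DVHs discard spatial dose information; sub-regional sensitivity of the
  gland is invisible to every model here.
- `D_max` is taken as the largest dose edge with nonzero differential
  volume, so DVHs with long low-volume tails have `D_max` dominated by
  numerically tiny bins; at `n = 1` this cancels exactly, and at small `n`
  it is part of the model family rather than a separate artifact.
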