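# Methods

## Problem and scope

Given an `n × d` mixed-type table with a schema declaring each variable
*continuous* or *categorical* and each role *independent* (imputation
target) or *dependent* (fully observed outcome), the package (i) simulates
missing-at-random (MAR) holes in the independent variables of a complete
table, (ii) imputes them with an adversarially trained generator network
or with reference baselines, and (iii) scores imputations per variable
against the known truth. It evaluates imputation *accuracy* only:
post-imputation inference (Rubin's rules, confidence-interval coverage) is
out of scope, as is longitudinal/repeated-measures data.

## Encoding

Continuous variables are min-max scaled to [0,1] using the observed
minimum and maximum (at least two distinct observed values are required;
a constant column is a "degenerate scale" error). Categorical variables
are one-hot encoded in schema category order, one contiguous block per
variable. Min-max rather than z-scoring is used so that the generator's
sigmoid outputs decode directly; imputed continuous values are therefore
always clipped to the observed range. Decoding takes the block argmax,
ties broken deterministically toward the lowest category index. The
encoded mask is defined per variable and replicated across one-hot
blocks — a categorical value is observed or missing as a whole.

## The adversarial imputer

Generator and discriminator are fully connected networks (default: 2
hidden layers of width D, relu), implemented in numpy with manual
backpropagation; no deep-learning framework is used. The generator input
is the concatenation `[mean-filled encoded data ‖ encoded mask]` (2D
columns); its output head applies a sigmoid to continuous columns and a
softmax within each one-hot block, so proposals live in [0,1]^D and
observed categorical blocks compete as probability vectors. The
discriminator input is `[imputed data ‖ hint]`; its output is a per-entry
observedness probability via sigmoid.

Three departures from the original GAIN construction target mixed-type
clinical tables:

1. **Mean fill instead of noise.** Missing entries of the generator input
   carry their column's observed mean (for one-hot blocks, the observed
   class-frequency vector) rather than uniform noise, which starts the
   optimization at the marginal solution.
2. **Batch normalization** on the generator's hidden layers (batch
   statistics during training, running statistics at imputation time).
   The discriminator is left un-normalized: normalizing the adversary is
   known to destabilize the game.
3. **Split reconstruction loss.** The generator loss is
   `L = −mean_{missing} log D(X̂,H) + α·MSE_obs,cont + β·CE_obs,cat`,
   with the squared-error term normalized by the number of observed
   continuous entries and the cross-entropy term by the number of observed
   categorical blocks, so α and β keep their meaning across missingness
   rates. Defaults α = β = 10.

Training alternates `k` discriminator updates (k = 1 by default;
interpreted as discriminator steps per generator step) with one generator
update per iteration, each on a fresh uniform minibatch (default 128
rows). The hint matrix is `H = B⊙M + 0.5(1−B)` with `B ~ Bernoulli(p_hint)`
per (row, variable), replicated over blocks; default `p_hint = 0.9`. The
discriminator loss is the mean binary cross-entropy over *all* entries
(the convention of the widely used reference implementation), with
probabilities clipped at 1e-8. Imputation computes
`X̂ = M⊙X + (1−M)⊙G(X̄,M)`, decodes, and then copies the observed cells
from the input verbatim, so observed data are preserved exactly, not
round-tripped through the encoder.

**Optimizer.** `sgd`, `momentum` (0.9) and `adam` (β₁ = 0.9, β₂ = 0.999)
are available. The default is adam at learning rate 1e-3: in our testing,
plain SGD at practical rates is seed-sensitive on one-hot blocks — a
categorical variable's imputation can collapse to worse-than-mode — while
adam trains stably across seeds. Adam is also what the original GAIN
reference code uses. Parameters are initialized fan-in uniform from a
seeded stream; training, and hence the whole pipeline, is bit-reproducible
given the config seed. Default iteration budget is 5,000; the sanity
experiments in the test suite use 2,000, which suffices on small tables.

**Repeated imputation.** `multiple_impute` derives m independent training
seeds from the config seed (default m = 100 repeats per incomplete
dataset; desk-scale runs use small m).

## MAR amputation

For each independent variable j, each cell of a complete table is masked
independently with probability `sigmoid(c_j + w_jᵀ z_i)`, where `z_i` are
the dependent (outcome) variables of row i — encoded, reference-coded
(one indicator column per categorical driver is dropped so the design is
full-rank and every weight is identifiable), and standardized per column.
Weights are drawn i.i.d. standard normal per (target, driver column) and
re-drawn per replicate; the intercept `c_j` is calibrated by bisection so
that the *expected* missingness of each target equals the nominal rate
(20% or 50% by default) to 1e-6 on the calibration table. The
logistic link makes that calibration monotone, hence the root unique.
Dependent variables are never masked. Zero weights reduce the mechanism
to MCAR exactly. Mechanism drawing and mask sampling use separate seeded
streams, so replicate sets are exactly reproducible; the default is ten
replicate incomplete datasets per rate.

## Evaluation

Metrics are computed over the masked cells only, per variable — observed
cells are preserved by construction, so scoring them would dilute every
method toward zero error:

* `NRMSE = sqrt((1/N)Σ(x̂−x)²) / ((1/N)Σx)` over the N masked cells of a
  continuous variable. The denominator is the mean of the *true* values of
  those cells; a near-zero mean (|mean| ≤ 1e-12) is an error, not a silent
  fallback. By this formula PFC's analogue of scale-invariance holds:
  NRMSE is invariant to positive rescaling of the variable.
* `PFC = 1 − N_correct/N` for categorical variables; bounded in [0,1] by
  construction.

Repeated imputations are summarized as mean ± SD of the per-repeat
metric. Method comparison follows the benchmark's protocol: Shapiro-Wilk
on pooled residuals per variable; one-way ANOVA if normality is not
rejected, Kruskal-Wallis otherwise; pairwise tests (Welch t, or
Mann-Whitney in the non-normal branch) only when the omnibus test rejects
at 0.05. P-values are reported raw, without multiplicity correction.

## Baselines

* **Mean/mode**: observed column mean, or modal category with ties broken
  by schema order. The null reference — any method exploiting covariate
  structure should beat it.
* **Iterative chained imputer** (missForest-style): initialize by
  mean/mode; visit variables in order of increasing missingness; re-fit a
  per-variable predictor on the currently completed data and re-predict
  the missing cells; stop when the difference criterion (continuous: sum
  of squared changes over the sum of squares of the new imputation;
  categorical: fraction of changed cells; summed) first increases —
  returning the previous iterate — or after at most 10 passes. Predictors
  are random forests with 20 trees and sqrt-dimensionality feature
  sampling (the standard missForest configuration), or plain
  linear/logistic regression as a transparent alternative. Predictive mean
  matching is deliberately not re-implemented; externally produced
  imputations can be scored through the `evaluate` CLI's CSV contract.

## Hyperparameter tuning

`greedy_search` sweeps the hyperparameters once, coordinate-wise, in the
order structure → optimization → loss weights → adversarial knobs
(`n_iterations, hidden_layers, neurons_per_layer, learning_rate,
optimizer, activation, alpha, beta, p_hint, k`), holding the others at the
incumbent and keeping each sweep's argmin (ties toward the first
candidate). The score of a configuration is its imputation error on a
validation holdout: an extra Bernoulli(0.1) share of the observed
independent cells is hidden, the model trains on the reduced table, and
the held-out cells are scored as mean per-variable NRMSE plus mean
per-variable PFC. The search returns the best configuration it evaluated,
so the log minimum always equals the returned score. The single pass and
the single holdout split keep cost linear in the grid size; the scoring
function is injectable, which is also how the search's behaviour is
verified against exhaustive enumeration on synthetic score surfaces.

## Synthetic data

A Gaussian copula couples all predictors; margins are shaped
independently: normal or shifted lognormal for continuous variables (the
lognormal σ is solved from a target skewness via
`skew = (e^{σ²}+2)√(e^{σ²}−1)`, monotone in σ), and quantile thresholding
for categorical variables at the cut points implied by target
proportions. Binary outcomes are Bernoulli draws from a logistic model on
the standardized predictors, so the MAR mechanism — which is driven by the
outcomes — induces missingness genuinely related to the predictors being
imputed. Presets `dm_like` (15 continuous + 6 categorical predictors,
7 outcomes, default n = 50,000; skewness from ≈0 to ≈11.45, minority
proportions 8.5–47%) and `ht_like` (5 + 5 predictors, 2 outcomes, default
n = 10,000; skewness up to ≈7, minorities 7.5–41%) copy the variable
counts and the skewness/imbalance *profile* of two large primary-care
cohorts; all location/scale/correlation values are plausible synthetic
magnitudes chosen here (inter-predictor correlation decays as 0.5^|i−j|),
**not** estimates of any restricted dataset. `demo_correlated_spec` builds
a small equicorrelated table (ρ = 0.9 by default) where every variable is
predictable from the others — the fixture on which a learning imputer must
clearly beat mean/mode.

What passing tests on these generators shows: the mechanics are correct
(calibration, structure, determinism) and the imputer exploits
between-variable dependence when it exists. What they do not show:
performance on real cohorts, whose dependence strength, measurement error
and missingness patterns the copula does not claim to match.

## Problem sizes and observed desk-scale behaviour

The full-scale experimental design (n = 50,000, 10 replicates per rate,
m = 100 repeats, tuned hyperparameters) is hours of compute. The package's
test suite and `scripts/acceptance.py` run the identical pipeline at desk
scale: n = 2,000, 2 replicates, 2–5 repeats, 1,500–2,000 training
iterations. At that scale, on the moderately correlated `ht_like` preset,
the adversarial imputer beats mean/mode on most variables but not on the
most heavily skewed margin, where the adversarial term's sampling spread
inflates RMS error and the aggregate NRMSE with it; on the strongly
correlated fixture it roughly halves both NRMSE and PFC relative to
mean/mode. This is the expected trade-off: the discriminator rewards
imputations that look like draws from the data distribution, which is not
the RMS-optimal conditional mean, and the gap matters most when the
exploitable signal is weak relative to the margin's spread.

## Numerical choices and degenerate inputs

* Probabilities are clipped at ε = 1e-8 inside both losses; softmax is
  computed with max-subtraction; the sigmoid is the numerically stable
  two-branch form.
* Intercept calibration brackets by doubling and bisects to 1e-9 in c
  (realized rate within 1e-6).
* Encoder errors: constant continuous column (degenerate scale), fully
  missing encoded column (cannot mean-fill / train).
* Argmax and mode ties break toward the schema's first category;
  greedy-search score ties toward the first candidate — all
  reproducibility-motivated.
* A driver column with zero variance is given unit standard deviation
  (its weight then has no effect) rather than raising.
* Non-finite training losses raise immediately, naming the iteration.
* Seeds everywhere are derived with `numpy.random.SeedSequence` and kept
  below 2³¹.

## Known limitations

* PFC is bounded in [0,1] by its definition; error magnitudes above 1 for
  categorical variables cannot occur under this implementation.
* The hyperparameter "k" (discriminator steps per generator step) and the
  exact training-loop body follow the original GAIN construction; other
  readings of that hyperparameter are possible.
* Single imputation uncertainty is captured only descriptively (SD over
  repeats); no pooling rules are provided.
* The iterative baseline is a faithful loop/stopping-rule re-expression
  around scikit-learn forests, not a bug-for-bug reimplementation of the
  R packages it emulates.
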