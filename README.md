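# gainimpute

Adversarial imputation of missing values in mixed-type clinical tables,
with a missing-at-random (MAR) amputation simulator and an NRMSE/PFC
benchmarking harness.

Cohort datasets in clinical and epidemiological research routinely mix
continuous measurements (blood pressure, lab values) with categorical ones
(sex, drug usage), and routinely have holes: non-response, lost follow-up,
tests that were simply not ordered. Deleting incomplete records biases
inference and wastes data; classical imputers either struggle with
non-linear structure (chained equations with linear models) or become
prohibitively slow on large cohorts (random-forest imputation). This
package implements a generative adversarial imputation network (GAIN)
adapted for mixed-type tabular data, for researchers who want a fast,
accurate single-model imputer on large tables — plus everything needed to
*benchmark* it honestly: a calibrated MAR amputation simulator, reference
baselines, and per-variable error metrics.

## The model

Let `X` be the table in encoded form (continuous variables min-max scaled
to [0,1], categorical variables one-hot per block) and `M` the observedness
mask (1 = observed). The **generator** `G` maps the mean-filled data and
the mask to an imputation proposal:

    X̄ = M ⊙ X + (1 − M) ⊙ column-mean(X)        (mean fill, not noise)
    G(X̄, M) ∈ [0,1]^D                            (sigmoid / per-block softmax)
    X̂ = M ⊙ X + (1 − M) ⊙ G(X̄, M)               (observed cells kept)

The **discriminator** `D` receives `X̂` together with a hint matrix
`H = B ⊙ M + 0.5·(1 − B)`, `B ~ Bernoulli(p_hint)` per variable, and
predicts which entries were actually observed. Training alternates `k`
discriminator steps (cross-entropy of `D(X̂, H)` against `M`) with one
generator step minimizing

    L_G = −E[ log D(X̂, H) over missing entries ]
          + α · MSE(observed continuous entries)
          + β · CE(observed categorical blocks)

Three modifications adapt the construction to mixed-type clinical tables:
the random noise of the original formulation is replaced by column means,
generator hidden layers are batch-normalized, and the reconstruction loss
is split into continuous (α) and categorical (β) terms. A greedy
coordinate-wise search tunes the hyperparameters (`k`, `p_hint`, α, β,
iterations, layers, neurons, activation, learning rate, optimizer) against
a validation holdout. The networks are plain fully connected stacks
implemented in numpy with manual backpropagation; training is
bit-deterministic given the seed.

Imputation accuracy is scored on the amputed cells only, per variable:

    NRMSE = sqrt(mean((x̂ − x)²)) / mean(x)       (continuous)
    PFC   = 1 − N_correct / N                    (categorical)

MAR missingness is simulated per independent variable as
`P(missing) = sigmoid(c_j + w_jᵀ z)` over the standardized, fully observed
outcome variables, with `w_j` randomized per replicate and `c_j` calibrated
by bisection so the expected rate hits the nominal 20% or 50% exactly.

## Worked example

```python
from gainimpute import (GAINImputer, ampute, demo_correlated_spec,
                        draw_mechanism, generate, nrmse, pfc)

table = generate(demo_correlated_spec(n=2000, seed=7))   # complete truth
mech = draw_mechanism(table, 0.2, rng_seed=11)           # MAR mechanism
incomplete = ampute(table, mech, rng_seed=12)            # ~20% holes

imp = GAINImputer(table.schema, n_iterations=2000, seed=0)
completed = imp.fit_transform(incomplete.values)

nrmse(completed, table.values, incomplete.mask, table.schema, "x0")
pfc(completed, table.values, incomplete.mask, table.schema, "c0")
```

On this strongly correlated synthetic table the run above prints, per
variable, against the mean/mode null baseline:

```
x0 NRMSE gain 0.101 | mean-fill 0.198
x1 NRMSE gain 0.085 | mean-fill 0.154
x2 NRMSE gain 0.066 | mean-fill 0.135
c0 PFC   gain 0.171 | mode-fill 0.245
c1 PFC   gain 0.138 | mode-fill 0.279
```

i.e. the learned imputer roughly halves the error of filling in column
means and modes, for both variable types: it is actually exploiting the
between-variable structure. `GAINImputer`, `MeanModeImputer`,
`ChainedImputer` (an iterative missForest-style baseline: 20 trees, sqrt
feature sampling, at most 10 passes) and `MARAmputer` are scikit-learn
estimators (`fit`/`transform`/`get_params`) over pandas DataFrames with a
declared schema.

The same experiment runs from the shell:

```sh
gainimpute generate --preset ht_like --n 2000 --seed 0 \
    --out data.csv --schema-out schema.yaml
gainimpute ampute --in data.csv --schema schema.yaml --rate 0.2 \
    --replicates 10 --seed 0 --out-dir amputed/
gainimpute impute --method gain --in amputed/replicate-01/data.csv \
    --schema schema.yaml --m 5 --seed 0 --out-dir imputed/gain/
gainimpute evaluate --truth data.csv --mask amputed/replicate-01/mask.csv \
    --schema schema.yaml --imputed-dir imputed/ --out report.tsv
gainimpute benchmark --desk --out-dir bench/ --seed 0   # the whole loop
```

Synthetic presets `dm_like` (15 continuous + 6 categorical predictors,
7 binary outcomes, skewness up to ~11, minority classes down to ~8.5%) and
`ht_like` (5 + 5 predictors, 2 outcomes) emulate the *shape* of large
primary-care cohorts; their parameter values are plausible synthetic
magnitudes, not estimates of any real dataset.

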