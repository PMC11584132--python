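# Methods

This note records the model implemented by `aganimpute`, the choices made
where the design was genuinely open, and what the shipped tests do and do
not demonstrate.

## Data model

A table is an `n × d` float matrix with `NaN` as the missing marker. The
mask `M` has `m_ij = 1` where the cell is observed. Column types are
inferred from observed cells only: a column is *real* (code 0) if any
observed value has a nonzero fractional part, *binary* (code 1) if it is
integer-valued with exactly two distinct levels, and *nominal* (code 2)
otherwise. Nominal categories are assumed integer-coded on input;
free-text levels (e.g. `"Yes"/"No"`) must be mapped to numbers at read
time via `label_map`. A column with no observed cell has no decidable
type and is an error.

Min-max normalization maps each column onto [0, 1] using the observed
minimum and maximum only — missing cells cannot contribute, and using the
full-data statistics would leak ground truth in benchmark mode. A
constant column (zero span) maps to all zeros and denormalizes to its
constant; this keeps the round trip exact and avoids 0/0. Observed cells
survive a normalize→denormalize round trip to within 1e-9 relative
error; the imputer additionally copies the original observed values into
its output verbatim, so preservation is exact, not approximate.

## The adversarial imputer

Generator and discriminator are two-hidden-layer perceptrons (64 units
per layer by default) with swish activations `x·σ(βx)` and sigmoid
outputs, implemented directly in numpy with hand-derived reverse-mode
gradients.

* **Generator input** — the noise-filled matrix
  `Z = M⊙X + (1−M)⊙N`, `N ~ U[−0.01, 0.01]`, concatenated with `M`
  (input width `2d`). Fresh noise is drawn for every minibatch. The
  attribute codes steer the *output* stage (projection), not the network
  input.
* **Discriminator input** — the composite `X̂ = M⊙X + (1−M)⊙X̄` alone,
  width `d`, with a per-cell sigmoid output: entry `(i,j)` estimates the
  probability that cell `(i,j)` is observed. No hint/prompt matrix is
  supplied; the discriminator must localize the generated cells
  unaided.
* **Discriminator loss** — per-cell binary cross-entropy against `M`,
  plus `λ` times a gradient penalty (below). Probabilities are clamped to
  `[1e-7, 1−1e-7]` before logs; the backward pass uses the standard
  BCE-with-logits form, which needs no clamp.
* **Generator loss** — `−log D` averaged over missing cells (defined as 0
  for a batch without missing cells) plus `α` times the mean squared
  reconstruction error on observed cells.
* **Gradient penalty** — `mean_i (‖g_i‖₂ − 1)²` where
  `g_i = ∇_{x_i} Σ_j z_ij` is the input-gradient of row *i*'s summed
  *pre-sigmoid* logits. Taking the gradient of the unsquashed critic
  score makes the penalty behave like the usual critic regularizer and
  gives the clean closed forms used as test oracles (a constant
  discriminator scores exactly 1; a linear one scores `(‖w‖−1)²`). The
  penalty is evaluated at the imputed batch itself — no real/fake
  interpolation. Its exact parameter gradient requires differentiating
  through the input-gradient; this is implemented as a forward-mode
  (tangent) sweep along the constant co-vector followed by a reverse
  sweep over the doubled graph, using the first two swish derivatives.
  The whole construction is verified against finite differences in the
  test suite.
* **Training schedule** — generator-only pretraining on the
  reconstruction objective (the only non-adversarial objective
  available) for `pretrain_epochs` passes, then the adversarial loop:
  one discriminator Adam step every `d_update_period = 8` generator
  steps, `epochs × ceil(n / batch_size)` generator steps in total. Any
  non-finite loss aborts with the iteration index.
* **Output stage** — after training, one full-table generator pass fills
  the missing cells; the composite is denormalized and every value in a
  binary/nominal column is snapped to the nearest member of that
  column's observed category set (idempotent), so the completed table is
  type-valid by construction.

### Hyperparameters

| parameter | default | notes |
| --- | --- | --- |
| `learning_rate` | 1e-6 | Adam, β₁/β₂ = 0.9/0.999 |
| `batch_size` | 128 | |
| `epochs` | 200 | generator steps = epochs × ⌈n/128⌉ |
| `pretrain_epochs` | 30 | reconstruction-only |
| `d_update_period` | 8 | G steps per D step |
| `hidden_units` | 64 | two hidden layers in both nets |
| `noise_low/high` | ±0.01 | uniform fill noise |
| `alpha` | 10 | reconstruction weight in `L_G` |
| `lambda_gp` | 10 | gradient-penalty weight in `L_D` |
| `swish_beta` | 1.0 | or `"learned"` (per-layer trainable scalar) |
| `noise_dim` | 64 | optional extra input channel, unused by default |

`alpha` and `lambda_gp` have the values customary for reconstruction-
regularized adversarial imputers and critic gradient penalties; the rest
is the method's reference configuration. Weight initialization is
Glorot-uniform from the run's seeded generator; a single integer seed
drives initialization, batching, and noise, so identical
(seed, data, config) yields bit-identical results.

In the learned-β mode the swish slopes receive gradients from the main
losses but the penalty term's (third-order) dependence on β is not
differentiated; the mode is off by default.

### A note on scale

At the default learning rate, a cohort of ~10³ rows yields only ~2 × 10³
Adam steps, so each weight moves by at most ~2 × 10⁻³ over a run: the
adversarial pair trains only marginally at this scale, and the imputer's
advantage over zero filling comes mostly from its sigmoid output matching
the location of the normalized data plus the slight reconstruction fit.
The same configuration performs ~5 × 10⁵ steps on a 3 × 10⁵-row cohort,
where it trains substantially. Raising `learning_rate` (e.g. to 1e-3) is
the natural adjustment for small tables; the package keeps the reference
default and exposes the knob.

## Amputation

`ampute_mcar` removes exactly `round(rate · n · d_eligible)` cells drawn
uniformly without replacement — a global cell-wise draw, not per-column
Bernoulli — independent of all values (MCAR). An optional label column is
excluded, since downstream classification needs intact outcomes. Every
column retains at least `min_observed_per_column = 2` observed cells so
normalization and type inference stay defined; when the uniform draw
violates the floor, cells are restored in deficient columns and
re-removed in columns with slack until the exact count and the floor
coexist (infeasible requests error out). The removed values are returned
as a ground-truth map.

## Baselines

*Zero imputation* writes 0 into missing cells and is applied on the
normalized scale, where 0 is the observed column minimum — the
no-information reference. *KNN* uses the partial Euclidean distance
`sqrt(mean over shared observed columns of squared differences)`; rows
sharing no observed column are infinitely far apart. Each missing cell is
filled from the `k = 5` nearest rows that observe that column — mean for
real columns, mode (smallest value on ties) for categorical ones; ties in
distance break by row index; a cell with no usable donor falls back to
the column mean/mode with a warning. The distance is a constant multiple
of scikit-learn's nan-euclidean distance, which the tests exploit as an
independent cross-check on all-real data. More elaborate competitors
(chained-equation, forest-based, other adversarial imputers) are not
re-implemented; the benchmark accepts externally supplied imputer
callables so installed third-party implementations can join the
comparison without becoming dependencies.

## Metrics

* **RMSE** is computed only over missing cells, on the normalized scale,
  *before* attribute projection — it measures the continuous prediction.
* **PFC** is the fraction of missing binary/nominal cells filled with the
  wrong category, computed *after* projection, where categories exist.
* **ROC/AUC** delegate to scikit-learn; ties get the half-credit
  Mann-Whitney convention. The tests verify AUC against brute-force
  pair counting.
* **Downstream AUC** one-hot encodes nominal columns, standardizes real
  columns, and pools out-of-fold decision scores of an L2-regularized
  logistic regression under stratified 5-fold cross-validation. The
  classifier choice is this package's; absolute values are comparable
  only across imputers evaluated identically, and only the ordering
  should be read.

Benchmark runs report mean ± standard deviation over repeated seeds in a
tidy table carrying (method, rate, seed, metrics, config hash).

## Synthetic cohorts

The generator draws equicorrelated standard-normal latents
(`L = √ρ·common + √(1−ρ)·noise`), keeps them as the real columns,
thresholds at the sample median for binary columns, and cuts equiprobable
quantile bins for nominal columns — a Gaussian-copula-style construction.
The binary outcome follows a logistic link on a random weighted latent
combination with slope `4 × label_signal` and an intercept solved by
bisection to hit the requested prevalence. Defaults: n = 1000 with 6
real, 4 binary and 4 nominal columns (a typical 14-feature clinical
mix), ρ = 0.8, label_signal = 0.75, balanced classes.

The construction gives every pipeline stage a known ground truth:
attribute inference recovers the true codes exactly, ρ = 0 yields no
exploitable inter-column signal while ρ = 0.8 yields a lot. It does *not*
emulate real marginal distributions, nonlinear dependencies, or
informative missingness — passing tests show the machinery is correct
and that signal present in the data is used, not that clinical-grade
accuracy would be reached on any particular cohort.

## Problem sizes

The test suite trains on cohorts of 80–1000 rows; the end-to-end learning
checks use the default 1000 × 14 cohort with 5 seeds per missing rate,
and `scripts/acceptance.py` uses 3 repetitions over rates
{10 %, 30 %, 60 %} — sizes chosen so a full reproduction runs in minutes
on one CPU while keeping the sampling error of the reported means well
below the effect sizes being checked.

## Known limitations

* MCAR only; MAR/MNAR amputation mechanisms are out of scope.
* The discriminator's per-cell output and the no-hint design mean the
  adversarial signal is weak when the missing rate is low in a batch.
* At small n the default learning rate barely trains the networks (see
  *A note on scale*).
* KNN is O(n²d) in time and O(n²) in memory — fine to ~10⁴ rows,
  impractical beyond.
* Attribute inference can misread a column given pathological
  missingness (e.g. a real column whose observed cells happen to be
  integers); inference always uses what is observable.
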