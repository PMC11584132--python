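# aganimpute

Adversarial imputation of missing values in mixed-type clinical tables —
an attribute-aware GAN imputer (AGAN) together with the full benchmarking
protocol around it: MCAR amputation, zero/KNN reference imputers, and
RMSE / PFC / downstream-AUC evaluation.

## The problem

Epidemiological and clinical tabular datasets — think heart-disease
cohorts assembled from registries or telephone surveys — routinely arrive
with a substantial fraction of cells missing. Deleting incomplete records
loses information and biases the sample; naive filling (zeros, column
means) distorts the joint distribution that downstream risk models depend
on. The columns of such tables are heterogeneous: some are real-valued
(BMI, cholesterol), some binary (sex, smoking), some nominal with a
handful of levels (chest-pain type). A useful imputer must both exploit
the correlation between columns and return values that are *valid* for
each column's type — a filled "smoking" cell must be 0 or 1, not 0.63.

## The model

Write the table as `X ∈ R^{n×d}` with mask `M ∈ {0,1}^{n×d}`
(`m_ij = 1` iff cell observed) and per-column attribute codes
`a_j ∈ {0,1,2}` (real / binary / nominal). After min-max normalizing each
column onto [0, 1] using its observed cells, the generator `G` receives
the noise-filled matrix

    Z = M ⊙ X + (1 − M) ⊙ N,   N_ij ~ U[−0.01, 0.01]

concatenated with `M`, and produces a complete candidate `X̄ ∈ [0,1]^{n×d}`
through swish hidden layers (`x·σ(βx)`) and a sigmoid output. The
discriminator `D` scores every cell of the composite
`X̂ = M ⊙ X + (1 − M) ⊙ X̄` with the probability that it is observed
rather than generated — no hint matrix is supplied. Training minimizes

    L_D = BCE(D(X̂), M) + λ · mean_i (‖∇_{x_i} D(x_i)‖₂ − 1)²
    L_G = −mean_{m=0} log D(X̂) + α · mean_{m=1} (X − X̄)²

with Adam, one discriminator step per 8 generator steps, after a
generator-only reconstruction pretraining phase. The completed table is
denormalized and every filled cell in a binary/nominal column is snapped
to the nearest member of that column's observed category set (the
*attribute projection*), so the output is type-valid by construction and
observed cells are preserved exactly.

Evaluation follows the standard amputation protocol: delete cells from a
complete table completely at random (MCAR) at a chosen rate, impute, then
score RMSE over the deleted cells on the normalized scale, PFC (the
fraction of deleted categorical cells filled with the wrong category),
and the AUC of a logistic classifier trained on the completed table.

## Worked example

```python
import numpy as np
from aganimpute import (
    SyntheticSpec, generate, AmputationSpec, ampute_mcar,
    TrainingConfig, impute, normalize, rmse_missing, pfc, zero_impute,
    downstream_auc,
)

# a complete synthetic cohort: 1000 samples, 6 real + 4 binary + 4 nominal
# columns with strong latent correlation, and a binary outcome
table, labels, attrs = generate(SyntheticSpec(seed=7))
holed, mask, truth = ampute_mcar(table, AmputationSpec(rate=0.3, seed=7))
print(f"amputated {mask.n_missing} of {table.n * table.d} cells")

result = impute(holed, TrainingConfig(seed=7))

x_norm, params = normalize(holed, mask)
span = np.where(params.span == 0, 1.0, params.span)
truth_norm = (table.values - params.col_min) / span

print(f"RMSE (AGAN): {rmse_missing(truth_norm, result.x_composite_norm, mask):.4f}")
print(f"RMSE (zero): {rmse_missing(truth_norm, zero_impute(x_norm).values, mask):.4f}")
print(f"PFC  (AGAN): {pfc(table.values, result.x_hat.values, mask, result.attributes):.4f}")
print(f"AUC  downstream: {downstream_auc(result.x_hat, labels, seed=7):.4f}")
```

prints

```
amputated 4200 of 14000 cells
RMSE (AGAN): 0.3510
RMSE (zero): 0.6204
PFC  (AGAN): 0.6172
AUC  downstream: 0.8358
```

At a 30 % missing rate the adversarial imputer roughly halves the
normalized RMSE of the zero-filling reference (0.35 vs 0.62), and a
classifier trained on the completed table still recovers most of the
outcome signal (AUC 0.84). `result.x_hat` is the completed table on the
original scale; its observed cells equal the input bit for bit, and every
filled binary/nominal cell lies in that column's category set.

There is also a CLI with three subcommands:

```bash
aganimpute synth --n 1000 --seed 1 --out cohort.csv       # make a complete table
aganimpute impute incomplete.csv completed.csv --seed 1   # fill missing cells
aganimpute benchmark --methods agan,zero,knn --rates 0.1,0.3 \
    --repeats 5 --seed 1 --out-dir results                # run the protocol
```

`benchmark` writes a tidy CSV (one row per method × rate × seed with
rmse/pfc/auc and a config hash) plus a mean ± std summary. Training
hyperparameters can be supplied as a YAML file mirroring
`TrainingConfig` field for field via `--config`.

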