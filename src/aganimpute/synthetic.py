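"""Synthetic mixed-type tables with a binary outcome.

The generator emulates the *structure* of tabular heart-disease cohorts —
a mix of real-valued, binary and nominal columns with inter-column
correlation and a binary disease label — via a Gaussian-copula-style
construction:

1. draw equicorrelated standard-normal latents
   ``L = sqrt(rho) * common + sqrt(1 - rho) * independent``,
2. real columns keep their latent as-is; binary columns threshold at the
   sample median; nominal columns are cut into equiprobable quantile bins
   coded ``0 .. n_categories-1``,
3. the label follows a logistic link on a random weighted sum of the
   latents, with slope scaled by ``label_signal`` and intercept solved (by
   bisection) so the expected positive rate equals ``class_balance``.

The default column mix (6 real, 4 binary, 4 nominal, n = 1000) mirrors a
typical 14-feature clinical table.  The construction exercises every code
path of the package; it does not attempt to mimic real cardiac physiology
or marginal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .table import AttributeVector, BINARY, MixedTypeTable, NOMINAL, REAL

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    n: int = 1000
    d_real: int = 6
    d_binary: int = 4
    d_nominal: int = 4
    n_categories: int = 4
    latent_correlation: float = 0.8
    label_signal: float = 0.75
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.d_real + self.d_binary + self.d_nominal < 1:
            raise ValueError("need at least one column")
        if min(self.d_real, self.d_binary, self.d_nominal) < 0:
            raise ValueError("column counts must be nonnegative")
        if not 0 <= self.latent_correlation < 1:
            raise ValueError("latent_correlation must be in [0, 1)")
        if not 0 <= self.label_signal <= 1:
            raise ValueError("label_signal must be in [0, 1]")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.d_nominal > 0 and self.n_categories < 2:
            raise ValueError("nominal columns need >= 2 categories")

    @property
    def d(self) -> int:
        return self.d_real + self.d_binary + self.d_nominal


def _balance_intercept(raw: np.ndarray, slope: float, target: float) -> float:
    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expit(slope * raw + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(
    spec: SyntheticSpec,
) -> tuple[MixedTypeTable, np.ndarray, AttributeVector]:
    """Draw a complete table, its labels and the true attribute codes.

    Fully reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.latent_correlation
    common = rng.standard_normal((spec.n, 1))
    latent = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(
        (spec.n, spec.d)
    )

    values = np.empty_like(latent)
    codes = np.empty(spec.d, dtype=int)
    cats: dict[int, np.ndarray] = {}
    j = 0
    for _ in range(spec.d_real):
        values[:, j] = latent[:, j]
        codes[j] = REAL
        j += 1
    for _ in range(spec.d_binary):
        values[:, j] = (latent[:, j] > np.median(latent[:, j])).astype(float)
        codes[j] = BINARY
        cats[j] = np.array([0.0, 1.0])
        j += 1
    for _ in range(spec.d_nominal):
        qs = np.quantile(latent[:, j], np.linspace(0, 1, spec.n_categories + 1)[1:-1])
        values[:, j] = np.digitize(latent[:, j], qs).astype(float)
        codes[j] = NOMINAL
        cats[j] = np.arange(spec.n_categories, dtype=float)
        j += 1

    w = rng.standard_normal(spec.d)
    raw = latent @ (w / np.linalg.norm(w))
    slope = 4.0 * spec.label_signal
    intercept = _balance_intercept(raw, slope, spec.class_balance)
    p = expit(slope * raw + intercept)
    labels = (rng.uniform(size=spec.n) < p).astype(int)

    names = (
        [f"real_{k}" for k in range(spec.d_real)]
        + [f"bin_{k}" for k in range(spec.d_binary)]
        + [f"nom_{k}" for k in range(spec.d_nominal)]
    )
    table = MixedTypeTable(values, names)
    return table, labels, AttributeVector(codes, cats)
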