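"""MCAR amputation: delete cells of a complete table completely at random.

Benchmarking an imputer needs inputs with known ground truth, so cells are
removed from a complete table under the missing-completely-at-random
mechanism: ``round(rate * n * d_eligible)`` cells are drawn uniformly
without replacement, independent of any cell value.  An optional label
column can be protected (it is never amputated), and every column is
guaranteed to retain at least ``min_observed_per_column`` observed cells so
that normalization and attribute inference stay well-defined downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import MaskMatrix, MixedTypeTable

__all__ = ["AmputationSpec", "AmputationError", "ampute_mcar"]


class AmputationError(ValueError):
    """The requested missingness pattern is infeasible."""


@dataclass
class AmputationSpec:
    rate: float
    seed: int = 0
    protect_label: str | None = None
    min_observed_per_column: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise AmputationError(f"rate must be in [0, 1), got {self.rate}")
        if self.min_observed_per_column < 0:
            raise AmputationError("min_observed_per_column must be >= 0")


def ampute_mcar(
    t: MixedTypeTable, spec: AmputationSpec
) -> tuple[MixedTypeTable, MaskMatrix, dict[tuple[int, int], float]]:
    """Remove cells uniformly at random from a complete table.

    Returns the amputated table, its mask, and a ground-truth map from the
    removed cell coordinates to their original values.  Deterministic given
    ``spec.seed``.
    """
    if t.n_missing:
        raise AmputationError("input table must be complete (no missing cells)")
    rng = np.random.default_rng(spec.seed)
    eligible = [
        j for j, name in enumerate(t.column_names) if name != spec.protect_label
    ]
    if spec.protect_label is not None and len(eligible) == t.d:
        raise AmputationError(f"protected column {spec.protect_label!r} not found")
    n, d_elig = t.n, len(eligible)
    k = int(round(spec.rate * n * d_elig))
    capacity = max(n - spec.min_observed_per_column, 0) * d_elig
    if k > capacity:
        raise AmputationError(
            f"cannot remove {k} cells while keeping "
            f"{spec.min_observed_per_column} observed per column"
        )
    flat = rng.choice(n * d_elig, size=k, replace=False)
    missing = np.zeros((n, d_elig), dtype=bool)
    missing[flat // d_elig, flat % d_elig] = True

    # repair columns that fell below the observedness floor, keeping the
    # total count exact by re-amputating cells in columns with slack
    for _ in range(1000):
        observed = n - missing.sum(axis=0)
        deficit = np.maximum(spec.min_observed_per_column - observed, 0)
        if not deficit.any():
            break
        for col in np.flatnonzero(deficit):
            rows = rng.choice(
                np.flatnonzero(missing[:, col]), size=deficit[col], replace=False
            )
            missing[rows, col] = False
        shortfall = k - int(missing.sum())
        slack_cells = np.flatnonzero(
            ~missing
            & (n - missing.sum(axis=0) > spec.min_observed_per_column)[None, :]
        )
        extra = rng.choice(slack_cells, size=shortfall, replace=False)
        missing[np.unravel_index(extra, missing.shape)] = True
    else:  # pragma: no cover - capacity check above prevents this
        raise AmputationError("could not satisfy min_observed_per_column")

    values = t.values.copy()
    ground_truth: dict[tuple[int, int], float] = {}
    for jj, j in enumerate(eligible):
        rows = np.flatnonzero(missing[:, jj])
        for i in rows:
            ground_truth[(int(i), int(j))] = float(values[i, j])
        values[rows, j] = np.nan
    out = MixedTypeTable(values, list(t.column_names))
    mask = MaskMatrix((~np.isnan(values)).astype(np.int8))
    return out, mask, ground_truth
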