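"""Benchmark orchestration: ampute -> impute -> score, repeated over seeds.

For each (missing rate, seed) pair the harness removes cells from a
complete table under MCAR, runs every requested imputer, and scores the
results with RMSE over missing cells (normalized scale, before attribute
projection), PFC (after projection) and the downstream classification AUC.
The output is a tidy table with one row per method x rate x seed plus a
config hash for provenance, and a mean +/- std summary over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amputate import AmputationSpec, ampute_mcar
from .baselines import BaselineSpec, knn_impute, zero_impute
from .gan import AGANImputer, TrainingConfig, attribute_projection
from .metrics import MetricError, aggregate_reports, downstream_auc, pfc, rmse_missing
from .table import MixedTypeTable, build_mask, denormalize, infer_attributes, normalize

__all__ = ["BenchmarkPlan", "BenchmarkError", "run_benchmark", "plot_rmse_vs_rate"]

DEFAULT_RATES = (0.1, 0.2, 0.3, 0.4, 0.6)


class BenchmarkError(ValueError):
    pass


@dataclass
class BenchmarkPlan:
    methods: tuple[str, ...] = ("agan", "zero", "knn")
    missing_rates: tuple[float, ...] = DEFAULT_RATES
    repeats: int = 20
    seed: int = 0
    seeds: tuple[int, ...] | None = None
    k_neighbors: int = 5
    folds: int = 5
    agan_config: TrainingConfig = field(default_factory=TrainingConfig)
    compute_auc: bool = True
    compute_pfc: bool = True

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise BenchmarkError("repeats must be >= 1")
        if any(not 0 < r < 1 for r in self.missing_rates):
            raise BenchmarkError("missing rates must lie in (0, 1)")
        for mth in self.methods:
            if mth not in ("agan", "zero", "knn") and not mth.startswith("external:"):
                raise BenchmarkError(f"unknown method {mth!r}")

    def seed_list(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [self.seed + 1000 * r for r in range(self.repeats)]


def _impute_normalized(method, table_miss, mask, attrs, params, plan, seed):
    """Return the imputed matrix on the normalized scale, pre-projection."""
    span = np.where(params.span == 0, 1.0, params.span)
    x_norm = MixedTypeTable(
        (table_miss.values - params.col_min) / span, list(table_miss.column_names)
    )
    if method == "zero":
        return zero_impute(x_norm, mask).values
    if method == "knn":
        spec = BaselineSpec("knn", k_neighbors=plan.k_neighbors, seed=seed)
        return knn_impute(x_norm, mask, spec, attributes=attrs).values
    if method == "agan":
        cfg = TrainingConfig(**{**plan.agan_config.to_dict(), "seed": seed})
        imp = AGANImputer(**cfg.to_dict())
        imp.fit(table_miss)
        return imp.imputation_result(table_miss).x_composite_norm
    if method.startswith("external:"):
        raise BenchmarkError(
            f"{method!r}: external imputers must be registered by the caller"
        )
    raise BenchmarkError(f"unknown method {method!r}")


def run_benchmark(
    table: MixedTypeTable,
    labels: np.ndarray | None,
    plan: BenchmarkPlan,
    external_imputers: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full protocol on a complete table.

    ``external_imputers`` optionally maps ``"external:<name>"`` to a
    callable ``f(x_norm_matrix_with_nan) -> completed matrix`` so
    third-party methods can join the comparison without being a package
    dependency.

    Returns ``(tidy_rows, summary)``.
    """
    if table.n_missing:
        raise BenchmarkError(
            "benchmark mode needs a complete table with ground truth; "
            "use impute mode for tables that are already incomplete"
        )
    if labels is not None:
        labels = np.asarray(labels).astype(int)
        if len(labels) != table.n:
            raise BenchmarkError("labels length must match the table")
    external_imputers = external_imputers or {}
    attrs_true = infer_attributes(table)
    rows = []
    for rate in plan.missing_rates:
        for seed in plan.seed_list():
            amp_table, mask, _ = ampute_mcar(
                table, AmputationSpec(rate=rate, seed=seed)
            )
            attrs = infer_attributes(amp_table)
            _, params = normalize(amp_table, mask)
            span = np.where(params.span == 0, 1.0, params.span)
            x_true_norm = (table.values - params.col_min) / span
            for method in plan.methods:
                if method.startswith("external:"):
                    fn = external_imputers.get(method)
                    if fn is None:
                        raise BenchmarkError(f"no imputer registered for {method!r}")
                    span_ = span
                    x_norm_miss = (amp_table.values - params.col_min) / span_
                    x_imp_norm = np.asarray(fn(x_norm_miss), dtype=float)
                else:
                    x_imp_norm = _impute_normalized(
                        method, amp_table, mask, attrs, params, plan, seed
                    )
                rmse = rmse_missing(x_true_norm, x_imp_norm, mask)
                row = {
                    "method": method,
                    "rate": rate,
                    "seed": seed,
                    "rmse": rmse,
                    "config_hash": plan.agan_config.hash(),
                }
                x_imp = denormalize(
                    MixedTypeTable(x_imp_norm, list(table.column_names)), params
                )
                x_proj = attribute_projection(x_imp.values, attrs)
                if plan.compute_pfc:
                    try:
                        row["pfc"] = pfc(table.values, x_proj, mask, attrs)
                    except MetricError:
                        row["pfc"] = np.nan
                if plan.compute_auc and labels is not None:
                    completed = MixedTypeTable(x_proj, list(table.column_names))
                    row["auc"] = downstream_auc(
                        completed, labels, folds=plan.folds, seed=seed,
                        attributes=attrs,
                    )
                rows.append(row)
    tidy = pd.DataFrame(rows)
    summary = aggregate_reports(tidy)
    return tidy, summary


def plot_rmse_vs_rate(summary: pd.DataFrame, path) -> None:
    """Line chart of mean RMSE against missing rate, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in summary.groupby("method"):
        grp = grp.sort_values("rate")
        ax.errorbar(
            grp["rate"], grp["rmse_mean"], yerr=grp["rmse_std"].fillna(0),
            marker="o", capsize=3, label=method,
        )
    ax.set_xlabel("missing rate")
    ax.set_ylabel("RMSE over missing cells (normalized)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
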