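"""Data model for incomplete mixed-type tables.

A table is an ``n x d`` float matrix with ``NaN`` as the internal missing
marker, plus column names.  Three per-column attribute codes describe the
cell type::

    0  real-valued   (any observed value has a fractional part)
    1  binary        (integer-coded, exactly two observed levels)
    2  nominal       (integer-coded, any other number of levels)

The companion mask matrix ``M`` has ``m_ij = 1`` where the cell is observed
and ``0`` where it is missing, and min-max normalization maps every observed
cell of a column onto ``[0, 1]`` using statistics computed from the observed
cells only.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixedTypeTable",
    "MaskMatrix",
    "AttributeVector",
    "NormalizationParams",
    "TableParseError",
    "UndecidableAttributeError",
    "ShapeMismatchError",
    "REAL",
    "BINARY",
    "NOMINAL",
    "DEFAULT_MISSING_TOKENS",
    "read_table",
    "write_table",
    "build_mask",
    "infer_attributes",
    "normalize",
    "denormalize",
]

REAL, BINARY, NOMINAL = 0, 1, 2

#: tokens recognised as missing on CSV input (the empty field always counts)
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN"})


class TableParseError(ValueError):
    """A CSV cell could not be interpreted; carries the offending location."""

    def __init__(self, row: int, column: str, cell: str):
        self.row, self.column, self.cell = row, column, cell
        super().__init__(
            f"cell {cell!r} at row {row}, column {column!r} is neither numeric, "
            "a missing token, nor present in label_map"
        )


class UndecidableAttributeError(ValueError):
    """A column with no observed cell has no decidable attribute code."""


class ShapeMismatchError(ValueError):
    """Array dimensions do not agree with the table they are paired with."""


@dataclass
class MixedTypeTable:
    """An ``n x d`` matrix of floats with ``NaN`` marking missing cells."""

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeMismatchError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ShapeMismatchError("table needs at least one row and one column")
        self.column_names = [str(c) for c in self.column_names]
        if len(self.column_names) != d:
            raise ShapeMismatchError(
                f"{len(self.column_names)} column names for {d} columns"
            )
        observed = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-missing cells must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "MixedTypeTable":
        return MixedTypeTable(self.values.copy(), list(self.column_names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MixedTypeTable":
        return cls(df.to_numpy(dtype=float), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


@dataclass
class MaskMatrix:
    """Binary observedness indicator: ``m_ij = 0`` iff cell (i, j) missing."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        if not np.isin(self.m, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.m = self.m.astype(np.int8)

    @property
    def n_missing(self) -> int:
        return int((self.m == 0).sum())


@dataclass
class AttributeVector:
    """Per-column type codes plus the observed category set of each
    non-real column (ordered ascending)."""

    codes: np.ndarray
    category_sets: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if not np.isin(self.codes, (REAL, BINARY, NOMINAL)).all():
            raise ValueError("attribute codes must be in {0, 1, 2}")
        for j, code in enumerate(self.codes):
            if code in (BINARY, NOMINAL):
                cats = np.sort(np.asarray(self.category_sets.get(j, ()), dtype=float))
                if cats.size == 0:
                    raise ValueError(f"non-real column {j} needs a category set")
                if code == BINARY and cats.size != 2:
                    raise ValueError(f"binary column {j} must have 2 categories")
                self.category_sets[j] = cats

    @property
    def d(self) -> int:
        return self.codes.size

    def categorical_columns(self) -> np.ndarray:
        return np.flatnonzero(self.codes != REAL)


@dataclass
class NormalizationParams:
    """Per-column observed min / max, as used by min-max scaling."""

    col_min: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        self.col_min = np.asarray(self.col_min, dtype=float)
        self.col_max = np.asarray(self.col_max, dtype=float)
        if self.col_min.shape != self.col_max.shape:
            raise ShapeMismatchError("col_min / col_max shapes differ")
        if np.any(self.col_min > self.col_max):
            raise ValueError("col_min must not exceed col_max")

    @property
    def span(self) -> np.ndarray:
        return self.col_max - self.col_min


def read_table(
    path,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    label_map: dict[str, float] | None = None,
) -> MixedTypeTable:
    """Read a header-ed CSV into a :class:`MixedTypeTable`.

    Cells matching ``missing_tokens`` (after whitespace stripping) become
    missing; cells found in ``label_map`` are replaced by the mapped number
    (e.g. ``{"Yes": 1, "No": 0}`` for an outcome column); everything else
    must parse as a number.

    Raises
    ------
    TableParseError
        Naming the first offending row/column if a cell is unparseable.
    """
    missing_tokens = {str(t).strip() for t in missing_tokens}
    label_map = {str(k).strip(): float(v) for k, v in (label_map or {}).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = np.empty(df.shape, dtype=float)
    for jcol, col in enumerate(df.columns):
        s = df[col].str.strip()
        is_missing = s.isin(missing_tokens)
        mapped = s.map(label_map)
        numeric = pd.to_numeric(s.where(mapped.isna(), other=np.nan), errors="coerce")
        bad = ~is_missing & mapped.isna() & numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(i, col, s.iloc[i])
        # final conversion through numpy's correctly-rounded strtod so that
        # write -> read round trips are exact to the last ulp
        plain = ~is_missing & mapped.isna()
        column = np.full(len(s), np.nan)
        column[plain.to_numpy()] = s[plain].to_numpy(dtype=float)
        has_map = mapped.notna().to_numpy()
        column[has_map] = mapped.to_numpy(dtype=float)[has_map]
        out[:, jcol] = column
    return MixedTypeTable(out, list(df.columns))


def write_table(t: MixedTypeTable, path) -> None:
    """Write a table as CSV: missing cells as empty fields, integer-typed
    columns without a fractional part (``1`` not ``1.0``)."""
    cols = {}
    for j, name in enumerate(t.column_names):
        col = t.values[:, j]
        obs = col[~np.isnan(col)]
        integral = obs.size > 0 and np.all(obs == np.round(obs))
        rendered = []
        for v in col:
            if np.isnan(v):
                rendered.append("")
            elif integral:
                rendered.append(str(int(round(v))))
            else:
                rendered.append(repr(float(v)))
        cols[name] = rendered
    pd.DataFrame(cols, columns=t.column_names).to_csv(path, index=False)


def build_mask(t: MixedTypeTable) -> MaskMatrix:
    """Mask matrix of a table: 1 where observed, 0 where missing."""
    return MaskMatrix((~np.isnan(t.values)).astype(np.int8))


def infer_attributes(t: MixedTypeTable) -> AttributeVector:
    """Infer per-column attribute codes from the observed cells.

    A column is *real* if any observed value has a nonzero fractional part,
    *binary* if integer-valued with exactly two distinct levels, and
    *nominal* otherwise.  All-missing columns are undecidable.
    """
    codes = np.empty(t.d, dtype=int)
    cats: dict[int, np.ndarray] = {}
    for j in range(t.d):
        col = t.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise UndecidableAttributeError(
                f"column {t.column_names[j]!r} has no observed cell"
            )
        if np.any(obs != np.round(obs)):
            codes[j] = REAL
            continue
        uniq = np.unique(obs)
        codes[j] = BINARY if uniq.size == 2 else NOMINAL
        cats[j] = uniq
    return AttributeVector(codes, cats)


def normalize(
    t: MixedTypeTable, m: MaskMatrix | None = None
) -> tuple[MixedTypeTable, NormalizationParams]:
    """Min-max scale every observed cell onto [0, 1].

    Statistics come from observed cells only; missing cells stay missing.
    A constant column maps to all zeros (and denormalizes back to its
    constant), avoiding the 0/0 division.
    """
    if m is not None and m.m.shape != t.values.shape:
        raise ShapeMismatchError("mask shape does not match table")
    vals = t.values
    if np.all(np.isnan(vals), axis=0).any():
        raise UndecidableAttributeError("every column needs >= 1 observed cell")
    col_min = np.nanmin(vals, axis=0)
    col_max = np.nanmax(vals, axis=0)
    span = col_max - col_min
    safe = np.where(span == 0, 1.0, span)
    scaled = (vals - col_min) / safe
    return (
        MixedTypeTable(scaled, list(t.column_names)),
        NormalizationParams(col_min, col_max),
    )


def denormalize(t_norm: MixedTypeTable, p: NormalizationParams) -> MixedTypeTable:
    """Invert :func:`normalize`; constant columns recover ``col_min``."""
    if p.col_min.size != t_norm.d:
        raise ShapeMismatchError(
            f"params cover {p.col_min.size} columns, table has {t_norm.d}"
        )
    vals = t_norm.values * p.span + p.col_min
    return MixedTypeTable(vals, list(t_norm.column_names))
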