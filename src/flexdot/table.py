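"""The universal long-format dot-plot table.

A dot plot spreads two categorical factors along the x and y axes and displays
1-4 additional *display factors* (quantitative or qualitative) for each (x, y)
combination through the dot's size, color, text and shape. The input is a
delimited table whose first two columns hold the axis factors and whose
remaining columns hold the display factors — the format produced by, e.g.,
per-cluster marker summaries of scRNA-seq data, CNV calls per gene and patient,
or ligand-receptor interaction scores.

This module defines the validated in-memory form (:class:`DotTable`), the
reader/writer for the delimited format, factor-type inference, grid completion
and wide pivoting (the reshape that feeds the factor-analysis ordering step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    DuplicationError,
    FactorLookupError,
    FormatError,
    ValidationError,
)

#: Tokens treated as missing on read (case-insensitive). "NA" is written back.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Hard cap on display factors: one per channel (size, color, text, shape).
MAX_FACTORS = 4


class FactorKind(str, Enum):
    """Type of a display factor.

    Quantitative factors parse as finite real numbers (missing allowed) and may
    drive any channel; qualitative factors are unordered category labels and
    may drive color, text or shape but never size.
    """

    QUANTITATIVE = "quantitative"
    QUALITATIVE = "qualitative"


def is_missing_token(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def infer_factor_kind(values: Sequence[str]) -> FactorKind:
    """Infer a factor's kind from its raw string values.

    A column is quantitative iff every non-missing value parses as a finite
    real number; otherwise it is qualitative. All-missing columns are
    undecidable and must be declared explicitly.
    """
    if len(values) == 0:
        raise ValidationError("cannot infer factor kind from an empty column")
    seen_any = False
    numeric = True
    for v in values:
        if is_missing_token(str(v)):
            continue
        seen_any = True
        try:
            x = float(v)
        except (TypeError, ValueError):
            numeric = False
            break
        if not math.isfinite(x):
            numeric = False
            break
    if not seen_any:
        raise ValidationError(
            "factor kind undecidable: every value is missing; declare the kind"
        )
    return FactorKind.QUANTITATIVE if numeric else FactorKind.QUALITATIVE


def _unique_in_order(values: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class DotTable:
    """Validated long-format dot-plot table.

    ``data`` holds one row per supplied (x, y) combination with columns
    ``[x_name, y_name, *factor_names]``. Quantitative factors are float64 with
    NaN for missing; qualitative factors are object dtype with NaN for missing.
    """

    x_name: str
    y_name: str
    data: pd.DataFrame
    factor_kinds: dict[str, FactorKind]
    x_levels: list[str] = field(default_factory=list)
    y_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.x_levels:
            self.x_levels = _unique_in_order(self.data[self.x_name].tolist())
        if not self.y_levels:
            self.y_levels = _unique_in_order(self.data[self.y_name].tolist())
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        cols = list(self.data.columns)
        if cols[:2] != [self.x_name, self.y_name]:
            raise ValidationError(
                f"first two columns must be ({self.x_name!r}, {self.y_name!r}); "
                f"got {cols[:2]!r}"
            )
        factors = cols[2:]
        if len(factors) < 1:
            raise FormatError("a dot table needs at least one display factor")
        if len(factors) > MAX_FACTORS:
            raise CapacityError(
                f"{len(factors)} display factors exceed the {MAX_FACTORS} "
                f"available channels (size, color, text, shape)"
            )
        if set(factors) != set(self.factor_kinds):
            raise ValidationError(
                f"factor_kinds keys {sorted(self.factor_kinds)} do not match "
                f"factor columns {factors}"
            )
        dup = self.data.duplicated(subset=[self.x_name, self.y_name], keep=False)
        if dup.any():
            first = self.data.loc[dup, [self.x_name, self.y_name]].iloc[0]
            raise DuplicationError(
                f"combination ({first[self.x_name]!r}, {first[self.y_name]!r}) "
                f"occurs more than once"
            )
        bad_x = set(self.data[self.x_name]) - set(self.x_levels)
        bad_y = set(self.data[self.y_name]) - set(self.y_levels)
        if bad_x or bad_y:
            raise ValidationError(
                f"rows reference levels outside the declared level lists: "
                f"x={sorted(bad_x)} y={sorted(bad_y)}"
            )

    # -- convenience ------------------------------------------------------

    @property
    def factor_names(self) -> list[str]:
        return list(self.data.columns[2:])

    def kind_of(self, factor: str) -> FactorKind:
        try:
            return self.factor_kinds[factor]
        except KeyError:
            raise FactorLookupError(
                f"unknown factor {factor!r}; available: {self.factor_names}"
            ) from None

    def is_complete(self) -> bool:
        return len(self.data) == len(self.x_levels) * len(self.y_levels)

    def copy(self) -> "DotTable":
        return DotTable(
            x_name=self.x_name,
            y_name=self.y_name,
            data=self.data.copy(),
            factor_kinds=dict(self.factor_kinds),
            x_levels=list(self.x_levels),
            y_levels=list(self.y_levels),
        )


# -- reading / writing ----------------------------------------------------


def _coerce_factor(raw: pd.Series, kind: FactorKind) -> pd.Series:
    mask = raw.astype(str).map(is_missing_token)
    if kind is FactorKind.QUANTITATIVE:
        out = pd.to_numeric(raw.where(~mask), errors="raise").astype(float)
        bad = out[~out.isna() & ~np.isfinite(out)]
        if len(bad):
            raise FormatError(
                f"non-finite value {bad.iloc[0]!r} in quantitative column {raw.name!r}"
            )
        return out
    return raw.astype(object).where(~mask, other=np.nan)


def parse_table(
    path: str | Path,
    declared_kinds: Mapping[str, FactorKind] | None = None,
    sep: str | None = None,
) -> DotTable:
    """Read a delimited dot-plot table.

    Column 1 is the x-axis factor, column 2 the y-axis factor, columns 3..6 the
    display factors. The delimiter is sniffed (CSV/TSV) unless ``sep`` is
    given. Factor kinds are taken from ``declared_kinds`` when present, else
    inferred (:func:`infer_factor_kind`). Level order is first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            engine="python" if sep is None else "c",
            dtype=str,
            keep_default_na=False,
            encoding="utf-8",
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: a dot table needs at least 3 columns "
            f"(x factor, y factor, one display factor); found {df.shape[1]}"
        )
    if df.shape[1] > 2 + MAX_FACTORS:
        raise CapacityError(
            f"{path}: {df.shape[1] - 2} display factors exceed the "
            f"{MAX_FACTORS} available channels"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    x_name, y_name = df.columns[0], df.columns[1]
    declared = dict(declared_kinds or {})
    kinds: dict[str, FactorKind] = {}
    data = df.copy()
    data[x_name] = data[x_name].astype(str)
    data[y_name] = data[y_name].astype(str)
    for col in df.columns[2:]:
        kind = FactorKind(declared[col]) if col in declared else infer_factor_kind(
            df[col].tolist()
        )
        kinds[col] = kind
        data[col] = _coerce_factor(df[col], kind)
    return DotTable(x_name=x_name, y_name=y_name, data=data, factor_kinds=kinds)


def write_table(table: DotTable, path: str | Path, sep: str = ",") -> None:
    """Write a :class:`DotTable` back to a delimited file (missing → "NA")."""
    table.data.to_csv(path, sep=sep, index=False, na_rep="NA", encoding="utf-8")


# -- grid operations ------------------------------------------------------


def complete_grid(table: DotTable) -> DotTable:
    """Return a table whose rows cover the full x-level × y-level grid.

    Combinations absent from the input are added with missing values for every
    display factor; supplied rows are unchanged. Idempotent.
    """
    if table.is_complete():
        out = table.copy()
    else:
        idx = pd.MultiIndex.from_product(
            [table.x_levels, table.y_levels], names=[table.x_name, table.y_name]
        )
        wide = table.data.set_index([table.x_name, table.y_name]).reindex(idx)
        out = DotTable(
            x_name=table.x_name,
            y_name=table.y_name,
            data=wide.reset_index(),
            factor_kinds=dict(table.factor_kinds),
            x_levels=list(table.x_levels),
            y_levels=list(table.y_levels),
        )
    # canonical row order: y-major within x (stable for writing/round-trips)
    out.data = (
        out.data.set_index([out.x_name, out.y_name])
        .reindex(
            pd.MultiIndex.from_product(
                [out.x_levels, out.y_levels], names=[out.x_name, out.y_name]
            )
        )
        .reset_index()
    )
    return out


def pivot_wide(table: DotTable, factor: str, axis: str = "x") -> pd.DataFrame:
    """Pivot one factor into a levels × levels matrix.

    Rows are the chosen axis's levels, columns the other axis's levels; cell
    [i, j] is the factor's value at that combination. Requires a completed
    grid (see :func:`complete_grid`). ``pivot_wide(..., axis="x")`` is the
    elementwise transpose of ``pivot_wide(..., axis="y")``.
    """
    if axis not in ("x", "y"):
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    if factor not in table.factor_names:
        raise FactorLookupError(
            f"unknown factor {factor!r}; available: {table.factor_names}"
        )
    if not table.is_complete():
        raise ValidationError("pivot_wide requires a completed grid; run complete_grid")
    index, columns = (
        (table.x_name, table.y_name) if axis == "x" else (table.y_name, table.x_name)
    )
    row_levels = table.x_levels if axis == "x" else table.y_levels
    col_levels = table.y_levels if axis == "x" else table.x_levels
    wide = table.data.pivot(index=index, columns=columns, values=factor)
    return wide.reindex(index=row_levels, columns=col_levels)
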