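"""Mapping factor values onto the four dot channels.

Each display factor can drive one channel:

* ``size`` — dot area (points²), linear in the value; quantitative only.
* ``color`` — continuous gradient for quantitative factors (blue–white–red,
  symmetric around 0 when negatives are present, as for z-scores; else
  white→blue), discrete palette cycled in level order for qualitative ones.
* ``text`` — a label centered on the dot: numbers formatted (default:
  round-half-away-from-zero to integer, the usual style for percentage
  labels), category labels verbatim.
* ``shape`` — qualitative: one symbol per level from an ordered symbol list;
  quantitative: either a *fraction pie* (a filled circular sector spanning
  2π·fraction over a light full-circle outline — a natural glyph for
  percentages) or a binned ordered symbol series.

Size maps value to area, not radius, so perceived dot magnitude tracks the
value honestly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.colors import to_hex, to_rgb

from .errors import CapacityError, FactorLookupError, ValidationError
from .table import DotTable, FactorKind

CHANNELS = ("size", "color", "text", "shape")

#: Ordered default symbols for qualitative shape / symbol-series binning.
DEFAULT_SYMBOLS = ("circle", "square", "triangle", "diamond", "star")

#: Diverging / sequential gradient anchors (colorbrewer-style).
DIVERGING_ANCHORS = ("#2166ac", "#f7f7f7", "#b2182b")
SEQUENTIAL_ANCHORS = ("#ffffff", "#2166ac")

#: Discrete palette for qualitative color (tab10).
DEFAULT_DISCRETE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

MISSING_COLOR = "#bdbdbd"


@dataclass
class ChannelSpec:
    """Assignment of display factors to channels plus style options.

    ``assignments`` maps channel name → factor name and must be injective in
    the factor (one factor drives at most one channel). ``size_range`` is
    (min_area, max_area) in points²; ``size_domain`` / ``color_domain`` /
    ``shape_domain`` optionally pin the value bounds (else observed min/max).
    """

    assignments: dict[str, str] = field(default_factory=dict)
    size_range: tuple[float, float] = (10.0, 220.0)
    size_domain: tuple[float, float] | None = None
    color_domain: tuple[float, float] | None = None
    shape_domain: tuple[float, float] | None = None
    palette: tuple[str, ...] | None = None
    discrete_palette: tuple[str, ...] = DEFAULT_DISCRETE
    shape_symbols: tuple[str, ...] = DEFAULT_SYMBOLS
    shape_style: str = "fraction_pie"  # or "symbol_series"
    text_format: str | None = None  # printf-style; None = integer rounding
    missing_color: str = MISSING_COLOR
    hide_legends: tuple[str, ...] = ()

    def validate(self, factor_kinds: dict[str, FactorKind]) -> None:
        if not self.assignments:
            raise ValidationError("at least one channel must be assigned a factor")
        for channel, factor in self.assignments.items():
            if channel not in CHANNELS:
                raise ValidationError(
                    f"unknown channel {channel!r}; channels are {CHANNELS}"
                )
            if factor not in factor_kinds:
                raise FactorLookupError(
                    f"channel {channel!r} bound to unknown factor {factor!r}; "
                    f"available: {sorted(factor_kinds)}"
                )
        bound = list(self.assignments.values())
        if len(bound) != len(set(bound)):
            dup = sorted({f for f in bound if bound.count(f) > 1})
            raise ValidationError(
                f"factor(s) {dup} bound to more than one channel"
            )
        size_factor = self.assignments.get("size")
        if size_factor is not None and (
            FactorKind(factor_kinds[size_factor]) is not FactorKind.QUANTITATIVE
        ):
            raise ValidationError(
                f"size channel requires a quantitative factor; "
                f"{size_factor!r} is qualitative"
            )
        lo, hi = self.size_range
        if lo < 0 or hi <= lo:
            raise ValidationError(
                f"size_range must satisfy 0 <= min < max, got {self.size_range}"
            )
        if self.shape_style not in ("fraction_pie", "symbol_series"):
            raise ValidationError(
                f"shape_style must be 'fraction_pie' or 'symbol_series', "
                f"got {self.shape_style!r}"
            )


@dataclass
class GlyphStyle:
    """Resolved visual attributes of one dot."""

    area: float  # points², >= 0
    fill_color: str  # hex RGB
    symbol: str | float | None = None  # symbol name, pie fraction, or None
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.area >= 0):
            raise ValidationError(f"glyph area must be >= 0, got {self.area}")
        if isinstance(self.symbol, float) and not (0.0 <= self.symbol <= 1.0):
            raise ValidationError(f"pie fraction must be in [0,1], got {self.symbol}")


def _domain(
    values: np.ndarray, override: tuple[float, float] | None
) -> tuple[float, float]:
    if override is not None:
        return float(override[0]), float(override[1])
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return 0.0, 1.0
    return float(finite.min()), float(finite.max())


def size_scale(
    values: Sequence[float], spec: ChannelSpec, kind: FactorKind = FactorKind.QUANTITATIVE
) -> np.ndarray:
    """Map values linearly onto [min_area, max_area]; missing → NaN (omitted)."""
    if FactorKind(kind) is not FactorKind.QUANTITATIVE:
        raise ValidationError("size channel requires a quantitative factor")
    v = np.asarray(values, dtype=float)
    min_a, max_a = spec.size_range
    lo, hi = _domain(v, spec.size_domain)
    if hi == lo:
        warnings.warn(
            "size domain is degenerate (hi == lo); all dots mid-range",
            UserWarning,
            stacklevel=2,
        )
        out = np.full_like(v, (min_a + max_a) / 2.0)
    else:
        frac = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        out = min_a + frac * (max_a - min_a)
    out[~np.isfinite(v)] = np.nan
    return out


def _interp_color(value: float, lo: float, hi: float, anchors: Sequence[str]) -> str:
    rgbs = np.array([to_rgb(a) for a in anchors])
    if hi == lo:
        t = 0.5
    else:
        t = min(max((value - lo) / (hi - lo), 0.0), 1.0)
    pos = np.linspace(0.0, 1.0, len(rgbs))
    rgb = tuple(float(np.interp(t, pos, rgbs[:, k])) for k in range(3))
    return to_hex(rgb)


def continuous_anchors(values: np.ndarray, spec: ChannelSpec) -> tuple[tuple[str, ...], float, float]:
    """Resolve gradient anchors and domain for a quantitative color factor."""
    finite = values[np.isfinite(values)]
    has_neg = finite.size > 0 and finite.min() < 0
    anchors = spec.palette if spec.palette else (
        DIVERGING_ANCHORS if has_neg else SEQUENTIAL_ANCHORS
    )
    if spec.color_domain is not None:
        lo, hi = spec.color_domain
    elif has_neg:
        m = float(np.abs(finite).max()) if finite.size else 1.0
        lo, hi = -m, m  # symmetric: 0 hits the middle anchor exactly
    else:
        lo, hi = _domain(values, None)
    return tuple(anchors), float(lo), float(hi)


def color_map(
    values: Sequence, kind: FactorKind, spec: ChannelSpec,
    levels: Sequence[str] | None = None,
) -> list[str]:
    """Resolve one hex color per value; missing → neutral grey."""
    if FactorKind(kind) is FactorKind.QUANTITATIVE:
        v = np.asarray(values, dtype=float)
        anchors, lo, hi = continuous_anchors(v, spec)
        return [
            spec.missing_color if not np.isfinite(x) else _interp_color(x, lo, hi, anchors)
            for x in v
        ]
    pal = tuple(spec.palette) if spec.palette else spec.discrete_palette
    if levels is None:
        levels = [str(v) for v in dict.fromkeys(
            x for x in values if not _is_missing(x)
        )]
    if len(levels) > len(pal):
        warnings.warn(
            f"{len(levels)} levels but {len(pal)} discrete colors; palette cycles",
            UserWarning,
            stacklevel=2,
        )
    lut = {lev: pal[i % len(pal)] for i, lev in enumerate(levels)}
    return [
        spec.missing_color if _is_missing(x) else lut[str(x)] for x in values
    ]


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def text_labels(
    values: Sequence, kind: FactorKind, spec: ChannelSpec
) -> list[str]:
    """Format one label per value; missing → empty string."""
    out: list[str] = []
    for x in values:
        if _is_missing(x):
            out.append("")
        elif FactorKind(kind) is FactorKind.QUANTITATIVE:
            if spec.text_format:
                out.append(spec.text_format % float(x))
            else:
                out.append(str(_round_half_away(float(x))))
        else:
            out.append(str(x))
    return out


def shape_encode(
    values: Sequence,
    kind: FactorKind,
    spec: ChannelSpec,
    levels: Sequence[str] | None = None,
) -> list:
    """Resolve the shape channel.

    Qualitative: injective level → symbol map in level order (capacity error
    when levels outnumber symbols). Quantitative: ``fraction_pie`` maps the
    value to a clamped fraction of the shape domain; ``symbol_series`` bins it
    into ≤5 equal-width bins over the domain, mapped to the ordered symbol
    list. Missing → None (no shape drawn).
    """
    if FactorKind(kind) is FactorKind.QUALITATIVE:
        if levels is None:
            levels = [str(v) for v in dict.fromkeys(
                x for x in values if not _is_missing(x)
            )]
        if len(levels) > len(spec.shape_symbols):
            raise CapacityError(
                f"{len(levels)} shape levels exceed the {len(spec.shape_symbols)} "
                f"available symbols {spec.shape_symbols}"
            )
        lut = {lev: spec.shape_symbols[i] for i, lev in enumerate(levels)}
        return [None if _is_missing(x) else lut[str(x)] for x in values]
    v = np.asarray(values, dtype=float)
    lo, hi = _domain(v, spec.shape_domain)
    span = hi - lo
    out: list = []
    if spec.shape_style == "fraction_pie":
        for x in v:
            if not np.isfinite(x):
                out.append(None)
            else:
                frac = 0.5 if span == 0 else (x - lo) / span
                out.append(float(min(max(frac, 0.0), 1.0)))
        return out
    n_bins = min(5, len(spec.shape_symbols))
    for x in v:
        if not np.isfinite(x):
            out.append(None)
        else:
            frac = 0.5 if span == 0 else min(max((x - lo) / span, 0.0), 1.0)
            idx = min(int(frac * n_bins), n_bins - 1)
            out.append(spec.shape_symbols[idx])
    return out


def qualitative_levels(table: DotTable, factor: str) -> list[str]:
    """First-appearance level order of a qualitative factor's values."""
    vals = table.data[factor]
    return [str(v) for v in dict.fromkeys(v for v in vals if not _is_missing(v))]
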