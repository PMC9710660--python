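"""Scene assembly: grid of glyphs, dendrograms and legends.

:func:`compose` resolves a :class:`~flexdot.table.DotTable` plus a
:class:`~flexdot.glyphs.ChannelSpec` (and optional axis dendrograms) into a
self-contained :class:`DotScene` — positioned glyph styles, dendrogram
polyline segments and legend blocks — that the renderer turns into SVG/PNG
without looking back at the inputs.

:func:`split_columns` implements the cell-communication layout: each
interaction column "A|B" is divided into two adjacent sub-columns carrying
each partner's own expression, which can reveal asymmetries a single
interaction dot hides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConsistencyError, FormatError, ValidationError
from .glyphs import (
    ChannelSpec,
    GlyphStyle,
    color_map,
    continuous_anchors,
    qualitative_levels,
    shape_encode,
    size_scale,
    text_labels,
)
from .ordering import Dendrogram
from .table import DotTable, FactorKind, complete_grid


@dataclass
class LegendBlock:
    """One legend panel: reference entries for a single bound channel."""

    channel: str  # size | color | shape | text
    kind: str  # size_dots | color_gradient | color_swatches | shape_symbols | shape_pie | text_note
    title: str
    entries: list[tuple[str, object]] = field(default_factory=list)
    anchors: tuple[str, ...] = ()  # gradient anchors for color_gradient


@dataclass
class RenderOptions:
    """Output options for the renderer."""

    format: str = "svg"  # svg | png
    dpi: float = 150.0
    font_family: str = "DejaVu Sans"
    font_size: float = 8.0
    cell_size: float = 30.0  # points per grid cell

    def __post_init__(self) -> None:
        if self.format not in ("svg", "png"):
            raise ValidationError(f"unknown output format {self.format!r}")
        if not self.dpi > 0:
            raise ValidationError("dpi must be > 0")
        if not self.cell_size > 0:
            raise ValidationError("cell size must be > 0")


@dataclass
class DotScene:
    """Renderable scene graph for one dot plot.

    ``glyphs`` holds (x_index, y_index, GlyphStyle) with indices into
    ``x_labels`` / ``y_labels`` (x rightward, y downward: first y label at
    the top). Dendrogram segments are (pos1, h1, pos2, h2) line segments in
    (leaf-position, height) coordinates; leaf i sits at position i + 0.5.
    """

    x_labels: list[str]
    y_labels: list[str]
    glyphs: list[tuple[int, int, GlyphStyle]]
    legends: list[LegendBlock] = field(default_factory=list)
    col_dend_segments: list[tuple[float, float, float, float]] = field(default_factory=list)
    row_dend_segments: list[tuple[float, float, float, float]] = field(default_factory=list)
    title: str = ""
    x_name: str = ""
    y_name: str = ""

    def __post_init__(self) -> None:
        nx, ny = len(self.x_labels), len(self.y_labels)
        for xi, yi, _ in self.glyphs:
            if not (0 <= xi < nx and 0 <= yi < ny):
                raise ValidationError(
                    f"glyph index ({xi},{yi}) outside {nx}×{ny} grid"
                )


def _dend_segments(dend: Dendrogram) -> list[tuple[float, float, float, float]]:
    """U-link segments of a dendrogram in (leaf-position, height) coordinates."""
    n = len(dend.labels)
    pos_of_label = {lab: i + 0.5 for i, lab in enumerate(dend.leaf_order)}
    # node -> (center position, height)
    node_pos: dict[int, tuple[float, float]] = {
        i: (pos_of_label[dend.labels[i]], 0.0) for i in range(n)
    }
    segs: list[tuple[float, float, float, float]] = []
    for k, (a, b, h) in enumerate(dend.merges):
        (xa, ha), (xb, hb) = node_pos[a], node_pos[b]
        segs.append((xa, ha, xa, h))  # riser over child a
        segs.append((xb, hb, xb, h))  # riser over child b
        segs.append((xa, h, xb, h))  # crossbar
        node_pos[n + k] = ((xa + xb) / 2.0, h)
    return segs


def _check_dend(dend: Dendrogram, levels: Sequence[str], axis: str) -> None:
    if set(dend.labels) != set(levels):
        missing = sorted(set(levels) - set(dend.labels))
        extra = sorted(set(dend.labels) - set(levels))
        raise ConsistencyError(
            f"{axis}-axis dendrogram leaves disagree with axis levels: "
            f"missing {missing}, unexpected {extra}"
        )


def compose(
    table: DotTable,
    spec: ChannelSpec,
    row_dend: Dendrogram | None = None,
    col_dend: Dendrogram | None = None,
    title: str = "",
) -> DotScene:
    """Assemble the scene for a table under a channel specification.

    Axis orders follow the dendrogram leaf orders when given, else the table's
    level orders. One glyph is emitted per (x, y) combination whose
    size-channel value is present (all combinations when size is unbound);
    a legend block is built for every bound channel unless suppressed via
    ``spec.hide_legends``.
    """
    table = complete_grid(table)
    spec.validate(table.factor_kinds)
    x_order = list(table.x_levels)
    y_order = list(table.y_levels)
    col_segs: list[tuple[float, float, float, float]] = []
    row_segs: list[tuple[float, float, float, float]] = []
    if col_dend is not None:
        _check_dend(col_dend, table.x_levels, "x")
        x_order = list(col_dend.leaf_order)
        col_segs = _dend_segments(col_dend)
    if row_dend is not None:
        _check_dend(row_dend, table.y_levels, "y")
        y_order = list(row_dend.leaf_order)
        row_segs = _dend_segments(row_dend)

    df = table.data.set_index([table.x_name, table.y_name])
    keys = [(x, y) for y in y_order for x in x_order]  # row-major
    cells = df.loc[keys]

    n = len(keys)
    mid_area = sum(spec.size_range) / 2.0

    def factor_values(channel: str):
        name = spec.assignments.get(channel)
        if name is None:
            return None, None, None
        kind = table.factor_kinds[name]
        vals = cells[name].tolist()
        levels = (
            qualitative_levels(table, name)
            if kind is FactorKind.QUALITATIVE
            else None
        )
        return name, kind, (vals, levels)

    s_name, s_kind, s_payload = factor_values("size")
    c_name, c_kind, c_payload = factor_values("color")
    t_name, t_kind, t_payload = factor_values("text")
    h_name, h_kind, h_payload = factor_values("shape")

    areas = (
        size_scale(s_payload[0], spec, s_kind)
        if s_name
        else np.full(n, mid_area)
    )
    colors = (
        color_map(c_payload[0], c_kind, spec, levels=c_payload[1])
        if c_name
        else ["#4878d0"] * n
    )
    labels = text_labels(t_payload[0], t_kind, spec) if t_name else [""] * n
    symbols = (
        shape_encode(h_payload[0], h_kind, spec, levels=h_payload[1])
        if h_name
        else [None] * n
    )

    xi_of = {x: i for i, x in enumerate(x_order)}
    yi_of = {y: i for i, y in enumerate(y_order)}
    glyphs: list[tuple[int, int, GlyphStyle]] = []
    for i, (x, y) in enumerate(keys):
        if s_name and not np.isfinite(areas[i]):
            continue  # absent, not zero: dot omitted entirely
        glyphs.append(
            (
                xi_of[x],
                yi_of[y],
                GlyphStyle(
                    area=float(areas[i]),
                    fill_color=colors[i],
                    symbol=symbols[i],
                    label=labels[i],
                ),
            )
        )

    legends = build_legends(spec, table)
    return DotScene(
        x_labels=x_order,
        y_labels=y_order,
        glyphs=glyphs,
        legends=legends,
        col_dend_segments=col_segs,
        row_dend_segments=row_segs,
        title=title,
        x_name=table.x_name,
        y_name=table.y_name,
    )


def build_legends(
    spec: ChannelSpec, table: DotTable, size_breaks: int = 3
) -> list[LegendBlock]:
    """One legend block per bound, non-suppressed channel.

    Size: reference dots at ``size_breaks`` evenly spaced domain values.
    Color: gradient bar with 5 ticks (quantitative) or one swatch per level.
    Shape: symbol ↔ level pairs, or reference sectors at fractions 0/0.5/1.
    Text: a note naming the factor.
    """
    blocks: list[LegendBlock] = []
    hidden = set(spec.hide_legends)
    table = complete_grid(table)

    def values_of(name: str) -> np.ndarray:
        return np.asarray(
            pd.to_numeric(table.data[name], errors="coerce"), dtype=float
        )

    name = spec.assignments.get("size")
    if name and "size" not in hidden:
        v = values_of(name)
        lo, hi = (
            spec.size_domain if spec.size_domain else _finite_range(v)
        )
        breaks = np.linspace(lo, hi, max(size_breaks, 2))
        areas = size_scale(breaks, spec)
        blocks.append(
            LegendBlock(
                channel="size",
                kind="size_dots",
                title=name,
                entries=[(_fmt_break(b), float(a)) for b, a in zip(breaks, areas)],
            )
        )

    name = spec.assignments.get("color")
    if name and "color" not in hidden:
        kind = table.factor_kinds[name]
        if kind is FactorKind.QUANTITATIVE:
            v = values_of(name)
            anchors, lo, hi = continuous_anchors(v, spec)
            ticks = np.linspace(lo, hi, 5)
            blocks.append(
                LegendBlock(
                    channel="color",
                    kind="color_gradient",
                    title=name,
                    entries=[(_fmt_break(t), float(t)) for t in ticks],
                    anchors=anchors,
                )
            )
        else:
            levels = qualitative_levels(table, name)
            swatches = color_map(levels, kind, spec, levels=levels)
            blocks.append(
                LegendBlock(
                    channel="color",
                    kind="color_swatches",
                    title=name,
                    entries=list(zip(levels, swatches)),
                )
            )

    name = spec.assignments.get("shape")
    if name and "shape" not in hidden:
        kind = table.factor_kinds[name]
        if kind is FactorKind.QUALITATIVE:
            levels = qualitative_levels(table, name)
            syms = shape_encode(levels, kind, spec, levels=levels)
            blocks.append(
                LegendBlock(
                    channel="shape",
                    kind="shape_symbols",
                    title=name,
                    entries=list(zip(levels, syms)),
                )
            )
        elif spec.shape_style == "fraction_pie":
            v = values_of(name)
            lo, hi = spec.shape_domain if spec.shape_domain else _finite_range(v)
            blocks.append(
                LegendBlock(
                    channel="shape",
                    kind="shape_pie",
                    title=name,
                    entries=[
                        (_fmt_break(lo), 0.0),
                        (_fmt_break((lo + hi) / 2), 0.5),
                        (_fmt_break(hi), 1.0),
                    ],
                )
            )
        else:
            v = values_of(name)
            syms = shape_encode(v, kind, spec)
            lo, hi = spec.shape_domain if spec.shape_domain else _finite_range(v)
            n_bins = min(5, len(spec.shape_symbols))
            edges = np.linspace(lo, hi, n_bins + 1)
            blocks.append(
                LegendBlock(
                    channel="shape",
                    kind="shape_symbols",
                    title=name,
                    entries=[
                        (
                            f"{_fmt_break(edges[i])}–{_fmt_break(edges[i + 1])}",
                            spec.shape_symbols[i],
                        )
                        for i in range(n_bins)
                    ],
                )
            )

    name = spec.assignments.get("text")
    if name and "text" not in hidden:
        blocks.append(
            LegendBlock(channel="text", kind="text_note", title=name, entries=[])
        )
    return blocks


def _finite_range(v: np.ndarray) -> tuple[float, float]:
    finite = v[np.isfinite(v)]
    if finite.size == 0:
        return 0.0, 1.0
    return float(finite.min()), float(finite.max())


def _fmt_break(x: float) -> str:
    return f"{x:g}" if abs(x - round(x)) > 1e-9 else str(int(round(x)))


def split_columns(
    table: DotTable,
    pair_separator: str,
    left_factor: str,
    right_factor: str,
    shared: str = "both",
) -> DotTable:
    """Split each interaction column "A<sep>B" into adjacent partner columns.

    The left sub-column ("A<sep>B:A") carries ``left_factor``'s value and the
    right one ("A<sep>B:B") carries ``right_factor``'s, merged into a single
    display factor. Remaining factors are carried on ``shared`` ∈
    {"both", "left", "right"} side(s); the unchosen side holds missing.
    Doubles the x-level count and the row count.
    """
    for f in (left_factor, right_factor):
        if table.kind_of(f) is not FactorKind.QUANTITATIVE:
            raise ValidationError(f"split factor {f!r} must be quantitative")
    if shared not in ("both", "left", "right"):
        raise ValidationError(f"shared must be both|left|right, got {shared!r}")
    for level in table.x_levels:
        if level.count(pair_separator) != 1:
            raise FormatError(
                f"x level {level!r} must contain the separator "
                f"{pair_separator!r} exactly once"
            )
    merged = (
        left_factor
        if left_factor == right_factor
        else f"{left_factor}/{right_factor}"
    )
    other = [f for f in table.factor_names if f not in (left_factor, right_factor)]
    new_x: list[str] = []
    for level in table.x_levels:
        a, b = level.split(pair_separator)
        new_x += [f"{level}:{a}", f"{level}:{b}"]
    rows: list[dict] = []
    for _, rec in table.data.iterrows():
        level = rec[table.x_name]
        a, b = level.split(pair_separator)
        for side, sub, factor in (("left", a, left_factor), ("right", b, right_factor)):
            out = {
                table.x_name: f"{level}:{sub}",
                table.y_name: rec[table.y_name],
                merged: rec[factor],
            }
            for f in other:
                out[f] = rec[f] if shared in ("both", side) else np.nan
            rows.append(out)
    kinds = {merged: FactorKind.QUANTITATIVE}
    for f in other:
        kinds[f] = table.factor_kinds[f]
    data = pd.DataFrame(rows, columns=[table.x_name, table.y_name, merged, *other])
    return DotTable(
        x_name=table.x_name,
        y_name=table.y_name,
        data=data,
        factor_kinds=kinds,
        x_levels=new_x,
        y_levels=list(table.y_levels),
    )
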