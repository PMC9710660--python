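"""Rendering a :class:`~flexdot.scene.DotScene` to SVG/PNG via matplotlib.

The scene is drawn onto a plain :class:`matplotlib.figure.Figure` (no pyplot
state), which is also what :func:`as_plot_object` hands back so callers can
add custom layers before saving. SVG output is byte-deterministic: element
ids are salted with a fixed string, the creation date is stripped, and scene
elements are drawn in a fixed order (dendrograms, glyphs row-major, axis
labels, legends). Every glyph's primary patch carries an SVG group id
``glyph-<x>-<y>`` so downstream tooling can count or restyle dots.

Glyph geometry: the size channel fixes the glyph *area* in points²; symbols
(square, triangle, diamond, star) are scaled to the same area as the
equivalent circle. The quantitative-shape "fraction pie" draws a light
full-circle outline plus a filled sector of angle 2π·fraction, clockwise from
12 o'clock.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib as mpl
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import to_rgb
from matplotlib.figure import Figure
from matplotlib.patches import Circle, PathPatch, Rectangle, RegularPolygon, Wedge
from matplotlib.path import Path as MplPath

from .errors import ValidationError
from .scene import DotScene, LegendBlock, RenderOptions

_HASH_SALT = "flexdot"
_DEND_BAND = 0.15  # dendrogram band, fraction of the grid extent
_PT = 1.0 / 72.0  # points → inches


def _luminance(color: str) -> float:
    r, g, b = to_rgb(color)
    return 0.299 * r + 0.587 * g + 0.114 * b


def _text_color(fill: str) -> str:
    return "#000000" if _luminance(fill) > 0.5 else "#ffffff"


def _star_path(r_outer: float) -> MplPath:
    pts = []
    r_inner = 0.381966 * r_outer  # regular pentagram inner/outer ratio
    for k in range(10):
        ang = math.pi / 2 + k * math.pi / 5
        r = r_outer if k % 2 == 0 else r_inner
        pts.append((r * math.cos(ang), r * math.sin(ang)))
    pts.append(pts[0])
    codes = [MplPath.MOVETO] + [MplPath.LINETO] * 9 + [MplPath.CLOSEPOLY]
    return MplPath(pts, codes)


def _add_symbol(ax, x: float, y: float, symbol: str, r_data: float, **kw):
    """Add an equal-area symbol patch centered at (x, y); returns the patch."""
    area = math.pi * r_data**2
    if symbol == "square":
        side = math.sqrt(area)
        patch = Rectangle((x - side / 2, y - side / 2), side, side, **kw)
    elif symbol == "triangle":
        rr = math.sqrt(4 * area / (3 * math.sqrt(3)))
        patch = RegularPolygon((x, y), 3, radius=rr, **kw)
    elif symbol == "diamond":
        rr = math.sqrt(area / 2)
        patch = RegularPolygon((x, y), 4, radius=rr, **kw)
    elif symbol == "star":
        base = _star_path(1.0)
        # pentagram area with unit outer radius ≈ 1.12257 (5 kite quadrilaterals)
        rr = math.sqrt(area / 1.1225699)
        verts = base.vertices * rr + np.array([x, y])
        patch = PathPatch(MplPath(verts, base.codes), **kw)
    else:  # circle (default)
        patch = Circle((x, y), radius=r_data, **kw)
    ax.add_patch(patch)
    return patch


def _draw_glyph(ax, xi: int, yi: int, style, cell_pt: float, font_size: float):
    """Draw one dot at grid cell (xi, yi); 1 data unit = cell_pt points."""
    cx, cy = xi + 0.5, yi + 0.5
    r_data = math.sqrt(max(style.area, 0.0) / math.pi) / cell_pt
    gid = f"glyph-{xi}-{yi}"
    if isinstance(style.symbol, float):  # fraction pie
        outline = Circle(
            (cx, cy), radius=r_data, facecolor="none",
            edgecolor="#c8c8c8", linewidth=0.8,
        )
        outline.set_gid(gid)
        ax.add_patch(outline)
        frac = style.symbol
        if frac >= 1.0:
            ax.add_patch(Circle((cx, cy), radius=r_data, facecolor=style.fill_color,
                                edgecolor="none"))
        elif frac > 0.0:
            # clockwise from 12 o'clock; y axis is inverted so sweep CCW in data
            ax.add_patch(Wedge((cx, cy), r_data, 90.0, 90.0 + 360.0 * frac,
                               facecolor=style.fill_color, edgecolor="none"))
    else:
        patch = _add_symbol(
            ax, cx, cy, style.symbol or "circle", r_data,
            facecolor=style.fill_color, edgecolor="#404040", linewidth=0.4,
        )
        patch.set_gid(gid)
    if style.label:
        ax.text(
            cx, cy, style.label, ha="center", va="center",
            fontsize=font_size * 0.8, color=_text_color(style.fill_color),
            zorder=5,
        )


def build_figure(scene: DotScene, opts: RenderOptions | None = None) -> Figure:
    """Lay out the scene on a fresh Figure (grid, dendrograms, legends)."""
    opts = opts or RenderOptions()
    nx, ny = len(scene.x_labels), len(scene.y_labels)
    cell = opts.cell_size
    grid_w, grid_h = nx * cell, ny * cell
    label_w = (max((len(s) for s in scene.y_labels), default=1) * 0.62
               + 2) * opts.font_size
    label_h = (max((len(s) for s in scene.x_labels), default=1) * 0.62
               + 2) * opts.font_size
    dend_w = _DEND_BAND * grid_w if scene.row_dend_segments else 0.0
    dend_h = _DEND_BAND * grid_h if scene.col_dend_segments else 0.0
    legend_w = 110.0 if scene.legends else 0.0
    title_h = 20.0 if scene.title else 6.0
    pad = 8.0

    fig_w = dend_w + label_w + grid_w + legend_w + 3 * pad
    fig_h = title_h + dend_h + grid_h + label_h + 2 * pad
    fig = Figure(figsize=(fig_w * _PT, fig_h * _PT))
    FigureCanvasAgg(fig)

    def rect(x0, y0, w, h):  # points → figure fraction
        return [x0 / fig_w, y0 / fig_h, w / fig_w, h / fig_h]

    grid_x0 = dend_w + label_w + pad
    grid_y0 = label_h + pad

    # dendrograms first (fixed draw order)
    if scene.col_dend_segments:
        axd = fig.add_axes(rect(grid_x0, grid_y0 + grid_h, grid_w, dend_h))
        hmax = max((max(s[1], s[3]) for s in scene.col_dend_segments), default=1.0)
        axd.set_xlim(0, nx)
        axd.set_ylim(0, max(hmax, 1e-9) * 1.05)
        axd.axis("off")
        for x1, h1, x2, h2 in scene.col_dend_segments:
            axd.plot([x1, x2], [h1, h2], color="#404040", linewidth=0.8,
                     solid_capstyle="butt")
    if scene.row_dend_segments:
        axd = fig.add_axes(rect(pad / 2, grid_y0, dend_w, grid_h))
        hmax = max((max(s[1], s[3]) for s in scene.row_dend_segments), default=1.0)
        axd.set_xlim(max(hmax, 1e-9) * 1.05, 0)  # heights grow leftward
        axd.set_ylim(ny, 0)
        axd.axis("off")
        for p1, h1, p2, h2 in scene.row_dend_segments:
            axd.plot([h1, h2], [p1, p2], color="#404040", linewidth=0.8,
                     solid_capstyle="butt")

    ax = fig.add_axes(rect(grid_x0, grid_y0, grid_w, grid_h))
    ax.set_xlim(0, nx)
    ax.set_ylim(ny, 0)  # first y label at the top
    ax.set_aspect("equal")
    for spine in ax.spines.values():
        spine.set_visible(False)
    ax.set_xticks([i + 0.5 for i in range(nx)])
    ax.set_xticklabels(scene.x_labels, rotation=90, fontsize=opts.font_size)
    ax.set_yticks([i + 0.5 for i in range(ny)])
    ax.set_yticklabels(scene.y_labels, fontsize=opts.font_size)
    ax.tick_params(length=0)

    for xi, yi, style in sorted(scene.glyphs, key=lambda g: (g[1], g[0])):
        _draw_glyph(ax, xi, yi, style, cell, opts.font_size)

    if scene.title:
        fig.suptitle(scene.title, fontsize=opts.font_size + 2, y=1 - 4 / fig_h)

    if scene.legends:
        _draw_legends(fig, scene.legends,
                      rect(grid_x0 + grid_w + pad, grid_y0, legend_w, grid_h + dend_h),
                      opts)
    return fig


def _draw_legends(fig: Figure, blocks: list[LegendBlock], rect, opts: RenderOptions):
    ax = fig.add_axes(rect)
    ax.axis("off")
    ax.set_xlim(0, 1)
    ax.set_ylim(1, 0)
    fs = opts.font_size
    # rows are laid out in a virtual row grid; convert row index → axes y
    total_rows = sum(2 + max(len(b.entries), 1) + 1 for b in blocks)
    total_rows = max(total_rows, 1)
    row_h = 1.0 / max(total_rows, 12)
    y = 0.0
    ax_w_pt = rect[2] * fig.get_figwidth() / _PT
    ax_h_pt = rect[3] * fig.get_figheight() / _PT
    for block in blocks:
        ax.text(0.0, y + row_h / 2, block.title, fontsize=fs, fontweight="bold",
                va="center")
        y += row_h * 1.4
        if block.kind == "size_dots":
            from matplotlib.patches import Ellipse

            for label, area in block.entries:
                r_pt = math.sqrt(max(float(area), 0.0) / math.pi)
                ax.add_patch(Ellipse(
                    (0.14, y + row_h / 2),
                    2 * r_pt / ax_w_pt, 2 * r_pt / ax_h_pt,
                    facecolor="#808080", edgecolor="none",
                ))
                ax.text(0.32, y + row_h / 2, label, fontsize=fs, va="center")
                y += row_h * 1.2
        elif block.kind == "color_gradient":
            steps = 24
            bar_h = row_h * 3
            for i in range(steps):
                t0 = i / steps
                ax.add_patch(Rectangle(
                    (0.0 + 0.26 * t0, y), 0.26 / steps * 1.05, bar_h,
                    facecolor=_gradient_color(block.anchors, t0 + 0.5 / steps),
                    edgecolor="none",
                ))
            lo, hi = block.entries[0][0], block.entries[-1][0]
            mid = block.entries[len(block.entries) // 2][0]
            ax.text(0.30, y + bar_h * 0.1, hi, fontsize=fs * 0.9, va="center")
            ax.text(0.30, y + bar_h * 0.5, mid, fontsize=fs * 0.9, va="center")
            ax.text(0.30, y + bar_h * 0.9, lo, fontsize=fs * 0.9, va="center")
            y += bar_h + row_h * 0.5
        elif block.kind == "color_swatches":
            for label, color in block.entries:
                ax.add_patch(Rectangle((0.04, y + row_h * 0.15), 0.16, row_h * 0.7,
                                       facecolor=str(color), edgecolor="#404040",
                                       linewidth=0.4))
                ax.text(0.28, y + row_h / 2, label, fontsize=fs, va="center")
                y += row_h
        elif block.kind == "shape_symbols":
            for label, symbol in block.entries:
                _legend_symbol(ax, 0.12, y + row_h / 2, str(symbol),
                               row_h * 0.35, ax_w_pt, ax_h_pt)
                ax.text(0.28, y + row_h / 2, label, fontsize=fs, va="center")
                y += row_h
        elif block.kind == "shape_pie":
            for label, frac in block.entries:
                _legend_pie(ax, 0.12, y + row_h / 2, float(frac), row_h * 0.4,
                            ax_w_pt, ax_h_pt)
                ax.text(0.28, y + row_h / 2, label, fontsize=fs, va="center")
                y += row_h
        elif block.kind == "text_note":
            ax.text(0.0, y + row_h / 2, f"text: {block.title}", fontsize=fs * 0.9,
                    va="center", style="italic")
            y += row_h
        y += row_h * 0.8


def _gradient_color(anchors, t: float) -> str:
    from matplotlib.colors import to_hex

    rgbs = np.array([to_rgb(a) for a in anchors])
    pos = np.linspace(0, 1, len(rgbs))
    return to_hex(tuple(float(np.interp(t, pos, rgbs[:, k])) for k in range(3)))


def _ellipse_pts(ax, cx, cy, ry, w_pt, h_pt):
    """x/y radii giving a visually circular marker in a non-equal-aspect axes."""
    rx = ry * h_pt / w_pt
    return rx, ry


def _legend_symbol(ax, cx, cy, symbol, ry, w_pt, h_pt):
    from matplotlib.patches import Ellipse, Polygon

    rx, ry = _ellipse_pts(ax, cx, cy, ry, w_pt, h_pt)
    kw = dict(facecolor="#808080", edgecolor="#404040", linewidth=0.4)
    if symbol == "square":
        ax.add_patch(Rectangle((cx - rx, cy - ry), 2 * rx, 2 * ry, **kw))
    elif symbol == "triangle":
        ax.add_patch(Polygon([(cx, cy - ry), (cx - rx, cy + ry), (cx + rx, cy + ry)],
                             closed=True, **kw))
    elif symbol == "diamond":
        ax.add_patch(Polygon([(cx, cy - ry), (cx + rx, cy), (cx, cy + ry),
                              (cx - rx, cy)], closed=True, **kw))
    elif symbol == "star":
        base = _star_path(1.0)
        verts = base.vertices * np.array([rx, ry]) + np.array([cx, cy])
        ax.add_patch(PathPatch(MplPath(verts, base.codes), **kw))
    else:
        ax.add_patch(Ellipse((cx, cy), 2 * rx, 2 * ry, **kw))


def _legend_pie(ax, cx, cy, frac, ry, w_pt, h_pt):
    from matplotlib.patches import Ellipse

    rx, ry = _ellipse_pts(ax, cx, cy, ry, w_pt, h_pt)
    ax.add_patch(Ellipse((cx, cy), 2 * rx, 2 * ry, facecolor="none",
                         edgecolor="#c8c8c8", linewidth=0.8))
    if frac >= 1.0:
        ax.add_patch(Ellipse((cx, cy), 2 * rx, 2 * ry, facecolor="#808080",
                             edgecolor="none"))
    elif frac > 0.0:
        theta = np.linspace(math.pi / 2, math.pi / 2 - 2 * math.pi * frac, 48)
        pts = [(cx, cy)] + [
            (cx + rx * math.cos(t), cy - ry * math.sin(t)) for t in theta
        ]
        from matplotlib.patches import Polygon

        ax.add_patch(Polygon(pts, closed=True, facecolor="#808080",
                             edgecolor="none"))


def render(scene: DotScene, opts: RenderOptions | None = None,
           path: str | Path = "dotplot.svg") -> Path:
    """Render the scene to ``path``.

    SVG output is byte-deterministic for identical scene + options; PNG is
    rasterized at ``opts.dpi``. The format comes from ``opts.format``.
    """
    opts = opts or RenderOptions()
    path = Path(path)
    with mpl.rc_context({
        "svg.hashsalt": _HASH_SALT,
        "font.family": opts.font_family,
        "svg.fonttype": "path",
    }):
        fig = build_figure(scene, opts)
        try:
            if opts.format == "svg":
                fig.savefig(path, format="svg", metadata={"Date": None})
            elif opts.format == "png":
                fig.savefig(path, format="png", dpi=opts.dpi)
            else:  # RenderOptions validates, but guard direct misuse
                raise ValidationError(f"unknown output format {opts.format!r}")
        except OSError as exc:
            raise ValidationError(f"cannot write {path}: {exc}") from exc
    return path


def as_plot_object(scene: DotScene, opts: RenderOptions | None = None) -> Figure:
    """Return an extensible matplotlib Figure for the scene.

    Each call builds an independent Figure; saved unmodified (same rc
    settings) it renders identically to :func:`render`. Callers may add
    annotation layers (``fig.axes[...].axhline(...)`` etc.) before saving.
    """
    with mpl.rc_context({
        "svg.hashsalt": _HASH_SALT,
        "font.family": (opts or RenderOptions()).font_family,
        "svg.fonttype": "path",
    }):
        return build_figure(scene, opts)
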