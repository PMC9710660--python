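"""Scene composition, split columns, legends, deterministic rendering."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from flexdot import (
    ChannelSpec,
    ConsistencyError,
    DotTable,
    FactorKind,
    FormatError,
    RenderOptions,
    ValidationError,
    as_plot_object,
    build_legends,
    compose,
    order_axis,
    render,
    split_columns,
)
from flexdot.fixtures import synthetic_dot_table
from flexdot.ordering import Dendrogram


@pytest.fixture
def table32():
    return synthetic_dot_table(3, 2, 2, 1, seed=4)


class TestCompose:
    def test_glyph_and_legend_counts(self, table32):
        spec = ChannelSpec(assignments={"size": "quant1", "color": "quant2"})
        scene = compose(table32, spec)
        assert len(scene.glyphs) == 6
        assert len(scene.legends) == 2

    def test_missing_size_value_omits_glyph(self, table32):
        table32.data.loc[0, "quant1"] = np.nan
        spec = ChannelSpec(assignments={"size": "quant1"})
        scene = compose(table32, spec)
        assert len(scene.glyphs) == 5

    def test_size_unbound_draws_all_combinations(self, table32):
        table32.data.loc[0, "quant1"] = np.nan
        spec = ChannelSpec(assignments={"color": "quant1"})
        scene = compose(table32, spec)
        assert len(scene.glyphs) == 6

    def test_dendrogram_orders_axes(self, table32):
        rd = order_axis(table32, "y")
        cd = order_axis(table32, "x")
        spec = ChannelSpec(assignments={"size": "quant1"})
        scene = compose(table32, spec, row_dend=rd, col_dend=cd)
        assert scene.y_labels == rd.leaf_order
        assert scene.x_labels == cd.leaf_order
        assert scene.col_dend_segments and scene.row_dend_segments

    def test_wrong_dendrogram_labels_is_consistency_error(self, table32):
        bad = Dendrogram(labels=["a", "b"], merges=[(0, 1, 1.0)],
                         leaf_order=["a", "b"])
        spec = ChannelSpec(assignments={"size": "quant1"})
        with pytest.raises(ConsistencyError, match="missing"):
            compose(table32, spec, col_dend=bad)

    def test_glyph_indices_within_grid(self, table32):
        spec = ChannelSpec(assignments={"size": "quant1", "shape": "qual1"})
        scene = compose(table32, spec)
        for xi, yi, style in scene.glyphs:
            assert 0 <= xi < 3 and 0 <= yi < 2
            assert style.area >= 0


class TestSplitColumns:
    @pytest.fixture
    def interactions(self):
        rows = []
        for pair in ["TAM|TP1", "TAM|TP2", "TAM|CD8", "TP1|TP2"]:
            for y in ["CD74/MIF", "PDL1/PD1"]:
                rows.append((pair, y, 1.0 + len(rows), 100.0 - len(rows), "yes"))
        df = pd.DataFrame(rows, columns=["pair", "interaction", "left_expr",
                                         "right_expr", "signif"])
        return DotTable(
            x_name="pair", y_name="interaction", data=df,
            factor_kinds={
                "left_expr": FactorKind.QUANTITATIVE,
                "right_expr": FactorKind.QUANTITATIVE,
                "signif": FactorKind.QUALITATIVE,
            },
        )

    def test_doubles_columns_and_rows_preserving_adjacency(self, interactions):
        out = split_columns(interactions, "|", "left_expr", "right_expr")
        assert len(out.x_levels) == 8
        assert len(out.data) == 2 * len(interactions.data)
        assert out.x_levels[0] == "TAM|TP1:TAM"
        assert out.x_levels[1] == "TAM|TP1:TP1"

    def test_equal_values_render_both_sides_identically(self, interactions):
        interactions.data["right_expr"] = interactions.data["left_expr"]
        out = split_columns(interactions, "|", "left_expr", "right_expr")
        merged = "left_expr/right_expr"
        wide = out.data.set_index(["pair", "interaction"])[merged]
        for pair in ["TAM|TP1", "TAM|TP2"]:
            a, b = pair.split("|")
            left = wide[f"{pair}:{a}"]
            right = wide[f"{pair}:{b}"]
            assert (left.to_numpy() == right.to_numpy()).all()

    def test_shared_factor_sides(self, interactions):
        both = split_columns(interactions, "|", "left_expr", "right_expr",
                             shared="both")
        assert both.data["signif"].notna().all()
        left = split_columns(interactions, "|", "left_expr", "right_expr",
                             shared="left")
        # right-side rows (odd positions in level order) carry missing
        right_levels = left.x_levels[1::2]
        mask = left.data["pair"].isin(right_levels)
        assert left.data.loc[mask, "signif"].isna().all()

    def test_separator_missing_is_format_error(self, interactions):
        with pytest.raises(FormatError, match="exactly once"):
            split_columns(interactions, "+", "left_expr", "right_expr")

    def test_qualitative_split_factor_rejected(self, interactions):
        with pytest.raises(ValidationError):
            split_columns(interactions, "|", "signif", "right_expr")


class TestLegends:
    def test_size_breaks_at_domain_min_mid_max(self, table32):
        spec = ChannelSpec(assignments={"size": "quant1"},
                           size_domain=(0.0, 100.0))
        blocks = build_legends(spec, table32)
        assert len(blocks) == 1
        labels = [lab for lab, _ in blocks[0].entries]
        assert labels == ["0", "50", "100"]

    def test_qualitative_color_swatches_in_level_order(self, table32):
        spec = ChannelSpec(assignments={"color": "qual1"})
        blocks = build_legends(spec, table32)
        assert blocks[0].kind == "color_swatches"
        from flexdot.glyphs import qualitative_levels
        from flexdot.table import complete_grid

        assert [lab for lab, _ in blocks[0].entries] == qualitative_levels(
            complete_grid(table32), "qual1"
        )

    def test_suppression_flag_removes_block(self, table32):
        spec = ChannelSpec(
            assignments={"size": "quant1", "color": "quant2"},
            hide_legends=("size",),
        )
        blocks = build_legends(spec, table32)
        assert [b.channel for b in blocks] == ["color"]

    def test_pie_legend_reference_fractions(self, table32):
        spec = ChannelSpec(assignments={"shape": "quant1"},
                           shape_domain=(0.0, 100.0))
        blocks = build_legends(spec, table32)
        assert blocks[0].kind == "shape_pie"
        assert [f for _, f in blocks[0].entries] == [0.0, 0.5, 1.0]


class TestRender:
    def _scene(self, seed=4):
        t = synthetic_dot_table(3, 4, 2, 1, seed=seed)
        spec = ChannelSpec(
            assignments={"size": "quant1", "color": "quant2", "shape": "qual1"}
        )
        return compose(t, spec, row_dend=order_axis(t, "y"),
                       col_dend=order_axis(t, "x"))

    def test_svg_byte_deterministic_across_three_runs(self, tmp_path):
        scene = self._scene()
        hashes = set()
        for i in range(3):
            p = tmp_path / f"r{i}.svg"
            render(scene, RenderOptions(), p)
            hashes.add(hashlib.sha256(p.read_bytes()).hexdigest())
        assert len(hashes) == 1

    def test_svg_contains_one_group_per_glyph(self, tmp_path):
        scene = self._scene()
        p = tmp_path / "fig.svg"
        render(scene, RenderOptions(), p)
        text = p.read_text()
        assert text.count('id="glyph-') == len(scene.glyphs) == 12

    def test_png_output(self, tmp_path):
        scene = self._scene()
        p = tmp_path / "fig.png"
        render(scene, RenderOptions(format="png", dpi=72), p)
        assert p.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"

    def test_unknown_format_rejected(self):
        with pytest.raises(ValidationError):
            RenderOptions(format="pdf")

    def test_plot_object_equivalent_and_independent(self, tmp_path):
        scene = self._scene()
        fig1 = as_plot_object(scene)
        fig2 = as_plot_object(scene)
        assert fig1 is not fig2
        n_gid = sum(
            1 for ax in fig1.axes for a in ax.patches
            if (a.get_gid() or "").startswith("glyph-")
        )
        assert n_gid == len(scene.glyphs)
        # adding a custom layer leaves glyphs unchanged
        fig1.axes[-2].axhline(1.0)
        n_after = sum(
            1 for ax in fig1.axes for a in ax.patches
            if (a.get_gid() or "").startswith("glyph-")
        )
        assert n_after == n_gid

    def test_fraction_pie_scene_renders(self, tmp_path):
        t = synthetic_dot_table(2, 2, 2, 0, seed=9)
        spec = ChannelSpec(assignments={"size": "quant1", "shape": "quant2"},
                           shape_style="fraction_pie")
        scene = compose(t, spec)
        assert all(isinstance(g[2].symbol, float) for g in scene.glyphs)
        p = tmp_path / "pie.svg"
        render(scene, RenderOptions(), p)
        assert p.stat().st_size > 0
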