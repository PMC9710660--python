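"""PCA / MCA / FAMD dispatch and agglomerative axis ordering."""

import numpy as np
import pandas as pd
import pytest

from flexdot import FactorKind, ValidationError, famd, mca, order_axis, pca
from flexdot.fixtures import synthetic_dot_table
from flexdot.ordering import dendrogram_from_coordinates, embed_axis_profiles
from flexdot.table import complete_grid

from _oracles import brute_mca_eigenvalues, merge_leafsets, naive_agglomerate


class TestPCA:
    def test_two_point_diagonal_by_hand(self):
        # centered rows (-1,-1),(1,1): covariance eigenvalues (4, 0)
        e = pca(np.array([[0.0, 0.0], [2.0, 2.0]]), scale=False)
        assert e.eigenvalues == pytest.approx([4.0, 0.0], abs=1e-12)
        assert e.coordinates[:, 1] == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_constant_column_dropped_without_changing_eigenvalues(self, rng):
        x = rng.normal(size=(6, 3))
        base = pca(x, scale=False)
        with pytest.warns(UserWarning, match="zero-variance"):
            aug = pca(np.column_stack([x, np.full(6, 7.0)]), scale=False)
        assert aug.eigenvalues == pytest.approx(base.eigenvalues, abs=1e-10)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        x = rng.normal(size=(6, 4))
        for scale in (True, False):
            e = pca(x, scale=scale)
            proc = x - x.mean(axis=0)
            if scale:
                proc = proc / proc.std(axis=0, ddof=0)
            total_var = proc.var(axis=0, ddof=1).sum()
            assert e.eigenvalues.sum() == pytest.approx(total_var, rel=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        x = rng.normal(size=(8, 3))
        e = pca(x, scale=False)
        sk = SkPCA().fit(x)
        assert e.eigenvalues[:3] == pytest.approx(sk.explained_variance_, abs=1e-10)
        ours = np.abs(e.coordinates[:, :3])
        theirs = np.abs(sk.transform(x))
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.array([[1.0, 2.0]]))
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                pca(np.ones((4, 2)))


class TestMCA:
    def test_balanced_two_binary_columns_inertia_is_one(self):
        df = pd.DataFrame({"a": ["u", "u", "v", "v"], "b": ["p", "q", "p", "q"]})
        e = mca(df)
        # (J - Q)/Q = (4 - 2)/2 = 1
        assert e.eigenvalues.sum() == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_associated_columns_leading_eigenvalue_one(self):
        df = pd.DataFrame({"a": ["u", "v", "u", "v"], "b": ["p", "q", "p", "q"]})
        e = mca(df)
        assert e.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_ca_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        cols = {
            f"c{k}": rng.choice(list("abcd")[: 2 + k], size=n).tolist()
            for k in range(3)
        }
        df = pd.DataFrame(cols)
        e = mca(df)
        oracle = np.sort(brute_mca_eigenvalues(list(cols.values())))[::-1]
        ours = np.zeros(len(oracle))
        ours[: len(e.eigenvalues)] = e.eigenvalues
        assert ours == pytest.approx(oracle, abs=1e-10)
        j = sum(df[c].nunique() for c in df)
        q = df.shape[1]
        assert e.eigenvalues.sum() == pytest.approx((j - q) / q, abs=1e-10)

    def test_single_category_column_dropped(self):
        df = pd.DataFrame({"a": ["u", "u", "u"], "b": ["p", "q", "p"]})
        with pytest.warns(UserWarning, match="single category"):
            e = mca(df)
        assert e.eigenvalues.sum() == pytest.approx(1.0, abs=1e-12)  # (2-1)/1
        with pytest.raises(ValidationError):
            mca(pd.DataFrame({"a": ["u", "u"]}))


class TestFAMD:
    def test_all_quantitative_reduces_to_scaled_pca(self, rng):
        x = rng.normal(size=(7, 3))
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        kinds = {c: FactorKind.QUANTITATIVE for c in df}
        ep = pca(x, scale=True)
        ef = famd(df, kinds)
        k = min(ep.coordinates.shape[1], ef.coordinates.shape[1])
        # component-sign-invariant comparison
        for j in range(k):
            col_p, col_f = ep.coordinates[:, j], ef.coordinates[:, j]
            assert np.abs(col_f) == pytest.approx(np.abs(col_p), abs=1e-8)

    def test_all_qualitative_scales_mca_by_column_count(self):
        # under indicator/sqrt(p) weighting the exact relation is
        # famd_eig = Q * mca_eig; inertia proportions coincide
        df = pd.DataFrame({"a": ["u", "u", "v", "v"], "b": ["p", "q", "p", "q"]})
        kinds = {c: FactorKind.QUALITATIVE for c in df}
        ef = famd(df, kinds)
        em = mca(df)
        q = df.shape[1]
        k = min(len(ef.eigenvalues), len(em.eigenvalues))
        assert ef.eigenvalues[:k] == pytest.approx(q * em.eigenvalues[:k], abs=1e-10)
        prop_f = ef.eigenvalues / ef.eigenvalues.sum()
        prop_m = em.eigenvalues / em.eigenvalues.sum()
        assert prop_f[:k] == pytest.approx(prop_m[:k], abs=1e-10)

    def test_mixed_inertia_by_hand(self, rng):
        # 1 standardized quantitative column contributes 1; a binary
        # qualitative column contributes (2 - 1) = 1; total inertia 2
        df = pd.DataFrame(
            {"q": rng.normal(size=6), "c": ["u", "v", "u", "v", "u", "v"]}
        )
        e = famd(df, {"q": FactorKind.QUANTITATIVE, "c": FactorKind.QUALITATIVE})
        assert e.eigenvalues.sum() == pytest.approx(2.0, abs=1e-10)

    def test_eigenvalues_nonincreasing_nonnegative(self, rng):
        df = pd.DataFrame(
            {
                "q1": rng.normal(size=8),
                "q2": rng.uniform(size=8),
                "c": rng.choice(["a", "b", "c"], size=8),
            }
        )
        e = famd(df, {"q1": FactorKind.QUANTITATIVE, "q2": FactorKind.QUANTITATIVE,
                      "c": FactorKind.QUALITATIVE})
        assert (e.eigenvalues >= 0).all()
        assert (np.diff(e.eigenvalues) <= 1e-12).all()


class TestOrderAxis:
    def test_near_identical_profiles_merge_first(self):
        rows = []
        profiles = {"x0": (0.0, 0.0), "x1": (0.0, 0.1), "x2": (5.0, 5.0)}
        for x, (v1, v2) in profiles.items():
            rows += [(x, "y0", v1), (x, "y1", v2)]
        t = _table_from_rows(rows)
        d = order_axis(t, axis="x", linkage="single")
        first_merge = set(d.merges[0][:2])
        assert first_merge == {0, 1}  # x0 and x1 are near-identical

    def test_single_level_axis_degenerate(self):
        t = _table_from_rows([("x0", "y0", 1.0), ("x0", "y1", 2.0)])
        with pytest.warns(UserWarning, match="single level"):
            d = order_axis(t, axis="x")
        assert d.merges == [] and d.leaf_order == ["x0"]

    @pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_matches_naive_oracle(self, linkage, n, rng):
        coords = rng.normal(size=(n, 3))
        labels = [f"L{i}" for i in range(n)]
        d = dendrogram_from_coordinates(coords, labels, linkage=linkage)
        oracle = naive_agglomerate(coords, linkage)
        assert [h for _, _, h in d.merges] == pytest.approx(
            [h for _, _, h in oracle], abs=1e-10
        )
        assert merge_leafsets(n, d.merges) == merge_leafsets(n, oracle)

    def test_leaf_order_is_permutation_with_contiguous_subtrees(self, rng):
        coords = rng.normal(size=(7, 2))
        labels = [f"L{i}" for i in range(7)]
        d = dendrogram_from_coordinates(coords, labels, linkage="average")
        assert sorted(d.leaf_order) == sorted(labels)
        leafsets = merge_leafsets(7, d.merges)
        pos = {lab: i for i, lab in enumerate(d.leaf_order)}
        for ls in leafsets:
            positions = sorted(pos[labels[i]] for i in ls)
            assert positions == list(range(positions[0], positions[-1] + 1))

    def test_dispatch_by_kind(self):
        t_quant = synthetic_dot_table(4, 3, 2, 0, seed=1)
        t_qual = synthetic_dot_table(4, 3, 0, 2, seed=1)
        t_mixed = synthetic_dot_table(4, 3, 1, 1, seed=1)
        assert embed_axis_profiles(t_quant, "x").method == "pca"
        assert embed_axis_profiles(t_qual, "x").method == "mca"
        # mixed table defaults to quantitative factors only -> pca
        assert embed_axis_profiles(t_mixed, "x").method == "pca"
        assert embed_axis_profiles(
            t_mixed, "x", factors=["quant1", "qual1"]
        ).method == "famd"

    def test_missing_values_imputed_with_warning(self):
        t = _table_from_rows(
            [("x0", "y0", 1.0), ("x0", "y1", 2.0), ("x1", "y0", 3.0)]
        )
        t = complete_grid(t)
        with pytest.warns(UserWarning, match="mean-imputed"):
            d = order_axis(t, axis="x")
        assert sorted(d.leaf_order) == ["x0", "x1"]

    def test_newick_export_parses(self, rng):
        coords = rng.normal(size=(5, 2))
        d = dendrogram_from_coordinates(coords, list("abcde"), linkage="ward")
        nwk = d.to_newick()
        assert nwk.endswith(";") and nwk.count(",") == 4
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcde")


def _table_from_rows(rows):
    import flexdot

    df = pd.DataFrame(rows, columns=["xf", "yf", "v"])
    return flexdot.DotTable(
        x_name="xf", y_name="yf", data=df,
        factor_kinds={"v": FactorKind.QUANTITATIVE},
    )
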