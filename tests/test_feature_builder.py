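import numpy as np
import pandas as pd
import pytest

from omcboost.feature_builder import (
    build_cna_matrix,
    build_continuous_matrix,
    build_snv_matrix,
    intersect_with_primary,
)


def variants(rows):
    return pd.DataFrame(rows, columns=["cell_id", "gene", "variant_class"])


class TestBuildSnvMatrix:
    def test_encoding_rule(self):
        v = variants([("c1", "A", "missense"), ("c2", "B", "nonsense")])
        m = build_snv_matrix(v, ["A"], ["c1", "c2"])
        assert list(m.columns) == ["A"]
        np.testing.assert_array_equal(m["A"].to_numpy(), [1, 0])

    def test_all_zero_column_retained(self):
        v = variants([("c1", "A", "missense")])
        m = build_snv_matrix(v, ["A", "Z"], ["c1", "c2"])
        assert list(m.columns) == ["A", "Z"]
        assert m["Z"].sum() == 0

    def test_duplicate_variant_rows_idempotent(self):
        v = variants([("c1", "A", "missense"), ("c1", "A", "nonsense"),
                      ("c1", "A", "frameshift")])
        m = build_snv_matrix(v, ["A"], ["c1"])
        assert m.at["c1", "A"] == 1

    def test_variant_classes_pooled(self):
        v = variants([("c1", "A", "missense"), ("c2", "A", "gene_fusion")])
        m = build_snv_matrix(v, ["A"], ["c1", "c2"])
        assert m["A"].tolist() == [1, 1]

    def test_unknown_cell_warns_and_drops(self):
        v = variants([("c1", "A", "x"), ("ghost", "A", "x")])
        with pytest.warns(UserWarning, match="ghost"):
            m = build_snv_matrix(v, ["A"], ["c1"])
        assert m.shape == (1, 1)

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            build_snv_matrix(variants([("c1", "A", "x")]), [], ["c1"])

    def test_row_order_stability(self):
        rows = [("c2", "B", "x"), ("c1", "A", "x"), ("c3", "A", "x")]
        a = build_snv_matrix(variants(rows), ["A", "B"], ["c1", "c2", "c3"])
        b = build_snv_matrix(variants(rows[::-1]), ["A", "B"], ["c1", "c2", "c3"])
        pd.testing.assert_frame_equal(a, b)


class TestIntersectWithPrimary:
    def test_basic_intersection_preserves_order(self):
        assert intersect_with_primary(["s1", "s2", "s3"], ["s2", "s3", "s4"]) == ["s2", "s3"]

    def test_disjoint_gives_empty(self):
        assert intersect_with_primary(["a"], ["b"]) == []

    def test_subset_unchanged(self):
        cell = ["s1", "s2", "s3"]
        assert intersect_with_primary(cell, ["s3", "s2", "s1", "s9"]) == cell


def segments(rows):
    return pd.DataFrame(rows, columns=["cancer_type", "region_id", "cell_id", "altered"])


class TestBuildCnaMatrix:
    def test_region_absent_from_tumors_dropped(self):
        seg = segments([("LUAD", "cna1", "c1", True), ("LUAD", "cna2", "c1", True)])
        m = build_cna_matrix(seg, ["cna1"], "LUAD", ["c1"])
        assert list(m.columns) == ["cna1"]

    def test_no_altered_cells_gives_zero_matrix(self):
        seg = segments([("LUAD", "cna1", "c1", False), ("LUAD", "cna1", "c2", False)])
        m = build_cna_matrix(seg, ["cna1"], "LUAD", ["c1", "c2"])
        assert m.to_numpy().sum() == 0

    def test_miniature_intersection_fixture(self):
        # 5 segments seen in cell lines, 3 shared with primary tumors
        seg = segments([("BRCA", f"cna{i}", "c1", True) for i in range(1, 6)])
        m = build_cna_matrix(seg, ["cna2", "cna4", "cna5", "cna9"], "BRCA", ["c1", "c2"])
        assert m.shape == (2, 3)
        assert list(m.columns) == ["cna2", "cna4", "cna5"]
        # independent set-algebra oracle on the same fixture
        expected = {f"cna{i}" for i in range(1, 6)} & {"cna2", "cna4", "cna5", "cna9"}
        assert set(m.columns) == expected

    def test_unknown_cancer_type_rejected(self):
        seg = segments([("LUAD", "cna1", "c1", True)])
        with pytest.raises(ValueError, match="SKCM"):
            build_cna_matrix(seg, ["cna1"], "SKCM", ["c1"])

    def test_binary_values_only(self):
        seg = segments([("LUAD", "cna1", "c1", True), ("LUAD", "cna2", "c2", True)])
        m = build_cna_matrix(seg, ["cna1", "cna2"], "LUAD", ["c1", "c2"])
        assert set(np.unique(m.to_numpy())) <= {0, 1}


def value_table(n_features=10, n_cells=4, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_features, n_cells)),
        index=[f"ENSG{i:03d}" for i in range(n_features)],
        columns=[f"c{i}" for i in range(n_cells)],
    )


class TestBuildContinuousMatrix:
    def test_pass_through_values(self):
        vals = value_table()
        keep = ["ENSG001", "ENSG003", "ENSG005", "ENSG007"]
        m, report = build_continuous_matrix(vals, keep, None, ["c0", "c2"])
        assert m.shape == (2, 4)
        assert report.unmapped == []
        np.testing.assert_allclose(m.loc["c2", "ENSG005"], vals.loc["ENSG005", "c2"])

    def test_unmappable_feature_reported_and_dropped(self):
        vals = value_table()
        m, report = build_continuous_matrix(
            vals, ["ENSG001", "ENSG002", "ORPHAN", "ENSG004"], None, ["c0"]
        )
        assert m.shape == (1, 3)
        assert report.unmapped == ["ORPHAN"]

    def test_id_map_translates_secondary_names(self):
        vals = value_table()
        m, report = build_continuous_matrix(
            vals, ["TP53"], {"TP53": "ENSG002"}, ["c0", "c1"]
        )
        assert list(m.columns) == ["TP53"]
        np.testing.assert_allclose(m["TP53"].to_numpy(), vals.loc["ENSG002", ["c0", "c1"]])

    def test_beta_values_validated(self):
        vals = value_table()  # normal draws stray outside [0, 1]
        with pytest.raises(ValueError, match="beta"):
            build_continuous_matrix(vals, ["ENSG001"], None, ["c0"], beta_values=True)
        ok = vals.clip(0.01, 0.99)
        m, _ = build_continuous_matrix(ok, ["ENSG001"], None, ["c0"], beta_values=True)
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            build_continuous_matrix(value_table(), ["ENSG001"], None, ["ghost"])

    def test_all_unmappable_rejected(self):
        with pytest.raises(ValueError):
            build_continuous_matrix(value_table(), ["NOPE"], None, ["c0"])
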