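import numpy as np
import pytest

from nnsym import (PointPattern, build_nnct, build_qsym, nearest_neighbors,
                   reduce_qsym)
from nnsym.datasets import load_nnct, load_qsym
from nnsym.tables import NNCT, QSymmetryTable, read_nnct_csv, read_qsym_csv


class TestNNCT:
    def test_collinear_counts(self, collinear3):
        t = build_nnct(collinear3, nearest_neighbors(collinear3))
        # labels A,B,A with nn (1,0,1): A->B twice, B->A once
        assert t.counts[0, 1] == 2 and t.counts[1, 0] == 1
        assert t.counts[0, 0] == 0 and t.counts[1, 1] == 0

    def test_corner_counts(self, corners):
        t = build_nnct(corners, nearest_neighbors(corners))
        assert t.counts[0, 0] == 2 and t.counts[1, 0] == 2
        assert t.counts[0, 1] == 0 and t.counts[1, 1] == 0

    def test_single_class_rejected(self):
        p = PointPattern(coords=[[0, 0], [1, 1]], labels=["A", "A"])
        with pytest.raises(ValueError, match="2 classes"):
            build_nnct(p, nearest_neighbors(p))

    def test_row_sums_are_class_sizes(self, make_pattern):
        for _ in range(50):
            pat = make_pattern(30, k=3)
            t = build_nnct(pat, nearest_neighbors(pat))
            assert np.array_equal(t.class_sizes, pat.class_sizes)
            assert t.column_sums.sum() == pat.n

    def test_class_order_is_first_appearance(self):
        p = PointPattern(coords=np.random.default_rng(0).uniform(size=(6, 2)),
                         labels=["zebra", "ant", "zebra", "ant", "ant", "zebra"])
        assert p.classes == ["zebra", "ant"]


class TestQSymmetryTable:
    def test_collinear_rows(self, collinear3):
        t = build_qsym(collinear3, nearest_neighbors(collinear3))
        # in-degrees (1,2,0): A row has one 0 and one 1, B row one 2
        assert t.counts[0, 0] == 1 and t.counts[0, 1] == 1
        assert t.counts[1, 2] == 1
        assert t.counts.sum() == 3

    def test_all_mutual_pairs_fill_column_one(self):
        coords = [[0, 0], [0.1, 0], [5, 5], [5.1, 5]]
        p = PointPattern(coords=coords, labels=list("ABAB"))
        t = build_qsym(p, nearest_neighbors(p))
        assert t.counts[:, 1].sum() == 4

    def test_overflow_pooled_into_last_column(self, make_pattern):
        pat = make_pattern(40)
        g = nearest_neighbors(pat)
        t = build_qsym(pat, g, m_max=2)
        assert t.counts.shape[1] == 3
        assert t.counts.sum() == 40

    def test_full_table_moment_identity(self, make_pattern):
        pat = make_pattern(60)
        t = build_qsym(pat, nearest_neighbors(pat))
        m = np.arange(t.counts.shape[1])
        assert (t.column_sums * m).sum() == pat.n


class TestReduction:
    def test_paper_default_merges_from_two(self):
        full = QSymmetryTable(np.array([[5, 6, 1, 2, 3, 4],
                                        [1, 1, 1, 1, 1, 1]]), ["A", "B"])
        red = reduce_qsym(full)
        assert red.counts.shape == (2, 3)
        assert red.counts[0, 2] == 1 + 2 + 3 + 4
        assert red.merge_boundary == 2

    def test_reduction_preserves_totals(self, make_pattern):
        pat = make_pattern(50, k=3)
        full = build_qsym(pat, nearest_neighbors(pat))
        red = reduce_qsym(full)
        assert np.array_equal(red.class_sizes, full.class_sizes)
        assert red.n == full.n

    def test_double_reduction_rejected(self):
        t = QSymmetryTable(np.ones((2, 6), int), ["A", "B"])
        red = reduce_qsym(t)
        with pytest.raises(ValueError, match="already reduced"):
            reduce_qsym(red)

    def test_expected_count_rule_keeps_satisfying_table(self):
        t = QSymmetryTable(np.full((3, 3), 30, int), list("ABC"))
        red = reduce_qsym(t, rule="expected-count")
        assert red.counts.shape == (3, 3)

    def test_expected_count_rule_stops_at_two_columns(self):
        counts = np.zeros((3, 6), int)
        counts[:, 0] = 2
        counts[:, 1] = 1
        red = reduce_qsym(QSymmetryTable(counts, list("ABC")),
                          rule="expected-count")
        assert red.counts.shape[1] == 2


class TestIO:
    def test_nnct_roundtrip(self, tmp_path):
        t = load_nnct("lansing")
        path = tmp_path / "nnct.csv"
        t.to_csv(path)
        back = read_nnct_csv(path)
        assert np.array_equal(back.counts, t.counts)
        assert back.classes == t.classes

    def test_qsym_roundtrip_preserves_reduction(self, tmp_path):
        t = load_qsym("lansing_qsym")
        assert t.reduced and t.merge_boundary == 2
        path = tmp_path / "qsym.csv"
        t.to_csv(path)
        back = read_qsym_csv(path)
        assert np.array_equal(back.counts, t.counts)
        assert back.reduced and back.merge_boundary == 2

    def test_lansing_qsym_values(self):
        t = load_qsym("lansing_qsym")
        assert t.counts.tolist() == [[37, 67, 31], [113, 259, 142],
                                     [143, 220, 85]]
        assert t.class_sizes.tolist() == [135, 514, 448]

    def test_json_roundtrip(self):
        t = load_nnct("lansing")
        back = NNCT.from_json(t.to_json())
        assert np.array_equal(back.counts, t.counts)

    def test_empty_table_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("class,A,B\n")
        with pytest.raises(ValueError, match="no data rows"):
            read_nnct_csv(path)

    def test_pattern_reader(self, tmp_path):
        path = tmp_path / "pat.csv"
        path.write_text("x,y,label\n0,0,A\n1,0,B\n2,0,A\n")
        pat = PointPattern.from_csv(path)
        assert pat.n == 3 and pat.classes == ["A", "B"]
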