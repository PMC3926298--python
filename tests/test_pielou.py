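import numpy as np
import pytest
from scipy import stats

from nnsym import (QSymmetryTable, binomial_symmetry, bowker_symmetry,
                   mcnemar_symmetry, pielou_q_symmetry)
from nnsym.datasets import load_nnct, load_qsym
from nnsym.pielou import CONSERVATIVE_WARNING
from nnsym.tables import NNCT


class TestMcNemar:
    def test_corrected_statistic(self):
        r = mcnemar_symmetry(35, 28, correction=True)
        assert r.statistic == pytest.approx(36 / 63)

    def test_symmetric_input_uncorrected(self):
        r = mcnemar_symmetry(5, 5, correction=False)
        assert r.statistic == 0 and r.p_value == 1

    def test_symmetric_input_corrected(self):
        assert mcnemar_symmetry(5, 5).statistic == pytest.approx(0.1)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="no mixed NN pairs"):
            mcnemar_symmetry(0, 0)

    def test_carries_conservativeness_warning(self):
        assert CONSERVATIVE_WARNING in mcnemar_symmetry(4, 9).warnings


class TestBinomial:
    def test_exact_two_sided_enumeration(self):
        # BIN(3, 1/2): outcomes {0,3} have probability 1/8 each
        assert binomial_symmetry(3, 0).p_value == pytest.approx(0.25)

    def test_balanced_is_mode(self):
        assert binomial_symmetry(7, 7).p_value == pytest.approx(1.0)

    def test_one_sided_full_support(self):
        assert binomial_symmetry(0, 3, sidedness="greater").p_value == 1.0

    def test_z_statistic_reported(self):
        r = binomial_symmetry(9, 4)
        assert r.extras["Z_I"] == pytest.approx((9 - 4) / np.sqrt(13))

    def test_doubled_tail_variant(self):
        p1 = binomial_symmetry(8, 2).p_value
        p2 = binomial_symmetry(8, 2, doubled=True).p_value
        assert p2 == pytest.approx(2 * stats.binom.cdf(2, 10, 0.5))
        assert 0 < p1 <= 1 and 0 < p2 <= 1


class TestBowker:
    def test_symmetric_table_statistic_zero(self):
        c = np.array([[3, 4, 5], [4, 2, 6], [5, 6, 1]])
        r = bowker_symmetry(NNCT(c, list("ABC")), correction=False)
        assert r.statistic == 0 and r.p_value == 1 and r.df == 3

    def test_two_classes_reduces_to_mcnemar(self):
        t = NNCT(np.array([[10, 7], [3, 12]]), ["A", "B"])
        assert bowker_symmetry(t).statistic == pytest.approx(
            mcnemar_symmetry(7, 3).statistic)

    def test_lansing_uncorrected_value(self):
        # independently computed from the published 3x3 NNCT
        r = bowker_symmetry(load_nnct("lansing"), correction=False)
        expected = 49 / 63 + 9 / 97 + 41 ** 2 / 281
        assert r.statistic == pytest.approx(expected, abs=1e-9)
        assert r.df == 3

    def test_empty_pair_dropped_from_df(self):
        c = np.array([[0, 5, 0], [3, 0, 0], [0, 0, 0]])
        r = bowker_symmetry(NNCT(c, list("ABC")), correction=False)
        assert r.df == 1

    def test_invariant_under_simultaneous_permutation(self, rng):
        c = rng.integers(0, 30, size=(4, 4))
        t = NNCT(c, list("ABCD"))
        perm = rng.permutation(4)
        tp = NNCT(c[np.ix_(perm, perm)], [list("ABCD")[i] for i in perm])
        assert bowker_symmetry(t).statistic == pytest.approx(
            bowker_symmetry(tp).statistic)


class TestPielouQSymmetry:
    def test_lansing_overall(self):
        r = pielou_q_symmetry(load_qsym("lansing_qsym"))
        assert r.statistic == pytest.approx(16.595, abs=0.005)
        assert r.df == 4

    def test_restricted_maple_whiteoak(self):
        r = pielou_q_symmetry(load_qsym("lansing_pair_qsym_maple_wo"))
        assert r.statistic == pytest.approx(10.806, abs=0.005)
        assert r.df == 2

    def test_proportional_rows_give_zero(self):
        t = QSymmetryTable(np.array([[10, 20, 10], [5, 10, 5]]), ["A", "B"],
                           reduced=True, merge_boundary=2)
        assert pielou_q_symmetry(t).statistic == pytest.approx(0.0)

    def test_zero_columns_dropped_with_df_reduction(self):
        t = QSymmetryTable(np.array([[10, 20, 0], [5, 10, 0]]), ["A", "B"])
        r = pielou_q_symmetry(t)
        assert r.df == 1
        assert any("zero-total" in w for w in r.warnings)

    def test_matches_generic_pearson_routine(self, rng):
        # dual route: independent generic contingency chi-square
        for _ in range(100):
            c = rng.integers(1, 40, size=(rng.integers(2, 5),
                                          rng.integers(2, 7)))
            t = QSymmetryTable(c, [f"c{i}" for i in range(c.shape[0])])
            ours = pielou_q_symmetry(t)
            ref = stats.chi2_contingency(c, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.df == ref.dof
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_row_permutation_invariance(self, rng):
        c = rng.integers(1, 30, size=(3, 3))
        t1 = QSymmetryTable(c, list("ABC"))
        t2 = QSymmetryTable(c[[2, 0, 1]], list("CAB"))
        assert pielou_q_symmetry(t1).statistic == pytest.approx(
            pielou_q_symmetry(t2).statistic)
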