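import itertools

import numpy as np
import pytest

from nnsym import (NNCT, PointPattern, build_nnct, dixon_overall, dixon_z,
                   dixon_z_pairwise, nearest_neighbors, nnct_cell_covariance,
                   rl_enumeration_oracle, rl_moments, symmetry_vector,
                   ts_covariance)
from conftest import random_pattern


class TestTupleProbabilities:
    def test_pair_probability(self):
        m = rl_moments([2, 2], Q=4, R=2)
        assert m.tuple_probability((0, 1)) == pytest.approx(4 / 12)

    def test_singleton_class_higher_orders_vanish(self):
        m = rl_moments([1, 3], Q=2, R=2)
        assert m.tuple_probability((0, 0)) == 0.0

    def test_quartet_probability_closed_form(self):
        m = rl_moments([5, 7], Q=6, R=4)
        n1, n2, n = 5, 7, 12
        expect = n1 * (n1 - 1) * n2 * (n2 - 1) / (n * (n - 1) * (n - 2) * (n - 3))
        assert m.tuple_probability((0, 0, 1, 1)) == pytest.approx(expect)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            rl_moments([1, 2], Q=0, R=2)


class TestMomentsAgainstOracle:
    def test_corners_variance_matches_enumeration(self, corners):
        g = nearest_neighbors(corners)
        m = rl_moments([2, 2], g.Q, g.R)
        o = rl_enumeration_oracle(g, [2, 2])
        assert m.var(0, 1) == pytest.approx(o["Var"][0, 1], abs=1e-12)
        assert m.expected(0, 1) == pytest.approx(o["E"][0, 1], abs=1e-12)

    def test_all_cases_match_enumeration_small_patterns(self, rng):
        # analytic E / Var / Cov vs exhaustive relabeling, all class splits
        for trial in range(12):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 5))
            pat = random_pattern(rng, n, k=min(k, n - 1))
            g = nearest_neighbors(pat)
            sizes = pat.class_sizes
            m = rl_moments(sizes, g.Q, g.R)
            o = rl_enumeration_oracle(g, sizes)
            kk = len(sizes)
            for i, j in itertools.permutations(range(kk), 2):
                assert m.expected(i, j) == pytest.approx(o["E"][i, j], abs=1e-12)
                for a, b in itertools.permutations(range(kk), 2):
                    assert nnct_cell_covariance(m, i, j, a, b) == pytest.approx(
                        o["Cov"][i, j, a, b], abs=1e-12)

    def test_case6_difference_covariance_exactly_zero(self, rng):
        pat = random_pattern(rng, 8, k=4)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        assert ts_covariance(m, 0, 1, 2, 3) == 0.0

    def test_enumeration_cap(self, make_pattern):
        pat = make_pattern(30)
        g = nearest_neighbors(pat)
        with pytest.raises(ValueError, match="cap"):
            rl_enumeration_oracle(g, pat.class_sizes, cap=100)


class TestArcPairDecomposition:
    def test_coincidence_class_counts(self, make_pattern):
        # ordered arc pairs split into (n, R, Q, n-R, n-R, remainder)
        for n in (10, 25, 40):
            g = nearest_neighbors(make_pattern(n))
            nn = g.nn_index
            same = refl = shared = chain1 = chain2 = other = 0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        same += 1
                    elif nn[i] == j and nn[j] == i:
                        refl += 1
                    elif nn[i] == nn[j]:
                        shared += 1
                    elif nn[i] == j:
                        chain1 += 1
                    elif nn[j] == i:
                        chain2 += 1
                    else:
                        other += 1
            assert same == n
            assert refl == g.R
            assert shared == g.Q
            assert chain1 == chain2 == n - g.R
            assert other == n * n - 3 * n - g.Q + g.R


class TestDixonTests:
    def test_symmetric_table_z_zero(self, make_pattern):
        pat = make_pattern(20)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        t = NNCT(np.array([[4, 6], [6, 4]]), pat.classes)
        r = dixon_z(t, m)
        assert r.statistic == 0 and r.p_value == 1

    def test_sign_follows_offdiagonal_difference(self, make_pattern):
        pat = make_pattern(30)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        t = build_nnct(pat, g)
        if t.counts[0, 1] != t.counts[1, 0]:
            r = dixon_z(t, m)
            assert np.sign(r.statistic) == np.sign(
                t.counts[0, 1] - t.counts[1, 0])

    def test_pairwise_matches_two_class(self, make_pattern):
        pat = make_pattern(24)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        t = build_nnct(pat, g)
        assert dixon_z(t, m).statistic == dixon_z_pairwise(t, m, 0, 1).statistic

    def test_pairwise_variance_matches_oracle(self, rng):
        pat = random_pattern(rng, 8, k=3)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        o = rl_enumeration_oracle(g, pat.class_sizes)
        var_an = (nnct_cell_covariance(m, 0, 1, 0, 1)
                  + nnct_cell_covariance(m, 1, 0, 1, 0)
                  - 2 * nnct_cell_covariance(m, 0, 1, 1, 0))
        var_or = (o["Var"][0, 1] + o["Var"][1, 0] - 2 * o["Cov"][0, 1, 1, 0])
        assert var_an == pytest.approx(var_or, abs=1e-12)

    def test_overall_equals_z_squared_for_two_classes(self, make_pattern):
        pat = make_pattern(30)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        t = build_nnct(pat, g)
        r2 = dixon_overall(t, m)
        z = dixon_z(t, m)
        assert r2.statistic == pytest.approx(z.statistic ** 2)
        assert r2.df == 1

    def test_overall_symmetric_table_zero(self, make_pattern):
        pat = make_pattern(21, k=3)
        g = nearest_neighbors(pat)
        m = rl_moments(pat.class_sizes, g.Q, g.R)
        c = np.array([[3, 2, 2], [2, 3, 2], [2, 2, 3]])
        r = dixon_overall(NNCT(c, pat.classes), m)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_sigma_sym_positive_semidefinite(self, rng):
        for k in (2, 3, 4):
            for _ in range(25):
                pat = random_pattern(rng, int(rng.integers(4 * k, 60)), k=k)
                g = nearest_neighbors(pat)
                m = rl_moments(pat.class_sizes, g.Q, g.R)
                t = build_nnct(pat, g)
                sv = symmetry_vector(t, m)
                assert np.linalg.eigvalsh(sv.sigma).min() > -1e-10
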