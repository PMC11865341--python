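from fractions import Fraction
from math import factorial

import numpy as np
import pytest
import scipy.stats as st

from spatzone.aggregation import (
    classify_significant, connected_components, fisher_contingency,
    fisher_exact_p, same_type_density, select_positive_bins,
    significance_stars,
)
from spatzone.io import ParameterError

from conftest import make_scores


class TestSelectPositiveBins:
    def test_five_percent_removed_from_nonnegative_scores(self, rng):
        sv = make_scores(rng.uniform(0, 1, 1000))
        pos = select_positive_bins(sv, 0.05)
        assert len(pos) == 950
        assert pos.n_negative_removed == 0
        assert pos.n_quantile_removed == 50

    def test_all_negative_gives_empty_set_with_warning(self, caplog):
        sv = make_scores([-1.0, -0.5, -2.0])
        with caplog.at_level("WARNING", logger="spatzone"):
            pos = select_positive_bins(sv)
        assert len(pos) == 0
        assert any("no bins retained" in r.message for r in caplog.records)

    def test_sequential_filter_oracle(self, rng):
        # 100 negative + 100 non-negative -> 100 - floor(5) = 95 retained
        values = np.concatenate([rng.uniform(-2, -0.01, 100),
                                 rng.uniform(0, 1, 100)])
        pos = select_positive_bins(make_scores(rng.permutation(values)), 0.05)
        assert len(pos) == 95
        assert pos.n_negative_removed == 100
        assert pos.n_quantile_removed == 5
        assert (pos.scores >= 0).all()

    def test_quantile_removes_lowest_scores(self):
        sv = make_scores(np.arange(100, dtype=float))
        pos = select_positive_bins(sv, 0.10)
        assert sorted(pos.scores) == list(np.arange(10.0, 100.0))

    def test_quantile_first_order(self):
        # 10 bins: 4 negative; quantile_first removes floor(0.1*10)=1 globally
        # (the most negative), then the remaining 3 negatives
        sv = make_scores([-4.0, -3.0, -2.0, -1.0, 1, 2, 3, 4, 5, 6])
        seq = select_positive_bins(sv, 0.10)
        first = select_positive_bins(sv, 0.10, order="quantile_first")
        assert len(seq) == 6 and seq.n_quantile_removed == 0
        assert len(first) == 6
        assert first.n_quantile_removed == 1 and first.n_negative_removed == 3


class TestSameTypeDensity:
    def test_interior_lattice_closed_form(self):
        # fully occupied lattice: interior bin has 4 neighbors at 1, 4 at sqrt2
        xs, ys = np.meshgrid(np.arange(11), np.arange(11))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        sv = make_scores(np.ones(len(coords)))
        pos = select_positive_bins(sv, 0.0, coords=coords)
        density, truncated = same_type_density(pos, k=8)
        center = np.flatnonzero((coords == [5, 5]).all(axis=1))[0]
        assert density[center] == pytest.approx((1 + np.sqrt(2)) / 2, abs=1e-12)
        assert not truncated.any()

    def test_two_bins_truncated_k(self, caplog):
        sv = make_scores([1.0, 1.0])
        pos = select_positive_bins(sv, 0.0, coords=np.array([[0, 0], [3, 4]]))
        with caplog.at_level("WARNING", logger="spatzone"):
            density, truncated = same_type_density(pos, k=8)
        assert density == pytest.approx([5.0, 5.0])
        assert truncated.all()

    def test_singleton_flagged_not_error(self):
        sv = make_scores([1.0])
        pos = select_positive_bins(sv, 0.0, coords=np.array([[2, 2]]))
        density, truncated = same_type_density(pos)
        assert np.isnan(density[0]) and truncated[0]

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.integers(0, 40, (30, 2))
        coords = np.unique(coords, axis=0)
        sv = make_scores(np.ones(len(coords)))
        pos = select_positive_bins(sv, 0.0, coords=coords)
        density, _ = same_type_density(pos, k=8)
        for i in range(len(coords)):
            d = np.hypot(*(coords - coords[i]).T)
            d = np.sort(np.delete(d, i))[:8]
            assert density[i] == pytest.approx(d.mean(), abs=1e-12)

    def test_translation_and_rotation_invariance(self, rng):
        coords = np.unique(rng.integers(0, 30, (40, 2)), axis=0)
        sv = make_scores(np.ones(len(coords)))
        base, _ = same_type_density(
            select_positive_bins(sv, 0.0, coords=coords))
        shifted, _ = same_type_density(
            select_positive_bins(sv, 0.0, coords=coords + [17, -3]))
        rotated, _ = same_type_density(  # 90 degrees: (x, y) -> (-y, x)
            select_positive_bins(sv, 0.0, coords=np.column_stack(
                [-coords[:, 1], coords[:, 0]])))
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(rotated, base, atol=1e-9)


def union_find_components(coords):
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pts = np.asarray(coords)
    for i in range(len(pts)):
        cheb = np.abs(pts - pts[i]).max(axis=1)
        for j in np.flatnonzero((cheb <= 1)):
            if j != i:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(len(pts)):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


class TestConnectedComponents:
    def test_hand_enumerated_example(self):
        coords = np.array([[0, 0], [0, 1], [1, 1], [10, 10]])
        sv = make_scores(np.ones(4))
        pos = select_positive_bins(sv, 0.0, coords=coords)
        res = connected_components(pos)
        assert res.areas == [3]
        assert res.proportion == pytest.approx(3 / 4)
        assert set(res.components[0]) == {"b0", "b1", "b2"}

    def test_no_adjacent_bins_gives_zero_components(self):
        coords = np.array([[0, 0], [5, 5], [10, 0]])
        pos = select_positive_bins(make_scores(np.ones(3)), 0.0, coords=coords)
        res = connected_components(pos)
        assert res.components == [] and res.proportion == 0.0

    def test_diagonal_strand_connected_under_8_not_4(self):
        coords = np.array([[0, 0], [1, 1], [2, 2]])
        pos = select_positive_bins(make_scores(np.ones(3)), 0.0, coords=coords)
        assert connected_components(pos, adjacency=8).areas == [3]
        assert connected_components(pos, adjacency=4).areas == []

    def test_matches_union_find_oracle(self, rng):
        coords = np.unique(rng.integers(0, 60, (2000, 2)), axis=0)
        sv = make_scores(np.ones(len(coords)))
        pos = select_positive_bins(sv, 0.0, coords=coords)
        res = connected_components(pos)
        mine = {frozenset(pos.bin_ids.index(b) for b in comp)
                for comp in res.components}
        assert mine == union_find_components(coords)

    def test_partition_invariant_under_translation_and_relabeling(self, rng):
        coords = np.unique(rng.integers(0, 25, (150, 2)), axis=0)
        sv = make_scores(np.ones(len(coords)))
        pos = select_positive_bins(sv, 0.0, coords=coords)
        base = connected_components(pos)
        perm = rng.permutation(len(coords))
        sv_p = make_scores(np.ones(len(coords)))
        pos_p = select_positive_bins(sv_p, 0.0, coords=coords[perm] + [100, 7])
        permuted = connected_components(pos_p)
        to_orig = {f"b{i}": f"b{perm[i]}" for i in range(len(coords))}
        assert ({frozenset(c) for c in base.components}
                == {frozenset(to_orig[b] for b in c) for c in permuted.components})

    def test_proportion_bounds(self, rng):
        coords = np.unique(rng.integers(0, 30, (300, 2)), axis=0)
        pos = select_positive_bins(make_scores(np.ones(len(coords))), 0.0,
                                   coords=coords)
        res = connected_components(pos)
        assert 0.0 <= res.proportion <= 1.0
        assert sum(res.areas) <= len(pos)


class TestClassifySignificant:
    def test_strict_boundary_at_500(self):
        assert classify_significant([500]) == [False]
        assert classify_significant([501]) == [True]

    def test_empty_input(self):
        assert classify_significant([]) == []

    def test_mixed_areas(self):
        areas = [2, 30, 31, 499, 500, 501]
        assert classify_significant(areas) == [False] * 5 + [True]


def oracle_fisher(table):
    """Exact two-sided Fisher p via factorial Fractions, fully enumerated."""
    (a, b), (c, d) = table
    n = a + b + c + d

    def prob(a_):
        b_, c_ = a + b - a_, a + c - a_
        d_ = n - a_ - b_ - c_
        if min(b_, c_, d_) < 0:
            return None
        f = factorial
        return Fraction(f(a + b) * f(c + d) * f(a + c) * f(b + d),
                        f(n) * f(a_) * f(b_) * f(c_) * f(d_))

    p_obs = prob(a)
    total = Fraction(0)
    for a_ in range(n + 1):
        p = prob(a_)
        if p is not None and p <= p_obs:
            total += p
    return total


class TestFisherExact:
    def test_spec_example_table(self):
        assert fisher_exact_p([[3, 1], [1, 3]]) == pytest.approx(
            0.485714285714, abs=1e-10)

    def test_identical_conditions_p_one(self):
        assert fisher_exact_p([[5, 5], [5, 5]]) == 1.0

    def test_extreme_table_closed_form(self):
        from math import comb
        expected = float(Fraction(2, comb(20, 10)))
        assert fisher_exact_p([[0, 10], [10, 0]]) == pytest.approx(
            expected, abs=1e-15)

    def test_zero_margin_convention(self, caplog):
        with caplog.at_level("WARNING", logger="spatzone"):
            assert fisher_exact_p([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_oracle_small_margins(self, rng):
        # random sample of tables with total <= 30 (margins <= 30)
        for _ in range(300):
            t = rng.integers(0, 8, (2, 2))
            assert fisher_exact_p(t) == pytest.approx(
                float(oracle_fisher(t.tolist())), abs=1e-12)

    def test_matches_scipy_on_tables_without_probability_ties(self, rng):
        for _ in range(50):
            t = rng.integers(0, 40, (2, 2)) + rng.integers(1, 5, (2, 2))
            ours = fisher_exact_p(t)
            ref = st.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_stars_mapping(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(9e-4) == "***"
        assert significance_stars(9e-5) == "****"


class TestFisherContingency:
    def test_dichotomizes_spots_by_component_size(self):
        # condition A: one 3x3 block (area 9) plus an isolated bin
        xs, ys = np.meshgrid(np.arange(3), np.arange(3))
        coords_a = np.vstack([np.column_stack([xs.ravel(), ys.ravel()]),
                              [[20, 20]]])
        pos_a = select_positive_bins(make_scores(np.ones(10)), 0.0,
                                     coords=coords_a)
        res_a = connected_components(pos_a, condition="SPF")
        # condition B: five isolated bins
        coords_b = np.array([[0, 0], [5, 0], [10, 0], [15, 0], [20, 0]])
        pos_b = select_positive_bins(make_scores(np.ones(5)), 0.0,
                                     coords=coords_b)
        res_b = connected_components(pos_b, condition="GF")
        c = fisher_contingency(res_a, res_b, threshold=5)
        assert c.table.tolist() == [[9, 1], [0, 5]]
        assert c.p_value == pytest.approx(float(oracle_fisher([[9, 1], [0, 5]])),
                                          abs=1e-12)
        assert c.conditions == ("SPF", "GF")

    def test_mismatched_adjacency_rejected(self):
        coords = np.array([[0, 0], [0, 1]])
        pos = select_positive_bins(make_scores(np.ones(2)), 0.0, coords=coords)
        a = connected_components(pos, adjacency=8)
        b = connected_components(pos, adjacency=4)
        with pytest.raises(ParameterError, match="adjacency"):
            fisher_contingency(a, b)
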