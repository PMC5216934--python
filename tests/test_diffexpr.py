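"""Differential expression: normalization, paired tests, screening, clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from hypothesis import given, settings, strategies as hst

from netkit.dataio import DataIOError
from netkit.diffexpr import (
    apply_filter,
    bh_fdr,
    cluster_order,
    de_test,
    fc_tier,
    quantile_normalize,
)

from conftest import (
    brute_force_bh,
    naive_average_linkage,
    paired_t_oracle,
    toy_matrix,
)


class TestQuantileNormalize:
    def test_hand_computed_toy(self):
        m = toy_matrix(np.array([[1.0, 4.0], [2.0, 6.0], [3.0, 8.0]]).reshape(3, 2),
                       n_pairs=1)
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 4.0, 5.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 4.0, 5.5])

    def test_identical_columns_are_fixed_point(self, rng):
        col = rng.normal(size=10)
        m = toy_matrix(np.column_stack([col, col, col, col]), n_pairs=2)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   m.values.to_numpy())

    def test_column_sums_equal_after_normalization(self, rng):
        m = toy_matrix(rng.normal(8, 2, size=(50, 6)), n_pairs=3)
        sums = quantile_normalize(m).values.sum(axis=0)
        np.testing.assert_allclose(sums, sums.iloc[0])

    def test_ties_mapped_identically(self):
        vals = np.array([[5.0, 1.0], [5.0, 2.0], [1.0, 3.0], [7.0, 4.0]])
        out = quantile_normalize(toy_matrix(vals, n_pairs=1)).values.to_numpy()
        assert out[0, 0] == out[1, 0]  # tied inputs share one output value

    def test_single_sample_rejected(self):
        m = toy_matrix(np.zeros((3, 2)), n_pairs=1)
        m.values = m.values.iloc[:, :1]
        with pytest.raises(Exception):
            quantile_normalize(m)


class TestDeTest:
    def test_zero_differences_are_ns(self):
        vals = np.tile(np.array([5.0, 5.0, 5.0, 5.0]), (3, 1))
        table = de_test(toy_matrix(vals, n_pairs=2))
        assert (table["direction"] == "ns").all()
        assert (table["log2fc"] == 0).all()
        assert table["zero_var"].all()
        assert (table["p_value"] == 1.0).all()

    def test_constant_shift_recovered(self, rng):
        n_pairs = 6
        tumor = 8.0 + 2.0 + rng.normal(0, 0.01, n_pairs)
        vals = np.empty((1, 2 * n_pairs))
        vals[0, ::2] = tumor
        vals[0, 1::2] = 8.0
        table = de_test(toy_matrix(vals, n_pairs=n_pairs))
        assert table.loc[0, "log2fc"] == pytest.approx(2.0, abs=0.05)
        assert table.loc[0, "p_value"] < 1e-6
        assert table.loc[0, "direction"] == "up"

    def test_matches_textbook_paired_t(self, rng):
        vals = rng.normal(8, 1, size=(100, 10))
        m = toy_matrix(vals, n_pairs=5)
        table = de_test(m)
        tum, nrm = m.paired_columns()
        for i, tid in enumerate(m.transcript_ids):
            expected = paired_t_oracle(m.values.loc[tid, tum].to_numpy(),
                                       m.values.loc[tid, nrm].to_numpy())
            assert table.loc[i, "p_value"] == pytest.approx(expected,
                                                            abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(DataIOError, match="pairs"):
            de_test(toy_matrix(np.zeros((2, 2)), n_pairs=1))


class TestBhFdr:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.03])), [0.03])

    def test_worked_step_up_example(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=40))
    def test_equals_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestScreening:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "log2fc",
                                           "p_value", "fdr"])

    def test_fold_change_boundary_inclusive(self):
        rec = self._records([("a", 1.0, 0.01, 0.01)])  # FC exactly 2.0
        up, down = apply_filter(rec)
        assert list(up["transcript_id"]) == ["a"] and down.empty

    def test_p_boundary_strict(self):
        rec = self._records([("a", 2.0, 0.05, 0.01)])  # p exactly 0.05
        up, down = apply_filter(rec)
        assert up.empty and down.empty

    def test_fdr_boundary_strict(self):
        rec = self._records([("a", 2.0, 0.01, 0.05)])
        up, down = apply_filter(rec)
        assert up.empty and down.empty

    def test_empty_input(self):
        up, down = apply_filter(self._records([]))
        assert up.empty and down.empty

    def test_fc_tier_membership(self):
        rec = self._records([("big", 4.0, 1e-4, 1e-4),
                             ("small", 1.5, 1e-4, 1e-4)])
        tier_up, _ = fc_tier(rec, fc_min=10)
        assert list(tier_up["transcript_id"]) == ["big"]  # FC 16 in, 2.83 out

    def test_tier_nested_in_filter(self, rng):
        rows = [(f"t{i}", rng.normal(0, 2), rng.uniform(0, 0.1),
                 rng.uniform(0, 0.1)) for i in range(200)]
        rec = self._records(rows)
        up, down = apply_filter(rec)
        tu, td = fc_tier(rec, fc_min=10)
        assert set(tu["transcript_id"]) <= set(up["transcript_id"])
        assert set(td["transcript_id"]) <= set(down["transcript_id"])


class TestClusterOrder:
    def test_identical_profiles_adjacent(self, rng):
        base = rng.normal(size=8)
        vals = np.vstack([base, rng.normal(size=(3, 8)), base])
        m = toy_matrix(vals, n_pairs=4, ids=["dup1", "r1", "r2", "r3", "dup2"])
        order, _, _ = cluster_order(m)
        i, j = order.index("dup1"), order.index("dup2")
        assert abs(i - j) == 1  # r = 1 means distance 0, merged first

    def test_negated_profile_distance_two(self, rng):
        from netkit.diffexpr import _correlation_distance

        x = rng.normal(size=8)
        dist, _ = _correlation_distance(np.vstack([x, -x]))
        assert dist[0, 1] == pytest.approx(2.0)

    def test_constant_row_flagged(self, rng):
        vals = np.vstack([np.full(8, 3.0), rng.normal(size=(2, 8))])
        m = toy_matrix(vals, n_pairs=4, ids=["const", "a", "b"])
        order, _, flagged = cluster_order(m)
        assert flagged == ["const"]
        assert set(order) == {"const", "a", "b"}

    def test_merge_structure_matches_naive_agglomeration(self, rng):
        from netkit.diffexpr import _correlation_distance

        rows = rng.normal(size=(6, 8))
        dist, _ = _correlation_distance(rows)
        naive = naive_average_linkage(dist)
        Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
        # rebuild merge steps from the scipy linkage matrix
        members = {i: frozenset([i]) for i in range(6)}
        for step, (a, b, h, _cnt) in enumerate(Z):
            sa, sb = members[int(a)], members[int(b)]
            na, nb, nh = naive[step]
            assert {sa, sb} == {na, nb}
            assert h == pytest.approx(nh, abs=1e-10)
            members[6 + step] = sa | sb
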