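"""Densification chain: zero elimination, proportion merging, echelon
reordering, circle finding/reversal and in-place input permutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echelonsnn import (apply_circles_inplace, apply_merge_to_input,
                        build_input_map, build_weight_delay_map,
                        echelon_reorder, find_circles, proportion_merge,
                        reverse_circles, synaptic_oracle, zero_eliminate)
from echelonsnn.densify import CircleSet, MergeRecord
from conftest import random_instance


class TestZeroEliminate:
    def test_keeps_only_nonzero_rows(self):
        reduced, sel = zero_eliminate(np.array([[0, 0], [1, 2]]))
        assert sel.kept == [1]
        assert reduced.tolist() == [[1, 2]]

    def test_all_zero_map_empty_selection(self):
        reduced, sel = zero_eliminate(np.zeros((4, 4), dtype=int))
        assert sel.kept == [] and reduced.shape[0] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matched_elimination_preserves_product(self, rng, seed):
        r = np.random.default_rng(seed)
        b = (r.random((24, 8)) < 0.3) * r.integers(-5, 6, (24, 8))
        a = r.integers(0, 2, (4, 24))
        reduced, sel = zero_eliminate(b)
        assert np.array_equal(a[:, sel.kept] @ reduced, a @ b)


class TestProportionMerge:
    def test_scalar_multiple_rows_collapse(self):
        merged, rec = proportion_merge(np.array([[2, 4, 6], [1, 2, 3]]))
        assert merged.tolist() == [[1, 2, 3]]
        (group,) = rec.groups
        assert group.base_row == 0
        assert dict(group.members) == {0: 2, 1: 1}

    def test_no_proportional_rows_is_identity(self):
        b = np.array([[1, 0], [0, 1], [1, 1]])
        merged, rec = proportion_merge(b)
        assert rec.is_identity and np.array_equal(merged, b)

    def test_sign_flipped_rows_do_not_merge(self):
        merged, rec = proportion_merge(np.array([[1, 2], [-1, -2]]))
        assert rec.is_identity and merged.shape[0] == 2

    def test_overflow_guard_leaves_group_unmerged(self):
        b = np.array([[100, 0], [50, 0]])  # factor sum 150 > 127
        merged, rec = proportion_merge(b, max_factor_sum=127)
        assert rec.is_identity and merged.shape[0] == 2
        merged2, rec2 = proportion_merge(b, max_factor_sum=200)
        assert merged2.tolist() == [[1, 0]] and not rec2.is_identity

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_proportional_rows_preserve_product(self, seed):
        r = np.random.default_rng(seed)
        base = r.integers(-3, 4, (6, 10))
        factors = r.integers(1, 5, 6)
        planted = np.vstack([base, base * factors[:, None]])
        a = r.integers(0, 2, (4, planted.shape[0]))
        merged, rec = proportion_merge(planted)
        assert merged.shape[0] < planted.shape[0]
        a2 = apply_merge_to_input(a, rec)
        assert np.array_equal(a2 @ merged, a @ planted)


class TestApplyMerge:
    def test_empty_record_is_identity(self):
        a = np.arange(12).reshape(3, 4)
        assert np.array_equal(apply_merge_to_input(a, MergeRecord()), a)

    def test_weighted_column_sum(self):
        a = np.array([[1, 0]])  # spike in column 0 only
        merged, rec = proportion_merge(np.array([[2, 4], [1, 2]]))
        out = apply_merge_to_input(a, rec)
        assert out.tolist() == [[2]]  # factor 2 lifts the 1-bit spike


class TestEchelonReorder:
    def test_already_echelon_identity(self):
        b = np.array([[1, 2, 0], [0, 3, 0], [0, 0, 4]])
        e = echelon_reorder(b)
        assert np.array_equal(e.tgt_idx_list, [0, 1, 2])
        assert np.array_equal(e.values, b)

    def test_sort_by_first_nonzero(self):
        # first nonzeros at columns [2, 0, 1] -> emission order rows 1, 2, 0
        b = np.array([[0, 0, 7], [5, 0, 0], [0, 6, 0]])
        e = echelon_reorder(b)
        assert e.values.tolist() == [[5, 0, 0], [0, 6, 0], [0, 0, 7]]
        assert e.tgt_idx_list.tolist() == [2, 0, 1]

    def test_all_zero_rows_placed_last(self):
        b = np.array([[0, 0], [1, 0], [0, 0]])
        e = echelon_reorder(b)
        assert e.values[0].tolist() == [1, 0]
        assert (e.values[1:] == 0).all()
        assert e.boundary.tolist() == [0, 2, 2]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_stable_sort_oracle(self, seed):
        r = np.random.default_rng(seed)
        b = (r.random((30, 20)) < 0.2) * r.integers(-5, 6, (30, 20))
        e = echelon_reorder(b)
        # boundary invariant and zero lower-left region
        assert (np.diff(e.boundary) >= 0).all()
        for row, bd in zip(e.values, e.boundary):
            assert not row[:bd].any()
        # row multiset unchanged, order = stable sort on first nonzero
        first = np.where(b.any(axis=1), (b != 0).argmax(axis=1), b.shape[1])
        order = sorted(range(30), key=lambda i: (first[i], i))
        assert np.array_equal(e.values, b[order])


class TestCircles:
    def test_worked_permutation_example(self):
        cs = find_circles(list(range(6)), [3, 4, 1, 0, 5, 2])
        assert cs.circles_list == [[0, 3], [1, 4, 5, 2]]
        assert cs.circle_count == 2
        rev = reverse_circles(cs)
        assert rev.reversed_circle_list == [[0, 3], [1, 2, 5, 4]]

    def test_identity_permutation_gives_singletons(self):
        cs = find_circles(list(range(5)), list(range(5)))
        assert cs.circles_list == [[i] for i in range(5)]

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            find_circles([0, 1, 2], [0, 0, 2])

    def test_double_reversal_restores_order(self):
        cs = reverse_circles(find_circles(range(6), [3, 4, 1, 0, 5, 2]))
        again = reverse_circles(CircleSet(circles_list=cs.reversed_circle_list))
        assert again.reversed_circle_list == cs.circles_list

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.permutations(list(range(10))))
    def test_matches_textbook_cycle_decomposition(self, tgt):
        cs = find_circles(list(range(10)), tgt)
        # independent follow-the-map oracle
        seen, cycles = set(), []
        for start in range(10):
            if start in seen:
                continue
            cyc, cur = [], start
            while cur not in seen:
                seen.add(cur)
                cyc.append(cur)
                cur = tgt[cur]
            cycles.append(cyc)
        assert cs.circles_list == cycles
        flat = [i for c in cs.circles_list for i in c]
        assert sorted(flat) == list(range(10))  # partition


class TestApplyCircles:
    def test_identity_circles_leave_map_unchanged(self):
        a = np.arange(20).reshape(4, 5)
        cs = reverse_circles(find_circles(range(5), range(5)))
        out, moves = apply_circles_inplace(a.copy(), cs, count_moves=True)
        assert np.array_equal(out, a) and moves == 0

    def test_equals_gather_oracle(self):
        tgt = [3, 4, 1, 0, 5, 2]
        a = np.arange(24).reshape(4, 6)
        want = np.empty_like(a)
        want[:, tgt] = a  # out-of-place gather: column tgt[s] <- column s
        cs = reverse_circles(find_circles(range(6), tgt))
        out = apply_circles_inplace(a.copy(), cs)
        assert np.array_equal(out, want)

    def test_round_trip_with_inverse_permutation(self, rng):
        tgt = rng.permutation(12)
        inv = np.empty(12, dtype=int)
        inv[tgt] = np.arange(12)
        a = rng.integers(0, 2, (8, 12))
        cs = reverse_circles(find_circles(range(12), tgt))
        cs_inv = reverse_circles(find_circles(range(12), inv))
        out = apply_circles_inplace(apply_circles_inplace(a.copy(), cs), cs_inv)
        assert np.array_equal(out, a)

    @pytest.mark.parametrize("seed", range(5))
    def test_move_budget(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 40))
        tgt = r.permutation(n)
        cs = reverse_circles(find_circles(range(n), tgt))
        a = r.integers(0, 2, (4, n))
        _, moves = apply_circles_inplace(a, cs, count_moves=True)
        assert moves <= n + cs.circle_count

    def test_index_out_of_range(self):
        cs = reverse_circles(find_circles(range(4), [1, 0, 3, 2]))
        with pytest.raises(IndexError):
            apply_circles_inplace(np.zeros((2, 2), dtype=int), cs)


@pytest.mark.parametrize("seed", range(50))
def test_end_to_end_product_preservation(seed):
    """Full densification of B with matched preprocessing of A preserves the
    matrix product (hence the synaptic currents) integer-exactly."""
    model, spikes = random_instance(seed, max_pre=32, max_post=32)
    d = model.delay_range
    wd = build_weight_delay_map(model)
    a = build_input_map(spikes, d - 1, d, model).values
    want = synaptic_oracle(model, spikes, d - 1, d)

    reduced, sel = zero_eliminate(wd)
    merged, rec = proportion_merge(reduced)
    e = echelon_reorder(merged)
    cs = reverse_circles(find_circles(e.src_idx_list, e.tgt_idx_list))

    a2 = apply_merge_to_input(a[:, sel.kept], rec)
    a3 = apply_circles_inplace(a2.copy(), cs)
    got = (a3 @ e.values)[:d, :model.n_post]
    assert np.array_equal(got, want)
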