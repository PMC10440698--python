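"""Alignment splitting, mixed MAC+ARM splitting, core splitting and the
processor-selection heuristic."""

import numpy as np
import pytest

from echelonsnn import (Preference, Processor, Rectangle, SplitMode,
                        alignment_split, choose_processor, core_split,
                        core_split_mixed, echelon_reorder,
                        mixed_alignment_split, residual_m)
from echelonsnn.costmodel import (CostParams, final_block_mac_cycles,
                                  strip_arm_cycles)
from echelonsnn.operands import align
from echelonsnn.splitting import InfeasibleSplitError
from conftest import brute_force_min_area, random_echelon


def covered_cells(rects, shape):
    cover = np.zeros(shape, dtype=int)
    for r in rects:
        cover[r.row_start:r.row_end, r.col_start:r.col_end] += 1
    return cover


class TestAlignmentSplit:
    def test_dense_matrix_single_rectangle(self):
        e = echelon_reorder(np.ones((8, 32), dtype=int))
        (rect,) = alignment_split(e)
        assert (rect.row_start, rect.row_count) == (0, 8)
        assert (rect.col_start, rect.col_count) == (0, 32)

    def test_last_block_only_gives_width_16(self):
        b = np.zeros((8, 32), dtype=int)
        b[:, 20] = 5  # all first nonzeros inside the final 16-column block
        (rect,) = alignment_split(echelon_reorder(b))
        assert rect.col_start == 16 and rect.col_count == 16

    def test_non_echelon_rejected(self):
        e = echelon_reorder(np.eye(8, dtype=int))
        e.boundary = e.boundary[::-1].copy()
        with pytest.raises(ValueError):
            alignment_split(e)

    @pytest.mark.parametrize("seed", range(30))
    def test_area_is_brute_force_minimum(self, seed):
        e = random_echelon(np.random.default_rng(seed))
        rects = alignment_split(e)
        assert sum(r.area for r in rects) == brute_force_min_area(e)

    @pytest.mark.parametrize("seed", range(10))
    def test_rectangles_cover_all_nonzeros_disjointly(self, seed):
        e = random_echelon(np.random.default_rng(100 + seed))
        rects = alignment_split(e)
        rows4 = align(e.n_rows, 4)
        cover = covered_cells(rects, (rows4, align(e.n_cols, 16)))
        assert cover.max(initial=0) <= 1
        nz_r, nz_c = np.nonzero(e.values)
        assert (cover[nz_r, nz_c] == 1).all()


class TestMixedSplit:
    def test_residual_m_convention(self):
        assert residual_m(20) == 4
        assert residual_m(16) == 16
        assert residual_m(1) == 1
        with pytest.raises(ValueError):
            residual_m(0)

    def test_m16_identical_to_pure(self):
        e = random_echelon(np.random.default_rng(0), max_cols=32)
        e2 = echelon_reorder(np.pad(e.values, ((0, 0), (0, 32 - e.n_cols))))
        mac, strip = mixed_alignment_split(e2, true_cols=32)
        assert strip is None
        assert mac == alignment_split(e2)

    def test_single_true_column_strip_is_sixteenth(self):
        b = np.zeros((12, 16), dtype=int)
        b[:10, 0] = 3  # one true column, padded to 16
        e = echelon_reorder(b)
        pure = alignment_split(e)
        mac, strip = mixed_alignment_split(e, true_cols=1)
        assert mac == []
        # every pure rectangle is right-anchored, so each contributes one
        # 16-wide band to the final block
        final_block_area = sum(r.row_count * 16 for r in pure)
        assert strip.area * 16 == final_block_area * 1

    @pytest.mark.parametrize("seed", range(10))
    def test_mixed_coverage_cell_by_cell(self, seed):
        rng = np.random.default_rng(200 + seed)
        e = random_echelon(rng)
        true_cols = e.n_cols
        mac, strip = mixed_alignment_split(e, true_cols)
        rects = mac + ([strip] if strip else [])
        rows4 = align(e.n_rows, 4)
        cover = covered_cells(rects, (rows4, align(e.n_cols, 16)))
        assert cover.max(initial=0) <= 1
        nz_r, nz_c = np.nonzero(e.values[:, :true_cols])
        assert (cover[nz_r, nz_c] == 1).all()

    def test_strip_memory_identity(self):
        """stored(ARM strip) / stored(pure final block) = m / 16 exactly."""
        rng = np.random.default_rng(7)
        e = random_echelon(rng, max_rows=40, max_cols=30)
        m = residual_m(e.n_cols)
        if m == 16:
            pytest.skip("no residual in this draw")
        pure = alignment_split(e)
        mac, strip = mixed_alignment_split(e, e.n_cols)
        cols16 = align(e.n_cols, 16)
        final_block = sum(r.row_count * 16 for r in pure)  # every rect is
        # right-anchored, so each contributes one 16-wide band to the block
        assert strip.area * 16 == final_block * m


class TestCoreSplit:
    def test_two_pe_example(self):
        plan = core_split([Rectangle(0, 8, 0, 16)], per_pe_value_budget=64)
        assert plan.pe_count == 2
        assert plan.per_pe_value_counts == [64, 64]
        for group in plan.pe_groups:
            (frag,) = group
            assert frag.row_count == 4 and frag.col_count == 16

    def test_everything_fits_one_pe(self):
        plan = core_split([Rectangle(0, 8, 0, 16)], per_pe_value_budget=1000)
        assert plan.pe_count == 1
        assert plan.pe_groups[0] == [Rectangle(0, 8, 0, 16)]

    def test_budget_below_one_slice_is_infeasible(self):
        with pytest.raises(InfeasibleSplitError):
            core_split([Rectangle(0, 8, 0, 16)], per_pe_value_budget=63)

    @pytest.mark.parametrize("seed", range(25))
    def test_balance_and_conservation(self, seed):
        rng = np.random.default_rng(seed)
        rects, top = [], 0
        for _ in range(int(rng.integers(1, 6))):
            h = 4 * int(rng.integers(1, 12))
            w = 16 * int(rng.integers(1, 5))
            rects.append(Rectangle(top, h, 0, w))
            top += h
        total = sum(r.area for r in rects)
        widest_slice = max(4 * r.col_count for r in rects)
        budget = int(rng.integers(widest_slice, max(total, widest_slice) + 1))
        plan = core_split(rects, budget)
        assert plan.pe_count == -(-total // budget)
        assert sum(plan.per_pe_value_counts) == total
        assert max(plan.per_pe_value_counts) - min(plan.per_pe_value_counts) \
            <= widest_slice

    def test_mixed_core_split_pairs_mac_and_arm_groups(self):
        mac = [Rectangle(0, 8, 0, 32)]
        strip = Rectangle(0, 8, 32, 5, Processor.ARM)
        plan = core_split_mixed(mac, strip, per_pe_value_budget=160)
        assert plan.mode is SplitMode.MIXED
        assert plan.pe_count == 2
        for group in plan.pe_groups:
            assert any(f.processor is Processor.ARM for f in group)
        total = sum(r.area for r in mac) + strip.area
        assert sum(plan.per_pe_value_counts) == total


class TestChooseProcessor:
    def _echelon(self, rows, cols):
        return echelon_reorder(np.ones((rows, cols), dtype=int))

    def test_no_residual_always_pure(self):
        e = self._echelon(8, 32)
        for pref in (Preference.SPEED, Preference.MEMORY):
            assert choose_processor(e, pref, true_cols=32) is SplitMode.PURE_MAC

    def test_memory_preference_takes_mixed(self):
        e = self._echelon(8, 16)
        assert choose_processor(e, Preference.MEMORY, true_cols=1) \
            is SplitMode.MIXED

    def test_speed_preference_is_argmin_of_cycle_estimates(self):
        params = CostParams()
        e = self._echelon(4, 16)
        t_mac = final_block_mac_cycles(4, 4, params)
        t_arm = strip_arm_cycles(4, 1, 4, params)
        want = SplitMode.MIXED if t_arm < t_mac else SplitMode.PURE_MAC
        assert choose_processor(e, Preference.SPEED, true_cols=1, batch=4) is want
        # and for a tall matrix the MAC side must win
        tall = self._echelon(400, 16)
        assert choose_processor(tall, Preference.SPEED, true_cols=1) \
            is SplitMode.PURE_MAC
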