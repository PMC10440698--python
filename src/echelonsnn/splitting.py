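"""Two-stage splitting of the echelon matrix onto fixed-geometry cores.

*Alignment splitting* covers the nonzeros of an echelon matrix with
right-anchored rectangles whose column starts sit on 16-column gridlines and
whose heights are multiples of 4 rows — the operand geometry the 4x16 MAC
array accepts — choosing, per 4-row band, the rightmost admissible start, so
the total covered area is minimal within that family.  The mixed variant
peels the final 16-column block (mostly alignment padding when the residual
``m = true_cols mod 16`` is small) into a narrow strip handled by the ARM
core instead.

*Core splitting* then cuts the rectangles horizontally at 4-row granularity
and deals the slices, in scan order, to the minimum number of processing
elements (PEs) such that per-PE stored-value counts stay balanced to within
one 4-row slice of the widest rectangle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .densify import EchelonMatrix
from .operands import align

__all__ = ["Processor", "SplitMode", "Preference", "Rectangle", "SplitPlan",
           "alignment_split", "mixed_alignment_split", "core_split",
           "core_split_mixed", "residual_m", "choose_processor",
           "InfeasibleSplitError"]

ROW_ALIGN = 4
COL_ALIGN = 16


class Processor(str, enum.Enum):
    MAC = "MAC"
    ARM = "ARM"


class SplitMode(str, enum.Enum):
    PURE_MAC = "PURE_MAC"
    MIXED = "MIXED"


class Preference(str, enum.Enum):
    SPEED = "SPEED"
    MEMORY = "MEMORY"


class InfeasibleSplitError(ValueError):
    """The per-PE budget cannot hold even one 4-row slice."""


@dataclass(frozen=True)
class Rectangle:
    row_start: int
    row_count: int
    col_start: int
    col_count: int
    processor: Processor = Processor.MAC

    def __post_init__(self) -> None:
        if self.row_count <= 0 or self.col_count <= 0:
            raise ValueError("rectangle must have positive extent")
        if self.processor is Processor.MAC:
            if self.row_count % ROW_ALIGN:
                raise ValueError("MAC rectangle height must be a multiple of 4")
            if self.col_start % COL_ALIGN or self.col_count % COL_ALIGN:
                raise ValueError("MAC rectangle columns must sit on 16-grid")

    @property
    def area(self) -> int:
        return self.row_count * self.col_count

    @property
    def row_end(self) -> int:
        return self.row_start + self.row_count

    @property
    def col_end(self) -> int:
        return self.col_start + self.col_count


@dataclass
class SplitPlan:
    rectangles: list[Rectangle]
    pe_groups: list[list[Rectangle]]
    per_pe_value_counts: list[int]
    m: int
    mode: SplitMode
    arm_strip: Rectangle | None = None

    @property
    def pe_count(self) -> int:
        return len(self.pe_groups)

    @property
    def total_values(self) -> int:
        return sum(r.area for g in self.pe_groups for r in g)


def _check_echelon(e: EchelonMatrix) -> None:
    if np.any(np.diff(e.boundary) < 0):
        raise ValueError("matrix is not in echelon form (boundary decreases)")


def _band_tops(e: EchelonMatrix) -> tuple[list[int], int, int]:
    """Horizontal dividing lines of the alignment split.

    Returns (per-gridline 4-aligned top rows, last covered row, padded cols).
    """
    n_cols16 = align(e.n_cols, COL_ALIGN)
    nnz_rows = int(np.sum(e.boundary < e.n_cols))
    last = align(nnz_rows, ROW_ALIGN)
    bounded = e.boundary[:nnz_rows]
    tops = []
    for v in range(n_cols16 // COL_ALIGN):
        top = int(np.searchsorted(bounded, v * COL_ALIGN, side="left"))
        tops.append(min(align(top, ROW_ALIGN), last))  # shift line downwards
    return tops, last, n_cols16


def alignment_split(e: EchelonMatrix) -> list[Rectangle]:
    """Minimal right-anchored rectangle cover of an echelon matrix.

    For each 16-column gridline, the dividing line sits where the echelon
    boundary crosses it, shifted downwards to 4-row granularity; the band
    between consecutive lines becomes one rectangle spanning from that
    gridline to the padded right edge.  Bands may extend past the stored
    rows by up to 3 virtual zero-padding rows.
    """
    _check_echelon(e)
    tops, last, n_cols16 = _band_tops(e)
    rects: list[Rectangle] = []
    lines = tops + [last]
    for v in range(len(tops)):
        height = lines[v + 1] - lines[v]
        if height > 0:
            rects.append(Rectangle(lines[v], height, v * COL_ALIGN,
                                   n_cols16 - v * COL_ALIGN, Processor.MAC))
    return rects


def residual_m(true_cols: int) -> int:
    """Residual column count ``m = true_cols mod 16``, with 16 standing for 0."""
    if true_cols < 1:
        raise ValueError("true_cols must be >= 1")
    return true_cols % COL_ALIGN or COL_ALIGN


def mixed_alignment_split(e: EchelonMatrix, true_cols: int
                          ) -> tuple[list[Rectangle], Rectangle | None]:
    """Alignment split with the final 16-column block delegated to ARM.

    MAC rectangles are truncated to exclude the final block (rows whose data
    lies only there get none); the ARM strip stores just the ``m`` true
    residual columns over the full banded row extent, hence exactly m/16 of
    the final-block area the pure split would store.  When ``m`` is 16 the
    result is identical to the pure split.
    """
    _check_echelon(e)
    m = residual_m(true_cols)
    pure = alignment_split(e)
    if m == COL_ALIGN:
        return pure, None
    n_cols16 = align(e.n_cols, COL_ALIGN)
    cut = n_cols16 - COL_ALIGN
    mac_rects = []
    for r in pure:
        width = cut - r.col_start
        if width > 0:
            mac_rects.append(Rectangle(r.row_start, r.row_count, r.col_start,
                                       width, Processor.MAC))
    _, last, _ = _band_tops(e)
    strip = None
    if last > 0:
        strip = Rectangle(0, last, cut, m, Processor.ARM)
    return mac_rects, strip


# ---------------------------------------------------------------------------
# core splitting
# ---------------------------------------------------------------------------

def _slices(rectangles: list[Rectangle]) -> list[Rectangle]:
    out = []
    for r in rectangles:
        step = ROW_ALIGN if r.processor is Processor.MAC else ROW_ALIGN
        for top in range(r.row_start, r.row_end, step):
            h = min(step, r.row_end - top)
            out.append(Rectangle(top, h, r.col_start, r.col_count, r.processor))
    return out

def _coalesce(slices: list[Rectangle]) -> list[Rectangle]:
    """Re-join vertically adjacent slices of the same column span."""
    merged: list[Rectangle] = []
    for s in slices:
        if (merged and merged[-1].processor is s.processor
                and merged[-1].col_start == s.col_start
                and merged[-1].col_count == s.col_count
                and merged[-1].row_end == s.row_start):
            prev = merged.pop()
            s = Rectangle(prev.row_start, prev.row_count + s.row_count,
                          s.col_start, s.col_count, s.processor)
        merged.append(s)
    return merged


def _window_cuts(prefix: np.ndarray, pe_count: int,
                 s_max: int) -> list[int] | None:
    """Exact fallback: contiguous cuts with every load inside some window
    of width ``s_max``, if such a partition exists.

    For a candidate minimum load ``m`` the set of prefix indices reachable
    with k parts whose loads lie in [m, m + s_max] is an interval, so
    feasibility is O(pe_count) bisections per candidate.  Candidates only
    need to lie in [avg - s_max, avg] since the window must contain the
    average load.
    """
    n = len(prefix) - 1
    avg = prefix[-1] / pe_count
    diffs = (prefix[None, 1:] - prefix[:-1, None]).ravel()
    cands = np.unique(diffs[(diffs >= max(avg - s_max, 0)) & (diffs <= avg)])
    for m in cands[::-1]:
        hi_bound = m + s_max
        lo, hi = 0, 0
        intervals = [(0, 0)]
        ok = True
        for _ in range(pe_count):
            lo = int(np.searchsorted(prefix, prefix[lo] + m, side="left"))
            hi = int(np.searchsorted(prefix, prefix[hi] + hi_bound,
                                     side="right")) - 1
            if lo > hi or lo > n:
                ok = False
                break
            intervals.append((lo, hi))
        if not ok or not (intervals[-1][0] <= n <= intervals[-1][1]):
            continue
        cuts = [n]
        for k in range(pe_count - 1, 0, -1):
            lo_k, hi_k = intervals[k]
            # any j in [lo_k, hi_k] with load(j -> cuts[-1]) inside the window
            j_lo = int(np.searchsorted(prefix, prefix[cuts[-1]] - hi_bound,
                                       side="left"))
            j_hi = int(np.searchsorted(prefix, prefix[cuts[-1]] - m,
                                       side="right")) - 1
            j = min(hi_k, j_hi)
            if j < max(lo_k, j_lo):
                cuts = None
                break
            cuts.append(j)
        if cuts is not None:
            cuts.append(0)
            return cuts[::-1]
    return None


def _partition(slices: list[Rectangle], pe_count: int) -> list[list[Rectangle]]:
    """Contiguous scan-order partition with near-equal value counts.

    Cut points start at the prefix sums nearest to the equal-share targets
    and a local repair pass then shifts single slices across cuts while that
    shrinks the max-min load spread.
    """
    if pe_count <= 1:
        return [_coalesce(list(slices))]
    sizes = [s.area for s in slices]
    prefix = np.concatenate([[0], np.cumsum(sizes)])
    n = len(slices)

    # adaptive greedy seeding: each PE stops at whichever side of its
    # remaining-equal-share target is closer
    cuts = [0]
    for k in range(1, pe_count):
        lo = cuts[-1]
        remaining_pes = pe_count - k + 1
        target = prefix[lo] + (prefix[-1] - prefix[lo]) / remaining_pes
        idx = int(np.searchsorted(prefix, target, side="left"))
        if idx > lo and abs(prefix[idx - 1] - target) <= abs(
                prefix[min(idx, n)] - target):
            idx -= 1
        idx = min(max(idx, lo), n - (pe_count - k))
        cuts.append(idx)
    cuts.append(n)

    def load(j):
        return int(prefix[cuts[j + 1]] - prefix[cuts[j]])

    # pairwise diffusion: shift single slices across a cut while that lowers
    # the larger of the two neighbouring loads (ties broken by local spread)
    for _ in range(8 * n + 32):
        changed = False
        for j in range(1, pe_count):
            a, b = load(j - 1), load(j)
            for delta in (-1, 1):
                nj = cuts[j] + delta
                if not (cuts[j - 1] <= nj <= cuts[j + 1]):
                    continue
                na = int(prefix[nj] - prefix[cuts[j - 1]])
                nb = int(prefix[cuts[j + 1]] - prefix[nj])
                if (max(na, nb), abs(na - nb)) < (max(a, b), abs(a - b)):
                    cuts[j] = nj
                    changed = True
                    break
        if not changed:
            break

    # cascade shuttles: push one slice per boundary along the whole path from
    # the heaviest PE towards the lightest, while that shrinks the spread
    def all_loads():
        return [load(j) for j in range(pe_count)]

    for _ in range(4 * n + 16):
        cur = all_loads()
        spread = max(cur) - min(cur)
        hi = int(np.argmax(cur))
        lo_pe = int(np.argmin(cur))
        if hi == lo_pe:
            break
        trial = list(cuts)
        step = 1 if hi < lo_pe else -1
        for j in range(hi + 1, lo_pe + 1) if step == 1 \
                else range(hi, lo_pe, -1):
            trial[j] -= step
        if all(trial[k] <= trial[k + 1] for k in range(pe_count)):
            saved = cuts[:]
            cuts[:] = trial
            new = all_loads()
            if max(new) - min(new) >= spread:
                cuts[:] = saved
                break
        else:
            break

    s_max = max(sizes)
    final = [load(j) for j in range(pe_count)]
    if max(final) - min(final) > s_max:
        exact = _window_cuts(prefix, pe_count, s_max)
        if exact is not None:
            cuts = exact
    return [_coalesce(slices[cuts[i]:cuts[i + 1]]) for i in range(pe_count)]


def core_split(rectangles: list[Rectangle], per_pe_value_budget: int
               ) -> SplitPlan:
    """Deal alignment-split rectangles onto the fewest balanced PEs.

    ``pe_count`` is the ceiling of total stored values over the per-PE value
    budget — never more.  Rectangles are cut horizontally at 4-row
    granularity and assigned contiguously in scan order.
    """
    total = sum(r.area for r in rectangles)
    if not rectangles or total == 0:
        return SplitPlan([], [[]], [0], COL_ALIGN, SplitMode.PURE_MAC)
    widest_slice = max(ROW_ALIGN * r.col_count for r in rectangles)
    if per_pe_value_budget < widest_slice:
        raise InfeasibleSplitError(
            f"budget {per_pe_value_budget} cannot hold one 4-row slice "
            f"({widest_slice} values) of the widest rectangle")
    pe_count = math.ceil(total / per_pe_value_budget)
    groups = _partition(_slices(rectangles), pe_count)
    counts = [sum(r.area for r in g) for g in groups]
    return SplitPlan(list(rectangles), groups, counts, COL_ALIGN,
                     SplitMode.PURE_MAC)


def core_split_mixed(mac_rectangles: list[Rectangle],
                     arm_strip: Rectangle | None,
                     per_pe_value_budget: int) -> SplitPlan:
    """Core splitting for the mixed approach.

    The PE count comes from the combined MAC + strip value total; the MAC
    rectangles and the ARM strip are each dealt into that many contiguous
    groups, and PE ``i`` receives MAC group ``i`` plus strip group ``i``.
    """
    if arm_strip is None:
        plan = core_split(mac_rectangles, per_pe_value_budget)
        plan.mode = SplitMode.MIXED
        return plan
    total = sum(r.area for r in mac_rectangles) + arm_strip.area
    widest = max([ROW_ALIGN * r.col_count for r in mac_rectangles]
                 + [ROW_ALIGN * arm_strip.col_count])
    if per_pe_value_budget < widest:
        raise InfeasibleSplitError(
            f"budget {per_pe_value_budget} cannot hold one 4-row slice "
            f"({widest} values)")
    pe_count = math.ceil(total / per_pe_value_budget)
    mac_groups = (_partition(_slices(mac_rectangles), pe_count)
                  if mac_rectangles else [[] for _ in range(pe_count)])
    arm_groups = _partition(_slices([arm_strip]), pe_count)
    groups = [mg + ag for mg, ag in zip(mac_groups, arm_groups)]
    counts = [sum(r.area for r in g) for g in groups]
    m = arm_strip.col_count
    return SplitPlan(list(mac_rectangles), groups, counts, m, SplitMode.MIXED,
                     arm_strip=arm_strip)


def choose_processor(e: EchelonMatrix, preference: Preference,
                     true_cols: int, batch: int = 4,
                     cost_params=None) -> SplitMode:
    """Pick pure-MAC or mixed processing for the final 16-column block.

    With a MEMORY preference the mixed mode wins whenever there is a
    residual (its strip stores m/16 of the block).  With a SPEED preference
    pure MAC wins unless the cycle model puts the ARM strip ahead, which
    happens only for small residuals and few rows, where the MAC invocation
    overhead dominates.
    """
    from .costmodel import CostParams, final_block_mac_cycles, strip_arm_cycles
    m = residual_m(true_cols)
    if m == COL_ALIGN:
        return SplitMode.PURE_MAC
    if preference is Preference.MEMORY:
        return SplitMode.MIXED
    params = cost_params or CostParams()
    nnz_rows = int(np.sum(e.boundary < e.n_cols))
    t_mac = final_block_mac_cycles(nnz_rows, batch, params)
    t_arm = strip_arm_cycles(nnz_rows, m, batch, params)
    return SplitMode.MIXED if t_arm < t_mac else SplitMode.PURE_MAC
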