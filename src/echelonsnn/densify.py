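"""Information densification of the stacked operands.

Four lossless transformations shrink operand B offline and are mirrored by a
cheap runtime preprocessing of operand A, preserving the matrix product
bit-for-bit:

* **Zero Elimination** — drop all-zero rows of B and the matching columns
  of A.
* **Proportion Merger** — collapse rows of B that are exact positive-integer
  multiples of a common primitive row into that base row; the integer
  factors migrate into A as weighted column sums (this is also what lifts
  1-bit spikes into the 8/16-bit operand range).
* **Echelon Reorder** — permute the rows of B so first-nonzero column
  indices are non-decreasing, leaving an all-zero lower-left region that
  rectangular covers can skip.
* **Circle Reverse** — decompose that row permutation into cycles and
  reverse each cycle so the matching column permutation of A can be applied
  in place with one spare column per cycle (O(n) moves, no full copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operands import WeightDelayMap

__all__ = [
    "RowSelection", "MergeGroup", "MergeRecord", "EchelonMatrix", "CircleSet",
    "zero_eliminate", "proportion_merge", "apply_merge_to_input",
    "echelon_reorder", "find_circles", "reverse_circles",
    "apply_circles_inplace",
]


@dataclass
class RowSelection:
    """Retained row indices of operand B (= column indices of operand A)."""

    kept: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise ValueError("kept indices must be strictly increasing")


@dataclass
class MergeGroup:
    """One proportional family: ``original row = factor * base row``."""

    base_row: int                      # index (pre-merge space) of the kept row
    members: list[tuple[int, int]]     # (original row index, positive factor)


@dataclass
class MergeRecord:
    """Outcome of Proportion Merger on a reduced weight-delay matrix.

    ``kept`` lists, in order, the pre-merge row indices that survive as rows
    of the merged matrix; merged base rows appear under their base index.
    """

    groups: list[MergeGroup] = field(default_factory=list)
    kept: list[int] = field(default_factory=list)

    @property
    def is_identity(self) -> bool:
        return not self.groups


@dataclass
class EchelonMatrix:
    """Row-reordered operand B with non-decreasing first-nonzero boundary."""

    values: np.ndarray
    tgt_idx_list: np.ndarray   # destination row of each source row
    src_idx_list: np.ndarray   # identity-ordered source indices
    boundary: np.ndarray       # per (reordered) row: first nonzero column

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class CircleSet:
    """Cycle decomposition of a row permutation, optionally reversed."""

    circles_list: list[list[int]]
    reversed_circle_list: list[list[int]] = field(default_factory=list)

    @property
    def circle_count(self) -> int:
        return len(self.circles_list)


def zero_eliminate(b: WeightDelayMap | np.ndarray) -> tuple[np.ndarray, RowSelection]:
    """Drop all-zero rows of B, recording which rows were kept.

    The same indices select the columns of operand A that survive.
    """
    values = b.values if isinstance(b, WeightDelayMap) else np.asarray(b)
    mask = np.any(values != 0, axis=1)
    kept = np.flatnonzero(mask)
    return values[kept].copy(), RowSelection(kept=[int(k) for k in kept])


def proportion_merge(b: np.ndarray, max_factor_sum: int = 127
                     ) -> tuple[np.ndarray, MergeRecord]:
    """Merge exactly-proportional rows of B into single primitive base rows.

    Two rows merge when both are positive-integer multiples of the same
    primitive row (row divided by the positive gcd of its magnitudes; sign
    pattern retained, so a row and its negation do *not* merge).  A family is
    merged only if the sum of its factors fits the operand precision
    (``max_factor_sum``), since that sum bounds the preprocessed entries of
    operand A.  All-zero rows are left untouched (Zero Elimination owns them).
    """
    b = np.asarray(b)
    n_rows = b.shape[0]
    families: dict[bytes, list[tuple[int, int]]] = {}
    nonzero = b.any(axis=1)
    factors = np.gcd.reduce(np.abs(b), axis=1) if b.size else \
        np.zeros(n_rows, dtype=np.int64)
    bases = np.where(nonzero[:, None], b // np.maximum(factors, 1)[:, None], 0)
    for r in range(n_rows):
        if not nonzero[r]:
            continue
        families.setdefault(bases[r].tobytes(), []).append((r, int(factors[r])))

    groups: list[MergeGroup] = []
    drop: set[int] = set()
    rebase: set[int] = set()
    for key, members in families.items():
        if len(members) < 2:
            continue
        if sum(f for _, f in members) > max_factor_sum:
            continue  # would overflow the operand precision at runtime
        base_row = members[0][0]
        groups.append(MergeGroup(base_row=base_row, members=list(members)))
        rebase.add(base_row)
        drop.update(r for r, _ in members[1:])

    kept = [r for r in range(n_rows) if r not in drop]
    merged = b[kept].astype(np.int64, copy=True)
    for out_idx, r in enumerate(kept):
        if r in rebase:
            merged[out_idx] = bases[r]
    return merged, MergeRecord(groups=groups, kept=kept)


def apply_merge_to_input(a: np.ndarray, record: MergeRecord) -> np.ndarray:
    """Runtime companion of :func:`proportion_merge` on operand A columns.

    For each merged family the surviving column becomes the factor-weighted
    sum of the member columns; entries may then exceed 1 — this is where the
    1-bit spike data is lifted into the multi-bit operand range.
    """
    a = np.asarray(a)
    if record.is_identity and not record.kept:
        return a.copy()
    out = a[:, record.kept].astype(np.int64, copy=True)
    pos = {r: i for i, r in enumerate(record.kept)}
    for g in record.groups:
        col = np.zeros(a.shape[0], dtype=np.int64)
        for member, factor in g.members:
            col += factor * a[:, member]
        out[:, pos[g.base_row]] = col
    return out


def echelon_reorder(b: np.ndarray) -> EchelonMatrix:
    """Reorder rows of B by first-nonzero column into an echelon matrix.

    Scans columns left to right and emits each row once at its first nonzero
    (ties broken by ascending original row index, i.e. a stable sort on the
    first-nonzero index); all-zero rows, if any, are appended last.  The
    resulting boundary is non-decreasing and the lower-left region is zero.
    """
    b = np.asarray(b)
    n_rows, n_cols = b.shape
    nonzero = b != 0
    has_any = nonzero.any(axis=1)
    first_nz = np.where(has_any, np.argmax(nonzero, axis=1), n_cols)
    order = np.argsort(first_nz, kind="stable")        # source index per dest
    tgt = np.empty(n_rows, dtype=np.int64)             # dest index per source
    tgt[order] = np.arange(n_rows)
    return EchelonMatrix(
        values=b[order].copy(),
        tgt_idx_list=tgt,
        src_idx_list=np.arange(n_rows, dtype=np.int64),
        boundary=first_nz[order],
    )


def find_circles(src_idx_list, tgt_idx_list) -> CircleSet:
    """Cycle decomposition of the echelon row permutation.

    Starting from each unvisited source index, repeatedly step to
    ``tgt_idx_list[current]`` until returning to the start; the visited
    indices form one circle.
    """
    src = np.asarray(src_idx_list, dtype=np.int64)
    tgt = np.asarray(tgt_idx_list, dtype=np.int64)
    n = src.size
    if tgt.size != n or not np.array_equal(np.sort(src), np.sort(tgt)):
        raise ValueError("tgt_idx_list must be a permutation of src_idx_list")
    tgt_of = dict(zip(src.tolist(), tgt.tolist()))
    remaining = dict.fromkeys(src.tolist())  # insertion-ordered set
    circles: list[list[int]] = []
    while remaining:
        start = next(iter(remaining))
        del remaining[start]
        circle = [start]
        cur = tgt_of[start]
        while cur != start:
            del remaining[cur]
            circle.append(cur)
            cur = tgt_of[cur]
        circles.append(circle)
    return CircleSet(circles_list=circles)


def reverse_circles(circles: CircleSet) -> CircleSet:
    """Reverse each circle's traversal order, keeping its start point first."""
    rev = [[c[0]] + c[:0:-1] for c in circles.circles_list]
    return CircleSet(circles_list=[list(c) for c in circles.circles_list],
                     reversed_circle_list=rev)


def apply_circles_inplace(a: np.ndarray, circles: CircleSet,
                          count_moves: bool = False):
    """Permute operand-A columns in place via the reversed circles.

    After the call, column ``tgt_idx_list[s]`` holds what column ``s`` held
    before.  Per circle only its start column is buffered: walking the
    reversed order copies each column from its successor, then the buffered
    start column lands on the start's target.  Auxiliary storage is one
    column per circle; total column moves are at most n + circle_count.
    """
    if not circles.reversed_circle_list and circles.circles_list:
        raise ValueError("reversed circles missing; call reverse_circles first")
    n_cols = a.shape[1]
    moves = 0
    for rev in circles.reversed_circle_list:
        if len(rev) == 1:
            continue  # fixed point: nothing to move
        if max(rev) >= n_cols or min(rev) < 0:
            raise IndexError("circle index out of range for the input map")
        saved = a[:, rev[0]].copy()
        moves += 1
        for prev, nxt in zip(rev, rev[1:]):
            a[:, prev] = a[:, nxt]
            moves += 1
        a[:, rev[-1]] = saved  # rev[-1] is the start column's target
        moves += 1
    return (a, moves) if count_moves else a
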