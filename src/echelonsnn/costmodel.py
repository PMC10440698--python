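"""Analytic cost models: per-approach memory accounting, the memory
optimization rate, and the closed-form synaptic-vs-neural ratios.

Four synaptic-processing approaches are compared at fixed byte widths:

* ``SERIAL_ARM``   — per-synapse serial processing with a per-delay current
  ring buffer; operands unaligned.
* ``ORIGINAL_MAC`` — the stacked-operand MAC formulation without any
  densification: fully aligned input and weight-delay maps.
* ``ECHELON_MAC``  — densified operands split into pure-MAC rectangles on a
  Dominant/Subordinate deployment.
* ``ECHELON_MIXED``— likewise, with the final 16-column block stored as an
  m-column ARM strip.

The closed-form ratios use MLA = 2 and CMP = 1 cycles (whence the printed
coefficient 0.67 = 2/3) and the printed approximation coefficients for the
memory ratio; exact-accounting variants are provided alongside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densify import CircleSet, EchelonMatrix, MergeRecord
from .operands import align
from .splitting import Processor, SplitPlan

__all__ = [
    "Approach", "CostParams", "CostReport",
    "memory_report", "memory_optimization_rate", "column_alignment_rate",
    "synap_neural_time_ratio", "synap_neural_time_ratio_exact",
    "synap_neural_mem_ratio", "synap_neural_mem_ratio_exact",
    "mixed_vs_pure_strip_memory",
    "final_block_mac_cycles", "strip_arm_cycles",
    "circle_set_bytes", "merge_record_bytes",
]

ROW_ALIGN = 4
COL_ALIGN = 16


class Approach(str, enum.Enum):
    SERIAL_ARM = "SERIAL_ARM"
    ORIGINAL_MAC = "ORIGINAL_MAC"
    ECHELON_MAC = "ECHELON_MAC"
    ECHELON_MIXED = "ECHELON_MIXED"


@dataclass
class CostParams:
    """Byte widths and ARM/MAC cycle constants used by all accounting.

    Defaults: 8-bit operands, 32-bit outputs/currents, 32-bit indices,
    ARM multiply-accumulate 2 cycles and compare 1 cycle (giving the 2/3
    time coefficient), one MAC-array invocation costing ``mac_setup_cycles``
    of configuration overhead, and a 120 KB per-PE memory budget.
    """

    operand_bytes: int = 1
    output_bytes: int = 4
    index_bytes: int = 4
    mla_cycles: int = 2
    comp_cycles: int = 1
    mac_setup_cycles: int = 64
    pe_budget_bytes: int = 122_880

    def __post_init__(self) -> None:
        for name in ("operand_bytes", "output_bytes", "index_bytes",
                     "mla_cycles", "comp_cycles", "pe_budget_bytes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CostReport:
    approach: Approach
    components: dict[str, int]
    pe_count: int
    time_proxy_cycles: int
    per_frame: bool = False

    @property
    def total_bytes(self) -> int:
        return sum(self.components.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"approach": self.approach.value, "component": k, "bytes": v}
                for k, v in self.components.items()]
        return pd.DataFrame(rows)


def circle_set_bytes(circles: CircleSet, params: CostParams) -> int:
    """Bytes to ship the reversed circles: per stored (non-singleton)
    circle, its elements plus one length word."""
    return sum((len(c) + 1) * params.index_bytes
               for c in circles.circles_list if len(c) > 1)


def merge_record_bytes(record: MergeRecord, params: CostParams) -> int:
    """Bytes to ship the merge record: per group a base index, a length word
    and (member index, factor) pairs."""
    return sum((2 + 2 * len(g.members)) * params.index_bytes
               for g in record.groups)


# ---------------------------------------------------------------------------
# per-approach memory accounting
# ---------------------------------------------------------------------------

def _baseline_report(model, approach: Approach, batch: int,
                     params: CostParams) -> CostReport:
    n_pre, n_post, d = model.n_pre, model.n_post, model.delay_range
    if approach is Approach.SERIAL_ARM:
        comp = {
            "input_placeholder": batch * n_pre * params.operand_bytes,
            "weights": n_pre * n_post * d * params.operand_bytes,
            "output_placeholder": batch * n_post * params.output_bytes,
            "input_current_buffer": d * n_post * params.output_bytes,
        }
        cycles = batch * model.n_synapses * params.mla_cycles
        pe_count = max(1, -(-comp["weights"] // params.pe_budget_bytes))
        return CostReport(approach, comp, pe_count, cycles)
    rows = align(n_pre * d, ROW_ALIGN)
    cols = align(n_post, COL_ALIGN)
    b4 = align(batch, ROW_ALIGN)
    weight_bytes = rows * cols * params.operand_bytes
    pe_count = max(1, -(-weight_bytes // params.pe_budget_bytes))
    comp = {
        "input_placeholder": b4 * rows * params.operand_bytes,
        "weights": weight_bytes,
        "output_placeholder": b4 * cols * params.output_bytes,
        "temporary_output": pe_count * b4 * cols * params.output_bytes,
        "input_current_buffer": d * cols * params.output_bytes,
    }
    cycles = (b4 // ROW_ALIGN) * (cols // COL_ALIGN) * rows \
        + params.mac_setup_cycles
    return CostReport(approach, comp, pe_count, cycles)


def _echelon_report(model, approach: Approach, batch: int, params: CostParams,
                    e: EchelonMatrix, plan: SplitPlan, circles: CircleSet,
                    record: MergeRecord) -> CostReport:
    n_post = model.n_post
    cols = align(n_post, COL_ALIGN)
    b4 = align(batch, ROW_ALIGN)
    kept_cols = align(e.n_rows, ROW_ALIGN)
    comp = {
        "input_placeholder": b4 * kept_cols * params.operand_bytes,
        "reversed_order": circle_set_bytes(circles, params)
                          + merge_record_bytes(record, params),
        "output_placeholder": b4 * cols * params.output_bytes,
        "weights": sum(plan.per_pe_value_counts) * params.operand_bytes,
        "temporary_output": plan.pe_count * b4 * cols * params.output_bytes,
    }
    cycles = 0
    for group in plan.pe_groups:
        for frag in group:
            if frag.processor is Processor.MAC:
                cycles += (b4 // ROW_ALIGN) * (frag.col_count // COL_ALIGN) \
                    * frag.row_count + params.mac_setup_cycles
            else:
                cycles += batch * frag.col_count * frag.row_count \
                    * params.mla_cycles
    # online input reorder: one ARM move per permuted column entry
    cycles += sum(len(c) + 1 for c in circles.circles_list if len(c) > 1) * b4
    return CostReport(approach, comp, plan.pe_count, cycles)


def memory_report(model, approach: Approach, batch: int | None = None,
                  params: CostParams | None = None,
                  e: EchelonMatrix | None = None,
                  plan: SplitPlan | None = None,
                  circles: CircleSet | None = None,
                  record: MergeRecord | None = None) -> CostReport:
    """Component-wise memory bytes (and a cycle proxy) for one approach.

    Baselines count fully aligned stacked operands (``ORIGINAL_MAC``) or
    unaligned serial operands (``SERIAL_ARM``); echelon approaches count
    only the rectangle/strip-stored weights plus the Dominant PE's input
    map, reversed-order metadata and output.
    """
    params = params or CostParams()
    batch = batch or model.delay_range
    if approach in (Approach.SERIAL_ARM, Approach.ORIGINAL_MAC):
        return _baseline_report(model, approach, batch, params)
    if e is None or plan is None or circles is None or record is None:
        raise ValueError("echelon approaches need e, plan, circles and record")
    return _echelon_report(model, approach, batch, params, e, plan, circles,
                           record)


def memory_optimization_rate(e: EchelonMatrix, plan: SplitPlan) -> float:
    """Fraction of the aligned echelon-matrix area the plan never stores.

    ``r_opt = (aligned area - covered area) / aligned area``; zero for a
    dense matrix, approaching 1 as rectangles hug a steep echelon boundary.
    """
    aligned = align(e.n_rows, ROW_ALIGN) * align(e.n_cols, COL_ALIGN)
    covered = sum(c for c in plan.per_pe_value_counts)
    return (aligned - covered) / aligned


def column_alignment_rate(n_post: int) -> float:
    """Share of the aligned weight-delay map owed to column padding.

    ``r_align_c = (16 - m) / (n_post + 16 - m)`` with
    ``m = n_post mod 16`` (16 when the division is exact).
    """
    if n_post < 1:
        raise ValueError("n_post must be >= 1")
    m = n_post % COL_ALIGN or COL_ALIGN
    return (COL_ALIGN - m) / (n_post + COL_ALIGN - m)


def synap_neural_time_ratio(n_pre: int, d: int) -> float:
    """Printed closed form of synaptic over neural-update time: 0.67*n_pre*d."""
    if n_pre < 1 or d < 1:
        raise ValueError("n_pre and d must be >= 1")
    return 0.67 * n_pre * d


def synap_neural_time_ratio_exact(n_pre: int, d: int,
                                  params: CostParams | None = None) -> float:
    """Exact form n_pre*d*MLA/(MLA+CMP) behind the printed 0.67 coefficient."""
    params = params or CostParams()
    return n_pre * d * params.mla_cycles / (params.mla_cycles + params.comp_cycles)


def synap_neural_mem_ratio(n_pre: int, n_post: int, d: int) -> float:
    """Printed approximation of synaptic over neural-update memory:
    1.94 + 0.24 * n_pre * (4/n_post + d)."""
    if n_pre < 1 or n_post < 1 or d < 1:
        raise ValueError("arguments must be >= 1")
    return 1.94 + 0.24 * n_pre * (4.0 / n_post + d)


def synap_neural_mem_ratio_exact(n_pre: int, n_post: int, d: int) -> float:
    """Exact expansion (4*n_pre + n_pre*n_post*d + 8*n_post) / (4.125*n_post)
    of which the printed form is a two-decimal rounding."""
    return (4 * n_pre + n_pre * n_post * d + 8 * n_post) / (4.125 * n_post)


def mixed_vs_pure_strip_memory(m: int) -> float:
    """Mixed/pure stored-value ratio on the final 16-column block: m/16."""
    if not (1 <= m <= COL_ALIGN):
        raise ValueError("m must lie in [1, 16]")
    return m / COL_ALIGN


# ---------------------------------------------------------------------------
# cycle estimates for the processor-selection heuristic
# ---------------------------------------------------------------------------

def final_block_mac_cycles(rows: int, batch: int, params: CostParams) -> int:
    """Marginal MAC cycles for the final 16-column block of the echelon
    matrix: one 4x16 tile pass over the (4-padded) inner dimension, plus the
    array invocation overhead."""
    return (align(batch, ROW_ALIGN) // ROW_ALIGN) * align(rows, ROW_ALIGN) \
        + params.mac_setup_cycles


def strip_arm_cycles(rows: int, m: int, batch: int, params: CostParams) -> int:
    """ARM cycles to multiply the m-column strip serially: one MLA per
    (batch row, output column, inner row) triple."""
    return batch * m * rows * params.mla_cycles
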