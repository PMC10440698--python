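"""Integer emulation of the 4x16 MAC array and the multi-core
Dominant/Subordinate execution chain.

:func:`compile_layer` runs the full offline chain — operand stacking, zero
elimination, proportion merging, echelon reordering, circle reversal,
alignment and core splitting, deployment — and returns a
:class:`DeploymentPlan` whose online execution
(:func:`run_inference_step`) reproduces the dense synaptic oracle
bit-for-bit: the Dominant PE builds and preprocesses the input map, each
Subordinate multiplies its weight fragments on the emulated MAC array (or
plain integer arithmetic for ARM strips), and the partial products are
accumulated into the Dominant's output buffer.

The MAC array accepts operands whose shapes sit on the 4/16 grid and whose
entries fit the configured operand precision; accumulation is 32-bit, with
symmetric saturation when a narrower output precision is configured.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import densify
from .costmodel import (Approach, CostParams, circle_set_bytes,
                        merge_record_bytes)
from .model import LIFParams, NeuronState, SNNLayerModel, SpikeTrain, \
    lif_update, synaptic_oracle
from .operands import align, build_input_map, build_weight_delay_map
from .splitting import (Preference, Processor, Rectangle, SplitMode,
                        SplitPlan, alignment_split, choose_processor,
                        core_split, core_split_mixed, mixed_alignment_split)

__all__ = ["MACConfig", "Role", "Backend", "PEImage", "DeploymentPlan",
           "AlignmentError", "PrecisionError", "DeploymentError",
           "mac_matmul", "compile_layer", "build_deployment",
           "run_inference_step", "run_network"]

ROW_ALIGN = 4
COL_ALIGN = 16


class AlignmentError(ValueError):
    """Operand shape violates the MAC array's 4/16 geometry."""


class PrecisionError(ValueError):
    """Operand entries exceed the configured operand precision."""


class DeploymentError(RuntimeError):
    """A PE image exceeds its memory budget."""


class Role(str, enum.Enum):
    DOMINANT = "DOMINANT"
    SUBORDINATE = "SUBORDINATE"


class Backend(str, enum.Enum):
    ORACLE = "ORACLE"
    COMPILED = "COMPILED"


@dataclass
class MACConfig:
    array_rows: int = 4
    array_cols: int = 16
    operand_bits: int = 8
    output_bits: int = 32

    def __post_init__(self) -> None:
        if (self.array_rows, self.array_cols) != (4, 16):
            raise ValueError("the MAC array geometry is fixed at 4 x 16")
        if self.operand_bits not in (8, 16):
            raise ValueError("operand precision must be 8 or 16 bits")
        if self.output_bits not in (8, 16, 32):
            raise ValueError("output precision must be 8, 16 or 32 bits")

    @property
    def operand_max(self) -> int:
        return (1 << (self.operand_bits - 1)) - 1


def mac_matmul(a: np.ndarray, b: np.ndarray,
               config: MACConfig | None = None) -> tuple[np.ndarray, int]:
    """Exact integer matmul under MAC-array constraints, with a cycle count.

    Both operands must be pre-aligned (A rows and B rows to 4, B columns to
    16) and fit the operand precision — the emulator refuses rather than
    padding silently, mirroring the hardware contract.  The product is
    accumulated at 32 bits; narrower configured outputs saturate
    symmetrically.  Cycles count the 4x16 outer-product tiling:
    ``(a_rows/4) * (b_cols/16) * inner``.
    """
    config = config or MACConfig()
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim != 2 or b.ndim != 2:
        raise AlignmentError("operands must be matrices")
    if a.shape[0] % ROW_ALIGN or b.shape[0] % ROW_ALIGN:
        raise AlignmentError("operand row counts must be multiples of 4")
    if b.shape[1] % COL_ALIGN:
        raise AlignmentError("operand B column count must be a multiple of 16")
    if a.shape[1] != b.shape[0]:
        raise AlignmentError("inner dimensions do not match")
    bound = config.operand_max
    if np.abs(a).max(initial=0) > bound or np.abs(b).max(initial=0) > bound:
        raise PrecisionError(f"operand entries exceed {config.operand_bits}-bit range")
    c = a.astype(np.int64) @ b.astype(np.int64)
    if config.output_bits < 32:
        out_max = (1 << (config.output_bits - 1)) - 1
        c = np.clip(c, -out_max, out_max)
    cycles = (a.shape[0] // ROW_ALIGN) * (b.shape[1] // COL_ALIGN) * a.shape[1]
    return c, cycles


@dataclass
class PEImage:
    """Byte inventory of one processing element."""

    role: Role
    stored_objects: dict[str, int]
    budget_bytes: int = 122_880

    @property
    def byte_total(self) -> int:
        return sum(self.stored_objects.values())

    def check(self, name: str) -> None:
        if self.byte_total > self.budget_bytes:
            raise DeploymentError(
                f"{name} ({self.role.value}) needs {self.byte_total} bytes, "
                f"budget is {self.budget_bytes} "
                f"(over by {self.byte_total - self.budget_bytes})")


@dataclass
class DeploymentPlan:
    """Everything needed to run the compiled layer online."""

    model: SNNLayerModel
    split_plan: SplitPlan
    echelon: densify.EchelonMatrix
    circles: densify.CircleSet
    merge_record: densify.MergeRecord
    selection: densify.RowSelection
    pe_images: list[PEImage]
    batch: int
    mode: SplitMode
    mac_config: MACConfig
    fragments: list[list[Rectangle]] = field(default_factory=list)

    @property
    def pe_count(self) -> int:
        return len(self.pe_images)

    @property
    def dominant(self) -> PEImage:
        return next(p for p in self.pe_images if p.role is Role.DOMINANT)


def compile_layer(model: SNNLayerModel,
                  batch: int | None = None,
                  mode: SplitMode | None = None,
                  preference: Preference = Preference.MEMORY,
                  budget_bytes: int | None = None,
                  mac_config: MACConfig | None = None,
                  cost_params: CostParams | None = None) -> DeploymentPlan:
    """Run the offline chain and return a ready-to-execute deployment.

    ``batch`` defaults to the delay range so one matmul yields one result
    per delay; ``mode`` defaults to the processor-selection heuristic under
    ``preference``.
    """
    params = cost_params or CostParams()
    config = mac_config or MACConfig()
    budget = budget_bytes if budget_bytes is not None else params.pe_budget_bytes
    batch = batch or model.delay_range

    wd = build_weight_delay_map(model)
    reduced, selection = densify.zero_eliminate(wd)
    merged, record = densify.proportion_merge(reduced,
                                              max_factor_sum=config.operand_max)
    # pad to a 4-row multiple before reordering so fragment rows stay on-grid
    n_kept = merged.shape[0]
    padded = np.zeros((align(n_kept, ROW_ALIGN), wd.padded_cols), dtype=np.int64)
    padded[:n_kept] = merged
    ech = densify.echelon_reorder(padded)
    circles = densify.reverse_circles(
        densify.find_circles(ech.src_idx_list, ech.tgt_idx_list))

    if mode is None:
        mode = choose_processor(ech, preference, model.n_post,
                                batch=align(batch, ROW_ALIGN),
                                cost_params=params)
    # weight-value budget per PE: bytes left after the fixed per-PE buffers
    overhead = align(batch, ROW_ALIGN) * align(model.n_post, COL_ALIGN) \
        * params.output_bytes
    value_budget = max((budget - overhead) // params.operand_bytes, 1)
    if mode is SplitMode.MIXED:
        mac_rects, strip = mixed_alignment_split(ech, model.n_post)
        plan = core_split_mixed(mac_rects, strip, value_budget)
    else:
        plan = core_split(alignment_split(ech), value_budget)
        plan.m = model.n_post % COL_ALIGN or COL_ALIGN
    return build_deployment(plan, ech, circles, record, budget,
                            model=model, selection=selection, batch=batch,
                            mac_config=config, cost_params=params)


def build_deployment(split: SplitPlan, e: densify.EchelonMatrix,
                     circles: densify.CircleSet,
                     merge: densify.MergeRecord,
                     budget_bytes: int, *,
                     model: SNNLayerModel,
                     selection: densify.RowSelection,
                     batch: int,
                     mac_config: MACConfig | None = None,
                     cost_params: CostParams | None = None) -> DeploymentPlan:
    """Bind split fragments to PE images and audit every byte budget.

    One Dominant PE holds the (preprocessed) input map, the reversed-order
    metadata and the final output; each Subordinate holds its weight
    fragments and a temporary output.  Raises :class:`DeploymentError`
    naming the first over-budget PE.
    """
    params = cost_params or CostParams()
    config = mac_config or MACConfig()
    b4 = align(batch, ROW_ALIGN)
    cols16 = align(model.n_post, COL_ALIGN)
    dominant = PEImage(Role.DOMINANT, {
        "input_placeholder": b4 * align(e.n_rows, ROW_ALIGN) * params.operand_bytes,
        "circle_set": circle_set_bytes(circles, params),
        "merge_record": merge_record_bytes(merge, params),
        "output_placeholder": b4 * cols16 * params.output_bytes,
    }, budget_bytes)
    dominant.check("PE0")
    images = [dominant]
    for idx, group in enumerate(split.pe_groups, start=1):
        weight_values = sum(r.area for r in group)
        sub = PEImage(Role.SUBORDINATE, {
            "weights": weight_values * params.operand_bytes,
            "temporary_output": b4 * cols16 * params.output_bytes,
            "input_slice": 0,  # read remotely from the Dominant PE
        }, budget_bytes)
        sub.check(f"PE{idx}")
        images.append(sub)
    return DeploymentPlan(model=model, split_plan=split, echelon=e,
                          circles=circles, merge_record=merge,
                          selection=selection, pe_images=images, batch=batch,
                          mode=split.mode, mac_config=config,
                          fragments=[list(g) for g in split.pe_groups])


def _preprocessed_input(plan: DeploymentPlan, spikes: SpikeTrain,
                        t_start: int, batch: int) -> np.ndarray:
    """Dominant-PE online chain: stack, select, merge-weight, circle-reorder."""
    a0 = build_input_map(spikes, t_start, batch, plan.model).values
    a1 = a0[:, plan.selection.kept]
    a2 = densify.apply_merge_to_input(a1, plan.merge_record)
    n_rows = plan.echelon.n_rows
    a3 = np.zeros((a2.shape[0], n_rows), dtype=np.int64)
    a3[:, :a2.shape[1]] = a2
    return densify.apply_circles_inplace(a3, plan.circles)


def run_inference_step(plan: DeploymentPlan, spikes: SpikeTrain,
                       t_start: int, batch: int | None = None) -> np.ndarray:
    """One emulated multi-core synaptic-processing step.

    Returns exact integer currents of shape ``(batch, n_post)`` equal to
    :func:`echelonsnn.model.synaptic_oracle`.
    """
    batch = batch or plan.batch
    if spikes.n != plan.model.n_pre:
        raise ValueError("spike train width does not match the deployed model")
    a = _preprocessed_input(plan, spikes, t_start, batch)
    e = plan.echelon.values
    cols16 = align(plan.model.n_post, COL_ALIGN)
    out = np.zeros((a.shape[0], cols16), dtype=np.int64)
    for group in plan.fragments:
        partial = np.zeros_like(out)  # Subordinate temporary output
        for frag in group:
            rows = slice(frag.row_start, frag.row_start + frag.row_count)
            cols = slice(frag.col_start, frag.col_start + frag.col_count)
            block = np.zeros((frag.row_count, frag.col_count), dtype=np.int64)
            stored = e[rows, cols]  # may be short of virtual padding rows
            block[:stored.shape[0]] = stored
            a_slice = np.zeros((a.shape[0], frag.row_count), dtype=np.int64)
            real = a[:, rows]
            a_slice[:, :real.shape[1]] = real
            if frag.processor is Processor.MAC:
                c, _ = mac_matmul(a_slice, block, plan.mac_config)
            else:
                c = a_slice.astype(np.int64) @ block  # ARM integer path
            partial[:, cols] += c
        out += partial  # accumulated back on the Dominant PE
    return out[:batch, :plan.model.n_post]


def run_network(model: SNNLayerModel, spikes: SpikeTrain, lif: LIFParams,
                backend: Backend = Backend.ORACLE,
                plan: DeploymentPlan | None = None,
                **compile_kw) -> tuple[np.ndarray, np.ndarray]:
    """Full inference loop: synaptic processing plus LIF neural update.

    Starts at ``t = delay_range - 1`` (the first step with full history) and
    returns the spike raster and membrane trace, each of shape
    ``(T - delay_range + 1, n_post)``.  The COMPILED backend chunks the run
    into deployment batches; both backends are bit-identical in currents and
    therefore in spikes.
    """
    d = model.delay_range
    if spikes.T < d:
        raise ValueError("spike train must cover at least the delay range")
    if backend is Backend.COMPILED and plan is None:
        plan = compile_layer(model, **compile_kw)
    chunk = plan.batch if plan is not None else d
    t0 = d - 1
    n_steps = spikes.T - t0
    raster = np.zeros((n_steps, model.n_post), dtype=np.int64)
    vtrace = np.zeros((n_steps, model.n_post), dtype=np.float64)
    state = NeuronState.zeros(model.n_post)
    done = 0
    while done < n_steps:
        b = min(chunk, n_steps - done)
        if backend is Backend.COMPILED:
            currents = run_inference_step(plan, spikes, t0 + done, batch=b)
        else:
            currents = synaptic_oracle(model, spikes, t0 + done, b)
        for r in range(b):
            state = lif_update(state, currents[r], lif)
            raster[done + r] = state.z
            vtrace[done + r] = state.v
        done += b
    return raster, vtrace
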