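"""Operand stacking: turn a delayed layer into two aligned matmul operands.

The delay-stack formulation folds the per-delay weight matrices into a single
operand B (the *weight-delay map*) and the spike history into operand A (the
*input-spike-train map*) so one matrix multiplication yields the synaptic
currents of a whole batch of timesteps:

* B row ``k * n_pre + i``, column ``j`` holds ``W[j, i]`` for synapses with
  delay ``k`` (delay-major row layout), padded with zeros to a multiple of
  4 rows and 16 columns — the MAC-array operand geometry.
* A row ``r``, column ``k * n_pre + i`` holds ``x_i(t_start + r - k)``,
  rows padded to a multiple of 4.

Restricted to true rows/columns, ``A @ B`` equals the dense synaptic oracle
exactly, padding regions being all zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SNNLayerModel, SpikeTrain

__all__ = ["align", "WeightDelayMap", "InputSpikeTrainMap",
           "build_weight_delay_map", "build_input_map"]

ROW_ALIGN = 4
COL_ALIGN = 16


def align(value: int, multiple: int) -> int:
    """Smallest multiple of ``multiple`` that is >= ``value``; align(0, k) = 0."""
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    if value < 0:
        raise ValueError("value must be non-negative")
    return -(-value // multiple) * multiple


@dataclass
class WeightDelayMap:
    """Operand B: stacked per-delay weight matrices, alignment padded."""

    values: np.ndarray  # (padded_rows, padded_cols) int
    true_rows: int      # n_pre * delay_range
    true_cols: int      # n_post
    n_pre: int
    delay_range: int

    @property
    def padded_rows(self) -> int:
        return self.values.shape[0]

    @property
    def padded_cols(self) -> int:
        return self.values.shape[1]

    def row_of(self, delay: int, pre: int) -> int:
        """Delay-major row bijection (k, i) -> k * n_pre + i."""
        return delay * self.n_pre + pre


@dataclass
class InputSpikeTrainMap:
    """Operand A: batch rows of delayed spike history, alignment padded."""

    values: np.ndarray  # (padded_rows, padded_cols) int
    t_start: int
    batch: int

    @property
    def padded_rows(self) -> int:
        return self.values.shape[0]

    @property
    def padded_cols(self) -> int:
        return self.values.shape[1]


def build_weight_delay_map(model: SNNLayerModel) -> WeightDelayMap:
    """Stack the layer's weights along the delay axis into operand B."""
    n_pre, n_post, d = model.n_pre, model.n_post, model.delay_range
    true_rows = n_pre * d
    values = np.zeros((align(true_rows, ROW_ALIGN), align(n_post, COL_ALIGN)),
                      dtype=np.int64)
    j_idx, i_idx = np.nonzero(model.connected)
    rows = model.delays[j_idx, i_idx] * n_pre + i_idx
    values[rows, j_idx] = model.weights[j_idx, i_idx]
    return WeightDelayMap(values, true_rows, n_post, n_pre, d)


def build_input_map(spikes: SpikeTrain, t_start: int, batch: int,
                    model: SNNLayerModel) -> InputSpikeTrainMap:
    """Stack the spike history into operand A paired with the layer's map.

    Row ``r`` holds, for every delay ``k``, the spike vector at
    ``t_start + r - k``, so the product with the weight-delay map gives the
    currents for timesteps ``t_start .. t_start + batch - 1``.
    """
    n_pre, d = model.n_pre, model.delay_range
    if t_start < d - 1:
        raise IndexError(f"t_start={t_start} needs delay history of {d - 1} steps")
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if t_start + batch > spikes.T:
        raise IndexError("spike train too short for requested batch")
    if spikes.n != n_pre:
        raise ValueError("spike train width does not match n_pre")
    padded_cols = align(n_pre * d, ROW_ALIGN)  # = paired map's padded rows
    values = np.zeros((align(batch, ROW_ALIGN), padded_cols), dtype=np.int64)
    for k in range(d):
        block = spikes.values[t_start - k:t_start - k + batch, :]
        values[:batch, k * n_pre:(k + 1) * n_pre] = block
    return InputSpikeTrainMap(values, t_start, batch)
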