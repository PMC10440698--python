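"""Domain model: SNN layers with per-synapse integer delays, spike trains, and
leaky integrate-and-fire dynamics.

A layer connects ``n_pre`` pre-synaptic neurons to ``n_post`` post-synaptic
neurons.  Each connected synapse (j, i) carries an integer weight ``W[j, i]``
and an integer conduction delay ``D[j, i]`` in ``[0, delay_range - 1]``
timesteps.  The synaptic current into post-neuron j at timestep t is

    I_j(t) = sum_i W[j, i] * x_i(t - D[j, i])

with binary spikes x.  :func:`synaptic_oracle` computes this sum by direct
per-synapse gathering and is the bit-exact reference that every compiled
(stacked / densified / split / emulated) path in this package must match.

The neural update is the discrete LIF recurrence

    v' = I + alpha * v - z * v_th,      z' = [v' > v_th]

with decay factor ``alpha = exp(-dt/tau_m)`` (dt = one timestep) and soft
reset by threshold subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SNNLayerModel",
    "SpikeTrain",
    "LIFParams",
    "NeuronState",
    "generate_random_layer",
    "generate_cortex_like",
    "generate_gesture_like",
    "generate_poisson_spikes",
    "synaptic_oracle",
    "lif_update",
]

#: largest magnitude representable by the default signed 8-bit MAC operand
OPERAND_MAX_8BIT = 127


@dataclass
class SNNLayerModel:
    """A single SNN layer: weights, delays and connectivity, post-major.

    ``weights``, ``delays`` and ``connected`` are all ``(n_post, n_pre)``
    arrays; weights and delays are zero outside the connectivity mask.
    """

    n_pre: int
    n_post: int
    delay_range: int
    weights: np.ndarray
    delays: np.ndarray
    connected: np.ndarray
    density: float

    def __post_init__(self) -> None:
        if self.n_pre <= 0 or self.n_post <= 0 or self.delay_range <= 0:
            raise ValueError("n_pre, n_post and delay_range must be positive")
        shape = (self.n_post, self.n_pre)
        for name in ("weights", "delays", "connected"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        self.weights = np.asarray(self.weights, dtype=np.int64)
        self.delays = np.asarray(self.delays, dtype=np.int64)
        self.connected = np.asarray(self.connected, dtype=bool)
        if np.any(self.weights[~self.connected] != 0):
            raise ValueError("weights must be zero where not connected")
        d = self.delays[self.connected]
        if d.size and (d.min() < 0 or d.max() >= self.delay_range):
            raise ValueError("delays must lie in [0, delay_range - 1]")

    @property
    def n_synapses(self) -> int:
        return int(self.connected.sum())


@dataclass
class SpikeTrain:
    """Dense binary spike raster, shape ``(T, n)``: rows are timesteps."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("spike raster must be 2-D (timesteps x neurons)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("spike raster entries must be 0 or 1")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class LIFParams:
    """Leaky integrate-and-fire parameters.

    ``alpha`` is the per-timestep membrane decay (``exp(-1/tau_m)`` for a
    membrane time constant ``tau_m`` in timesteps).  ``strict_threshold``
    selects whether a neuron fires on ``v > v_th`` (default) or ``v >= v_th``.
    """

    alpha: float
    v_threshold: float
    tau_m: float | None = None
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.v_threshold <= 0:
            raise ValueError("v_threshold must be positive")

    @classmethod
    def from_tau(cls, tau_m: float, v_threshold: float, **kw) -> "LIFParams":
        return cls(alpha=math.exp(-1.0 / tau_m), v_threshold=v_threshold,
                   tau_m=tau_m, **kw)


@dataclass
class NeuronState:
    """Membrane potentials and binary spike states of the post population."""

    v: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.v.shape != self.z.shape or self.v.ndim != 1:
            raise ValueError("v and z must be 1-D vectors of equal length")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z entries must be 0 or 1")

    @classmethod
    def zeros(cls, n_post: int) -> "NeuronState":
        return cls(v=np.zeros(n_post), z=np.zeros(n_post, dtype=np.int64))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_random_layer(
    n_pre: int,
    n_post: int,
    delay_range: int,
    density: float,
    weight_bound: int = 32,
    seed: int | None = None,
    excitatory_only: bool = False,
) -> SNNLayerModel:
    """Bernoulli-connected layer with uniform integer weights and delays.

    Each (j, i) pair is connected independently with probability ``density``;
    connected weights are nonzero integers drawn uniformly from
    ``[-weight_bound, weight_bound]`` (or ``[1, weight_bound]`` when
    ``excitatory_only``); delays are uniform on ``[0, delay_range - 1]``.
    """
    if n_pre <= 0 or n_post <= 0 or delay_range <= 0:
        raise ValueError("n_pre, n_post and delay_range must be positive")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    if weight_bound < 1:
        raise ValueError("weight_bound must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (n_post, n_pre)
    connected = rng.random(shape) < density
    magnitude = rng.integers(1, weight_bound + 1, size=shape)
    if excitatory_only:
        sign = np.ones(shape, dtype=np.int64)
    else:
        sign = rng.choice(np.array([-1, 1]), size=shape)
    weights = np.where(connected, magnitude * sign, 0)
    delays = np.where(connected, rng.integers(0, delay_range, size=shape), 0)
    return SNNLayerModel(n_pre, n_post, delay_range, weights, delays,
                         connected, density)


def generate_cortex_like(seed: int | None = None) -> SNNLayerModel:
    """Excitatory-to-inhibitory projection of a balanced random network.

    A 1000-neuron cortex-like network at the classic 4:1 excitation/inhibition
    split: 800 excitatory pre-neurons project onto 200 inhibitory
    post-neurons with fixed connection probability 0.1 and synaptic delays
    uniform on {0, 1, 2, 3} timesteps.  Weights are positive (excitatory).
    """
    return generate_random_layer(800, 200, 4, 0.1, weight_bound=10, seed=seed,
                                 excitatory_only=True)


def generate_gesture_like(seed: int | None = None,
                          density: float = 0.0316) -> SNNLayerModel:
    """Input-to-hidden layer shaped like a radar gesture-recognition SNN.

    2048 input neurons, 20 hidden neurons, four synaptic delays, with the
    sparse trained-connectivity density of about 3.16% by default.
    """
    return generate_random_layer(2048, 20, 4, density, weight_bound=32,
                                 seed=seed)


def generate_poisson_spikes(rate: float, T: int, n_pre: int,
                            seed: int | None = None) -> SpikeTrain:
    """Discrete-time Poisson input: independent Bernoulli(rate) per bin."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    if T <= 0 or n_pre <= 0:
        raise ValueError("T and n_pre must be positive")
    rng = np.random.default_rng(seed)
    return SpikeTrain((rng.random((T, n_pre)) < rate).astype(np.int64))


# ---------------------------------------------------------------------------
# reference synaptic processing and neural update
# ---------------------------------------------------------------------------

def synaptic_oracle(model: SNNLayerModel, spikes: SpikeTrain, t_start: int,
                    batch: int) -> np.ndarray:
    """Dense per-synapse reference currents, shape ``(batch, n_post)``.

    Computes ``I_j(t_r) = sum_i W[j,i] * x_i(t_r - D[j,i])`` for
    ``t_r = t_start .. t_start + batch - 1`` by direct delayed gathering over
    every connected synapse, in exact integer arithmetic.  Independent of the
    stacked-operand formulation; anchors all correctness tests.
    """
    d = model.delay_range
    if t_start < d - 1:
        raise IndexError(f"t_start={t_start} needs delay history of {d - 1} steps")
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if t_start + batch > spikes.T:
        raise IndexError("spike train too short for requested batch")
    if spikes.n != model.n_pre:
        raise ValueError("spike train width does not match n_pre")
    x = spikes.values
    pre_idx = np.arange(model.n_pre)[None, :]  # (1, n_pre)
    out = np.zeros((batch, model.n_post), dtype=np.int64)
    for r in range(batch):
        t_r = t_start + r
        # delayed spike seen by each synapse (j, i)
        xd = x[t_r - model.delays, pre_idx]
        out[r] = np.sum(np.where(model.connected, model.weights * xd, 0), axis=1)
    return out


def lif_update(state: NeuronState, currents: np.ndarray,
               params: LIFParams) -> NeuronState:
    """One LIF step: decay, integrate, soft-reset, threshold."""
    currents = np.asarray(currents)
    if currents.shape != state.v.shape:
        raise ValueError("currents length must equal the population size")
    v_new = currents + params.alpha * state.v - state.z * params.v_threshold
    if params.strict_threshold:
        z_new = (v_new > params.v_threshold).astype(np.int64)
    else:
        z_new = (v_new >= params.v_threshold).astype(np.int64)
    return NeuronState(v=v_new, z=z_new)
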