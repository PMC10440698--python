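# echelonsnn

A compiler-and-emulator toolkit for accelerating spiking-neural-network
(SNN) synaptic processing on multi-core integer MAC arrays, written for
researchers who map SNN layers onto fixed-geometry neuromorphic accelerators
(one 4x16 multiply-accumulate array plus an ARM core per processing
element, 120 KB of local memory each) and need the accelerated path to be
*provably equivalent* to direct dense synaptic processing.

## The problem and the method

A layer of leaky integrate-and-fire (LIF) neurons with per-synapse integer
conduction delays evolves as

```
V_j(t+1) = Σ_i W_ji · x_i(t − d(j,i)) + α·V_j(t) − z_j(t)·V_th
```

The delayed weighted sum (synaptic processing) dominates both runtime and
memory — the package's closed forms put it at 10²–10³ times the cost of the
neural update for realistic layers — so it is the part worth pushing onto
the MAC array. The toolkit implements the full acceleration chain:

1. **Operand stacking** — fold the per-delay weight matrices into one
   *weight-delay map* (operand B, row `k·n_pre + i` holds the delay-`k`
   weights) and the spike history into an *input-spike-train map*
   (operand A), so a single aligned matmul yields one current vector per
   delay.
2. **Information densification** (lossless): *Zero Elimination* drops
   all-zero B rows and the matching A columns; *Proportion Merger* collapses
   rows that are exact integer multiples of a common base row, migrating the
   factors into runtime input preprocessing; *Echelon Reorder* permutes the
   rows so first-nonzero columns are non-decreasing; *Circle Reverse*
   decomposes that permutation into reversed cycles so A's columns can be
   permuted in place, O(n) moves with one spare column per cycle.
3. **Two-stage splitting** — *alignment splitting* covers the echelon
   matrix with a minimal family of right-anchored rectangles on the 4-row /
   16-column MAC grid (optionally trading the final 16-column block for an
   `m`-column ARM strip, `m = n_post mod 16`); *core splitting* deals the
   rectangles onto the fewest processing elements with per-PE loads balanced
   to within one 4-row slice.
4. **Role-based deployment and emulation** — one *Dominant* PE preprocesses
   the input map and collects results; *Subordinate* PEs hold weight
   fragments and run the emulated integer MAC array (32-bit accumulation,
   optional saturation). The compiled path reproduces the dense per-synapse
   reference bit-for-bit.
5. **Analytic cost models** — per-approach memory accounting (serial ARM,
   original MAC, echelon pure/mixed), the memory optimization rate, the
   column alignment rate `(16−m)/(n_post+16−m)`, and the closed-form
   synaptic/neural ratios `0.67·n_pre·d` (time) and
   `1.94 + 0.24·n_pre·(4/n_post + d)` (memory).

## Worked example

Compile and audit the cortex-like benchmark layer (800 excitatory neurons
projecting onto 200 inhibitory neurons with connection probability 0.1 and
delays uniform on 0..3):

```bash
python examples/03_split_and_deploy.py
```

prints (abridged):

```
benchmark layer: 800 -> 200, 16064 synapses, delays 0..3

PURE_MAC: 13 MAC rectangle(s)
  stored weight values: 562368 of 656448 aligned cells (85.7%)
  PEs: 1 Dominant + 5 Subordinate, per-PE value counts [112320, 112320, 112704, 112320, 112704]
  PE0 (DOMINANT   ):   29164 / 122880 bytes
  PE1 (SUBORDINATE):  115648 / 122880 bytes
  ...
MIXED: 12 MAC rectangle(s) + ARM strip of 8 column(s)
  stored weight values: 537120 of 656448 aligned cells (81.8%)
```

The echelon split stores 85.7% (pure MAC) or 81.8% (mixed) of the aligned
operand cells, the layer deploys as one Dominant plus five Subordinate PEs,
and every PE stays inside its 120 KB budget. `examples/05_cost_models.py`
extends this to the four-approach memory comparison (echelon mixed ends at
82.7% of the original-MAC footprint on this layer) and evaluates the
closed-form ratios — e.g. the gesture-shaped layer (2048 inputs, 20 hidden
neurons, 4 delays) gives a synaptic/neural time ratio of 5488.64 and a
memory ratio of 2066.32, meaning synaptic processing dwarfs the neural
update in both dimensions.

Every example verifies equivalence on the way: `04_emulate_network.py` runs
a 100-step Poisson-driven LIF network through both the dense reference and
the compiled multi-core pipeline and checks the spike rasters and membrane
traces are identical.

A thin CLI wraps the same library calls:

```bash
echelonsnn gen-model --kind cortex --seed 1 --out model.json
echelonsnn gen-spikes --rate 0.1 -T 50 --n-pre 800 --seed 2 --out spikes.csv
echelonsnn compile --model model.json --out plan.json
echelonsnn verify --model model.json --spikes spikes.csv   # "0 mismatches"
echelonsnn report --eq5 2048 20 4                          # 2066.32
```

## Layout

- `src/echelonsnn/` — `model` (layers, generators, dense oracle, LIF),
  `operands` (stacking/alignment), `densify` (the four densification
  algorithms), `splitting` (alignment/core splitting, processor choice),
  `emulator` (MAC array, deployment, execution), `costmodel` (accounting
  and closed forms), `io` (containers), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices and known limitations.
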