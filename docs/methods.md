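# Methods

## Model and scope

The package operates on a single SNN layer: `n_pre` pre-synaptic neurons
connected to `n_post` post-synaptic LIF neurons, each connected pair
carrying a signed integer weight `W_ji` and an integer conduction delay
`d(j,i)` in `[0, delay_range − 1]` timesteps. Synaptic processing at step
`t` is the delayed weighted spike sum `I_j(t) = Σ_i W_ji · x_i(t − d(j,i))`;
the neural update is the discrete LIF recurrence

```
v' = I + α·v − z·V_th,     z' = [v' > V_th]
```

with soft reset by threshold subtraction. The decay factor is
`α = exp(−Δt/τ_m)` with `Δt` = one timestep, so `0 < α < 1`; the threshold
comparison is strict by default with a documented flag
(`LIFParams.strict_threshold`) to switch to `≥`, since either convention is
defensible. Delay `0` means a spike contributes in the timestep it occurs.
Out of scope by design: conductance-based or multi-compartment neurons,
plasticity/training, refractory periods, multi-layer routing/placement, and
timing- or energy-accurate hardware simulation — communication between
emulated cores is modelled logically, not timed.

Everything downstream is anchored by `synaptic_oracle`, a direct
per-synapse delayed gather in exact integer arithmetic that shares no code
with the stacked/compiled path. "Correct" throughout the package means
*bit-identical to this oracle*, and the test suite enforces that across a
randomized grid (delays 1–8, densities 0.02–1, up to 256×64 neurons, both
splitting modes, full LIF runs included).

## Operand geometry

The target accelerator consumes 4 rows of operand A and 16 columns of
operand B per cycle, so operand shapes are aligned up to multiples of 4
(rows) and 16 (B columns). The weight-delay map stacks per-delay weight
matrices delay-major (row `k·n_pre + i`); the pre-major alternative is
mathematically equivalent, delay-major was chosen because it keeps each
per-delay block contiguous. The input map's batch defaults to
`delay_range`, so one matmul produces one result per delay — this is also
the granularity at which per-frame time accounting divides by the delay
count.

## Densification choices

* **Proportionality test**: exact integer proportionality only. A row's
  canonical form is the row divided by the positive gcd of its magnitudes;
  rows merge when they share that canonical form, so a row and its negation
  do *not* merge (factors must be positive) and no floating-point tolerance
  enters — bit-exactness is the contract. A family is merged only if the
  sum of its factors fits the operand precision (127 for signed 8-bit),
  because that sum bounds the preprocessed entries of operand A.
* **Echelon reorder** emits each row once at its first nonzero column,
  scanning columns left to right with ties broken by ascending row index —
  i.e. a stable sort on the first-nonzero index. This is the only reading
  that produces a permutation, which the cycle decomposition requires.
  All-zero rows (normally removed earlier by Zero Elimination) are
  defensively placed last.
* **Pipeline order** is fixed: Zero Elimination → Proportion Merger →
  Echelon Reorder; the merged matrix is zero-padded to a 4-row multiple
  *before* reordering so every split fragment lies on the MAC row grid and
  padding rows stay as fixed points at the bottom of the permutation.
* **Circle Reverse** stores each permutation cycle with its start first and
  the remaining elements reversed; applying a cycle buffers one column,
  walks the reversed order copying successor onto predecessor, and drops the
  buffer on the start's target. Singleton cycles are skipped entirely, so a
  dense layer (identity permutation) carries zero reorder metadata.

## Splitting

Alignment splitting covers the echelon matrix with *right-anchored*
rectangles whose column starts sit on 16-column gridlines and whose heights
are 4-row multiples: for each gridline, the dividing row is where the
echelon boundary crosses it, shifted downwards to the 4-row grid (safe
because the boundary is non-decreasing). Per 4-row band this picks the
rightmost admissible start, so the covered area is minimal within the
family — the tests verify this against an exhaustive per-band search. The
right-anchored family itself is a design choice inferred from the staircase
geometry (upper rows span full width); non-rectangular or column-cut
tilings are out of scope.

The mixed variant truncates the final 16-column block from the MAC
rectangles and stores instead an ARM strip of the `m` true residual columns
(`m = n_post mod 16`, with 16 meaning "no residual"). The strip spans the
full banded row extent — the same rows whose final block the pure split
stores — so the stored-value ratio on the differing region is exactly
`m/16`; restricting it to rows with residual data would save marginally
more but break that closed-form identity and complicate fragment
bookkeeping.

Core splitting computes `pe_count = ceil(total stored values / per-PE value
budget)` — never more, to keep cores full — cuts rectangles into 4-row
slices and assigns them contiguously in scan order. Balancing proceeds in
three stages: adaptive greedy seeding on remaining-equal-share targets,
pairwise diffusion of single slices across cut points, and (only if the
spread still exceeds one maximal slice) an exact feasibility search for a
load window of that width via interval reachability over prefix sums. The
budget is expressed in stored weight values; byte conversion (and the
fixed per-PE buffers subtracted from the 120 KB budget before weights are
dealt) lives in the cost model.

## Emulation

The MAC array emulator enforces the hardware contract rather than hiding
it: misaligned shapes or out-of-range operands raise instead of being
padded silently. Accumulation is 32-bit regardless of configured output
width; narrower outputs saturate with a symmetric clamp (±(2^(b−1)−1)) — a
package choice, since overflow semantics for narrow outputs are otherwise
unspecified. ARM-strip fragments use the same integer semantics, so the
mixed mode remains bit-exact. Cycle counts follow the outer-product tiling
`(a_rows/4)·(b_cols/16)·inner`, and every MAC invocation additionally pays
`CostParams.mac_setup_cycles` (default 64) of configuration overhead in the
*cost model* (not in the emulated arithmetic). That setup constant is what
makes the documented pure-vs-mixed speed crossover exist at all: with bare
per-element cycle counts (MLA = 2 cycles vs one tile-cycle per inner
element) the ARM strip could never beat the array, whereas with invocation
overhead it wins precisely for small residuals and few rows.

A deployment has exactly one Dominant PE (input map, merge record, reversed
circles, final output) and `pe_count` Subordinates (weight fragments plus a
temporary output); every image is byte-audited against the 120 KB budget at
build time and a violation names the offending PE and overage.

## Cost accounting

Byte widths are explicit `CostParams` (defaults: 1-byte operands, 4-byte
outputs/currents, 4-byte indices). The four approaches count:

* `SERIAL_ARM` — unaligned operands: per-batch input frames, dense
  `n_pre·n_post·d` weights, output, and a per-delay current ring buffer.
* `ORIGINAL_MAC` — the stacked-operand MAC baseline without densification:
  fully aligned input and weight-delay maps, aligned output, per-PE
  temporary outputs, current buffer.
* `ECHELON_MAC` / `ECHELON_MIXED` — Dominant (input map over surviving
  columns, reversed-order metadata, output) plus Subordinates
  (rectangle/strip-stored weights, temporary outputs).

The memory optimization rate is `r_opt = 1 − covered/aligned` over the
aligned echelon-matrix area. Monte-Carlo sweeps in the tests confirm its
qualitative behaviour: increasing in delay range, decreasing in density,
and sawtoothing with period 16 in `n_post` (a drop just past each multiple
of 16, a surge back at the next one, downward overall). One honest
limitation surfaced by the same accounting: on operands that are *not*
sparse (density ≳ 0.5, or fully dense layers whose per-delay blocks still
interleave), the rectangle cover saves almost no area while the
reversed-order metadata still costs a few hundred bytes, so the echelon
approaches can exceed the stacked-aligned baseline by a few percent. The
densification chain pays off exactly where it is intended to: sparse
operands, larger delay ranges — on the cortex-like benchmark the package
computes 86.3% (pure) / 82.7% (mixed) of the original-MAC footprint.

The closed-form ratios implement the printed coefficients verbatim —
`0.67·n_pre·d` for time and `1.94 + 0.24·n_pre·(4/n_post + d)` for memory —
so the reference values reproduce exactly at two decimals; the exact
expansions they round (`n_pre·d·MLA/(MLA+CMP)` with MLA = 2, CMP = 1, and
`(4·n_pre + n_pre·n_post·d + 8·n_post)/(4.125·n_post)`) are provided as
separately named `*_exact` variants and diverge from the rounded forms by
well under 2%.

## Synthetic data

No public dataset accompanies the benchmark layers, so the generators
emulate their published shapes: Bernoulli connectivity at a stated density,
uniform integer weights (positive-only for the excitatory cortex-like
projection, signed elsewhere; bounds of 10 and 32 keep comfortable headroom
inside 8-bit operands), uniform delays, and discrete-time Poisson input
realized as independent Bernoulli(rate) bins with `rate ≤ 1`. The
cortex-like layer fixes 800→200 neurons, probability 0.1, delays 0..3; the
gesture-shaped layer fixes 2048→20 neurons, 4 delays, default density
3.16%. These stand-ins match the real models in geometry, density and
precision but not in trained weight structure, so equivalence and
accounting results transfer while any claim about trained-model accuracy or
measured wall-clock/energy on physical hardware does not — hardware
percentages reported for the real systems are outside what this desk-scale
emulator can or does reproduce. Test problem sizes (grids up to 256×64
neurons, 100-step runs, 20-seed Monte-Carlo sweeps) were chosen as the
smallest scales at which every qualitative effect — delay, density and
alignment trends, multi-PE splitting — is exercised.

## Degenerate inputs and numerical notes

All arithmetic on the compiled path is integer; the only floating point is
the LIF membrane (float64), updated identically in both backends so
backend comparisons remain exact. Empty connectivity compiles to an empty
split plan and yields all-zero currents. `align(0, k) = 0`; a layer whose
columns are an exact multiple of 16 has `m = 16` and the mixed split
degenerates to the pure one. Generator edge rates 0 and 1 produce all-zero
and all-one trains. Random draws are all routed through
`numpy.random.default_rng(seed)`; equal seeds give byte-identical models,
trains and plans.
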