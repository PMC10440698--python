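"""Operand stacking: one matmul covers every synaptic delay.

Builds a small random layer with per-synapse delays, stacks its weights into
the weight-delay map (operand B) and the spike history into the
input-spike-train map (operand A), and checks that their product equals the
dense per-synapse reference currents bit-for-bit.
"""

import numpy as np

from echelonsnn import (build_input_map, build_weight_delay_map,
                        generate_poisson_spikes, generate_random_layer,
                        synaptic_oracle)

model = generate_random_layer(n_pre=48, n_post=20, delay_range=4,
                              density=0.15, seed=7)
spikes = generate_poisson_spikes(rate=0.2, T=32, n_pre=48, seed=8)

wd = build_weight_delay_map(model)
a = build_input_map(spikes, t_start=3, batch=4, model=model)

print(f"layer: {model.n_pre} pre -> {model.n_post} post, "
      f"{model.n_synapses} synapses over {model.delay_range} delays")
print(f"operand B (weight-delay map): {wd.values.shape} "
      f"(true {wd.true_rows} x {wd.true_cols}, padded to the 4x16 MAC grid)")
print(f"operand A (input map):        {a.values.shape} "
      f"(batch {a.batch} timesteps of stacked spike history)")

product = a.values @ wd.values
reference = synaptic_oracle(model, spikes, t_start=3, batch=4)
print("product == dense oracle:", np.array_equal(
    product[:4, :model.n_post], reference))
# True means the single stacked matmul reproduced the delayed synaptic
# currents of 4 consecutive timesteps exactly.
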