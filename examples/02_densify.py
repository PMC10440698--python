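"""Information densification: shrink operand B, preprocess operand A.

Runs Zero Elimination, Proportion Merger, Echelon Reorder and Circle Reverse
on a sparse weight-delay map, then applies the matched runtime
transformations to the input map and verifies the product is untouched.
"""

import numpy as np

from echelonsnn import (apply_circles_inplace, apply_merge_to_input,
                        build_input_map, build_weight_delay_map,
                        echelon_reorder, find_circles, generate_poisson_spikes,
                        generate_random_layer, proportion_merge,
                        reverse_circles, synaptic_oracle, zero_eliminate)

model = generate_random_layer(n_pre=64, n_post=24, delay_range=6,
                              density=0.05, seed=21)
spikes = generate_poisson_spikes(0.2, 40, 64, seed=22)

wd = build_weight_delay_map(model)
reduced, selection = zero_eliminate(wd)
merged, record = proportion_merge(reduced)
e = echelon_reorder(merged)
circles = reverse_circles(find_circles(e.src_idx_list, e.tgt_idx_list))

print(f"operand B rows: {wd.padded_rows} aligned "
      f"-> {reduced.shape[0]} after zero elimination "
      f"-> {merged.shape[0]} after merging "
      f"({len(record.groups)} proportional familie(s))")
print(f"echelon boundary: first nonzero column per row, "
      f"{e.boundary[0]} .. {e.boundary[-1]} (non-decreasing)")
print(f"row permutation splits into {circles.circle_count} circle(s); "
      f"reversed circles allow in-place input reordering with one spare "
      f"column per circle")

a = build_input_map(spikes, 5, 6, model).values
a = apply_merge_to_input(a[:, selection.kept], record)
a = np.pad(a, ((0, 0), (0, e.n_rows - a.shape[1])))
a, moves = apply_circles_inplace(a, circles, count_moves=True)
print(f"input columns moved in place: {moves} "
      f"(bound: columns + circles = {e.n_rows + circles.circle_count})")

got = (a @ e.values)[:6, :model.n_post]
want = synaptic_oracle(model, spikes, 5, 6)
print("densified product == dense oracle:", np.array_equal(got, want))
# The densified operands are smaller yet the currents are bit-identical.
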