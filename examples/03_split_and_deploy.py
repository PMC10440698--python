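"""Two-stage splitting and role-based deployment of a cortex-like layer.

Compiles the 800-excitatory -> 200-inhibitory benchmark layer (connection
probability 0.1, delays 0..3): alignment splitting covers the echelon matrix
with MAC-aligned rectangles, core splitting deals them onto balanced
processing elements, and the deployment assigns Dominant/Subordinate roles
under the 120 KB per-PE budget.
"""

from echelonsnn import SplitMode, compile_layer, generate_cortex_like

model = generate_cortex_like(seed=3)
print(f"benchmark layer: {model.n_pre} -> {model.n_post}, "
      f"{model.n_synapses} synapses, delays 0..{model.delay_range - 1}")

for mode in (SplitMode.PURE_MAC, SplitMode.MIXED):
    plan = compile_layer(model, mode=mode)
    split = plan.split_plan
    stored = sum(split.per_pe_value_counts)
    aligned = plan.echelon.n_rows * plan.echelon.n_cols
    print(f"\n{mode.value}: {len(split.rectangles)} MAC rectangle(s)"
          + (f" + ARM strip of {split.arm_strip.col_count} column(s)"
             if split.arm_strip else ""))
    print(f"  stored weight values: {stored} of {aligned} aligned cells "
          f"({stored / aligned:.1%})")
    print(f"  PEs: 1 Dominant + {split.pe_count} Subordinate, "
          f"per-PE value counts {split.per_pe_value_counts}")
    for i, img in enumerate(plan.pe_images):
        print(f"  PE{i} ({img.role.value:11s}): {img.byte_total:7d} / "
              f"{img.budget_bytes} bytes")
# Every PE stays inside its 120 KB budget; the mixed mode trades the final
# 16-column block for a narrow ARM strip, storing fewer aligned zeros.
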