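"""Analytic cost models: closed-form ratios and per-approach memory reports.

Evaluates the synaptic-vs-neural time and memory ratios at the two benchmark
geometries, then compares the memory accounting of the four synaptic
processing approaches on the cortex-like layer.
"""

from echelonsnn import (Approach, SplitMode, compile_layer,
                        generate_cortex_like, memory_report,
                        mixed_vs_pure_strip_memory, synap_neural_mem_ratio,
                        synap_neural_time_ratio)

for name, (n_pre, n_post, d) in {"gesture-like": (2048, 20, 4),
                                 "cortex-like": (800, 200, 4)}.items():
    t = synap_neural_time_ratio(n_pre, d)
    m = synap_neural_mem_ratio(n_pre, n_post, d)
    print(f"{name:13s} synaptic/neural time ratio {t:10.2f}  "
          f"memory ratio {m:8.2f}")
# Both ratios are far above 1: synaptic processing dominates SNN inference,
# which is why it is the part worth accelerating.

print(f"\nARM strip vs pure-MAC final block at residual m=1: "
      f"{mixed_vs_pure_strip_memory(1):.2%} of the memory")

model = generate_cortex_like(seed=9)
plans = {Approach.ECHELON_MAC: compile_layer(model, mode=SplitMode.PURE_MAC),
         Approach.ECHELON_MIXED: compile_layer(model, mode=SplitMode.MIXED)}
print(f"\nmemory accounting for the cortex-like layer "
      f"({model.n_pre}->{model.n_post}, density 0.1, d=4):")
baseline = None
for approach in Approach:
    if approach in plans:
        p = plans[approach]
        rep = memory_report(model, approach, e=p.echelon, plan=p.split_plan,
                            circles=p.circles, record=p.merge_record)
    else:
        rep = memory_report(model, approach)
    if approach is Approach.ORIGINAL_MAC:
        baseline = rep.total_bytes
    rel = f" ({rep.total_bytes / baseline:.1%} of original MAC)" \
        if baseline and approach is not Approach.ORIGINAL_MAC else ""
    print(f"  {approach.value:14s} {rep.total_bytes:8d} bytes, "
          f"{rep.pe_count} PE(s){rel}")
# The echelon approaches store only the rectangle/strip-covered weights and
# so undercut the fully aligned original-MAC operands on this sparse layer.
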