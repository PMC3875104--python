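"""Batch stability classification of seeded romantic-style scenarios.

Parameter sets are drawn from the sign regions of two named styles —
secure/cautious lover (alpha1 > 0, beta1 > 0) and hermit (alpha2 > 0,
beta2 < 0) — and each is classified by both stability criteria.
"""

from couplefde import run_sweep, sample_scenarios

scenarios = sample_scenarios(["secure_cautious", "hermit"], n=15, seed=42)
table = run_sweep(scenarios)

print(table[["alpha1", "beta1", "beta2", "a2_coeff",
             "routh_verdict", "arg_verdict"]].head(6).to_string(index=False))
print("\nverdict counts:", dict(table["routh_verdict"].value_counts()))
print("verdicts agree in", int(table["verdicts_agree"].sum()),
      "of", len(table), "scenarios")
print("\nAny draw with a2 < 0 would be unstable (a positive real eigenvalue")
print("exists); draws with a1, a2 > 0 are stable for all orders in (0, 1).")
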