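"""How surprising is a 12.45-year survival beyond age 110?

Evaluates the closed-form last-survivor exceedance probability for a cohort
of 80 plateau-phase individuals (annual survival 0.5), cross-checks it by
Monte Carlo, and shows how the probability grows with cohort size.
"""

from plateaurecord import ConstantHazard, estimate_exceedance_mc, last_survivor_exceedance, max_survivor_quantiles

T, N, P = 12.45, 80, 0.5

analytic = last_survivor_exceedance(T, N, P)
print(f"P(any of {N} survives >= {T} years | annual survival {P}) = {analytic:.4f}")

mc = estimate_exceedance_mc(T, N, ConstantHazard(P), reps=200_000, seed=1)
print(f"Monte Carlo ({mc.reps} cohorts): {mc.mc_estimate:.4f}, "
      f"95% CI ({mc.mc_ci[0]:.4f}, {mc.mc_ci[1]:.4f})")

for n_big in (500, 5000):
    print(f"  same record in a worldwide-scale cohort of {n_big}: "
          f"{last_survivor_exceedance(T, n_big, P):.3f}")

med, q99 = max_survivor_quantiles(N, ConstantHazard(P), reps=100_000, seed=2,
                                  quantiles=[0.5, 0.99])
print(f"Typical record in a cohort of {N}: median {med:.1f} years beyond entry, "
      f"99th percentile {q99:.1f} years")

print("\nReading: a 12.45-year record among 80 supercentenarians has ~1.4%")
print("probability under a constant-hazard plateau; the usual record is ~6-7")
print("years, and even the 99th percentile falls short of 12.45 years.")
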