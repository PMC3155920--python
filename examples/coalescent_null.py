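"""Build a per-gene coalescent null and compute an empirical p-value.

A gene with S = 25 segregating sites and a markedly negative Tajima's D is
compared against 1,000 neutral replicates matched to its sample size,
length and local recombination rate, conditioned on the same S.
"""

from panselect.coalescent import constant_model, empirical_pvalue, null_distributions

observed_tajima_d = -1.9

nulls = null_distributions(
    constant_model(48),
    L=8_000,
    rho=1.2e-8,
    B=1_000,
    seed=11,
    mode="fixed_S",
    S=25,
)
dist = nulls["tajima_d"]
p = empirical_pvalue(observed_tajima_d, dist, tail="lower")

print(f"null Tajima's D: mean {dist.values.mean():+.3f}, "
      f"2.5-97.5% range [{float(sorted(dist.values)[25]):+.2f}, "
      f"{float(sorted(dist.values)[-26]):+.2f}]  (B = {dist.B})")
print(f"observed D = {observed_tajima_d:+.2f}  ->  one-sided p = {p:.4f}")
print()
print("p is the fraction of neutral replicates at least as negative as the "
      "observation (with the +1 convention, so it is never exactly zero); "
      "p < 0.05 corroborates the rare-variant excess.")
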