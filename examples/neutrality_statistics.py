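"""Compute the per-gene neutrality statistics on a small simulated locus.

Simulates one neutral 5 kb locus for 48 chromosomes, wraps it as a
haplotype alignment with an outgroup, and prints the full statistics
record.  Under neutrality every test statistic should sit near zero;
pi and Watterson's theta should agree to within sampling noise.
"""

import numpy as np

from panselect import GeneAlignment, compute_all
from panselect.coalescent import constant_model, simulate_locus

model = constant_model(48, N=10_000, mu=1.5e-8)
locus = simulate_locus(model, L=5_000, rho=1e-8, seed=7)
aln = GeneAlignment.from_binary(locus.genotypes, gene_id="demo", population="AFR",
                                total_length=5_000)
st = compute_all(aln)

print(f"segregating sites S = {st.S}  (tested: {st.tested})")
print(f"pi per site        = {st.pi_site:.6f}")
print(f"theta_W per site   = {st.theta_w_site:.6f}")
print(f"Tajima's D         = {st.tajima_d:+.3f}")
print(f"Fu & Li D*/F*      = {st.fuli_d_star:+.3f} / {st.fuli_f_star:+.3f}")
print(f"Fu & Li D/F        = {st.fuli_d:+.3f} / {st.fuli_f:+.3f}")
print(f"Fay & Wu H (norm)  = {st.faywu_h_norm:+.3f}")
print()
print("All tests near zero is the neutral expectation; strongly negative "
      "values would indicate a rare/high-frequency-derived excess (sweep), "
      "strongly positive ones an intermediate-frequency excess (balancing).")
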