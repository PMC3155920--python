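"""Class-level tests: enrichment on the bundled panel and a permutation test.

First reproduces the published Fisher enrichment P-values from the bundled
132-gene innate-immunity panel calls, then demonstrates the label-
permutation test of class mean diversity on toy values.
"""

import numpy as np
import pandas as pd

from panselect import datasets
from panselect.enrichment import permutation_test_class_mean

enr = datasets.innate_panel_enrichment().set_index(["class_label", "population", "mode"])
for key in [("Acute Phase", "EUR", "balancing"), ("Acute Phase", "AFR", "balancing"),
            ("Complement", "AFR", "balancing"), ("Receptors", "EUR", "either")]:
    row = enr.loc[key]
    print(f"{key[0]:<12s} {key[1]} {key[2]:<9s} 2x2=({row.a},{row.b},{row.c},{row.d})"
          f"  P = {row.p_one_sided:.4f}")

print()
print("These one-sided hypergeometric tails round to the published 0.008, "
      "0.03, 0.01 and 0.04: acute-phase and complement genes are enriched "
      "for balancing-selection calls, receptors for selection overall.")
print()

# permutation test: a deliberately low-diversity 5-gene class among 40 genes
rng = np.random.default_rng(3)
pi = pd.Series(rng.lognormal(np.log(8e-4), 0.4, 40),
               index=[f"g{i:02d}" for i in range(40)])
core = list(pi.index[:5])
pi.loc[core] *= 0.5  # the planted constrained class
res = permutation_test_class_mean(pi, core, B=10_000, seed=1)
print(f"class mean = {res.observed_mean:.2e}; permutation p (lower tail) = "
      f"{res.p_lower:.4f} over B = {res.B} draws")
print("small p: random 5-gene classes almost never have a mean this low.")
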