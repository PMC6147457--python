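"""Two-locus epistasis test and digenic penetrance on planted data.

Simulates 115 animals whose affection status follows the digenic rule
(at least one variant allele at each of two unlinked loci) with a 3%
exception rate, then runs the logistic likelihood-ratio interaction test
and estimates the 3x3 penetrance table.
"""

import numpy as np

from craniomap import epistasis_lrt, genotype_class_label, penetrance_estimate

rng = np.random.default_rng(8)
n = 115
g1 = rng.binomial(2, 0.45, n).astype(float)   # occurrence locus
g2 = rng.binomial(2, 0.75, n).astype(float)   # onset modifier
y = ((g1 >= 1) & (g2 >= 1)).astype(float)
flip = rng.random(n) < 0.03
y = np.where(flip, 1 - y, y)

res = epistasis_lrt(y, g1, g2)
print(f"epistasis LRT: X2 = {res.chisq:.1f} (df = {res.df}), p = {res.p:.2e}")
print(f"log-likelihoods: null {res.ll_null:.2f} -> full {res.ll_full:.2f}")

table = penetrance_estimate(y, g1, g2)
print("\npenetrance P(affected | g1, g2):")
print(table.to_frame().round(2).to_string())
print(f"\ncounts per cell:\n{table.counts}")
print(f"rule concordance: {table.rule_concordance:.3f}")
print("\nexample genotype labels:",
      ", ".join(genotype_class_label(a, b) for a, b in [(0, 0), (1, 1), (2, 2)]))
print()
print("Reading: the interaction term is overwhelmingly supported (the additive")
print("model cannot express the AND rule), and the penetrance table is ~0 in")
print("the first row/column and ~1 in the double-carrier cells.")
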