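"""SVD information filter and gene-pair regression on expression data.

Simulates a four-group patient expression study (50/50/49/100 samples:
control, coronal, metopic, sagittal) where half the probe sets carry a
shared transcript signal and two genes are negatively correlated in the
coronal group only. Filters probe sets by Gene Information Content (the
fraction of a set's variance captured by its first singular value)
against a permuted-map 99th-percentile cutoff, then tests the gene pair
per group.
"""

from craniomap import gic_filter, group_anova_tukey, pair_regression, simulate_expression

study, truth = simulate_expression(
    n_sets=120, set_size=4, signal_fraction=0.5,
    pair_correlation=-0.5, pair_group="coronal", rng=21,
)

filtered, gic = gic_filter(study, n_perm=1000, quantile=0.99, rng=22)
n_sig_kept = len(set(truth["signal_sets"]) & set(filtered.probe_map.unique()))
n_noise_kept = len(set(truth["noise_sets"]) & set(filtered.probe_map.unique()))
print(f"GIC cutoff (99th pct of 1000 permutations): {gic.cutoff:.3f}")
print(f"probe-sets kept: {filtered.probe_map.nunique()}/{study.probe_map.nunique()} "
      f"(signal kept: {n_sig_kept}/{len(truth['signal_sets'])}, "
      f"noise kept: {n_noise_kept}/{len(truth['noise_sets'])})")

x = filtered.gene_expression("GENE_X")
y = filtered.gene_expression("GENE_Y")
anova = group_anova_tukey(y, filtered.groups)
print(f"\nGENE_Y group ANOVA: F = {anova['F']:.2f}, p = {anova['p']:.3g}")

res = pair_regression(x, y, filtered.groups)
print("\nper-group regression of GENE_Y on GENE_X:")
print(res.round(4).to_string())
print()
print("Reading: the filter keeps coherent (rank-1) probe sets and discards")
print("noise sets; the negative slope is significant only in the coronal")
print("group, where the anticorrelation was planted.")
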