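"""End-to-end digenic mapping on a simulated breeding colony.

Simulates a 104-animal colony segregating a two-locus synostosis-like
trait (affected iff at least one variant allele at both the occurrence
locus and the onset modifier; early onset iff modifier-homozygous), draws
the sequenced panel (12 EOS + 12 DOS + 22 ICN), and runs the full
pipeline: QC filters, IBS-kinship mixed-model scans for the occurrence
(synostotic vs normal) and onset (EOS vs DOS) contrasts, an LD block
around each top hit, and the two-locus epistasis/penetrance stage on the
whole colony.
"""

from craniomap import (
    ColonySpec, PipelineConfig, genotyped_subset, run_pipeline, simulate_colony,
)

study, growth, truth = simulate_colony(ColonySpec(), rng=41)
panel = genotyped_subset(study, rng=42)
result = run_pipeline(panel, growth=growth, config=PipelineConfig(),
                      epistasis_panel=study)

top_occ = result.occurrence.scan.nsmallest(1, "p").iloc[0]
top_ons = result.onset.scan.nsmallest(1, "p").iloc[0]
print(f"occurrence top hit : {top_occ['vid']}  p = {top_occ['p']:.2e}  "
      f"(planted block: {truth.occurrence_block_vids[0]}..{truth.occurrence_block_vids[-1]})")
print(f"onset top hit      : {top_ons['vid']}  p = {top_ons['p']:.2e}  "
      f"(planted block: {truth.modifier_block_vids[0]}..{truth.modifier_block_vids[-1]})")
print()
print("blocks around the occurrence hit:")
print(result.occurrence.block_table.to_string(index=False))
print()
best = result.epistasis_table.iloc[0]
print(f"best epistatic pair: {best['locus1']} x {best['locus2']}  "
      f"X2 = {best['chisq']:.1f}  p = {best['p']:.2e}")
print()
print("digenic penetrance table (rows: occurrence dosage, cols: modifier dosage):")
print(result.penetrance.to_frame().round(2).to_string())
print(f"rule concordance: {result.penetrance.rule_concordance:.3f}")
print()
print("Reading: both scans land in the planted blocks, the best-supported pair")
print("is the planted one, and the penetrance table shows the one-copy-of-each")
print("pattern (affected only when both dosages are >= 1). Interaction evidence")
print("is modest at colony scale: it rests on the few unaffected animals that")
print("carry one causal allele but not the other.")
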