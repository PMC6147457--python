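# Methods

This note documents the statistical models implemented in `craniomap`,
the choices made where the underlying methodology is ambiguous, what the
synthetic colony generator does and does not emulate, and the numerical
conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mixed-model association

**Model.** The scan treats the binary diagnosis as a quantitative 0/1
trait in a single-variance-component linear mixed model

    y = Xb + g·β + u + e,   u ~ N(0, σ_g² K),   e ~ N(0, σ_e² I),

with K the identity-by-state kinship matrix,
`K_ij = mean over co-called variants of (1 − |g_i − g_j|/2)`. Treating a
binary trait this way is the same approximation the EMMAX software makes;
it is adequate for ranking and thresholding in strongly familial cohorts
but its betas are not odds ratios.

**REML.** With X = intercept only, the restricted likelihood is a 1-D
function of the variance ratio δ = σ_e²/σ_g² after projecting out X and
eigendecomposing the projected kinship (the EMMA identity). δ is found by
a 200-point grid on log δ ∈ [−5, 5]·ln 10 followed by bounded Brent
refinement; the grid guards against multimodal profiles. When the profile
is flat (e.g. K = I, where only σ_g² + σ_e² is identified) the fit is
flagged non-identifiable. A diagonal jitter of 1e-8 is added to K before
decomposition.

**Per-SNP test.** Variance components are estimated once under the null
and reused for every SNP (the EMMAX approximation; an exact per-SNP REML
refit mode exists and is used as an oracle in tests). Each SNP is tested
by GLS on data whitened by (K + δI)^(−1/2), with a Wald t-test on n − 2
degrees of freedom: at K = I this reduces exactly to OLS simple
regression, which the tests assert at 1e-10. Missing genotypes are
mean-imputed within the analysis cohort *for the regression only*; they
remain missing everywhere else. Monomorphic variants reaching the scan
raise (the filter contract); polymorphic but constant-dosage variants
(every animal heterozygous) get NaN statistics. Genome-wide significance
is declared at p ≤ 5×10⁻⁸.

**Companion statistics.** The reported "proportion of variability
explained" is the squared Pearson correlation between phenotype and
dosage — the quantity is not standardly defined for this reporting and
the convention is explicit. The allelic χ² is Pearson's statistic on the
2×2 minor/major × case/control allele-count table (allele counting chosen
over genotype counting; the source convention is unstated). The relative
risk contrasts case rates in carriers (≥1 minor allele) versus
non-carriers, with the Haldane–Anscombe 0.5 correction (flagged) when any
cell is empty. FDR is Benjamini–Hochberg step-up.

## LD blocks

Two-locus haplotype frequencies for unphased genotypes come from EM
(only the double heterozygote is phase-ambiguous; convergence at relative
log-likelihood change < 1e-10). D′ uncertainty follows the
confidence-interval block method: with allele frequencies held at their
MLEs and the sign of D fixed at the EM estimate, the multinomial
likelihood of the 3×3 genotype table is evaluated on a 101-point |D′|
grid; the normalized cumulative likelihood's 0.05 and 0.95 crossings give
the bounds. LOD is log10 L(MLE)/L(D=0). Pair classes: strong LD iff
upper ≥ 0.95 and lower ≥ 0.55; strong recombination iff upper < 0.90
(the 0.90 is the conventional default — only the strong-LD bounds were
overridden in the source analysis); otherwise uninformative. A block is
any interval whose endpoint pair is strong LD and whose informative pairs
are ≥ 85% strong; maximal bp-span intervals are selected first, leftmost
on ties, non-overlapping. The "upper CI = 0.95" is read as a threshold on
the upper bound, not a redefinition of the interval level. Display
classes mirror the conventional LD-plot palette: bright red (LOD ≥ 2,
D′ = 1 within 1e-9), pink (LOD ≥ 2, D′ < 1), blue (LOD < 2, D′ = 1),
white otherwise; "LOD = 2" is read as LOD ≥ 2.

Tag SNPs are chosen greedily (most uncovered members at r² ≥ 0.8 first);
greedy set cover is within the usual logarithmic factor of optimal and
matches the exhaustive minimum on the small fixtures tested. Group MAF
mapping fixes each SNP's minor allele in the pooled cohort so per-group
values are comparable, treats per-SNP MAFs as replicates, and applies
one-way ANOVA with Tukey–Kramer post-hocs.

## Epistasis, penetrance, growth, diagnosis

Logistic regression is damped-Newton IRLS (gradient norm < 1e-8, ≤100
iterations, ridge 1e-10 on the Hessian for degenerate weights). Complete
separation is detected (all fitted probabilities saturated) and flagged;
inference then rests on the likelihood ratio, never Wald. The epistasis
test compares `y ~ g1 + g2` against `y ~ g1 + g2 + g1·g2` with additive
dosage coding (df = 1, the default) or genotype-factor coding (df = 4);
the source analysis does not state its coding, so both are exposed.
X² = 2ΔLL. The published table's "LL" column is internally inconsistent
with X² = 2ΔLL and is not reproduced; both model log-likelihoods are
reported instead.

Penetrance is the per-cell affected fraction over the 3×3 dosage grid;
rule concordance is the fraction of animals whose status matches the
deterministic digenic rule (affected ⇔ g1 ≥ 1 and g2 ≥ 1). Growth is
analyzed by two-way fixed-effects ANOVA (group × interval, type-II sums
of squares) with Tukey–Kramer comparisons of group means. Diagnosis from
radiographs: fused at day 10 → EOS; day-10→25 growth (averaged over
sides) strictly below the lower bound of the 95% *confidence interval of
the mean* of the unaffected reference → DOS; else ICN. That criterion is
the published one; because it uses the CI of the mean rather than a
prediction interval, it deliberately over-calls DOS among slow-growing
normals when the reference is large — a property visible in the
pipeline's diagnosis-vs-truth agreement (~0.9 on synthetic colonies).

## Case-control power

The indirect-association model: disease locus with risk allele frequency
`raf` and genotype relative risks scaled so that penetrances average to
the prevalence; marker haplotypes from D′ (D = D′·Dmax); expected marker
genotype frequencies in cases and *screened* (unaffected) controls by
Bayes inversion under random union of gametes. Power is the upper tail of
the noncentral chi-square at the α critical value.

Defaults where the source states nothing: prevalence 0.10, multiplicative
risks (rr_hom = rr_het², with additive and dominant modes available), 1:1
control:case ratio, marker allele frequency equal to the risk allele
frequency. The noncentrality is, by default, the likelihood-ratio (G²)
statistic evaluated on the expected 2×3 count table rather than the
Pearson form: at colony-scale samples (24 + 24) the Monte-Carlo power of
the realized Pearson test (null size verified nominal) is tracked closely
by the G² noncentrality, while the Pearson-on-expected-counts form
under-predicts it by several points; both are available via `ncp_kind`.
The 1-df option uses the Cochran–Armitage trend contrast on allele
dosage. The Monte-Carlo oracle simulates multinomial genotype counts per
study and applies the practitioner's chi-square test (empty genotype
columns dropped with the df reduced accordingly).

## Expression information filter

GIC of a probe set = σ₁²/Σσᵢ² of its row-centered probes × samples
submatrix (centering is a choice — "normalized data" does not pin it
down — and an uncentered mode exists). Single-probe sets score exactly 1,
so the permutation null is only meaningful on studies whose sets have ≥2
probes. The cutoff permutes the probe→set map (the multiset of set sizes
is preserved exactly: probes are permuted against a fixed set layout),
recomputes every permuted set's GIC — batched SVDs grouped by set size —
and takes the 99th percentile of the pooled permuted scores over 1,000
permutations by default. Gene-level summaries for ANOVA/regression are
the mean of a gene's surviving probes (first-right-singular-vector scores
available); GIC filtering is applied before group comparisons by default.

## Synthetic colony generator

**What it emulates.** A 104-animal, multi-generation breeding colony from
24 founders; 5,000 biallelic markers in 10-marker, ~250 kb blocks on 20
chromosomes; block-structured LD from per-block pools of 20 haplotypes
(founder chromosomes carry a balanced multiset of pool haplotypes, so
founder allele frequencies equal pool frequencies — the pool model exists
precisely to control frequency and D′); Mendelian gene-dropping of whole
block haplotypes; a planted digenic pair on separate chromosomes —
occurrence allele at pool frequency 0.45, onset-modifier at 0.80 —
with the phenotype rule *affected iff ≥1 copy at both loci*, a 2% label
exception rate, and early onset iff modifier-homozygous; growth at 72.5%
of normal (the stated 70–75% band is enforced as a hard validation) with
EOS animals fused at day 10; and a sequenced panel of 12 EOS + 12 DOS +
22 ICN drawn from the colony.

Why these frequencies: the group allele-frequency profile of the mapped
blocks shows the onset-modifier allele common in *every* diagnosis group
(so normal controls are mostly occurrence non-carriers, which is what
gives the occurrence contrast its power), and the normal-control minor
allele frequency at the occurrence locus near 0.37 — an occurrence allele
just under 0.5 reproduces that. The 2% exception rate reflects that the
digenic rule in real pedigree data is near- but not fully deterministic
(finite two-locus logistic likelihoods in the source's own interaction
table imply non-separated data); it is also what keeps the interaction
LRT non-degenerate.

**What it does not emulate.** No within-block recombination or hotspots,
no mutation, no X chromosome, no genotyping error or missingness (tests
plant missingness explicitly), no overlapping generations or non-random
mating, no laterality structure beyond the label. Interaction evidence in
a 104-animal colony is intrinsically thin: it rests on the few unaffected
animals carrying one causal allele but not the other (homozygous
occurrence carriers without the modifier are the decisive class), and
colonies that happen to lack that class support the digenic rule through
the penetrance table but not through a large interaction X². A green
recovery test therefore establishes block-level localization and rule
concordance, not a universally large epistasis statistic.

**Expression generator.** Four groups sized 50/50/49/100; a configurable
fraction of probe sets are rank-1 (latent sample score × per-probe
loading + noise), the rest i.i.d. noise; two designated genes, each with
a full rank-1 probe set, carry a planted correlation (default −0.5) in
exactly one designated group (default the coronal group).

**Determinism.** Every draw flows from the single `rng` argument;
identical seeds give bit-identical studies.

## Pipeline conventions

The occurrence contrast compares all synostotic animals against normal
controls; the onset contrast compares early-onset cases against
delayed-onset controls. Variant filters (missingness strictly > 10% of
the cohort, or MAF = 0, computed on the contrast cohort) are applied per
contrast before kinship and scanning. Hardy–Weinberg is computed (exact
conditional test, summing probabilities ≤ the observed table's) and
reported, never filtered on. Epistasis candidates are the genome-wide
significant hits of each contrast (capped at 1 occurrence × 5 onset, the
shape of the source's interaction table; the single top hit serves as
fallback when nothing is significant), and the two-locus stages run on
the widest genotyped panel supplied (`epistasis_panel`), reflecting a
design where candidate loci are retrospectively typed in many more
animals than were sequenced.

## Known limitations

- The 0/1-trait LMM is an approximation; no covariates beyond the
  intercept are supported (the source design used none).
- Under complete separation the epistasis X² = 2ΔLL is reported as is;
  its χ²(1) reference is then anti-conservative for noise pairs and the
  package flags such fits rather than penalizing them (no Firth
  correction).
- The Gabriel search is exhaustive over intervals (prefix-sum counts),
  quadratic in markers for candidate enumeration; it is intended for
  targeted regions, not genome-wide block partitioning.
- Tag-SNP selection is greedy, not minimum-cardinality.
- Power assumes HWE at the disease locus and random union of gametes —
  inbred colonies violate this; the power module describes the published
  *design* calculation, not colony-specific power.
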