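"""Seeded generators for colony-scale genotype/growth and expression data.

The colony generator emulates the statistical structure of a small,
multi-generation breeding colony segregating a two-locus trait:

* founders draw block haplotypes from small per-block pools, producing
  block-structured LD with controllable haplotype diversity;
* offspring arise by Mendelian gene-dropping (one block haplotype from
  each parent per block, no within-block recombination);
* the phenotype follows the digenic rule — affected iff the animal carries
  at least one variant allele at *both* the occurrence locus and the onset
  modifier locus (optional penetrance noise); among affected animals the
  onset is early (EOS) iff the modifier is homozygous, else delayed (DOS);
* coronal-suture growth is drawn per diagnosis, with affected animals
  growing a configurable fraction (default 0.725, i.e. 70–75%) of the
  unaffected mean; EOS animals are fused at day 10 and carry no marker
  measurements.

The expression generator emulates a four-group microarray study (group
sizes 50/50/49/100) with rank-1 probe-set structure and a planted negative
gene-pair correlation confined to one group.

Identical seeds give bit-identical outputs; every random draw flows from
the single ``rng`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeStudy, GrowthTable, VariantRecord
from .expression import ExpressionStudy, EXPRESSION_GROUPS


@dataclass
class ColonySpec:
    """The stated world of the synthetic colony.

    Defaults are sized to the mapping study: 104 animals bred from 24
    founders, 5,000 markers in ~250 kb blocks, a planted digenic causal
    pair following the one-copy-of-each rule with a 2% exception rate,
    affected growth at 72.5% of normal, and a genotyped subset of
    12 EOS + 12 DOS + 22 ICN animals.
    """

    n_animals: int = 104
    n_founders: int = 24
    mean_litter: float = 5.0
    n_variants: int = 5000
    n_chromosomes: int = 20
    markers_per_block: int = 10
    block_span_bp: int = 250_000
    marker_spacing_bp: int = 25_000
    pool_size: int = 20
    # pool haplotypes carrying each causal allele. The occurrence allele
    # segregates at intermediate frequency; the onset-modifier allele is
    # common in every diagnosis group (as in the colony's group MAF
    # profile), so normal controls are mostly occurrence non-carriers
    occurrence_pool_carriers: int = 9
    modifier_pool_carriers: int = 16
    block_coupling: float = 0.7        # P(a block-mate mirrors the causal column)
    block_coupling_noise: float = 0.08
    # P(label flip) applied to the digenic rule. The rule is near- but not
    # fully deterministic: a small exception rate is what makes two-locus
    # logistic likelihoods finite (no perfect separation), as observed in
    # real pedigree data; set to 0 for a strictly deterministic rule.
    penetrance_noise: float = 0.02
    icn_growth_mean: tuple[float, float] = (4.0, 2.0)   # mm, day 10→25 and 25→42
    icn_growth_sd: tuple[float, float] = (0.5, 0.4)
    affected_growth_fraction: float = 0.725             # of normal; 70–75% range
    day10_separation_mean: float = 1.5
    day10_separation_sd: float = 0.15
    genotyped_subset: tuple[int, int, int] = (12, 12, 22)  # EOS, DOS, ICN

    def __post_init__(self):
        if not (0.70 - 1e-9 <= self.affected_growth_fraction <= 0.75 + 1e-9):
            # the affected range is part of the stated world, not a dial
            raise ValueError("affected_growth_fraction must lie in [0.70, 0.75]")
        if not (0 <= self.penetrance_noise <= 1):
            raise ValueError("penetrance_noise must be a probability")
        for c in (self.occurrence_pool_carriers, self.modifier_pool_carriers):
            if c >= self.pool_size or c < 1:
                raise ValueError("causal alleles must segregate in the haplotype pool")

    @property
    def n_blocks(self) -> int:
        return int(np.ceil(self.n_variants / self.markers_per_block))


@dataclass
class ColonyTruth:
    """Ground truth of a simulated colony, for recovery checks."""

    occurrence_vid: str
    modifier_vid: str
    occurrence_block_vids: list[str]
    modifier_block_vids: list[str]
    occurrence_block_index: int
    modifier_block_index: int
    penetrance_noise: float
    diagnosis: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("occurrence", self.occurrence_vid), ("modifier", self.modifier_vid)]
        rows += [("occurrence_block", v) for v in self.occurrence_block_vids]
        rows += [("modifier_block", v) for v in self.modifier_block_vids]
        return pd.DataFrame(rows, columns=["role", "vid"])


def _breed_pedigree(spec: ColonySpec, rng: np.random.Generator):
    """Gene-drop scaffold: returns parent index pairs (−1 for founders) and sexes."""
    sires = []
    dams = []
    sex = []  # 0 = male, 1 = female
    for i in range(spec.n_founders):
        sires.append(-1)
        dams.append(-1)
        sex.append(i % 2)
    current = list(range(spec.n_founders))
    while len(sires) < spec.n_animals:
        males = [i for i in current if sex[i] == 0]
        females = [i for i in current if sex[i] == 1]
        if not males or not females:
            raise RuntimeError("pedigree extinct: a generation lacks one sex")
        next_gen = []
        pairs = min(len(males), len(females))
        males = list(rng.permutation(males))
        females = list(rng.permutation(females))
        for k in range(pairs):
            litter = 1 + rng.poisson(spec.mean_litter - 1)
            for _ in range(litter):
                if len(sires) >= spec.n_animals:
                    break
                sires.append(males[k])
                dams.append(females[k])
                sex.append(int(rng.integers(2)))
                next_gen.append(len(sires) - 1)
        current = next_gen if next_gen else current
    return np.array(sires), np.array(dams), np.array(sex)


def simulate_colony(
    spec: ColonySpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeStudy, GrowthTable, ColonyTruth]:
    """Simulate the full colony and return (study, growth, truth).

    The returned study contains *all* simulated animals with diagnoses and
    pedigree; use :func:`genotyped_subset` to draw the case/control panel
    the association modules expect.
    """
    spec = spec or ColonySpec()
    rng = np.random.default_rng(rng)
    n_blocks = spec.n_blocks
    # haplotype pools: per block, pool_size haplotypes over the block's markers
    pools = []
    for b in range(n_blocks):
        m = min(spec.markers_per_block, spec.n_variants - b * spec.markers_per_block)
        freq = rng.uniform(0.1, 0.9, size=m)
        pool = (rng.random((spec.pool_size, m)) < freq).astype(np.int8)
        # keep every marker segregating in the pool
        for col in range(m):
            if pool[:, col].min() == pool[:, col].max():
                flip = rng.integers(spec.pool_size)
                pool[flip, col] = 1 - pool[flip, col]
        pools.append(pool)

    # plant the causal pair in two distinct blocks on different chromosomes
    blocks_per_chrom = int(np.ceil(n_blocks / spec.n_chromosomes))
    occ_block = 0
    mod_block = blocks_per_chrom  # first block of the second chromosome
    if mod_block >= n_blocks:
        mod_block = n_blocks - 1
    for blk, n_carriers in (
        (occ_block, spec.occurrence_pool_carriers),
        (mod_block, spec.modifier_pool_carriers),
    ):
        pool = pools[blk]
        causal_col = pool.shape[1] // 2
        carriers = rng.choice(spec.pool_size, n_carriers, replace=False)
        pool[:, causal_col] = 0
        pool[carriers, causal_col] = 1
        # couple block-mates to the causal allele so the block shows LD
        for col in range(pool.shape[1]):
            if col == causal_col:
                continue
            if rng.random() < spec.block_coupling:
                noise = rng.random(spec.pool_size) < spec.block_coupling_noise
                pool[:, col] = np.where(noise, 1 - pool[:, causal_col], pool[:, causal_col])

    sires, dams, _sex = _breed_pedigree(spec, rng)
    n = len(sires)
    # haplotype indices per animal/block: which pool haplotype each copy is.
    # Founder chromosomes carry a *balanced* multiset of pool haplotypes so
    # realized founder allele frequencies equal the pool frequencies (the
    # point of the pool model is controllable frequency and D'); drift then
    # enters only through Mendelian segregation and family structure.
    n_founder_chrom = 2 * spec.n_founders
    balanced = np.tile(
        np.arange(spec.pool_size), int(np.ceil(n_founder_chrom / spec.pool_size))
    )[:n_founder_chrom]
    founder_chrom = np.stack(
        [rng.permutation(balanced) for _ in range(n_blocks)], axis=0
    )  # (n_blocks, 2*n_founders)
    hap = np.empty((n, n_blocks, 2), dtype=np.int8)
    for i in range(n):
        if sires[i] < 0:
            hap[i, :, 0] = founder_chrom[:, 2 * i]
            hap[i, :, 1] = founder_chrom[:, 2 * i + 1]
        else:
            pick_s = rng.integers(2, size=n_blocks)
            pick_d = rng.integers(2, size=n_blocks)
            hap[i, :, 0] = hap[sires[i], np.arange(n_blocks), pick_s]
            hap[i, :, 1] = hap[dams[i], np.arange(n_blocks), pick_d]

    # dosage matrix
    cols = []
    variants = []
    for b in range(n_blocks):
        pool = pools[b]
        m = pool.shape[1]
        chrom = f"chr{b // blocks_per_chrom + 1}"
        block_in_chrom = b % blocks_per_chrom
        dos = pool[hap[:, b, 0]] + pool[hap[:, b, 1]]  # (n, m)
        cols.append(dos)
        for c in range(m):
            pos = block_in_chrom * spec.block_span_bp + c * spec.marker_spacing_bp + 1
            variants.append(VariantRecord(chrom, pos, "A", "G"))
    dosages = np.concatenate(cols, axis=1).astype(np.int8)

    def block_vids(blk):
        start = sum(p.shape[1] for p in pools[:blk])
        return [variants[start + c].vid for c in range(pools[blk].shape[1])]

    occ_idx = sum(p.shape[1] for p in pools[:occ_block]) + pools[occ_block].shape[1] // 2
    mod_idx = sum(p.shape[1] for p in pools[:mod_block]) + pools[mod_block].shape[1] // 2
    g_occ = dosages[:, occ_idx].astype(int)
    g_mod = dosages[:, mod_idx].astype(int)

    affected = (g_occ >= 1) & (g_mod >= 1)
    if spec.penetrance_noise > 0:
        flip = rng.random(n) < spec.penetrance_noise
        affected = affected ^ flip
    eos = affected & (g_mod == 2)

    samples = [f"R{i:03d}" for i in range(n)]
    diagnoses = {
        s: ("EOS" if eos[i] else ("DOS" if affected[i] else "ICN"))
        for i, s in enumerate(samples)
    }
    pedigree = {
        s: (
            samples[sires[i]] if sires[i] >= 0 else None,
            samples[dams[i]] if dams[i] >= 0 else None,
        )
        for i, s in enumerate(samples)
    }
    study = GenotypeStudy(
        variants=variants, samples=samples, dosages=dosages,
        diagnoses=diagnoses, pedigree=pedigree,
    )

    # growth: day-10 baseline separation, then two growth intervals
    rows = []
    fused = set()
    frac = spec.affected_growth_fraction
    for i, s in enumerate(samples):
        if eos[i]:
            fused.add(s)
            continue
        scale = frac if affected[i] else 1.0
        for side in ("left", "right"):
            sep10 = max(rng.normal(spec.day10_separation_mean, spec.day10_separation_sd), 0.1)
            g1 = rng.normal(spec.icn_growth_mean[0] * scale, spec.icn_growth_sd[0])
            g2 = rng.normal(spec.icn_growth_mean[1] * scale, spec.icn_growth_sd[1])
            rows.append((s, 10, side, sep10))
            rows.append((s, 25, side, max(sep10 + g1, 0.0)))
            rows.append((s, 42, side, max(sep10 + g1 + g2, 0.0)))
    growth = GrowthTable(
        data=pd.DataFrame(rows, columns=list(GrowthTable.COLUMNS)),
        fused_at_day10=frozenset(fused),
    )

    truth = ColonyTruth(
        occurrence_vid=variants[occ_idx].vid,
        modifier_vid=variants[mod_idx].vid,
        occurrence_block_vids=block_vids(occ_block),
        modifier_block_vids=block_vids(mod_block),
        occurrence_block_index=occ_block,
        modifier_block_index=mod_block,
        penetrance_noise=spec.penetrance_noise,
        diagnosis=dict(diagnoses),
    )
    return study, growth, truth


def genotyped_subset(
    study: GenotypeStudy,
    n_eos: int = 12,
    n_dos: int = 12,
    n_icn: int = 22,
    rng: np.random.Generator | int | None = None,
) -> GenotypeStudy:
    """Draw the sequenced case/control panel from the full colony.

    Takes up to the requested number of animals per diagnosis class
    (fewer if the colony produced fewer); raises only when a class is
    entirely absent.
    """
    rng = np.random.default_rng(rng)
    chosen: list[str] = []
    for label, want in (("EOS", n_eos), ("DOS", n_dos), ("ICN", n_icn)):
        pool = [s for s in study.samples if study.diagnoses.get(s) == label]
        if not pool:
            raise ValueError(f"colony contains no {label} animals")
        take = min(want, len(pool))
        chosen.extend(rng.choice(pool, size=take, replace=False))
    return study.subset_samples(chosen)


def simulate_expression(
    n_per_group: tuple[int, int, int, int] = (50, 50, 49, 100),
    n_sets: int = 100,
    set_size: int = 4,
    signal_fraction: float = 0.5,
    signal_strength: float = 2.0,
    pair_correlation: float = -0.5,
    pair_group: str = "coronal",
    plant_pair: bool = True,
    noise_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionStudy, dict]:
    """Simulate a four-group expression study with planted structure.

    A ``signal_fraction`` of probe-sets are rank-1 (shared latent score per
    sample scaled per probe by ``signal_strength``); the rest are i.i.d.
    noise. Two designated single-probe genes (``GENE_X``, ``GENE_Y``) carry
    a correlation of ``pair_correlation`` in ``pair_group`` only. Group
    sizes default to the retrospective patient cohort (50/50/49/100).
    """
    rng = np.random.default_rng(rng)
    groups = []
    for name, ng in zip(EXPRESSION_GROUPS, n_per_group):
        groups += [name] * ng
    n_samples = len(groups)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    group_s = pd.Series(groups, index=sample_ids)

    probes, rows, truth_signal = [], [], []
    n_signal = int(round(signal_fraction * n_sets))
    for si in range(n_sets):
        is_signal = si < n_signal
        truth_signal.append(is_signal)
        latent = rng.normal(0, 1, n_samples)
        for pi in range(set_size):
            probe = f"set{si:03d}_p{pi}"
            probes.append(probe)
            base = rng.normal(7.0, 0.5)
            if is_signal:
                load = signal_strength * rng.uniform(0.7, 1.3)
                rows.append(base + load * latent + rng.normal(0, noise_sd * 0.3, n_samples))
            else:
                rows.append(base + rng.normal(0, noise_sd, n_samples))
    probe_map = {p: p.split("_")[0] for p in probes}

    # planted gene pair: correlated only within pair_group
    if not plant_pair:
        expr = pd.DataFrame(np.vstack(rows), index=probes, columns=sample_ids)
        study = ExpressionStudy(expr=expr, probe_map=pd.Series(probe_map), groups=group_s)
        truth = dict(
            signal_sets=[f"set{si:03d}" for si in range(n_sets) if truth_signal[si]],
            noise_sets=[f"set{si:03d}" for si in range(n_sets) if not truth_signal[si]],
            pair_genes=None, pair_group=None, pair_correlation=None,
        )
        return study, truth
    z = rng.normal(0, 1, n_samples)
    x = z + rng.normal(0, 0.3, n_samples)
    y = rng.normal(0, 1, n_samples)
    in_grp = (group_s == pair_group).to_numpy()
    rho = pair_correlation
    y[in_grp] = rho * z[in_grp] + np.sqrt(1 - rho**2) * rng.normal(0, 1, int(in_grp.sum()))
    # each planted gene gets a full rank-1 probe set around its signal so
    # it behaves like any other measured gene under the information filter
    for gname, vals in (("GENE_X", x), ("GENE_Y", y)):
        for pi in range(set_size):
            probe = f"{gname}_p{pi}"
            probes.append(probe)
            base = rng.normal(7.0, 0.5)
            load = signal_strength * rng.uniform(0.7, 1.3)
            rows.append(base + load * vals + rng.normal(0, noise_sd * 0.3, n_samples))
            probe_map[probe] = gname

    expr = pd.DataFrame(np.vstack(rows), index=probes, columns=sample_ids)
    study = ExpressionStudy(expr=expr, probe_map=pd.Series(probe_map), groups=group_s)
    truth = dict(
        signal_sets=[f"set{si:03d}" for si in range(n_sets) if truth_signal[si]],
        noise_sets=[f"set{si:03d}" for si in range(n_sets) if not truth_signal[si]],
        pair_genes=("GENE_X", "GENE_Y"),
        pair_group=pair_group,
        pair_correlation=pair_correlation,
    )
    return study, truth
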