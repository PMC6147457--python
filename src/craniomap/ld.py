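"""Linkage-disequilibrium estimation and confidence-interval block calling.

Haplotype frequencies at a pair of unphased biallelic loci are estimated by
EM (only the double heterozygote is phase-ambiguous). D′ uncertainty is
summarized Gabriel-style: the multinomial likelihood of the observed 3×3
genotype table is profiled over |D′| on a grid (allele frequencies held at
their MLEs), normalized to a unit mass, and the 5th/95th percentiles of the
cumulative likelihood give the confidence bounds. Pairs are classed as
*strong LD* (upper bound ≥ 0.95 and lower bound ≥ 0.55), *strong
recombination* (upper bound < 0.90) or *uninformative*, and a block is any
maximal marker interval whose endpoint pair is strong LD and whose
informative pairs are ≥ 85% strong LD — the thresholds used throughout the
colony mapping. LOD is log10 of the likelihood ratio against D = 0, as in
Haploview's LD display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass
class BlockConfig:
    """Thresholds for pair classification and block acceptance."""

    ci_upper_min: float = 0.95
    ci_lower_min: float = 0.55
    strong_fraction_min: float = 0.85
    recomb_upper_max: float = 0.90
    ci_grid_points: int = 101

    def __post_init__(self):
        for name in ("ci_upper_min", "ci_lower_min", "strong_fraction_min", "recomb_upper_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class LDPair:
    """Pairwise LD summary between two loci (indices i < j)."""

    i: int
    j: int
    D: float
    Dprime: float
    r2: float
    LOD: float
    ci_low: float
    ci_high: float
    pair_class: str = "uninformative"
    color: str = "white"


@dataclass
class HaplotypeBlock:
    chrom: str
    start_pos: int
    end_pos: int
    member_ids: list[str] = field(default_factory=list)
    member_indices: list[int] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        """Block span as end − start (the convention behind e.g. a "253 kb" block)."""
        return self.end_pos - self.start_pos


def genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3×3 co-called genotype count table (rows: locus-1 dosage 0/1/2)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if not ok.any():
        raise ValueError("no co-called samples at this locus pair")
    tab = np.zeros((3, 3), dtype=int)
    for a, b in zip(g1[ok].astype(int), g2[ok].astype(int)):
        tab[a, b] += 1
    return tab


def _cell_probs(h: np.ndarray) -> np.ndarray:
    """Genotype-cell probabilities from haplotype freqs (order 11,10,01,00).

    ``h[k]`` is the frequency of the haplotype carrying allele patterns
    (a1, a2) = (1,1), (1,0), (0,1), (0,0); random union of gametes.
    """
    hap_alleles = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])
    P = np.zeros((3, 3))
    for k, l in itertools.product(range(4), repeat=2):
        a = hap_alleles[k, 0] + hap_alleles[l, 0]
        b = hap_alleles[k, 1] + hap_alleles[l, 1]
        P[a, b] += h[k] * h[l]
    return P


def _loglik(counts: np.ndarray, h: np.ndarray) -> float:
    P = _cell_probs(np.clip(h, 1e-12, None))
    return float((counts * np.log(np.clip(P, 1e-300, None))).sum())


def em_haplotypes(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 5000):
    """EM haplotype-frequency estimate from a 3×3 genotype count table.

    Returns ``(h, ll)`` with ``h`` the frequencies of haplotypes
    (1,1), (1,0), (0,1), (0,0) and ``ll`` the final multinomial
    log-likelihood. Every cell except the double heterozygote phases
    unambiguously; EM iterates the expected split of the (1,1) cell until
    the relative log-likelihood change falls below ``tol``.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotypes missing")
    # fixed haplotype contributions from unambiguous cells
    base = np.zeros(4)  # order (1,1),(1,0),(0,1),(0,0)
    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            # for unambiguous cells the multiset of two haplotypes is unique
            a1, a2 = (1 if a == 2 else (1 if a == 1 else 0), 1 if a == 2 else 0)
            b1, b2 = (1 if b == 2 else (1 if b == 1 else 0), 1 if b == 2 else 0)
            for aa, bb in ((a1, b1), (a2, b2)):
                idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(aa, bb)]
                base[idx] += c
    ndh = counts[1, 1]
    h = np.full(4, 0.25)
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: split double heterozygotes between cis (11/00) and trans (10/01)
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        hap_counts = base.copy()
        hap_counts[[0, 3]] += ndh * w
        hap_counts[[1, 2]] += ndh * (1 - w)
        h = hap_counts / (2.0 * n)
        ll = _loglik(counts, h)
        if ll - ll_old < tol * max(1.0, abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return h, float(ll_old)


def _hap_from_d(pA: float, pB: float, D: float) -> np.ndarray:
    return np.array(
        [pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D]
    )


def _dmax(pA: float, pB: float, sign: int) -> float:
    if sign >= 0:
        return min(pA * (1 - pB), (1 - pA) * pB)
    return min(pA * pB, (1 - pA) * (1 - pB))


def ld_from_haplotypes(h: np.ndarray) -> tuple[float, float, float]:
    """(D, D′, r²) from haplotype frequencies (order 11,10,01,00)."""
    pA = h[0] + h[1]
    pB = h[0] + h[2]
    D = h[0] - pA * pB
    denom = _dmax(pA, pB, 1 if D >= 0 else -1)
    Dp = 0.0 if denom == 0 else abs(D) / denom
    var = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if var == 0 else D * D / var
    return float(D), float(min(Dp, 1.0)), float(min(r2, 1.0))


def dprime_ci_lod(counts: np.ndarray, grid_points: int = 101) -> LDPair:
    """Likelihood-based D′ point estimate, confidence bounds and LOD.

    Monomorphic loci yield an uninformative pair with NaN fields. The
    profile fixes allele frequencies at their sample MLEs and the sign of D
    at the EM estimate's sign, evaluates the multinomial likelihood of the
    genotype table on a uniform |D′| grid over [0, 1], and reads the 5%/95%
    crossings of the normalized cumulative likelihood.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    pA = (2 * row[2] + row[1]) / (2 * n)
    pB = (2 * col[2] + col[1]) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDPair(-1, -1, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                      pair_class="uninformative")
    h_mle, _ = em_haplotypes(counts)
    D_mle, Dp_mle, r2 = ld_from_haplotypes(h_mle)
    sign = 1 if D_mle >= 0 else -1
    # allele-1 here counts the *alt* dosage allele; flip to make D positive
    dmax = _dmax(pA, pB, sign)
    grid = np.linspace(0.0, 1.0, grid_points)
    ll = np.array(
        [_loglik(counts, _hap_from_d(pA, pB, sign * dp * dmax)) for dp in grid]
    )
    L = np.exp(ll - ll.max())
    cum = np.cumsum(L) / L.sum()
    ci_low = float(grid[int(np.searchsorted(cum, 0.05))])
    ci_high = float(grid[min(int(np.searchsorted(cum, 0.95)), grid_points - 1)])
    ll0 = _loglik(counts, _hap_from_d(pA, pB, 0.0))
    lod = (ll.max() - ll0) / np.log(10.0)
    return LDPair(
        i=-1, j=-1, D=D_mle, Dprime=Dp_mle, r2=r2,
        LOD=float(max(lod, 0.0)), ci_low=ci_low, ci_high=ci_high,
    )


def classify_pair(pair: LDPair, config: BlockConfig | None = None) -> str:
    """Gabriel pair class from the D′ confidence bounds."""
    config = config or BlockConfig()
    if np.isnan(pair.ci_high):
        return "uninformative"
    if pair.ci_high >= config.ci_upper_min and pair.ci_low >= config.ci_lower_min:
        return "strong_ld"
    if pair.ci_high < config.recomb_upper_max:
        return "strong_recomb"
    return "uninformative"


def ld_color_class(pair: LDPair, tol: float = 1e-9) -> str:
    """Haploview's display classes: bright red (LOD ≥ 2, D′ = 1), pink
    (LOD ≥ 2, D′ < 1), blue (LOD < 2, D′ = 1), white otherwise."""
    if np.isnan(pair.Dprime):
        return "white"
    d1 = pair.Dprime >= 1.0 - tol
    hi = pair.LOD >= 2.0
    if hi and d1:
        return "bright_red"
    if hi:
        return "pink"
    if d1:
        return "blue"
    return "white"


def pairwise_ld(
    genotypes: np.ndarray, config: BlockConfig | None = None
) -> list[LDPair]:
    """All-pairs LD for a (samples × markers) dosage matrix (NaN = missing)."""
    config = config or BlockConfig()
    g = np.asarray(genotypes, dtype=float)
    m = g.shape[1]
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            pr = dprime_ci_lod(genotype_counts(g[:, i], g[:, j]), config.ci_grid_points)
            pr.i, pr.j = i, j
            pr.pair_class = classify_pair(pr, config)
            pr.color = ld_color_class(pr)
            pairs.append(pr)
    return pairs


def gabriel_blocks(
    variants, pairs: list[LDPair], config: BlockConfig | None = None
) -> list[HaplotypeBlock]:
    """Confidence-interval block calling over sorted markers.

    An interval [i, j] qualifies when its endpoint pair is strong LD and
    strong-LD pairs make up at least ``strong_fraction_min`` of the
    informative pairs inside it. Maximal non-overlapping blocks are chosen
    largest bp span first (ties: leftmost). ``variants`` must be sorted by
    position within one chromosome.
    """
    config = config or BlockConfig()
    m = len(variants)
    for a, b in zip(variants, variants[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise ValueError("variants must be sorted by position")
    strong = np.zeros((m, m), dtype=np.int64)
    informative = np.zeros((m, m), dtype=np.int64)
    for p in pairs:
        if p.pair_class == "strong_ld":
            strong[p.i, p.j] = 1
            informative[p.i, p.j] = 1
        elif p.pair_class == "strong_recomb":
            informative[p.i, p.j] = 1
    # 2-D prefix sums so interior pair counts for any interval are O(1)
    cs = strong.cumsum(0).cumsum(1)
    ci_ = informative.cumsum(0).cumsum(1)

    def _rect(c, i0, i1, j0, j1):  # inclusive rectangle sum
        tot = c[i1, j1]
        if i0 > 0:
            tot -= c[i0 - 1, j1]
        if j0 > 0:
            tot -= c[i1, j0 - 1]
        if i0 > 0 and j0 > 0:
            tot += c[i0 - 1, j0 - 1]
        return int(tot)

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if variants[i].chrom != variants[j].chrom:
                continue
            if not strong[i, j]:
                continue
            n_strong = _rect(cs, i, j, i, j)
            n_inf = _rect(ci_, i, j, i, j)
            if n_inf and n_strong / n_inf >= config.strong_fraction_min:
                span = variants[j].pos - variants[i].pos
                candidates.append((span, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            HaplotypeBlock(
                chrom=variants[i].chrom,
                start_pos=variants[i].pos,
                end_pos=variants[j].pos,
                member_ids=[variants[k].vid for k in range(i, j + 1)],
                member_indices=list(range(i, j + 1)),
            )
        )
    blocks.sort(key=lambda b: (b.chrom, b.start_pos))
    return blocks


def tag_snps(genotypes: np.ndarray, r2_min: float = 0.8) -> list[int]:
    """Greedy tag-SNP selection over a block's (samples × markers) matrix.

    Repeatedly picks the marker covering the most uncovered members at
    r² ≥ ``r2_min`` (ties: leftmost) until every member is covered.
    """
    g = np.asarray(genotypes, dtype=float)
    m = g.shape[1]
    r2 = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            h, _ = em_haplotypes(genotype_counts(g[:, i], g[:, j]))
            _, _, rij = ld_from_haplotypes(h)
            r2[i, j] = r2[j, i] = rij
    covered = np.zeros(m, dtype=bool)
    tags: list[int] = []
    while not covered.all():
        gain = ((r2 >= r2_min) & ~covered).sum(axis=1)
        t = int(np.argmax(gain))
        tags.append(t)
        covered |= r2[t] >= r2_min
        covered[t] = True
    return sorted(tags)


def group_maf_profile(
    genotypes: np.ndarray,
    group_labels: np.ndarray,
    variant_ids: list[str] | None = None,
) -> dict:
    """Per-group MAF across a block's SNPs, with one-way ANOVA + Tukey HSD.

    The minor allele of each SNP is fixed in the pooled cohort so the group
    values are comparable; per-SNP MAFs are treated as replicates of each
    group's allelic profile. Groups with no called genotypes are dropped
    with a warning.
    """
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(group_labels)
    m = g.shape[1]
    if m < 2:
        raise ValueError("need >= 2 SNPs")
    pooled_alt = np.nanmean(g, axis=0) / 2.0
    flip = pooled_alt > 0.5  # minor allele defined in the pooled cohort
    groups = list(dict.fromkeys(labels))
    maf = {}
    for grp in groups:
        sub = g[labels == grp]
        if np.all(np.isnan(sub)):
            logger.warning("group %r has no called genotypes; excluded", grp)
            continue
        freq = np.nanmean(sub, axis=0) / 2.0
        freq[flip] = 1.0 - freq[flip]
        maf[grp] = freq
    if len(maf) < 2:
        raise ValueError("need >= 2 groups with called genotypes")
    arrays = [v[~np.isnan(v)] for v in maf.values()]
    F, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labs = np.concatenate([[k] * len(v) for k, v in zip(maf.keys(), arrays)])
    tukey = pairwise_tukeyhsd(values, labs)
    table = pd.DataFrame(
        {grp: v for grp, v in maf.items()},
        index=variant_ids if variant_ids is not None else range(m),
    )
    return dict(
        maf=table,
        group_means={k: float(np.nanmean(v)) for k, v in maf.items()},
        group_sems={k: float(stats.sem(v, nan_policy="omit")) for k, v in maf.items()},
        F=float(F),
        p=float(p),
        tukey=pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        ),
    )


def ld_table(pairs: list[LDPair], variants=None) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            dict(
                i=p.i, j=p.j, D=p.D, Dprime=p.Dprime, r2=p.r2, LOD=p.LOD,
                ci_low=p.ci_low, ci_high=p.ci_high,
                pair_class=p.pair_class, color=p.color,
            )
        )
    return pd.DataFrame(rows)


def block_table(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            chrom=[b.chrom for b in blocks],
            start=[b.start_pos for b in blocks],
            end=[b.end_pos for b in blocks],
            span_bp=[b.span_bp for b in blocks],
            span_kb=[round(b.span_bp / 1000.0) for b in blocks],
            n_snps=[len(b.member_ids) for b in blocks],
        )
    )
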