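import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from craniomap import (
    BlockConfig,
    HaplotypeBlock,
    LDPair,
    VariantRecord,
    classify_pair,
    dprime_ci_lod,
    em_haplotypes,
    gabriel_blocks,
    genotype_counts,
    group_maf_profile,
    ld_color_class,
    ld_from_haplotypes,
    pairwise_ld,
    tag_snps,
)

HAP_ALLELES = [(1, 1), (1, 0), (0, 1), (0, 0)]


def cell_probs_oracle(h):
    """Independent genotype-cell probabilities by explicit pair enumeration."""
    P = np.zeros((3, 3))
    for (a1, b1), f1 in zip(HAP_ALLELES, h):
        for (a2, b2), f2 in zip(HAP_ALLELES, h):
            P[a1 + a2, b1 + b2] += f1 * f2
    return P


def loglik_oracle(counts, h):
    P = np.clip(cell_probs_oracle(h), 1e-300, None)
    return float((np.asarray(counts) * np.log(P)).sum())


def draw_genotypes(h, n, rng):
    """Sample unphased two-locus genotypes from a haplotype pool."""
    idx = rng.choice(4, size=(n, 2), p=h)
    alle = np.array(HAP_ALLELES)
    g1 = alle[idx[:, 0], 0] + alle[idx[:, 1], 0]
    g2 = alle[idx[:, 0], 1] + alle[idx[:, 1], 1]
    return g1.astype(float), g2.astype(float)


class TestEmHaplotypes:
    def test_no_double_het_equals_direct_counting(self):
        # without double heterozygotes phase is fully determined
        counts = np.array([[4, 2, 0], [1, 0, 3], [0, 2, 5]])
        counts[1, 1] = 0
        h, ll = em_haplotypes(counts)
        # direct haplotype counting oracle
        expect = np.zeros(4)
        for a in range(3):
            for b in range(3):
                c = counts[a, b]
                pairs = {
                    0: [(0, 0), (0, 0)], 1: [(0, 0), (0, 1)], 2: [(0, 1), (0, 1)],
                }
                a_h = [1, 1] if a == 2 else ([1, 0] if a == 1 else [0, 0])
                b_h = [1, 1] if b == 2 else ([1, 0] if b == 1 else [0, 0])
                for aa, bb in zip(a_h, b_h):
                    expect[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(aa, bb)]] += c
        expect /= expect.sum()
        np.testing.assert_allclose(h, expect, atol=1e-9)

    def test_recovers_pool_frequencies(self):
        rng = np.random.default_rng(11)
        h_true = np.array([0.4, 0.1, 0.2, 0.3])
        g1, g2 = draw_genotypes(h_true, 500, rng)
        h_hat, _ = em_haplotypes(genotype_counts(g1, g2))
        se = np.sqrt(h_true * (1 - h_true) / 1000)
        np.testing.assert_array_less(np.abs(h_hat - h_true), 3 * se + 1e-9)

    def test_loglik_beats_grid_oracle(self):
        rng = np.random.default_rng(12)
        g1, g2 = draw_genotypes(np.array([0.35, 0.15, 0.15, 0.35]), 120, rng)
        counts = genotype_counts(g1, g2)
        h_hat, ll = em_haplotypes(counts)
        # grid over the single free parameter p11 with margins fixed at MLE
        pA = h_hat[0] + h_hat[1]
        pB = h_hat[0] + h_hat[2]
        lo = max(0.0, pA + pB - 1.0)
        hi = min(pA, pB)
        best = -np.inf
        for p11 in np.linspace(lo, hi, 201):
            h = np.array([p11, pA - p11, pB - p11, 1 - pA - pB + p11])
            if (h < -1e-12).any():
                continue
            best = max(best, loglik_oracle(counts, np.clip(h, 0, None)))
        assert ll >= best - 1e-8

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            em_haplotypes(np.zeros((3, 3)))


class TestDprimeCi:
    def test_complete_ld(self):
        rng = np.random.default_rng(13)
        g1, g2 = draw_genotypes(np.array([0.5, 0.0, 0.0, 0.5]), 200, rng)
        pair = dprime_ci_lod(genotype_counts(g1, g2))
        assert pair.Dprime == pytest.approx(1.0, abs=1e-6)
        assert pair.ci_low > 0.9
        assert pair.LOD > 2

    def test_independent_loci(self):
        rng = np.random.default_rng(14)
        h = np.array([0.25, 0.25, 0.25, 0.25])
        g1, g2 = draw_genotypes(h, 200, rng)
        pair = dprime_ci_lod(genotype_counts(g1, g2))
        assert pair.Dprime < 0.25
        assert pair.LOD < 1.0

    def test_ci_equals_integration_oracle(self):
        rng = np.random.default_rng(15)
        g1, g2 = draw_genotypes(np.array([0.4, 0.1, 0.1, 0.4]), 80, rng)
        counts = genotype_counts(g1, g2)
        pair = dprime_ci_lod(counts)
        # independent normalized-likelihood integration on the same grid
        n = counts.sum()
        row, col = counts.sum(1), counts.sum(0)
        pA = (2 * row[2] + row[1]) / (2 * n)
        pB = (2 * col[2] + col[1]) / (2 * n)
        h_mle, _ = em_haplotypes(counts)
        sign = 1 if (h_mle[0] - pA * pB) >= 0 else -1
        dmax = min(pA * (1 - pB), (1 - pA) * pB) if sign > 0 else min(pA * pB, (1 - pA) * (1 - pB))
        grid = np.linspace(0, 1, 101)
        ll = np.array([
            loglik_oracle(counts, np.array([
                pA * pB + sign * d * dmax,
                pA * (1 - pB) - sign * d * dmax,
                (1 - pA) * pB - sign * d * dmax,
                (1 - pA) * (1 - pB) + sign * d * dmax,
            ])) for d in grid
        ])
        L = np.exp(ll - ll.max())
        cum = np.cumsum(L) / L.sum()
        lo = grid[int(np.searchsorted(cum, 0.05))]
        hi = grid[min(int(np.searchsorted(cum, 0.95)), 100)]
        assert pair.ci_low == pytest.approx(lo, abs=1e-12)
        assert pair.ci_high == pytest.approx(hi, abs=1e-12)

    def test_monomorphic_uninformative(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1] = 5
        counts[0, 0] = 5
        pair = dprime_ci_lod(counts)
        assert pair.pair_class == "uninformative"
        assert np.isnan(pair.Dprime)

    @given(st.integers(0, 3))
    @settings(deadline=None, derandomize=True, max_examples=4)
    def test_allele_relabeling_invariance(self, which):
        rng = np.random.default_rng(16)
        g1, g2 = draw_genotypes(np.array([0.45, 0.1, 0.15, 0.3]), 150, rng)
        base = dprime_ci_lod(genotype_counts(g1, g2))
        f1 = 2 - g1 if which in (1, 3) else g1
        f2 = 2 - g2 if which in (2, 3) else g2
        flipped = dprime_ci_lod(genotype_counts(f1, f2))
        assert flipped.Dprime == pytest.approx(base.Dprime, abs=1e-9)
        assert flipped.r2 == pytest.approx(base.r2, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.60, 0.96), "strong_ld"),
            ((0.50, 0.96), "uninformative"),
            ((0.10, 0.85), "strong_recomb"),
            ((0.55, 0.95), "strong_ld"),     # boundary inclusive
            ((0.10, 0.92), "uninformative"),
        ],
    )
    def test_pair_classes(self, ci, expected):
        pair = LDPair(0, 1, 0.1, 0.9, 0.5, 3.0, ci[0], ci[1])
        assert classify_pair(pair, BlockConfig()) == expected

    @pytest.mark.parametrize(
        "lod,dp,expected",
        [
            (3.0, 1.0, "bright_red"),
            (2.0, 1.0, "bright_red"),
            (3.0, 0.8, "pink"),
            (1.0, 1.0, "blue"),
            (0.5, 0.2, "white"),
        ],
    )
    def test_color_classes(self, lod, dp, expected):
        pair = LDPair(0, 1, 0.1, dp, 0.5, lod, 0.2, 0.9)
        assert ld_color_class(pair) == expected


def _variants(n, chrom="1", spacing=1000):
    return [VariantRecord(chrom, 1 + i * spacing, "A", "G") for i in range(n)]


def _pairs_from_classes(classes):
    pairs = []
    m = classes.shape[0]
    for i in range(m):
        for j in range(i + 1, m):
            c = classes[i, j]
            ci = {"S": (0.7, 0.98), "R": (0.1, 0.5), "U": (0.3, 0.92)}[c]
            p = LDPair(i, j, 0.1, 0.8, 0.5, 2.0, ci[0], ci[1])
            p.pair_class = {"S": "strong_ld", "R": "strong_recomb", "U": "uninformative"}[c]
            pairs.append(p)
    return pairs


def gabriel_oracle(variants, pairs, config):
    """Naive exhaustive interval search + largest-span-first selection."""
    m = len(variants)
    cls = {(p.i, p.j): p.pair_class for p in pairs}
    cands = []
    for i in range(m):
        for j in range(i + 1, m):
            if cls.get((i, j)) != "strong_ld":
                continue
            s = inf = 0
            for k in range(i, j + 1):
                for l in range(k + 1, j + 1):
                    c = cls.get((k, l))
                    if c == "strong_ld":
                        s += 1
                        inf += 1
                    elif c == "strong_recomb":
                        inf += 1
            if inf and s / inf >= config.strong_fraction_min:
                cands.append((variants[j].pos - variants[i].pos, i, j))
    cands.sort(key=lambda t: (-t[0], t[1]))
    taken = [False] * m
    out = []
    for span, i, j in cands:
        if any(taken[i : j + 1]):
            continue
        for k in range(i, j + 1):
            taken[k] = True
        out.append((i, j))
    return sorted(out)


class TestGabrielBlocks:
    def test_all_strong_single_block(self):
        m = 6
        classes = np.full((m, m), "S")
        variants = _variants(m)
        blocks = gabriel_blocks(variants, _pairs_from_classes(classes))
        assert len(blocks) == 1
        assert blocks[0].member_indices == list(range(m))

    def test_two_regions_match_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        m = 12
        classes = np.full((m, m), "U")
        for i in range(m):
            for j in range(i + 1, m):
                same_side = (i < 6) == (j < 6)
                if same_side:
                    classes[i, j] = "S" if rng.random() < 0.95 else "U"
                else:
                    classes[i, j] = "R"
        variants = _variants(m)
        pairs = _pairs_from_classes(classes)
        config = BlockConfig()
        blocks = gabriel_blocks(variants, pairs, config)
        got = sorted((b.member_indices[0], b.member_indices[-1]) for b in blocks)
        assert got == gabriel_oracle(variants, pairs, config)

    def test_random_classes_match_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(5):
            m = 10
            classes = np.full((m, m), "U")
            for i in range(m):
                for j in range(i + 1, m):
                    classes[i, j] = rng.choice(["S", "R", "U"], p=[0.5, 0.3, 0.2])
            variants = _variants(m)
            pairs = _pairs_from_classes(classes)
            config = BlockConfig()
            got = sorted(
                (b.member_indices[0], b.member_indices[-1])
                for b in gabriel_blocks(variants, pairs, config)
            )
            assert got == gabriel_oracle(variants, pairs, config)

    def test_uninformative_endpoint_never_a_block(self):
        m = 4
        classes = np.full((m, m), "S")
        classes[0, m - 1] = "U"
        blocks = gabriel_blocks(_variants(m), _pairs_from_classes(classes))
        assert all(
            not (b.member_indices[0] == 0 and b.member_indices[-1] == m - 1)
            for b in blocks
        )

    def test_unsorted_variants_rejected(self):
        variants = [VariantRecord("1", 100, "A", "G"), VariantRecord("1", 50, "A", "G")]
        with pytest.raises(ValueError, match="sorted"):
            gabriel_blocks(variants, [])

    def test_span_arithmetic_printed_boundaries(self):
        b1 = HaplotypeBlock("2", 6_388_292, 6_641_309)
        assert b1.span_bp == 253_017
        assert round(b1.span_bp / 1000) == 253
        b2 = HaplotypeBlock("19", 37_533_454, 37_824_932)
        assert b2.span_bp == 291_478
        assert round(b2.span_bp / 1000) == 291


class TestTagSnps:
    def test_single_tag_when_all_identical(self):
        rng = np.random.default_rng(19)
        col = rng.integers(0, 3, 60)
        g = np.tile(col[:, None], (1, 5)).astype(float)
        assert len(tag_snps(g)) == 1

    def test_every_snp_own_tag_when_independent(self):
        rng = np.random.default_rng(20)
        g = rng.integers(0, 3, (300, 4)).astype(float)
        assert len(tag_snps(g)) == 4

    def test_greedy_covers_and_near_minimal(self):
        rng = np.random.default_rng(21)
        # three clusters of duplicated columns -> exhaustive minimum = 3
        base = rng.integers(0, 3, (80, 3)).astype(float)
        g = np.column_stack([base[:, [0]]] * 3 + [base[:, [1]]] * 3 + [base[:, [2]]] * 2)
        tags = tag_snps(g)
        # coverage check
        from craniomap.ld import em_haplotypes as em, genotype_counts as gc

        for j in range(g.shape[1]):
            covered = any(
                ld_from_haplotypes(em(gc(g[:, j], g[:, t]))[0])[2] >= 0.8 or j == t
                for t in tags
            )
            assert covered
        assert len(tags) == 3  # equals the exhaustive minimum here


class TestGroupMafProfile:
    def test_identical_groups_f_zero(self):
        rng = np.random.default_rng(22)
        block = rng.integers(0, 3, (10, 5)).astype(float)
        g = np.vstack([block, block, block])
        labels = np.repeat(["EOS", "DOS", "ICN"], 10)
        res = group_maf_profile(g, labels)
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_offsets_detected(self):
        rng = np.random.default_rng(23)
        hits = 0
        for rep in range(20):
            freqs = {"EOS": 0.9, "DOS": 0.7, "ICN": 0.4}
            cols = {}
            for grp, f in freqs.items():
                cols[grp] = rng.binomial(2, f, size=(20, 12)).astype(float)
            g = np.vstack([cols["EOS"], cols["DOS"], cols["ICN"]])
            labels = np.repeat(["EOS", "DOS", "ICN"], 20)
            res = group_maf_profile(g, labels)
            tukey_ok = (res["tukey"]["p-adj"].astype(float) < 0.05).all()
            if res["p"] < 0.001 and tukey_ok:
                hits += 1
        assert hits >= 19  # >= 95% of replicates

    def test_minor_allele_defined_in_pooled_cohort(self):
        # one group's frequencies must be comparable across groups: a SNP at
        # pooled alt freq > 0.5 is reported on the same (flipped) allele in
        # every group
        g = np.array([[2, 2], [2, 2], [2, 2], [1, 1], [2, 2], [1, 2]], dtype=float)
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        res = group_maf_profile(g, labels)
        maf = res["maf"]
        assert (maf.loc[:, "A"] <= 0.5).all() or (maf.loc[:, "B"] >= maf.loc[:, "A"]).all()


class TestPairwiseLd:
    def test_planted_block_recovered(self):
        rng = np.random.default_rng(24)
        # 12 markers: 6-marker tight block flanked by independent markers
        n = 150
        pool = (rng.random((4, 6)) < 0.5).astype(int)
        pool[0] = 1 - pool[1]  # ensure diversity
        hap_idx = rng.integers(0, 4, size=(n, 2))
        block = pool[hap_idx[:, 0]] + pool[hap_idx[:, 1]]
        flank1 = rng.binomial(2, 0.4, size=(n, 3))
        flank2 = rng.binomial(2, 0.6, size=(n, 3))
        g = np.column_stack([flank1, block, flank2]).astype(float)
        variants = _variants(12)
        pairs = pairwise_ld(g)
        blocks = gabriel_blocks(variants, pairs)
        spans = [(b.member_indices[0], b.member_indices[-1]) for b in blocks]
        # the planted block occupies indices 3..8; allow 1-marker slack
        assert any(abs(a - 3) <= 1 and abs(b - 8) <= 1 for a, b in spans)
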