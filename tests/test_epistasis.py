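import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from craniomap import (
    GrowthTable,
    diagnose_from_growth,
    epistasis_lrt,
    genotype_class_label,
    growth_two_way_anova,
    logistic_irls,
    penetrance_estimate,
)


class TestLogisticIrls:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0.0])
        fit = logistic_irls(y, np.ones((5, 1)))
        phat = 3 / 5
        assert 1 / (1 + np.exp(-fit.coef[0])) == pytest.approx(phat, abs=1e-8)
        assert fit.log_likelihood == pytest.approx(
            5 * (phat * np.log(phat) + (1 - phat) * np.log(1 - phat)), abs=1e-8
        )

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(30)
        X = np.column_stack([np.ones(20), rng.normal(size=20), rng.integers(0, 3, 20)])
        eta = 0.3 - 0.8 * X[:, 1] + 0.5 * X[:, 2]
        y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_irls(y, X)
        ref = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_separation_flagged(self):
        x = np.array([-2, -1, -0.5, 0.5, 1, 2.0])
        y = (x > 0).astype(float)
        fit = logistic_irls(y, np.column_stack([np.ones(6), x]))
        assert fit.separation
        assert fit.log_likelihood > -1e-3  # saturates toward zero

    def test_rank_deficiency_named(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        y = np.array([0, 1] * 5, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            logistic_irls(y, X, column_names=["const", "a", "b"])


def simulate_digenic(n, rng, interaction=True, noise=0.0, f1=0.5, f2=0.5):
    g1 = rng.binomial(2, f1, n).astype(float)
    g2 = rng.binomial(2, f2, n).astype(float)
    if interaction:
        y = ((g1 >= 1) & (g2 >= 1)).astype(float)
    else:
        eta = -1.0 + 0.8 * g1 + 0.8 * g2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if noise > 0:
        flip = rng.random(n) < noise
        y = np.where(flip, 1 - y, y)
    return y, g1, g2


class TestEpistasisLrt:
    def test_locus_swap_invariance(self):
        rng = np.random.default_rng(31)
        y, g1, g2 = simulate_digenic(200, rng, noise=0.05)
        a = epistasis_lrt(y, g1, g2)
        b = epistasis_lrt(y, g2, g1)
        assert a.chisq == pytest.approx(b.chisq, abs=1e-6)

    def test_identical_loci_error(self):
        rng = np.random.default_rng(32)
        g = rng.binomial(2, 0.5, 50).astype(float)
        y = (g >= 1).astype(float)
        with pytest.raises(ValueError, match="identical|collinear"):
            epistasis_lrt(y, g, g.copy())

    def test_planted_interaction_power(self):
        rng = np.random.default_rng(33)
        hits = 0
        for _ in range(20):
            y, g1, g2 = simulate_digenic(115, rng, interaction=True, noise=0.03)
            if np.std(g1) == 0 or np.std(g2) == 0:
                continue
            res = epistasis_lrt(y, g1, g2)
            if res.p < 1e-4:
                hits += 1
        assert hits >= 18  # >= 90%

    def test_factor_coding_has_more_df(self):
        rng = np.random.default_rng(34)
        y, g1, g2 = simulate_digenic(300, rng, noise=0.05)
        add = epistasis_lrt(y, g1, g2, coding="additive")
        fac = epistasis_lrt(y, g1, g2, coding="factor")
        assert add.df == 1
        assert fac.df == 4


class TestPenetrance:
    def test_exact_rule_full_concordance(self):
        rng = np.random.default_rng(35)
        y, g1, g2 = simulate_digenic(200, rng, noise=0.0)
        table = penetrance_estimate(y, g1, g2)
        assert table.rule_concordance == 1.0
        observed = ~np.isnan(table.pi)
        rule = np.array([[0, 0, 0], [0, 1, 1], [0, 1, 1]], dtype=float)
        np.testing.assert_allclose(table.pi[observed], rule[observed])

    def test_all_unaffected(self):
        g1 = np.array([0, 1, 2, 1.0])
        g2 = np.array([0, 0, 0, 0.0])
        table = penetrance_estimate(np.zeros(4), g1, g2)
        assert np.nansum(table.pi) == 0.0

    def test_noisy_rule_concordance_calibrated(self):
        rng = np.random.default_rng(36)
        concs = [
            penetrance_estimate(*simulate_digenic(500, rng, noise=0.05)).rule_concordance
            for _ in range(30)
        ]
        se = np.sqrt(0.95 * 0.05 / 500)
        assert abs(np.mean(concs) - 0.95) < 3 * se

    def test_margins_match_single_locus_penetrance(self):
        rng = np.random.default_rng(37)
        y, g1, g2 = simulate_digenic(400, rng, noise=0.1)
        table = penetrance_estimate(y, g1, g2)
        for a in range(3):
            mask = g1 == a
            if mask.sum() == 0:
                continue
            marginal = y[mask].mean()
            weights = table.counts[a]
            cells = np.where(np.isnan(table.pi[a]), 0, table.pi[a])
            assert (cells * weights).sum() / weights.sum() == pytest.approx(marginal)


class TestGenotypeLabels:
    @pytest.mark.parametrize(
        "g1,g2,label",
        [(0, 0, "AA/CC"), (1, 1, "AG/CG"), (2, 2, "GG/GG"), (2, 1, "GG/CG")],
    )
    def test_reference_labels(self, g1, g2, label):
        assert genotype_class_label(g1, g2) == label

    def test_missing_dosage(self):
        assert genotype_class_label(float("nan"), 1) == "··/CG"


def _growth_df(depression=None, rng=None):
    """Two-interval growth data per genotype class, optionally depressed."""
    rng = rng or np.random.default_rng(38)
    classes = ["AA/CC", "AG/CG", "GG/CG", "GG/GG"]
    scale = depression or {c: 1.0 for c in classes}
    rows = []
    for c in classes:
        for day, mean in ((25, 4.0), (42, 2.0)):
            for _ in range(10):
                rows.append(dict(group=c, day=day, value=rng.normal(mean * scale[c], 0.3)))
    return pd.DataFrame(rows)


class TestGrowthAnova:
    def test_identical_groups_flat(self):
        rng = np.random.default_rng(39)
        df = _growth_df(rng=rng)
        res = growth_two_way_anova(df)
        assert res["p_group"] > 0.01
        assert res["p_day"] < 1e-6  # day effect is real by construction

    def test_genotype_ordered_depression_detected(self):
        rng = np.random.default_rng(40)
        depression = {"AA/CC": 1.0, "AG/CG": 0.8, "GG/CG": 0.6, "GG/GG": 0.4}
        res = growth_two_way_anova(_growth_df(depression, rng))
        assert res["p_group"] < 1e-6
        assert res["p_interaction"] < 1e-3  # depression scales with the mean
        tk = res["tukey"]
        worst = tk[(tk["group1"] == "GG/GG") | (tk["group2"] == "GG/GG")]
        assert (worst["p-adj"].astype(float) < 0.05).all()
        vs_ref = worst[(worst["group1"] == "AA/CC") | (worst["group2"] == "AA/CC")]
        assert (vs_ref["p-adj"].astype(float) < 1e-3).all()

    def test_empty_cell_reported(self):
        df = _growth_df()
        df = df[~((df["group"] == "GG/GG") & (df["day"] == 42))]
        with pytest.raises(ValueError, match="GG/GG"):
            growth_two_way_anova(df)


class TestDiagnoseFromGrowth:
    def _table(self, growths, fused=()):
        rows = []
        for s, g in growths.items():
            rows.append(dict(sample=s, day=10, side="left", separation=1.0))
            rows.append(dict(sample=s, day=25, side="left", separation=1.0 + g))
        return GrowthTable(pd.DataFrame(rows), fused_at_day10=frozenset(fused))

    def test_fused_is_eos(self):
        rng = np.random.default_rng(41)
        growths = {f"n{i}": 4.0 + rng.normal(0, 0.1) for i in range(6)}
        table = self._table(growths, fused=("e1",))
        diag = diagnose_from_growth(table, list(growths))
        assert diag["e1"] == "EOS"

    def test_mean_growth_is_icn_below_ci_is_dos(self):
        refs = {f"n{i}": g for i, g in enumerate([3.8, 3.9, 4.0, 4.1, 4.2])}
        table = self._table({**refs, "probe_mean": 4.0, "probe_low": 2.0})
        diag = diagnose_from_growth(table, list(refs))
        assert diag["probe_mean"] == "ICN"
        assert diag["probe_low"] == "DOS"

    def test_boundary_strictly_below(self):
        refs = {f"n{i}": 4.0 for i in range(4)}
        table = self._table({**refs, "edge": 4.0})
        diag = diagnose_from_growth(table, list(refs))
        assert diag["edge"] == "ICN"

    def test_small_reference_rejected(self):
        table = self._table({"a": 4.0, "b": 4.1, "x": 2.0})
        with pytest.raises(ValueError, match=">= 3"):
            diagnose_from_growth(table, ["a", "b"])
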