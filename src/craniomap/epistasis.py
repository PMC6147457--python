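"""Two-locus epistasis tests, digenic penetrance, growth ANOVA and diagnosis.

The epistasis test is a logistic-regression likelihood-ratio test: the null
model regresses affection status on the two dosages additively
(``y ~ g1 + g2``) and the full model adds their product; X² = 2·ΔLL is
referred to a χ² with 1 df (additive coding; a genotype-factor coding with
4 interaction df is available since the original analysis does not state
its coding). The digenic penetrance table estimates P(affected | g1, g2)
per dosage cell and scores concordance with the deterministic
"at least one copy of each variant allele" inheritance rule.

Growth across the coronal suture is analyzed by two-way fixed-effects ANOVA
(group × measurement interval) with Tukey–Kramer post-hoc comparisons, and
the radiographic diagnosis classifier reproduces the colony's criteria:
fused at day 10 → EOS; day-10→25 growth below the lower bound of the 95%
confidence interval of the unaffected mean → DOS; otherwise ICN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import GrowthTable

logger = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    coef: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool
    n_iter: int
    cov: np.ndarray | None = None

    def __post_init__(self):
        if self.log_likelihood > 1e-9:
            raise ValueError("log-likelihood of a Bernoulli model cannot be positive")


def logistic_irls(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    column_names: list[str] | None = None,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Stops when the score (gradient) norm drops below ``tol``. Complete or
    quasi-complete separation — fitted probabilities saturating at the
    observed labels while coefficients diverge — sets the ``separation``
    flag; inference should then use the likelihood ratio, not Wald
    standard errors. Rank-deficient designs raise, naming the collinear
    columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        names = column_names or [f"x{j}" for j in range(k)]
        # identify columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    beta = np.zeros(k)
    converged = False
    ridge = 1e-10
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X + ridge * np.eye(k)
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the likelihood does not decrease
        ll_old = float(y @ eta - np.logaddexp(0.0, eta).sum())
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            eta_c = np.clip(X @ cand, -35, 35)
            ll_new = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_new >= ll_old - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    w = mu * (1.0 - mu)
    separation = bool(np.max(w) < 1e-6) or (
        not converged and np.abs(beta).max() > 25
    )
    cov = None
    if not separation:
        try:
            cov = np.linalg.inv((X * np.clip(w, 1e-12, None)[:, None]).T @ X)
        except np.linalg.LinAlgError:
            cov = None
    if separation:
        logger.warning("logistic_irls: separation detected; use LRT-based inference")
    return LogisticFit(
        coef=beta, log_likelihood=min(ll, 0.0), converged=converged or separation,
        separation=separation, n_iter=it, cov=cov,
    )


@dataclass
class EpistasisResult:
    locus1: str
    locus2: str
    ll_null: float
    ll_full: float
    chisq: float
    df: int
    p: float
    separation: bool


def _factor_columns(g: np.ndarray) -> np.ndarray:
    """Dummy columns for dosage levels present (reference = lowest level)."""
    levels = np.unique(g)
    return np.column_stack([(g == lv).astype(float) for lv in levels[1:]])


def epistasis_lrt(
    y: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    coding: str = "additive",
    locus1: str = "locus1",
    locus2: str = "locus2",
) -> EpistasisResult:
    """Likelihood-ratio interaction test between two loci.

    ``coding="additive"`` uses dosages with a single product term (1 df);
    ``coding="factor"`` uses genotype indicator columns with all pairwise
    interaction dummies. Samples missing either genotype are dropped.
    Symmetric in locus order.
    """
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2) & ~np.isnan(y)
    y, g1, g2 = y[ok], g1[ok], g2[ok]
    if np.std(g1) == 0 or np.std(g2) == 0:
        raise ValueError("both loci must be polymorphic in the analyzed samples")
    if np.array_equal(g1, g2):
        raise ValueError("loci are identical (collinear)")
    one = np.ones_like(y)
    if coding == "additive":
        X0 = np.column_stack([one, g1, g2])
        X1 = np.column_stack([one, g1, g2, g1 * g2])
        names = ["const", "g1", "g2", "g1:g2"]
    elif coding == "factor":
        F1 = _factor_columns(g1)
        F2 = _factor_columns(g2)
        inter = np.column_stack(
            [F1[:, a] * F2[:, b] for a in range(F1.shape[1]) for b in range(F2.shape[1])]
        )
        X0 = np.column_stack([one, F1, F2])
        X1 = np.column_stack([X0, inter])
        names = None
    else:
        raise ValueError(f"unknown coding {coding!r}")
    fit0 = logistic_irls(y, X0)
    fit1 = logistic_irls(y, X1, column_names=names)
    df = X1.shape[1] - X0.shape[1]
    chisq = max(0.0, 2.0 * (fit1.log_likelihood - fit0.log_likelihood))
    p = float(stats.chi2.sf(chisq, df))
    return EpistasisResult(
        locus1=locus1, locus2=locus2,
        ll_null=fit0.log_likelihood, ll_full=fit1.log_likelihood,
        chisq=float(chisq), df=df, p=p,
        separation=fit0.separation or fit1.separation,
    )


@dataclass
class PenetranceTable:
    """3×3 penetrance over dosage pairs plus digenic-rule concordance."""

    pi: np.ndarray          # P(affected | g1=a, g2=b); NaN for empty cells
    counts: np.ndarray      # animals per cell
    rule_concordance: float # agreement with: affected ⇔ g1 ≥ 1 and g2 ≥ 1
    empty_cells: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pi,
            index=[f"g1={a}" for a in range(3)],
            columns=[f"g2={b}" for b in range(3)],
        )


def penetrance_estimate(y: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> PenetranceTable:
    """Per-cell penetrance and concordance with the one-copy-of-each rule."""
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2) & ~np.isnan(y)
    y, g1, g2 = y[ok], g1[ok].astype(int), g2[ok].astype(int)
    if y.size == 0:
        raise ValueError("no complete observations")
    pi = np.full((3, 3), np.nan)
    counts = np.zeros((3, 3), dtype=int)
    for a in range(3):
        for b in range(3):
            cell = (g1 == a) & (g2 == b)
            counts[a, b] = int(cell.sum())
            if counts[a, b]:
                pi[a, b] = float(y[cell].mean())
    predicted = ((g1 >= 1) & (g2 >= 1)).astype(float)
    concordance = float((predicted == y).mean())
    empty = [(a, b) for a in range(3) for b in range(3) if counts[a, b] == 0]
    return PenetranceTable(pi=pi, counts=counts, rule_concordance=concordance,
                           empty_cells=empty)


def genotype_class_label(
    g1: float, g2: float,
    alleles1: tuple[str, str] = ("A", "G"),
    alleles2: tuple[str, str] = ("C", "G"),
) -> str:
    """Biallelic two-locus label, e.g. dosage (1, 1) with default alleles → "AG/CG"."""
    def one(g, alleles):
        if g is None or (isinstance(g, float) and np.isnan(g)):
            return "··"
        g = int(g)
        if g not in (0, 1, 2):
            raise ValueError(f"dosage must be 0/1/2, got {g}")
        ref, var = alleles
        return {0: ref + ref, 1: ref + var, 2: var + var}[g]

    return f"{one(g1, alleles1)}/{one(g2, alleles2)}"


def growth_two_way_anova(data: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA of growth on group × day.

    ``data`` needs columns ``group``, ``day``, ``value`` with ≥2 groups,
    ≥2 days and ≥2 replicates per cell (empty cells raise, naming the
    cell). Returns the ANOVA table plus Tukey–Kramer comparisons of group
    means.
    """
    df = data.copy()
    for col in ("group", "day", "value"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    cells = df.groupby(["group", "day"], observed=True).size()
    groups = df["group"].unique()
    days = df["day"].unique()
    for grp in groups:
        for d in days:
            if (grp, d) not in cells.index:
                raise ValueError(f"empty design cell: group={grp!r}, day={d!r}")
    model = ols("value ~ C(group) * C(day)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
    out = dict(
        anova=table,
        F_group=float(table.loc["C(group)", "F"]),
        p_group=float(table.loc["C(group)", "PR(>F)"]),
        F_day=float(table.loc["C(day)", "F"]),
        p_day=float(table.loc["C(day)", "PR(>F)"]),
        F_interaction=float(table.loc["C(group):C(day)", "F"]),
        p_interaction=float(table.loc["C(group):C(day)", "PR(>F)"]),
        tukey=pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0]),
    )
    return out


def diagnose_from_growth(
    growth: GrowthTable,
    reference_samples: list[str],
    ci_level: float = 0.95,
) -> pd.Series:
    """Radiographic diagnosis from day-10→25 growth.

    ``reference_samples`` are known unaffected animals defining the normal
    range: the classifier computes the ``ci_level`` confidence interval of
    their mean growth and calls DOS for any animal strictly below its lower
    bound. Animals flagged fused at day 10 are EOS. Needs ≥3 reference
    animals.
    """
    g = growth.growth(10, 25)
    ref = g.reindex([s for s in reference_samples if s in g.index]).dropna()
    if len(ref) < 3:
        raise ValueError("reference cohort must contain >= 3 animals with growth data")
    mean = ref.mean()
    sem = ref.std(ddof=1) / np.sqrt(len(ref))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, len(ref) - 1)
    lower = mean - tcrit * sem
    out = {}
    for s, val in g.items():
        out[s] = "DOS" if val < lower else "ICN"
    for s in growth.fused_at_day10:  # fusion at first radiograph overrides
        out[s] = "EOS"
    return pd.Series(out, name="diagnosis")
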