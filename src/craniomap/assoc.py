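"""Kinship-aware single-marker association scan.

The scan follows the EMMAX recipe for small, heavily related cohorts such
as a breeding colony:

1. pairwise identity-by-state (IBS) kinship from the dosage matrix,
2. a single-variance-component linear mixed model
   ``y = Xb + u + e``, ``u ~ N(0, σ_g² K)``, ``e ~ N(0, σ_e² I)``, whose
   variance ratio ``δ = σ_e²/σ_g²`` is estimated once under the null by
   spectral REML (the EMMA trick: after projecting out the fixed effects,
   the restricted likelihood is a 1-D function of δ),
3. per-SNP generalized least squares on data rotated by the null
   covariance, with a Wald test on the dosage coefficient.

The binary case/control phenotype is treated as quantitative 0/1, the same
approximation the EMMAX software makes. Companion per-SNP statistics match
the study's reporting: BH q-value, proportion of variability explained
(squared phenotype–dosage correlation), cohort MAF, allelic chi-square and
carrier relative risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING, GenotypeStudy
from .qc import bh_fdr

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8  # genome-wide significance threshold

_K_JITTER = 1e-8
_LOG10_DELTA_RANGE = (-5.0, 5.0)


def ibs_kinship(study: GenotypeStudy) -> np.ndarray:
    """Identity-by-state kinship: mean over co-called variants of 1 − |gᵢ−gⱼ|/2.

    Symmetric with unit diagonal; raises if any sample pair shares no
    co-called variant.
    """
    g = study.dosages_float()
    n, m = g.shape
    if m < 2:
        raise ValueError("need at least 2 variants for kinship")
    called = ~np.isnan(g)
    g0 = np.where(called, g, 0.0)
    K = np.empty((n, n))
    for i in range(n):
        co = called[i] & called  # (n, m)
        diff = np.abs(g0[i] - g0) / 2.0
        share = np.where(co, 1.0 - diff, 0.0).sum(axis=1)
        denom = co.sum(axis=1)
        if (denom == 0).any():
            j = int(np.flatnonzero(denom == 0)[0])
            raise ValueError(
                f"samples {study.samples[i]!r} and {study.samples[j]!r} share no "
                "co-called variants"
            )
        K[i] = share / denom
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float          # sigma_e2 / sigma_g2
    reml_ll: float
    identifiable: bool = True

    def __post_init__(self):
        if self.sigma_g2 + self.sigma_e2 <= 0:
            raise ValueError("total variance must be positive")


def _reml_spectrum(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigen-structure of the projected kinship for the 1-D restricted likelihood."""
    n, q = X.shape
    Kj = K + _K_JITTER * np.eye(n)
    w = np.linalg.eigvalsh(Kj)
    if w.min() < -1e-6:
        raise ValueError("kinship matrix not positive semidefinite after jitter")
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    xi, U = np.linalg.eigh(S @ Kj @ S)
    keep = np.argsort(xi)[q:]          # drop the q null-space eigenvalues
    xi = xi[keep]
    xi = np.clip(xi, 0.0, None)
    eta = U[:, keep].T @ y
    return xi, eta, n - q


def _restricted_ll(log_delta: float, xi: np.ndarray, eta2: np.ndarray, nq: int) -> float:
    delta = np.exp(log_delta)
    denom = xi + delta
    s = float(np.sum(eta2 / denom))
    return 0.5 * (
        nq * (np.log(nq / (2.0 * np.pi)) - 1.0 - np.log(s)) - float(np.sum(np.log(denom)))
    )


def emma_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> VarianceComponents:
    """REML estimate of the variance ratio via spectral decomposition.

    The restricted log-likelihood is maximized over ``log δ`` on
    [−5, 5]·ln10 with a coarse grid followed by bounded Brent refinement,
    which is robust to the occasional multi-modal profile. When the
    likelihood is flat in δ (e.g. K = I, where only the total variance is
    identified) the ``identifiable`` flag is cleared.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    if n < 3:
        raise ValueError("need n >= 3")
    xi, eta, nq = _reml_spectrum(y, X, K)
    eta2 = eta**2
    lo, hi = (r * np.log(10.0) for r in _LOG10_DELTA_RANGE)
    grid = np.linspace(lo, hi, 200)
    vals = np.array([_restricted_ll(g, xi, eta2, nq) for g in grid])
    flat = vals.max() - vals.min() < 1e-8
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_restricted_ll(t, xi, eta2, nq),
        bounds=(a, b), method="bounded",
        options=dict(xatol=1e-10),
    )
    best = res.x if -res.fun >= vals[i] else grid[i]
    delta = float(np.exp(best))
    ll = _restricted_ll(best, xi, eta2, nq)
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / nq)
    sigma_e2 = delta * sigma_g2
    if flat:
        logger.warning("emma_reml: restricted likelihood flat in delta (non-identifiable)")
    return VarianceComponents(sigma_g2, sigma_e2, delta, float(ll), identifiable=not flat)


def _rotation(K: np.ndarray, delta: float) -> np.ndarray:
    """Whitening transform T with T V T' = I for V = K + δI (up to scale)."""
    n = K.shape[0]
    w, U = np.linalg.eigh(K + _K_JITTER * np.eye(n))
    w = np.clip(w, 0.0, None)
    return (U / np.sqrt(w + delta)).T


def allelic_chisq_rr(y: np.ndarray, g: np.ndarray) -> tuple[float, float, bool]:
    """Allelic chi-square and carrier relative risk for one SNP.

    Chi-square is Pearson's statistic on the 2×2 minor/major allele ×
    case/control count table. The relative risk contrasts the case rate in
    carriers of ≥1 minor allele against non-carriers. A zero cell triggers
    the Haldane–Anscombe 0.5 correction and sets the returned flag.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[ok], g[ok]
    alt_freq = g.sum() / (2 * g.size)
    minor_is_alt = alt_freq <= 0.5
    gm = g if minor_is_alt else 2 - g  # minor-allele dosage
    case = y == 1
    # allele-count table: rows case/control, cols minor/major
    table = np.array(
        [
            [gm[case].sum(), (2 - gm[case]).sum()],
            [gm[~case].sum(), (2 - gm[~case]).sum()],
        ],
        dtype=float,
    )
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chisq = 0.0
    else:
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        chisq = float(((table - exp) ** 2 / exp).sum())
    carrier = gm >= 1
    a = float((case & carrier).sum())
    b = float((~case & carrier).sum())
    c = float((case & ~carrier).sum())
    d = float((~case & ~carrier).sum())
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr = (a / (a + b)) / (c / (c + d))
    return chisq, float(rr), corrected


def variance_explained(y: np.ndarray, g: np.ndarray) -> float:
    """Proportion of phenotype variability explained by one SNP.

    Convention: squared Pearson correlation between the 0/1 phenotype and
    the dosage (pairwise-complete). NaN when either vector is constant.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[ok], g[ok]
    if y.size < 2 or np.std(y) == 0 or np.std(g) == 0:
        return float("nan")
    r = np.corrcoef(y, g)[0, 1]
    return float(r * r)


def emmax_scan(
    study: GenotypeStudy,
    case_mask: np.ndarray,
    K: np.ndarray | None = None,
    vc: VarianceComponents | None = None,
    refit_per_snp: bool = False,
    gw_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Mixed-model association scan of every variant against a case mask.

    ``case_mask`` selects the cases *within* the study's samples; all study
    samples form the analysis cohort (subset the study first to drop
    animals outside the contrast). Missing genotypes are mean-imputed
    within the cohort for testing only. Monomorphic variants are a
    contract violation (run ``apply_filters`` first).

    With ``refit_per_snp`` the variance ratio is re-estimated under each
    SNP's alternative model (exact EMMA); the default reuses the null fit
    (the EMMAX approximation).

    Returns a DataFrame with columns chrom, pos, vid, beta, se, p, q,
    var_explained, maf, chisq_allelic, rr, rr_corrected, genome_wide.
    """
    y = np.asarray(case_mask, dtype=float)
    n = study.n_samples
    if y.size != n:
        raise ValueError("case_mask length must equal number of samples")
    g = study.dosages_float()
    if K is None:
        K = ibs_kinship(study)
    X = np.ones((n, 1))
    if vc is None:
        vc = emma_reml(y, X, K)
    T = _rotation(K, vc.delta)
    ys = T @ y
    Xs = T @ X
    # cohort-mean imputation for the regression only
    col_mean = np.nanmean(g, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("variant with zero called genotypes reached the scan")
    alt_freq = col_mean / 2.0
    const = np.nanstd(g, axis=0) == 0
    mono = const & ((alt_freq == 0) | (alt_freq == 1))
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic variant(s) reached the scan; "
            "apply_filters first"
        )
    if const.any():
        # e.g. every sample heterozygous: polymorphic but untestable
        logger.warning(
            "emmax_scan: %d constant-dosage variant(s) get NaN statistics",
            int(const.sum()),
        )
    gi = np.where(np.isnan(g), col_mean, g)
    Gs = T @ gi
    one = Xs[:, 0]
    a11 = float(one @ one)
    a12 = one @ Gs
    a22 = (Gs * Gs).sum(axis=0)
    b1 = float(one @ ys)
    b2 = Gs.T @ ys
    det = a11 * a22 - a12**2
    beta = (a11 * b2 - a12 * b1) / det
    beta0 = (a22 * b1 - a12 * b2) / det
    yy = float(ys @ ys)
    rss = yy - (beta0 * b1 + beta * b2)
    dof = n - 2
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 * a11 / det)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[const] = se[const] = p[const] = np.nan
    if refit_per_snp:
        for j in range(g.shape[1]):
            Xj = np.column_stack([np.ones(n), gi[:, j]])
            vcj = emma_reml(y, Xj, K)
            Tj = _rotation(K, vcj.delta)
            ysj, Xsj = Tj @ y, Tj @ Xj
            coef, res_, rank_, _ = np.linalg.lstsq(Xsj, ysj, rcond=None)
            rssj = float(((ysj - Xsj @ coef) ** 2).sum())
            covj = np.linalg.inv(Xsj.T @ Xsj) * (rssj / dof)
            beta[j] = coef[1]
            se[j] = np.sqrt(covj[1, 1])
            p[j] = 2.0 * stats.t.sf(abs(coef[1] / se[j]), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    chisq = np.empty(g.shape[1])
    rr = np.empty(g.shape[1])
    rr_flag = np.zeros(g.shape[1], dtype=bool)
    var_exp = np.empty(g.shape[1])
    for j in range(g.shape[1]):
        chisq[j], rr[j], rr_flag[j] = allelic_chisq_rr(y, g[:, j])
        var_exp[j] = variance_explained(y, g[:, j])
    return pd.DataFrame(
        dict(
            chrom=[v.chrom for v in study.variants],
            pos=[v.pos for v in study.variants],
            vid=[v.vid for v in study.variants],
            beta=beta,
            se=se,
            p=p,
            q=q,
            var_explained=var_exp,
            maf=maf,
            chisq_allelic=chisq,
            rr=rr,
            rr_corrected=rr_flag,
            genome_wide=p <= gw_threshold,
        )
    )


def manhattan_data(scan: pd.DataFrame) -> pd.DataFrame:
    """(chrom, pos, −log10 p) export for Manhattan plotting."""
    return pd.DataFrame(
        dict(chrom=scan["chrom"], pos=scan["pos"], neglog10_p=-np.log10(scan["p"]))
    )
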