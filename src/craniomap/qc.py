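"""Per-variant summary statistics and exclusion filters.

The exclusion rules mirror the mapping study's pre-association filtering:
a SNP is dropped when its genotype call is missing in strictly more than
10% of the cohort, or when it is monomorphic (MAF = 0) in the cohort.
Hardy–Weinberg equilibrium is assessed with the exact conditional test
(probability of the observed heterozygote count given the allele count;
the p-value sums the probabilities of all tables no more probable than the
observed one). HWE is *reported*, never used as a filter by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the minor-allele count; enumerates every possible
    heterozygote count of matching parity and sums probabilities that do
    not exceed the observed table's probability.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no called genotypes")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # P(n_het | n, n_minor) ∝ n! / (hom_major! het! hom_minor!) * 2^het
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


@dataclass
class ExclusionLog:
    """Counts of variants removed by each filter rule."""

    n_input: int
    n_excluded_missing: int
    n_excluded_maf: int
    n_kept: int


def variant_qc(study: GenotypeStudy, cohort_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant QC statistics within a cohort.

    Returns a DataFrame indexed like ``study.variants`` with columns
    ``maf``, ``call_rate``, ``obs_het``, ``pred_het``, ``hwe_p``,
    ``n_called``. Variants with zero called genotypes get NaN statistics
    and are flagged in ``ok``. Predicted heterozygosity is 2·MAF·(1−MAF)
    on called genotypes only; the missingness denominator is the full
    cohort.
    """
    g = study.dosages
    if cohort_mask is not None:
        g = g[np.asarray(cohort_mask, dtype=bool), :]
    n_cohort = g.shape[0]
    called = g != MISSING
    n_called = called.sum(axis=0)
    gf = g.astype(float)
    gf[~called] = 0.0
    alt_count = gf.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt_count / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    n_het = ((g == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_het = n_het / n_called
    pred_het = 2.0 * maf * (1.0 - maf)
    hwe = np.full(g.shape[1], np.nan)
    for j in range(g.shape[1]):
        if n_called[j] == 0:
            continue
        col = g[:, j]
        hwe[j] = hwe_exact_p(
            int(((col == 0)).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    df = pd.DataFrame(
        dict(
            vid=[v.vid for v in study.variants],
            chrom=[v.chrom for v in study.variants],
            pos=[v.pos for v in study.variants],
            maf=maf,
            call_rate=n_called / n_cohort if n_cohort else np.nan,
            obs_het=obs_het,
            pred_het=pred_het,
            hwe_p=hwe,
            n_called=n_called,
        )
    )
    df["ok"] = df["n_called"] > 0
    n_bad = int((~df["ok"]).sum())
    if n_bad:
        logger.warning("variant_qc: %d variant(s) with zero called genotypes", n_bad)
    return df


def apply_filters(
    study: GenotypeStudy,
    max_missing: float = 0.10,
    min_maf: float = 0.0,
    cohort_mask: np.ndarray | None = None,
) -> tuple[GenotypeStudy, ExclusionLog]:
    """Drop variants failing the missingness/MAF rules; order preserved.

    A variant is excluded when its missing fraction is *strictly greater*
    than ``max_missing``, or when its cohort MAF is zero (``min_maf = 0``)
    or below ``min_maf`` (when positive). Idempotent: re-applying the same
    thresholds to the output removes nothing.
    """
    if not (0 <= max_missing <= 1) or not (0 <= min_maf <= 0.5):
        raise ValueError("thresholds out of range")
    qc = variant_qc(study, cohort_mask)
    miss_frac = 1.0 - qc["call_rate"].to_numpy()
    maf = qc["maf"].to_numpy()
    bad_missing = miss_frac > max_missing
    with np.errstate(invalid="ignore"):
        # monomorphic always out; a positive min_maf keeps maf >= min_maf
        bad_maf = ~(maf >= min_maf) | ~(maf > 0)
    keep = ~(bad_missing | bad_maf)
    log = ExclusionLog(
        n_input=study.n_variants,
        n_excluded_missing=int(bad_missing.sum()),
        n_excluded_maf=int((bad_maf & ~bad_missing).sum()),
        n_kept=int(keep.sum()),
    )
    logger.info(
        "apply_filters: kept %d/%d (missing>%g: %d, maf rule: %d)",
        log.n_kept, log.n_input, max_missing, log.n_excluded_missing, log.n_excluded_maf,
    )
    return study.subset_variants(keep), log


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    NaN inputs propagate to NaN (with a warning) and are excluded from the
    ranking. q-values are monotone in p-rank and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    nan = np.isnan(p)
    if nan.any():
        logger.warning("bh_fdr: %d NaN p-value(s) propagated", int(nan.sum()))
    pv = p[~nan]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    qq = np.empty(m)
    qq[order] = ranked
    q[~nan] = qq
    return q
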