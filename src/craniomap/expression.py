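"""Probe-set information filtering and group-level expression analysis.

Each probe set's Gene Information Content (GIC) is the fraction of its
row-centered expression variance captured by the first singular value —
near 1 when the probes move together (one underlying transcript signal),
near 1/min(p, n−1) for pure noise. The significance cutoff is empirical:
the probe → probe-set map is permuted (preserving the multiset of set
sizes), GIC is recomputed for every permuted set, and the 99th percentile
of the permuted scores is the cutoff; sets scoring below it are removed.

Downstream comparisons operate on gene-level summaries (mean of a gene's
surviving probes by default): one-way ANOVA with Tukey–Kramer post-hoc
tests across the four diagnosis groups, and per-group ordinary
least-squares regression of one gene's expression on another's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

EXPRESSION_GROUPS = ("control", "coronal", "metopic", "sagittal")


@dataclass
class ExpressionStudy:
    """Normalized log-scale expression with a probe→probe-set map.

    ``expr`` is probes × samples; ``probe_map`` maps each probe (row) to
    exactly one probe-set/gene; ``groups`` assigns each sample to one of
    the four diagnosis groups.
    """

    expr: pd.DataFrame
    probe_map: pd.Series
    groups: pd.Series

    def __post_init__(self):
        self.expr = pd.DataFrame(self.expr)
        self.probe_map = pd.Series(self.probe_map)
        self.groups = pd.Series(self.groups)
        missing = set(self.expr.index) - set(self.probe_map.index)
        if missing:
            raise ValueError(f"{len(missing)} probe(s) missing from probe_map")
        self.probe_map = self.probe_map.reindex(self.expr.index)
        bad = set(self.groups.unique()) - set(EXPRESSION_GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s) {sorted(bad)}")
        if list(self.groups.index) != list(self.expr.columns):
            self.groups = self.groups.reindex(self.expr.columns)
            if self.groups.isna().any():
                raise ValueError("every sample needs a group label")

    @property
    def probe_sets(self) -> dict[str, list[str]]:
        sets: dict[str, list[str]] = {}
        for probe, ps in self.probe_map.items():
            sets.setdefault(ps, []).append(probe)
        return sets

    def gene_expression(self, gene: str, summary: str = "mean") -> pd.Series:
        """Per-sample summary of one gene's probes (mean or first-SV scores)."""
        probes = [p for p, g in self.probe_map.items() if g == gene]
        if not probes:
            raise KeyError(f"no probes mapped to {gene!r}")
        sub = self.expr.loc[probes].to_numpy(dtype=float)
        if summary == "mean":
            vals = sub.mean(axis=0)
        elif summary == "svd":
            centered = sub - sub.mean(axis=1, keepdims=True)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            c = np.corrcoef(vt[0], sub.mean(axis=0))[0, 1]
            vals = vt[0] * (-1.0 if np.isfinite(c) and c < 0 else 1.0)
        else:
            raise ValueError(f"unknown summary {summary!r}")
        return pd.Series(vals, index=self.expr.columns, name=gene)


def gic_score(submatrix: np.ndarray, center: bool = True) -> float:
    """Fraction of variance explained by the first singular value.

    Rows (probes) are centered by default; a zero-variance submatrix is
    undefined and returns NaN. Single-probe sets score exactly 1.
    """
    A = np.atleast_2d(np.asarray(submatrix, dtype=float))
    if A.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if center:
        A = A - A.mean(axis=1, keepdims=True)
    s = np.linalg.svd(A, compute_uv=False)
    total = float((s**2).sum())
    if total == 0.0:
        return float("nan")
    return float(s[0] ** 2 / total)


@dataclass
class GICResult:
    scores: pd.Series               # per probe-set GIC
    cutoff: float
    passed: pd.Series = field(init=False)
    n_perm: int = 0
    quantile: float = 0.99

    def __post_init__(self):
        self.passed = self.scores >= self.cutoff


def gic_scores(study: ExpressionStudy, center: bool = True) -> pd.Series:
    """GIC of every probe-set in the study."""
    expr = study.expr.to_numpy(dtype=float)
    row_of = {p: i for i, p in enumerate(study.expr.index)}
    out = {}
    for ps, probes in study.probe_sets.items():
        out[ps] = gic_score(expr[[row_of[p] for p in probes]], center=center)
    return pd.Series(out, name="gic")


def gic_cutoff(
    study: ExpressionStudy,
    n_perm: int = 1000,
    quantile: float = 0.99,
    rng: np.random.Generator | int | None = None,
    center: bool = True,
) -> float:
    """Permutation cutoff for GIC scores.

    Each permutation shuffles which probes belong to which set while
    keeping the multiset of set sizes fixed (the probe rows are permuted
    against the fixed set layout); the cutoff is the ``quantile`` of all
    permuted scores pooled. Deterministic for a fixed ``rng`` seed.
    """
    rng = np.random.default_rng(rng)
    expr = study.expr.to_numpy(dtype=float)
    sizes = [len(v) for v in study.probe_sets.values()]
    if len(sizes) < 2:
        raise ValueError("need >= 2 probe-sets")
    n_probes = expr.shape[0]
    if center:
        expr = expr - expr.mean(axis=1, keepdims=True)
    # row offsets of each set in the (fixed) set layout
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    by_size: dict[int, list[int]] = {}
    for si, size in enumerate(sizes):
        by_size.setdefault(size, []).append(si)
    perms = np.stack([rng.permutation(n_probes) for _ in range(n_perm)])
    null = np.empty((n_perm, len(sizes)))
    for size, set_ids in by_size.items():
        # batched SVD over every (permutation, set) of this size at once
        rows = np.concatenate(
            [perms[:, offsets[si] : offsets[si] + size] for si in set_ids]
        )
        A = expr[rows]  # (n_perm * n_sets_of_size, size, n_samples)
        s = np.linalg.svd(A, compute_uv=False)
        tot = (s**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            gic = np.where(tot > 0, s[:, 0] ** 2 / tot, np.nan)
        null[:, set_ids] = gic.reshape(len(set_ids), n_perm).T
    return float(np.nanquantile(null.ravel(), quantile))


def filter_probesets(study: ExpressionStudy, result: GICResult) -> ExpressionStudy:
    """Remove probe-sets whose GIC is below the cutoff; survivors logged."""
    keep_sets = set(result.passed[result.passed].index)
    keep_probes = [p for p, ps in study.probe_map.items() if ps in keep_sets]
    logger.info(
        "filter_probesets: %d/%d probe-sets survive (cutoff %.4f)",
        len(keep_sets), result.scores.size, result.cutoff,
    )
    return replace(
        study,
        expr=study.expr.loc[keep_probes],
        probe_map=study.probe_map.loc[keep_probes],
    )


def gic_filter(
    study: ExpressionStudy,
    n_perm: int = 1000,
    quantile: float = 0.99,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionStudy, GICResult]:
    """Score, derive the permutation cutoff, and filter — in one call."""
    scores = gic_scores(study)
    cutoff = gic_cutoff(study, n_perm=n_perm, quantile=quantile, rng=rng)
    result = GICResult(scores=scores, cutoff=cutoff, n_perm=n_perm, quantile=quantile)
    return filter_probesets(study, result), result


def group_anova_tukey(values: pd.Series, groups: pd.Series) -> dict:
    """One-way ANOVA of a gene's expression across groups, plus Tukey HSD."""
    groups = groups.reindex(values.index)
    arrays = [values[groups == g].to_numpy(dtype=float) for g in groups.unique()]
    arrays = [a for a in arrays if a.size >= 2]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(values) == 0:
        return dict(F=0.0, p=1.0, tukey=None)
    F, p = stats.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(values.to_numpy(dtype=float), groups.to_numpy())
    return dict(
        F=float(F), p=float(p),
        tukey=pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0]),
    )


def pair_regression(x: pd.Series, y: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group OLS of y on x with a two-sided slope test.

    Mirrors the gene-pair analysis: one regression per diagnosis group,
    reporting slope, intercept, r and the slope p-value. Groups with fewer
    than 3 samples raise; a constant x within a group raises.
    """
    groups = groups.reindex(x.index)
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        xs = x[mask].to_numpy(dtype=float)
        ys = y[mask].to_numpy(dtype=float)
        if xs.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        if np.ptp(xs) == 0:
            raise ValueError(f"constant predictor in group {g!r}")
        fit = stats.linregress(xs, ys)
        rows.append(
            dict(group=g, n=xs.size, slope=fit.slope, intercept=fit.intercept,
                 r=fit.rvalue, p=fit.pvalue)
        )
    return pd.DataFrame(rows).set_index("group")


def read_expression_tsv(expr_path, map_path, groups_path) -> ExpressionStudy:
    """Assemble a study from three TSVs: matrix, probe map, sample groups."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    pmap = pd.read_csv(map_path, sep="\t", index_col=0).iloc[:, 0]
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionStudy(expr=expr, probe_map=pmap, groups=groups)
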