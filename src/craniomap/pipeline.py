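"""End-to-end orchestration: QC → scans → LD blocks → epistasis → reports.

`run_pipeline` chains the analysis the way the colony mapping was run:
the *occurrence* contrast compares all synostotic animals (EOS + DOS)
against ICN controls; the *onset* contrast compares EOS cases against DOS
controls. Each contrast gets its own variant filtering, kinship, mixed-
model scan, confidence-interval block around the top hit, and tag-SNP /
group-MAF summaries; candidate pairs across the two contrasts are then
tested for epistasis and the best pair is summarized as a digenic
penetrance table. Every stage's output is a DataFrame in the returned
bundle; ``write_results`` exports them as TSVs. All randomness flows from
``PipelineConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, epistasis, ld, qc
from .io import GenotypeStudy, GrowthTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gw_threshold: float = 5e-8
    max_missing: float = 0.10
    min_maf: float = 0.0
    block: ld.BlockConfig = field(default_factory=ld.BlockConfig)
    tag_r2_min: float = 0.8
    # candidate hits carried into the two-locus stage, per contrast; the
    # defaults mirror a discovery set with one occurrence hit and five
    # onset hits
    n_top_occurrence: int = 1
    n_top_onset: int = 5
    epistasis_coding: str = "additive"
    do_blocks: bool = True      # skip the LD-block stage (e.g. replicated runs)
    ld_window: int = 40
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gw_threshold < 1):
            raise ValueError("gw_threshold must lie in (0, 1)")
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must lie in [0, 1]")


@dataclass
class ScanBundle:
    contrast: str
    study: GenotypeStudy
    exclusions: qc.ExclusionLog
    qc_table: pd.DataFrame
    scan: pd.DataFrame
    blocks: list[ld.HaplotypeBlock]
    block_table: pd.DataFrame
    ld_pairs: pd.DataFrame | None
    tags: list[str]
    maf_profile: dict | None


@dataclass
class PipelineResult:
    occurrence: ScanBundle
    onset: ScanBundle
    epistasis_table: pd.DataFrame
    penetrance: epistasis.PenetranceTable | None
    diagnosis: pd.Series | None
    growth_anova: dict | None
    config: PipelineConfig

    def reports(self) -> dict[str, pd.DataFrame]:
        out = {
            "occurrence_qc": self.occurrence.qc_table,
            "occurrence_scan": self.occurrence.scan,
            "occurrence_blocks": self.occurrence.block_table,
            "onset_qc": self.onset.qc_table,
            "onset_scan": self.onset.scan,
            "onset_blocks": self.onset.block_table,
            "epistasis": self.epistasis_table,
        }
        if self.penetrance is not None:
            out["penetrance"] = self.penetrance.to_frame()
        if self.diagnosis is not None:
            out["diagnosis"] = self.diagnosis.to_frame()
        return out


def _scan_contrast(
    study: GenotypeStudy,
    case_labels: tuple[str, ...],
    control_labels: tuple[str, ...],
    config: PipelineConfig,
    contrast: str,
) -> ScanBundle:
    keep = [
        s for s in study.samples
        if study.diagnoses.get(s) in case_labels + control_labels
    ]
    sub = study.subset_samples(keep)
    filtered, log = qc.apply_filters(sub, config.max_missing, config.min_maf)
    qc_table = qc.variant_qc(filtered)
    case_mask = filtered.case_mask(case_labels)
    K = assoc.ibs_kinship(filtered)
    scan = assoc.emmax_scan(filtered, case_mask, K, gw_threshold=config.gw_threshold)

    if not config.do_blocks:
        return ScanBundle(
            contrast=contrast, study=filtered, exclusions=log, qc_table=qc_table,
            scan=scan, blocks=[], block_table=ld.block_table([]),
            ld_pairs=None, tags=[], maf_profile=None,
        )

    # CI blocks in a window around the top hit (targeted mapping)
    ld_window = config.ld_window
    top = int(scan["p"].idxmin())
    lo = max(0, top - ld_window // 2)
    hi = min(filtered.n_variants, top + ld_window // 2 + 1)
    window_chrom = filtered.variants[top].chrom
    idx = [i for i in range(lo, hi) if filtered.variants[i].chrom == window_chrom]
    region = filtered.subset_variants(np.array(idx))
    pairs = ld.pairwise_ld(region.dosages_float(), config.block)
    blocks = ld.gabriel_blocks(region.variants, pairs, config.block)
    btable = ld.block_table(blocks)

    tags: list[str] = []
    maf_profile = None
    target = next(
        (b for b in blocks
         if b.start_pos <= filtered.variants[top].pos <= b.end_pos
         and b.chrom == window_chrom),
        None,
    )
    if target is not None and len(target.member_indices) >= 2:
        gblk = region.dosages_float()[:, target.member_indices]
        tags = [target.member_ids[t] for t in ld.tag_snps(gblk, config.tag_r2_min)]
        labels = np.array([region.diagnoses.get(s, "?") for s in region.samples])
        try:
            maf_profile = ld.group_maf_profile(gblk, labels, target.member_ids)
        except ValueError:
            maf_profile = None
    return ScanBundle(
        contrast=contrast, study=filtered, exclusions=log, qc_table=qc_table,
        scan=scan, blocks=blocks, block_table=btable,
        ld_pairs=ld.ld_table(pairs), tags=tags, maf_profile=maf_profile,
    )


def run_pipeline(
    study: GenotypeStudy,
    growth: GrowthTable | None = None,
    config: PipelineConfig | None = None,
    epistasis_panel: GenotypeStudy | None = None,
) -> PipelineResult:
    """Run the full mapping analysis on one study.

    ``study`` is the sequenced case/control panel used for the two scans.
    ``epistasis_panel`` optionally supplies a larger retrospectively
    genotyped cohort (e.g. the whole colony) for the two-locus stages,
    mirroring a design where candidate loci are typed in many more animals
    than were sequenced; it defaults to ``study``. Deterministic given the
    inputs and config. Any stage failure is re-raised with the stage name
    prefixed.
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    occurrence = stage(
        "occurrence_scan", _scan_contrast, study, ("EOS", "DOS"), ("ICN",),
        config, "occurrence",
    )
    onset = stage(
        "onset_scan", _scan_contrast, study, ("EOS",), ("DOS",), config, "onset",
    )

    # epistasis between genome-wide significant hits of the two contrasts
    # (capped per contrast; the single best hit if none reach threshold)
    def candidates(scan, cap):
        sig = scan[scan["genome_wide"]]
        if len(sig) == 0:
            sig = scan
        return sig.nsmallest(cap, "p")

    occ_top = candidates(occurrence.scan, config.n_top_occurrence)
    ons_top = candidates(onset.scan, config.n_top_onset)
    panel = epistasis_panel if epistasis_panel is not None else study
    panel = panel.subset_samples(
        [s for s in panel.samples if panel.diagnoses.get(s) in ("EOS", "DOS", "ICN")]
    )
    y = panel.case_mask(("EOS", "DOS")).astype(float)
    g = panel.dosages_float()
    vid_index = {v.vid: j for j, v in enumerate(panel.variants)}
    rows = []
    for _, r1 in occ_top.iterrows():
        for _, r2 in ons_top.iterrows():
            if r1["vid"] == r2["vid"] or r2["vid"] not in vid_index:
                continue
            j1, j2 = vid_index[r1["vid"]], vid_index[r2["vid"]]
            try:
                res = stage(
                    "epistasis", epistasis.epistasis_lrt,
                    y, g[:, j1], g[:, j2],
                    coding=config.epistasis_coding,
                    locus1=r1["vid"], locus2=r2["vid"],
                )
            except RuntimeError as exc:
                logger.warning("%s", exc)
                continue
            rows.append(
                dict(
                    locus1=res.locus1, locus2=res.locus2,
                    chrom1=r1["chrom"], pos1=r1["pos"],
                    chrom2=r2["chrom"], pos2=r2["pos"],
                    ll_null=res.ll_null, ll_full=res.ll_full,
                    chisq=res.chisq, df=res.df, p=res.p,
                    separation=res.separation,
                )
            )
    etable = pd.DataFrame(rows).sort_values("p").reset_index(drop=True) if rows else pd.DataFrame()

    penetrance = None
    if len(etable):
        best = etable.iloc[0]
        j1, j2 = vid_index[best["locus1"]], vid_index[best["locus2"]]
        penetrance = stage(
            "penetrance", epistasis.penetrance_estimate, y, g[:, j1], g[:, j2]
        )

    diagnosis = None
    growth_anova = None
    if growth is not None:
        ref = [s for s in study.samples if study.diagnoses.get(s) == "ICN"]
        try:
            diagnosis = stage("diagnosis", epistasis.diagnose_from_growth, growth, ref)
        except RuntimeError as exc:
            logger.warning("%s", exc)
        wide = growth.growth(10, 25).rename("value").to_frame()
        wide["group"] = [study.diagnoses.get(s, "?") for s in wide.index]
        wide["day"] = 25
        g42 = growth.growth(25, 42).rename("value").to_frame()
        g42["group"] = [study.diagnoses.get(s, "?") for s in g42.index]
        g42["day"] = 42
        both = pd.concat([wide, g42], ignore_index=True)
        both = both[both["group"].isin(("ICN", "DOS"))]
        if len(both) and both["group"].nunique() >= 2:
            try:
                growth_anova = stage("growth_anova", epistasis.growth_two_way_anova, both)
            except RuntimeError as exc:
                logger.warning("%s", exc)

    return PipelineResult(
        occurrence=occurrence, onset=onset, epistasis_table=etable,
        penetrance=penetrance, diagnosis=diagnosis, growth_anova=growth_anova,
        config=config,
    )


def write_results(result: PipelineResult, outdir) -> list[Path]:
    """Export every stage's table as TSV; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in result.reports().items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=bool(df.index.name or name == "penetrance"))
        written.append(path)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"config: {result.config}\n")
        fh.write(
            f"occurrence: kept {result.occurrence.exclusions.n_kept}/"
            f"{result.occurrence.exclusions.n_input} variants\n"
        )
        fh.write(
            f"onset: kept {result.onset.exclusions.n_kept}/"
            f"{result.onset.exclusions.n_input} variants\n"
        )
    written.append(outdir / "run_log.txt")
    return written
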