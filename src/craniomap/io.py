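"""Reading, writing and validation of study inputs.

Genotypes travel as VCF v4.x (via pysam); phenotype/pedigree and growth
measurements as tab-separated tables. The in-memory containers here are
shared by every analysis stage: a :class:`GenotypeStudy` holds the sample ×
variant dosage matrix together with diagnoses and pedigree, and a
:class:`GrowthTable` holds the radiographic marker-separation measurements
taken at days 10, 25 and 42.

Coordinates are 1-based and inclusive throughout (VCF convention); block
spans elsewhere in the package are reported as ``end − start`` in bp.
Dosage counts copies of the ALT allele; the *minor* allele is always
recomputed per cohort downstream, never assumed from REF/ALT orientation.
Missing genotypes are stored as the sentinel :data:`MISSING` and are never
imputed at I/O time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype in the int8 dosage matrix
MISSING: int = -1

DIAGNOSES = ("ICN", "DOS", "EOS")
LATERALITIES = ("unilateral", "bilateral")
MEASUREMENT_DAYS = (10, 25, 42)
SIDES = ("left", "right")


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic SNP.

    ``pos`` is the 1-based base-pair coordinate. ``vid`` defaults to
    ``"chrom:pos"`` when the source carries no identifier.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vid: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only single-nucleotide alleles allowed, got {self.ref}/{self.alt}"
            )
        if not self.vid:
            object.__setattr__(self, "vid", f"{self.chrom}:{self.pos}")


@dataclass
class GenotypeStudy:
    """Genotypes plus per-sample diagnosis and pedigree for one cohort.

    ``dosages`` is an int8 matrix of shape (n_samples, n_variants) with
    entries in {0, 1, 2, MISSING} counting ALT alleles. ``diagnoses`` maps
    sample id to one of ``ICN``/``DOS``/``EOS``; ``laterality`` optionally
    refines affected samples; ``pedigree`` maps sample id to
    ``(sire | None, dam | None)`` where named parents must either be samples
    themselves or declared founders (parent of record outside the matrix).
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosages: np.ndarray
    diagnoses: dict[str, str] = field(default_factory=dict)
    laterality: dict[str, str] = field(default_factory=dict)
    pedigree: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self._check_sorted()
        for s, d in self.diagnoses.items():
            if d not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {d!r} for sample {s!r}")

    def _check_sorted(self):
        seen_chrom_last_pos: dict[str, int] = {}
        for v in self.variants:
            last = seen_chrom_last_pos.get(v.chrom)
            if last is not None and v.pos < last:
                raise ValueError(
                    f"variants not sorted by position within chromosome "
                    f"{v.chrom!r} (pos {v.pos} after {last})"
                )
            seen_chrom_last_pos[v.chrom] = v.pos

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing entries as NaN."""
        g = self.dosages.astype(float)
        g[self.dosages == MISSING] = np.nan
        return g

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def case_mask(self, case_labels=("DOS", "EOS")) -> np.ndarray:
        """Boolean mask over samples whose diagnosis is in ``case_labels``."""
        return np.array(
            [self.diagnoses.get(s) in case_labels for s in self.samples], dtype=bool
        )

    def diagnosis_mask(self, label: str) -> np.ndarray:
        return np.array([self.diagnoses.get(s) == label for s in self.samples], dtype=bool)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeStudy":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, keep_ids) -> "GenotypeStudy":
        idx = self.sample_index(keep_ids)
        ids = [self.samples[i] for i in idx]
        return replace(
            self,
            samples=ids,
            dosages=self.dosages[idx, :],
            diagnoses={s: d for s, d in self.diagnoses.items() if s in set(ids)},
            laterality={s: d for s, d in self.laterality.items() if s in set(ids)},
            pedigree={s: p for s, p in self.pedigree.items() if s in set(ids)},
        )


@dataclass
class GrowthTable:
    """Marker-separation measurements: (sample, day, side, separation mm).

    Days are restricted to the three cephalograph time points (10/25/42);
    separations are non-negative. ``fused_at_day10`` lists animals whose
    coronal suture was already fused at the first radiograph — these have no
    marker measurements and are diagnosed EOS downstream.
    """

    data: pd.DataFrame
    fused_at_day10: frozenset[str] = frozenset()

    COLUMNS = ("sample", "day", "side", "separation")

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing_cols = set(self.COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"growth table missing columns {sorted(missing_cols)}")
        df = df[list(self.COLUMNS)].copy()
        df["day"] = df["day"].astype(int)
        bad_day = ~df["day"].isin(MEASUREMENT_DAYS)
        if bad_day.any():
            raise ValueError(
                f"invalid measurement day(s) {sorted(df.loc[bad_day, 'day'].unique())}; "
                f"allowed: {MEASUREMENT_DAYS}"
            )
        bad_side = ~df["side"].isin(SIDES)
        if bad_side.any():
            raise ValueError(f"invalid side value(s) {df.loc[bad_side, 'side'].unique()}")
        df["separation"] = df["separation"].astype(float)
        if (df["separation"] < 0).any():
            raise ValueError("marker separation must be non-negative")
        self.data = df.reset_index(drop=True)
        self.fused_at_day10 = frozenset(self.fused_at_day10)

    def growth(self, day_from: int = 10, day_to: int = 25) -> pd.Series:
        """Per-animal growth between two measurement days, averaged over sides."""
        wide = self.data.pivot_table(
            index="sample", columns="day", values="separation", aggfunc="mean"
        )
        if day_from not in wide.columns or day_to not in wide.columns:
            raise ValueError(f"days {day_from}->{day_to} not measured")
        return (wide[day_to] - wide[day_from]).dropna()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeStudy:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeStudy`.

    Multi-allelic records and non-SNP alleles are skipped (counts logged).
    Missing or half-called genotypes become :data:`MISSING`. Diagnoses and
    pedigree are left empty; merge them with :func:`read_phenotypes`.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_skipped_multi = 0
    n_skipped_nonsnp = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_skipped_multi += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            n_skipped_nonsnp += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in gt if a == 1)
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        variants.append(VariantRecord(rec.chrom, rec.pos, ref, alt, vid))
        rows.append(col)
    vf.close()
    if n_skipped_multi or n_skipped_nonsnp:
        logger.info(
            "read_vcf: skipped %d multi-allelic and %d non-SNP records",
            n_skipped_multi, n_skipped_nonsnp,
        )
    dosages = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeStudy(variants=variants, samples=samples, dosages=dosages)


def write_vcf(study: GenotypeStudy, path) -> None:
    """Write a study's genotypes back out as an uncompressed VCF."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in study.variants):
        max_pos = max(v.pos for v in study.variants if v.chrom == chrom)
        header.contigs.add(chrom, length=max_pos + 1)
    for s in study.samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for j, v in enumerate(study.variants):
        rec = out.new_record(
            contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.ref, v.alt), id=v.vid
        )
        for i, s in enumerate(study.samples):
            d = int(study.dosages[i, j])
            if d == MISSING:
                rec.samples[s]["GT"] = (None, None)
            else:
                rec.samples[s]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# phenotype / pedigree table
# ---------------------------------------------------------------------------

def read_phenotypes(path, study: GenotypeStudy | None = None) -> GenotypeStudy | dict:
    """Read the sample/diagnosis/sire/dam table and merge into ``study``.

    Diagnosis labels are case-folded to the canonical upper-case forms.
    Duplicate sample rows and unknown labels are hard errors; samples that
    are genotyped but absent from the table are flagged with a warning.
    Returns the merged study, or the raw parsed dicts when ``study`` is None.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "diagnosis"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id(s) in phenotype table: {sorted(set(dup))}")
    diagnoses: dict[str, str] = {}
    laterality: dict[str, str] = {}
    pedigree: dict[str, tuple[str | None, str | None]] = {}
    for idx, row in df.iterrows():
        s = row["sample"]
        d = str(row["diagnosis"]).strip().upper()
        if d not in DIAGNOSES:
            raise ValueError(
                f"row {idx}: unknown diagnosis {row['diagnosis']!r} for sample {s!r} "
                f"(allowed: {DIAGNOSES})"
            )
        diagnoses[s] = d
        lat = row.get("laterality")
        if isinstance(lat, str) and lat.strip():
            lat = lat.strip().lower()
            if lat not in LATERALITIES:
                raise ValueError(f"row {idx}: unknown laterality {lat!r}")
            laterality[s] = lat
        sire = row.get("sire")
        dam = row.get("dam")
        sire = sire if isinstance(sire, str) and sire.strip() else None
        dam = dam if isinstance(dam, str) and dam.strip() else None
        pedigree[s] = (sire, dam)
    parsed = {"diagnoses": diagnoses, "laterality": laterality, "pedigree": pedigree}
    if study is None:
        return parsed
    unlabelled = [s for s in study.samples if s not in diagnoses]
    if unlabelled:
        logger.warning(
            "%d genotyped sample(s) missing from phenotype table: %s",
            len(unlabelled), unlabelled[:10],
        )
    return replace(study, diagnoses=diagnoses, laterality=laterality, pedigree=pedigree)


def write_phenotypes(study: GenotypeStudy, path) -> None:
    rows = []
    for s in study.samples:
        sire, dam = study.pedigree.get(s, (None, None))
        rows.append(
            dict(
                sample=s,
                diagnosis=study.diagnoses.get(s, ""),
                laterality=study.laterality.get(s, ""),
                sire=sire or "",
                dam=dam or "",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# growth table
# ---------------------------------------------------------------------------

def read_growth(path) -> GrowthTable:
    """Read the marker-separation table (TSV: sample, day, side, separation).

    An optional boolean column ``fused_at_day10`` marks animals with no
    measurable suture at the first radiograph.
    """
    df = pd.read_csv(path, sep="\t")
    fused: frozenset[str] = frozenset()
    if "fused_at_day10" in df.columns:
        fcol = df["fused_at_day10"].astype(str).str.lower().isin(("1", "true", "yes"))
        fused = frozenset(df.loc[fcol, "sample"].astype(str))
        df = df[~df["sample"].astype(str).isin(fused)]
    return GrowthTable(data=df[list(GrowthTable.COLUMNS)], fused_at_day10=fused)


def write_growth(table: GrowthTable, path) -> None:
    df = table.data.copy()
    if table.fused_at_day10:
        fused_rows = pd.DataFrame(
            dict(
                sample=sorted(table.fused_at_day10),
                day=10, side="left", separation=0.0,
            )
        )
        fused_rows["fused_at_day10"] = True
        df["fused_at_day10"] = False
        df = pd.concat([df, fused_rows], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
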