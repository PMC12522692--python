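"""Domain records and readers/writers for clinic cohort data.

The package consumes four kinds of input:

* genotypes as VCF v4.x (imputed dosages in a ``DS`` FORMAT field, or hard
  ``GT`` calls),
* a variant annotation table (gene, consequence, population allele
  frequency, REVEL, LOFTEE class, splice delta, curated ACMG class) as TSV,
* weight tables (common PRS block, the two APOE markers, the age-dependent
  rare block) as TSV,
* a subject phenotype table as CSV.

All tabular outputs of the pipeline are plain TSV so that every report cell
round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("memgs.cohort_io")

#: Raw clinical diagnoses accepted on input.
DIAGNOSES = ("SCD", "MCI", "AD", "FTD", "LBD", "VD", "PPD", "OtherDem")

#: The four analysis groups. Amyloid-positive MCI is analysed with AD; all
#: non-AD dementias and primary psychiatric disorders form "Other".
GROUPS = ("SCD", "MCI", "AD", "Other")

SEXES = ("female", "male", "unknown")
TRISTATE = ("yes", "no", "unknown")
CSF_STATES = ("positive", "negative", "unknown")


class FormatError(ValueError):
    """An input file violates its declared format."""


class VcfParseError(FormatError):
    """The VCF could not be parsed."""


def variant_key(chrom, pos, ref: str, alt: str) -> str:
    """Canonical variant identifier ``chrom:pos:ref:alt`` (1-based position)."""
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclass
class SubjectRecord:
    """One clinic patient: demographics, diagnosis and structural flags.

    ``curated_pathogenic`` carries externally curated (gene, ACMG class)
    findings that did not come from the variant panel (e.g. clinical add-on
    tests); it is empty for most subjects.
    """

    subject_id: str
    age_years: float
    sex: str
    diagnosis_raw: str
    family_history: str = "unknown"
    csf_amyloid: str = "unknown"
    c9orf72_expansion: bool = False
    app_duplication: bool = False
    curated_pathogenic: list = field(default_factory=list)

    def validate(self) -> "SubjectRecord":
        if not (18.0 < float(self.age_years) < 110.0):
            raise FormatError(
                f"subject {self.subject_id}: age {self.age_years} outside (18, 110)"
            )
        if self.diagnosis_raw not in DIAGNOSES:
            raise FormatError(
                f"subject {self.subject_id}: unknown diagnosis {self.diagnosis_raw!r}"
            )
        if self.sex not in SEXES:
            raise FormatError(f"subject {self.subject_id}: unknown sex {self.sex!r}")
        if self.family_history not in TRISTATE:
            raise FormatError(
                f"subject {self.subject_id}: family_history {self.family_history!r}"
            )
        if self.csf_amyloid not in CSF_STATES:
            raise FormatError(
                f"subject {self.subject_id}: csf_amyloid {self.csf_amyloid!r}"
            )
        return self


def group_phenotype(subject: SubjectRecord) -> str:
    """Map a raw diagnosis to one of the four analysis groups.

    SCD stays SCD; MCI with a positive CSF amyloid status is analysed with
    AD; all other dementias and primary psychiatric disorders map to Other.
    Total function: every valid record maps to exactly one group.
    """
    d = subject.diagnosis_raw
    if d == "SCD":
        return "SCD"
    if d == "AD":
        return "AD"
    if d == "MCI":
        return "AD" if subject.csf_amyloid == "positive" else "MCI"
    return "Other"


def read_phenotypes(path) -> list[SubjectRecord]:
    """Read the subject phenotype CSV.

    Required columns: ``subject_id, age, sex, diagnosis``. Optional columns
    (``family_history, csf_amyloid, c9orf72_expansion, app_duplication``)
    are unknown/false-tolerant; a fully absent CSF column yields
    ``csf_amyloid='unknown'`` for every subject. Lines starting with ``#``
    are treated as comments.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    required = ["subject_id", "age", "sex", "diagnosis"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{path}: duplicate subject_id values {dupes}")
    for col, default in (
        ("family_history", "unknown"),
        ("csf_amyloid", "unknown"),
    ):
        if col not in df.columns:
            logger.info("phenotypes: column %r absent, defaulting to %r", col, default)
            df[col] = default
        else:
            df[col] = df[col].fillna("unknown")
    for col in ("c9orf72_expansion", "app_duplication"):
        if col not in df.columns:
            logger.info("phenotypes: column %r absent, defaulting to False", col)
            df[col] = "0"
        else:
            df[col] = df[col].fillna("0")

    records = []
    for i, row in df.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: unparseable age {row['age']!r} in row {i + 1} "
                f"(subject {row['subject_id']})"
            ) from None
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            age_years=age,
            sex=str(row["sex"]).strip().lower(),
            diagnosis_raw=str(row["diagnosis"]).strip(),
            family_history=str(row["family_history"]).strip().lower(),
            csf_amyloid=str(row["csf_amyloid"]).strip().lower(),
            c9orf72_expansion=_parse_bool(row["c9orf72_expansion"]),
            app_duplication=_parse_bool(row["app_duplication"]),
        )
        records.append(rec.validate())
    return records


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes", "t")


def subjects_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (indexed by subject_id, with ``group``)."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "diagnosis_raw": [r.diagnosis_raw for r in records],
            "family_history": [r.family_history for r in records],
            "csf_amyloid": [r.csf_amyloid for r in records],
            "c9orf72_expansion": [r.c9orf72_expansion for r in records],
            "app_duplication": [r.app_duplication for r in records],
            "group": [group_phenotype(r) for r in records],
        }
    ).set_index("subject_id")
    return df


@dataclass
class DosageMatrix:
    """Subjects x variants dosage grid in [0, 2].

    ``dosages`` rows are subject ids, columns are variant keys; NaN marks a
    missing genotype. ``provenance`` labels each variant column as
    ``imputed_dosage`` (taken from a dosage FORMAT field) or ``hard_call``
    (counted from GT, entries in {0, 1, 2}).
    """

    dosages: pd.DataFrame
    provenance: pd.Series

    def validate(self) -> "DosageMatrix":
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise FormatError("dosages outside [0, 2]")
        hard = self.provenance[self.provenance == "hard_call"].index
        hv = self.dosages[hard].to_numpy(dtype=float)
        hv = hv[np.isfinite(hv)]
        if hv.size and not np.all(np.isin(hv, (0.0, 1.0, 2.0))):
            raise FormatError("hard_call dosages must be in {0, 1, 2}")
        if not self.provenance.index.equals(self.dosages.columns):
            raise FormatError("provenance index does not match dosage columns")
        return self


def read_vcf(path, panel=None, dosage_field: str = "DS"):
    """Read genotypes from a VCF.

    Returns ``(variants, DosageMatrix)`` where ``variants`` is a DataFrame
    (index = variant key, columns chrom/pos/ref/alt). Dosages are taken
    from ``dosage_field`` when present on a record, otherwise counted from
    hard GT calls (missing GT -> NaN). Multi-allelic sites are decomposed
    into one record per alternate allele.

    ``panel`` may be a :class:`~memgs.triage.PanelDefinition` with gene
    regions; when it carries regions, variants outside every region
    (flanks included) are skipped.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    keys: list[str] = []
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    prov: list[str] = []
    n_parsed = 0
    try:
        for var in vcf:
            n_parsed += 1
            if panel is not None and not _in_panel_regions(panel, var.CHROM, var.POS):
                continue
            ds = None
            try:
                ds = var.format(dosage_field)
            except KeyError:
                ds = None
            gts = var.genotypes if var.gt_types is not None else None
            if ds is None and (gts is None or len(gts) == 0):
                raise FormatError(
                    f"{path}: record {var.CHROM}:{var.POS} has neither "
                    f"{dosage_field} nor GT"
                )
            for ai, alt in enumerate(var.ALT):
                key = variant_key(var.CHROM, var.POS, var.REF, alt)
                if ds is not None:
                    col = np.asarray(ds, dtype=float)
                    col = col[:, ai] if col.ndim == 2 else col
                    col = np.where((col < 0) | ~np.isfinite(col), np.nan, col)
                    prov.append("imputed_dosage")
                else:
                    col = np.empty(len(samples))
                    for si, g in enumerate(gts):
                        alleles = [a for a in g[:-1]]
                        if all(a < 0 for a in alleles):
                            col[si] = np.nan
                        else:
                            col[si] = float(sum(1 for a in alleles if a == ai + 1))
                    prov.append("hard_call")
                keys.append(key)
                rows.append(
                    {"chrom": str(var.CHROM), "pos": int(var.POS),
                     "ref": var.REF, "alt": alt}
                )
                cols.append(col)
    except FormatError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: parse failure after record {n_parsed}: {exc}"
        ) from exc
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate variant keys")
    variants = pd.DataFrame(rows, index=pd.Index(keys, name="variant"))
    dosages = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="subject_id"),
        columns=pd.Index(keys, name="variant"),
    )
    dm = DosageMatrix(dosages, pd.Series(prov, index=dosages.columns, name="provenance"))
    return variants, dm.validate()


def _in_panel_regions(panel, chrom, pos) -> bool:
    regions = getattr(panel, "regions", None)
    if not regions:
        return True
    flank = getattr(panel, "flank_bp", 0)
    for intervals in regions.values():
        for c, start, end in intervals:
            if str(c) == str(chrom) and start - flank <= pos <= end + flank:
                return True
    return False


ANNOTATION_COLUMNS = [
    "variant", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "pop_af", "revel", "loftee", "splice_delta", "curated_class",
]

CONSEQUENCES = ("missense", "lof", "splice_region", "other")
ACMG_CLASSES = ("I", "II", "III", "IV", "V", "unclassified")


def read_annotation(path) -> pd.DataFrame:
    """Read the variant annotation TSV (one row per variant key).

    Enforces the containment invariants: a REVEL score on a non-missense
    row and a LOFTEE class on a non-LoF row are nulled with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    df = df.set_index("variant")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate variant keys in annotation")
    df["pos"] = df["pos"].astype(int)
    df["pop_af"] = df["pop_af"].astype(float)
    df["revel"] = pd.to_numeric(df["revel"], errors="coerce")
    df["splice_delta"] = pd.to_numeric(df["splice_delta"], errors="coerce")
    df["loftee"] = df["loftee"].where(df["loftee"].isin(("HC", "LC")))
    df["curated_class"] = df["curated_class"].fillna("unclassified")
    bad = df["curated_class"].isin(ACMG_CLASSES)
    if not bad.all():
        raise FormatError(f"{path}: invalid ACMG classes {df.loc[~bad, 'curated_class'].unique()}")
    stray_revel = df["revel"].notna() & (df["consequence"] != "missense")
    if stray_revel.any():
        logger.warning("annotation: nulled %d REVEL scores on non-missense rows",
                       int(stray_revel.sum()))
        df.loc[stray_revel, "revel"] = np.nan
    stray_loftee = df["loftee"].notna() & (df["consequence"] != "lof")
    if stray_loftee.any():
        logger.warning("annotation: nulled %d LOFTEE classes on non-LoF rows",
                       int(stray_loftee.sum()))
        df.loc[stray_loftee, "loftee"] = None
    return df


def read_weight_table(path, kind: str) -> pd.DataFrame:
    """Read a weight TSV.

    ``kind``: ``common``/``apoe`` expect columns
    ``variant, chrom, pos, ref, alt, effect_allele, beta`` (optionally
    ``effect_af``); ``rare`` expects
    ``variant, chrom, pos, ref, alt, gene, beta_early, beta_late``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    base = ["variant", "chrom", "pos", "ref", "alt"]
    if kind in ("common", "apoe"):
        need = base + ["effect_allele", "beta"]
    elif kind == "rare":
        need = base + ["gene", "beta_early", "beta_late"]
    else:
        raise ValueError(f"unknown weight table kind {kind!r}")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: weight table missing columns {missing}")
    df = df.set_index("variant")
    df["pos"] = df["pos"].astype(int)
    for col in ("beta", "beta_early", "beta_late", "effect_af"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


def write_table(df: pd.DataFrame, path, seed=None, index=True) -> None:
    """Write a report TSV; the optional seed is echoed in a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, index_col=0) -> pd.DataFrame:
    """Round-trip reader for :func:`write_table` output."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
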