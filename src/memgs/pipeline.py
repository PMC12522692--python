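"""Pipeline orchestration: triage -> scores -> statistics -> report tables.

`run_pipeline` drives the full clinic analysis and emits TSV report
surfaces: per-group demographics with test p-values, triage and per-gene
summaries, the genetic-score quintile association table (with per-quintile
confusion metrics), the per-gene interaction scan, the AUC/DeLong model
comparison, and the clinical-vs-genetic concordance of monogenic carriers.
Monogenic carriers are excluded before any score analysis. Every run
writes a machine-readable JSON manifest; re-running with the same inputs
and config reproduces every report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (DosageMatrix, read_annotation, read_phenotypes, read_vcf,
                        read_weight_table, subjects_frame, write_table)
from .scores import GeneticScoreModel
from .stats import (LogisticWald, auc, confusion_metrics, delong_test,
                    interaction_scan, lrt_pvalue, pearson_chi_square)
from .triage import (PanelDefinition, carrier_matrix, flag_monogenic_subjects,
                     gene_summary, triage_variants)

logger = logging.getLogger("memgs.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


@dataclass
class RunConfig:
    """Validated paths and options for one pipeline run."""

    vcf: str
    phenotypes: str
    annotation: str
    weights_common: str
    weights_apoe: str
    weights_rare: str
    out_dir: str
    panel: str | None = None
    gene_disease: str | None = None
    seed: int = 0
    standardize_on: str = "cohort"
    reference_group: str = "SCD"
    five_gene_restriction: bool = False
    age_cutoff: float = 65.0

    def validate(self) -> "RunConfig":
        for f in ("vcf", "phenotypes", "annotation", "weights_common",
                  "weights_apoe", "weights_rare"):
            p = getattr(self, f)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{f} input does not exist: {p}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def default_gene_disease() -> pd.Series:
    """The editable packaged gene -> implied-disease map."""
    with resources.files("memgs.data").joinpath("gene_disease.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("gene")["disease"]


# ---------------------------------------------------------------------------
# report surfaces
# ---------------------------------------------------------------------------

def demographics_table(subjects: pd.DataFrame, monogenic: pd.Series,
                       rare_carrier: pd.Series, apoe4_carrier: pd.Series,
                       groups=("SCD", "MCI", "AD", "Other")) -> pd.DataFrame:
    """Per-group demographics with a test p-value column.

    Count rows use a Pearson chi-square across groups; the age row uses a
    one-way ANOVA F-test (ages are continuous).
    """
    from scipy.stats import f_oneway

    gidx = {g: subjects.index[subjects["group"] == g] for g in groups}
    rows = {}
    rows["n"] = {g: len(gidx[g]) for g in groups} | {"p_value": np.nan}
    ages = [subjects.loc[gidx[g], "age_years"] for g in groups if len(gidx[g]) > 1]
    age_p = f_oneway(*ages).pvalue if len(ages) > 1 else np.nan
    rows["age_mean"] = {g: round(float(subjects.loc[gidx[g], "age_years"].mean()), 1)
                        for g in groups} | {"p_value": age_p}
    rows["age_sd"] = {g: round(float(subjects.loc[gidx[g], "age_years"].std(ddof=1)), 1)
                      for g in groups} | {"p_value": np.nan}

    def count_row(label, flag: pd.Series):
        counts = {g: int(flag.reindex(gidx[g]).fillna(False).sum()) for g in groups}
        table = np.array([[counts[g], len(gidx[g]) - counts[g]] for g in groups])
        try:
            _, _, p = pearson_chi_square(table)
        except ValueError:
            p = np.nan
        rows[label] = counts | {"p_value": p}

    count_row("n_female", subjects["sex"] == "female")
    count_row("n_family_history", subjects["family_history"] == "yes")
    count_row("n_monogenic", monogenic.astype(bool))
    count_row("n_rare_carrier", rare_carrier.astype(bool))
    count_row("n_apoe4", apoe4_carrier.astype(bool))
    count_row("n_csf_amyloid_pos", subjects["csf_amyloid"] == "positive")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "statistic"
    out["Total"] = out[list(groups)].sum(axis=1).where(
        out.index.str.startswith("n"), np.nan)
    return out[list(groups) + ["Total", "p_value"]]


def _sex_numeric(subjects: pd.DataFrame) -> pd.Series:
    s = subjects["sex"].map({"male": 1.0, "female": 0.0})
    n_unk = int(s.isna().sum())
    if n_unk:
        logger.info("models: %d subjects with unknown sex excluded", n_unk)
    return s


def _analysis_design(components, subjects, trem2_carrier):
    """Shared covariates for the score models (drops unknown-sex rows)."""
    df = pd.DataFrame({
        "age": subjects["age_years"],
        "sex": _sex_numeric(subjects),
        "gs_std": components["gs_std"],
        "quintile_value": components["quintile_value"],
        "prs": components["prs_common"],
        "trem2": trem2_carrier.reindex(subjects.index).fillna(False).astype(float),
        "group": subjects["group"],
    }).dropna(subset=["sex"])
    df["prs"] = (df["prs"] - df["prs"].mean()) / df["prs"].std(ddof=1)
    df["prs_x_trem2"] = df["prs"] * df["trem2"]
    return df


def quintile_association_table(components, subjects, trem2_carrier) -> pd.DataFrame:
    """Genetic-score quintile association among SCD and AD subjects.

    One logistic model with quintile dummies (reference = middle quintile)
    adjusted for age, sex and the common-PRS x TREM2-carrier interaction,
    plus a separate lowest-vs-highest contrast. Per-quintile confusion
    metrics use the sign rule: a negative quintile value predicts SCD, a
    positive one AD; the reference stratum is excluded.
    """
    d = _analysis_design(components, subjects, trem2_carrier)
    d = d[d["group"].isin(("SCD", "AD"))]
    y = (d["group"] == "AD").to_numpy(dtype=float)
    qvals = (-1.0, -0.5, 0.5, 1.0)
    dummies = {f"q{v:g}": (d["quintile_value"] == v).to_numpy(dtype=float)
               for v in qvals}
    X = np.column_stack(
        [np.ones(len(d))] + list(dummies.values())
        + [d[c].to_numpy() for c in ("prs", "trem2", "prs_x_trem2", "age", "sex")]
    )
    names = ["intercept"] + list(dummies) + ["prs", "trem2", "prs_x_trem2", "age", "sex"]
    res = LogisticWald().fit(X, y, names=names).result()

    rows = []
    actual_ad = d["group"] == "AD"
    nonref = d["quintile_value"] != 0.0
    for v in qvals:
        t = res.term(f"q{v:g}")
        in_q = (d["quintile_value"] == v) & nonref
        positive_is_ad = v > 0
        actual = actual_ad if positive_is_ad else ~actual_ad
        cm = confusion_metrics(in_q[nonref], actual[nonref])
        rows.append({"score": v, "effect": t["beta"], "se_beta": t["se"],
                     "p": t["p"], "OR": t["OR"], "ci_low": t["ci_low"],
                     "ci_high": t["ci_high"], "SE_pct": cm.se, "SP_pct": cm.sp,
                     "PPV_pct": cm.ppv, "NPV_pct": cm.npv})

    ext = d[d["quintile_value"].isin((-1.0, 1.0))]
    if ext["quintile_value"].nunique() == 2 and ext["group"].nunique() == 2:
        y_e = (ext["group"] == "AD").to_numpy(dtype=float)
        X_e = np.column_stack([
            np.ones(len(ext)), (ext["quintile_value"] == 1.0).to_numpy(dtype=float),
            ext["prs"], ext["trem2"], ext["prs_x_trem2"], ext["age"], ext["sex"],
        ])
        res_e = LogisticWald().fit(
            X_e, y_e,
            names=["intercept", "q5", "prs", "trem2", "prs_x_trem2", "age", "sex"],
        ).result()
        t = res_e.term("q5")
        cm = confusion_metrics(ext["quintile_value"] == 1.0, ext["group"] == "AD")
        rows.append({"score": "q1_vs_q5", "effect": t["beta"], "se_beta": t["se"],
                     "p": t["p"], "OR": t["OR"], "ci_low": t["ci_low"],
                     "ci_high": t["ci_high"], "SE_pct": cm.se, "SP_pct": cm.sp,
                     "PPV_pct": cm.ppv, "NPV_pct": cm.npv})
    return pd.DataFrame(rows).set_index("score")


def auc_comparison_table(components, subjects, trem2_carrier) -> pd.DataFrame:
    """AUC and paired DeLong comparison for the three discrimination models.

    Contrasts: SCD vs AD, and AD vs other dementia. Models: demographics
    (age + sex), genetics (GS plus the common-PRS x TREM2 interaction
    block), and both combined; DeLong compares each against demographics.
    """
    d_all = _analysis_design(components, subjects, trem2_carrier)
    contrasts = (("SCD_vs_AD", ("SCD", "AD")), ("AD_vs_nonAD", ("AD", "Other")))
    model_cols = {
        "age_sex": ["age", "sex"],
        "gs_prs_trem2": ["gs_std", "prs", "trem2", "prs_x_trem2"],
        "gs_prs_trem2_age_sex": ["gs_std", "prs", "trem2", "prs_x_trem2", "age", "sex"],
    }
    rows = []
    for contrast, keep in contrasts:
        d = d_all[d_all["group"].isin(keep)]
        y = (d["group"] == "AD").to_numpy(dtype=float)
        probs = {}
        lls = {}
        for mname, cols in model_cols.items():
            X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy() for c in cols])
            est = LogisticWald().fit(X, y, names=["intercept"] + cols)
            probs[mname] = est.predict_proba(X)
            null = LogisticWald().fit(np.ones((len(d), 1)), y, names=["intercept"])
            lls[mname] = (est.loglik_, null.loglik_, len(cols))
        for mname in model_cols:
            r = auc(probs[mname], y.astype(bool))
            ll, ll0, df = lls[mname]
            if mname == "age_sex":
                dl_p = np.nan
            else:
                dl_p = delong_test(probs[mname], probs["age_sex"], y.astype(bool)).p
            cm = confusion_metrics(probs[mname] >= 0.5, y.astype(bool))
            rows.append({"contrast": contrast, "model": mname, "auc": round(r.auc, 3),
                         "model_p": lrt_pvalue(ll, ll0, df), "delong_p": dl_p,
                         "SE_pct": cm.se, "SP_pct": cm.sp, "PPV_pct": cm.ppv,
                         "NPV_pct": cm.npv, "n": len(d)})
    return pd.DataFrame(rows).set_index(["contrast", "model"])


def diagnose_genetic_vs_clinical(carriers: pd.DataFrame,
                                 gene_disease: pd.Series | None = None):
    """Concordance of clinical diagnoses with gene-implied diagnoses.

    ``carriers`` needs ``diagnosis_raw`` and ``gene`` columns (one row per
    monogenic carrier). SCD carriers are excluded from the denominator
    (they may simply not have converted yet); carriers of genes without a
    disease mapping are excluded and counted. Returns ``(summary,
    per_carrier)``; the mismatch percentage is reported to 1 decimal and
    missing when no carrier is eligible.
    """
    if gene_disease is None:
        gene_disease = default_gene_disease()
    per = carriers.copy()
    per["implied"] = per["gene"].map(gene_disease)
    per["status"] = np.where(
        per["diagnosis_raw"] == "SCD", "scd_excluded",
        np.where(per["implied"].isna(), "unmappable",
                 np.where(per["implied"] == per["diagnosis_raw"], "match", "mismatch")),
    )
    n_unmappable = int((per["status"] == "unmappable").sum())
    if n_unmappable:
        logger.warning("concordance: %d carriers with unmappable genes excluded",
                       n_unmappable)
    eligible = per["status"].isin(("match", "mismatch"))
    n_eligible = int(eligible.sum())
    n_mismatch = int((per["status"] == "mismatch").sum())
    if n_eligible == 0:
        logger.warning("concordance: no eligible carriers; mismatch percentage undefined")
        pct = None
    else:
        pct = round(100.0 * n_mismatch / n_eligible, 1)
    summary = {
        "n_carriers": int(len(per)),
        "n_scd_excluded": int((per["status"] == "scd_excluded").sum()),
        "n_unmappable": n_unmappable,
        "n_eligible": n_eligible,
        "n_mismatch": n_mismatch,
        "mismatch_pct": pct,
    }
    return summary, per


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; writes report TSVs and returns them."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    with _stage("validate"):
        cfg.validate()
        panel = PanelDefinition.from_yaml(cfg.panel) if cfg.panel else PanelDefinition()
        gene_disease = (
            pd.read_csv(cfg.gene_disease, sep="\t").set_index("gene")["disease"]
            if cfg.gene_disease else default_gene_disease()
        )

    with _stage("read"):
        records = read_phenotypes(cfg.phenotypes)
        if not records:
            raise ValueError("empty cohort: phenotype table has no subjects")
        subjects = subjects_frame(records)
        variants, dosages = read_vcf(cfg.vcf)
        dosages = DosageMatrix(dosages.dosages.reindex(subjects.index),
                               dosages.provenance)
        annotation = read_annotation(cfg.annotation)
        w_common = read_weight_table(cfg.weights_common, "common")
        w_apoe = read_weight_table(cfg.weights_apoe, "apoe")
        w_rare = read_weight_table(cfg.weights_rare, "rare")

    with _stage("triage"):
        calls = triage_variants(annotation, panel)
        carriers = carrier_matrix(calls, annotation, dosages)
        genes_tab = gene_summary(calls, annotation, dosages)
        mono = flag_monogenic_subjects(subjects, calls, annotation, dosages, panel)
        results["triage_calls"] = calls
        results["gene_summary"] = genes_tab
        results["carriers"] = pd.concat(
            [carriers.flags.astype(int), carriers.counts], axis=1)
        results["monogenic_subjects"] = mono

    with _stage("demographics"):
        apoe4_key = w_apoe.index[0]
        apoe4 = (dosages.dosages.get(apoe4_key, pd.Series(np.nan, index=subjects.index))
                 >= 1)
        results["demographics"] = demographics_table(
            subjects, mono["monogenic"], carriers.flags.any(axis=1), apoe4)

    with _stage("concordance"):
        flagged = mono[mono["monogenic"]]
        carrier_rows = pd.DataFrame({
            "diagnosis_raw": subjects.loc[flagged.index, "diagnosis_raw"],
            "gene": flagged["genes"].str.split(";").str[0],
        })
        summary, per = diagnose_genetic_vs_clinical(carrier_rows, gene_disease)
        results["concordance"] = per
        results["concordance_summary"] = pd.DataFrame([summary])

    with _stage("scores"):
        analysis_ids = subjects.index[~mono["monogenic"]]
        n_excluded = int(mono["monogenic"].sum())
        logger.info("scores: excluded %d monogenic carriers before the GS", n_excluded)
        sub = subjects.loc[analysis_ids]
        model = GeneticScoreModel(
            w_common, w_apoe, w_rare, age_cutoff=cfg.age_cutoff,
            standardize_on=cfg.standardize_on, reference_group=cfg.reference_group,
            five_gene_restriction=cfg.five_gene_restriction,
        )
        comp = model.fit_transform((variants, dosages), sub)
        comp["apoe_diplotype"] = model.apoe_diplotypes_
        results["scores"] = comp

    with _stage("stats"):
        trem2 = carriers.flags.get("TREM2", pd.Series(False, index=subjects.index))
        results["quintile_association"] = quintile_association_table(comp, sub, trem2)
        d = _analysis_design(comp, sub, trem2)
        d_sa = d[d["group"].isin(("SCD", "AD"))]
        flags = carriers.flags.reindex(d_sa.index).fillna(False)
        flags = flags.assign(any_gene=flags.any(axis=1))
        results["interaction_scan"] = interaction_scan(
            (d_sa["group"] == "AD").to_numpy(dtype=float),
            d_sa["prs"].to_numpy(), flags,
            covariates=d_sa[["age", "sex"]].to_numpy(),
            covariate_names=["age", "sex"],
        )
        results["auc_comparison"] = auc_comparison_table(comp, sub, trem2)

    with _stage("write"):
        for name, df in results.items():
            write_table(df, out / f"{name}.tsv", seed=cfg.seed)
        manifest = {
            "package": "memgs",
            "version": __version__,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "inputs_sha256": {
                f: hashlib.sha256(Path(getattr(cfg, f)).read_bytes()).hexdigest()
                for f in ("vcf", "phenotypes", "annotation", "weights_common",
                          "weights_apoe", "weights_rare")
            },
            "n_subjects": int(len(subjects)),
            "n_monogenic_excluded": n_excluded,
            "gs_standardization": {"mean": model.mean_, "sd": model.sd_,
                                   "population": cfg.standardize_on},
            "quintile_boundaries": list(model.boundaries_.cuts),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
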