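"""Variant triage: monogenic candidates, rare AD risk variants, carriers.

Variants extracted from the monogenic-dementia panel and the eleven AD
risk/candidate genes are classified by an ordered filter cascade:

1. population allele frequency >= the rarity ceiling (default 1%) -> excluded;
2. gene outside the panel -> excluded;
3. curated ACMG class IV/V in a monogenic gene -> monogenic candidate;
4. SORL1 high-confidence LoF -> monogenic candidate (treated as causal);
5. in a risk/candidate gene: HC LoF, or missense with REVEL at or above the
   gene threshold, or splice delta at or above threshold -> rare risk;
6. otherwise excluded, with a machine-readable reason trail.

The default REVEL threshold (0.25 for every risk/candidate gene) and the
default monogenic gene set are package defaults, overridable per gene /
per panel; they are deliberately permissive placeholders, not study values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort_io import DosageMatrix

logger = logging.getLogger("memgs.triage")

RISK_GENES = ("ABCA1", "ABCA7", "ATP8B4", "TREM2", "SORL1")
CANDIDATE_GENES = ("ADAM10", "SRC", "RIN3", "CLU", "ZCWPW1", "ACE")

# Representative monogenic dementia panel (package default, overridable).
DEFAULT_MONOGENIC_GENES = (
    "APP", "PSEN1", "PSEN2", "SORL1",
    "MAPT", "GRN", "C9orf72", "TARDBP", "CTSF", "VCP", "CHMP2B", "TBK1",
    "FUS", "SQSTM1", "CHCHD10",
    "NOTCH3", "HTRA1", "HTT", "PRNP", "NPC1", "CSF1R", "ITM2B", "SNCA",
)

# Autosomal-recessive inheritance within the default panel.
DEFAULT_RECESSIVE_GENES = ("NPC1",)

MONOGENIC_CANDIDATE = "monogenic_candidate"
RARE_RISK = "rare_risk"
EXCLUDED = "excluded"


@dataclass
class PanelDefinition:
    """Gene panel and filter thresholds for the triage cascade."""

    monogenic_genes: frozenset = frozenset(DEFAULT_MONOGENIC_GENES)
    risk_genes: frozenset = frozenset(RISK_GENES)
    candidate_genes: frozenset = frozenset(CANDIDATE_GENES)
    recessive_genes: frozenset = frozenset(DEFAULT_RECESSIVE_GENES)
    flank_bp: int = 6
    maf_threshold: float = 0.01
    revel_default: float = 0.25
    revel_thresholds: dict = field(default_factory=dict)  # per-gene override
    splice_delta_threshold: float = 0.5
    regions: dict = field(default_factory=dict)  # gene -> [(chrom, start, end)]

    def __post_init__(self):
        self.monogenic_genes = frozenset(self.monogenic_genes)
        self.risk_genes = frozenset(self.risk_genes)
        self.candidate_genes = frozenset(self.candidate_genes)
        self.recessive_genes = frozenset(self.recessive_genes)
        if self.risk_genes & self.candidate_genes:
            raise ValueError("risk and candidate gene sets must be disjoint")
        if not (0 < self.maf_threshold <= 0.05):
            raise ValueError("maf_threshold must be in (0, 0.05]")

    def revel_threshold(self, gene: str) -> float:
        return float(self.revel_thresholds.get(gene, self.revel_default))

    @property
    def rare_panel_genes(self) -> frozenset:
        return self.risk_genes | self.candidate_genes

    def to_yaml(self, path) -> None:
        d = {
            "monogenic_genes": sorted(self.monogenic_genes),
            "risk_genes": sorted(self.risk_genes),
            "candidate_genes": sorted(self.candidate_genes),
            "recessive_genes": sorted(self.recessive_genes),
            "flank_bp": self.flank_bp,
            "maf_threshold": self.maf_threshold,
            "revel_default": self.revel_default,
            "revel_thresholds": dict(self.revel_thresholds),
            "splice_delta_threshold": self.splice_delta_threshold,
            "regions": {g: [list(iv) for iv in ivs] for g, ivs in self.regions.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PanelDefinition":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["regions"] = {
            g: [tuple(iv) for iv in ivs] for g, ivs in (d.get("regions") or {}).items()
        }
        return cls(**d)


@dataclass
class TriageCall:
    variant: str
    category: str
    reasons: list

    def __post_init__(self):
        if self.category == EXCLUDED and not self.reasons:
            raise ValueError("excluded calls require a non-empty reason trail")


def triage_variant(v, panel: PanelDefinition) -> TriageCall:
    """Apply the filter cascade to one annotated variant.

    ``v`` is any object/row with fields ``gene, consequence, pop_af, revel,
    loftee, splice_delta, curated_class`` and a variant key under
    ``name``/``variant``. Rules fire in order; the trail records every rule
    id that determined the call.
    """
    key = getattr(v, "name", None) or getattr(v, "variant", None) or v["variant"]
    gene = v["gene"] if not hasattr(v, "gene") else v.gene
    get = (lambda f: getattr(v, f)) if hasattr(v, "gene") else (lambda f: v[f])

    pop_af = float(get("pop_af"))
    if pop_af >= panel.maf_threshold:
        return TriageCall(key, EXCLUDED, ["af_above_threshold"])
    in_monogenic = gene in panel.monogenic_genes
    in_rare_panel = gene in panel.rare_panel_genes
    if not (in_monogenic or in_rare_panel):
        return TriageCall(key, EXCLUDED, ["gene_not_in_panel"])
    curated = get("curated_class")
    if in_monogenic and curated in ("IV", "V"):
        return TriageCall(key, MONOGENIC_CANDIDATE, ["curated_pathogenic"])
    consequence = get("consequence")
    loftee = get("loftee")
    if gene == "SORL1" and consequence == "lof" and loftee == "HC":
        return TriageCall(key, MONOGENIC_CANDIDATE, ["sorl1_lof_hc"])
    if in_rare_panel:
        if consequence == "lof" and loftee == "HC":
            return TriageCall(key, RARE_RISK, ["lof_hc"])
        if consequence == "missense":
            revel = get("revel")
            if revel is None or (isinstance(revel, float) and np.isnan(revel)):
                return TriageCall(key, EXCLUDED, ["missing_revel"])
            if float(revel) >= panel.revel_threshold(gene):
                return TriageCall(key, RARE_RISK, ["revel_ge_threshold"])
            return TriageCall(key, EXCLUDED, ["revel_below_threshold"])
        sd = get("splice_delta")
        if sd is not None and np.isfinite(float(sd)) and float(sd) >= panel.splice_delta_threshold:
            return TriageCall(key, RARE_RISK, ["splice_delta_ge_threshold"])
        return TriageCall(key, EXCLUDED, ["no_deleteriousness_evidence"])
    return TriageCall(key, EXCLUDED, ["monogenic_gene_not_curated"])


def triage_variants(annotation: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    """Triage every annotated variant; returns a calls table.

    Index = variant key; columns ``category`` and ``reason`` (rule ids
    joined by ``;``). Every variant receives exactly one category.
    """
    calls = [triage_variant(row, panel) for _, row in annotation.iterrows()]
    return pd.DataFrame(
        {
            "category": [c.category for c in calls],
            "reason": [";".join(c.reasons) for c in calls],
        },
        index=annotation.index,
    )


class VariantTriager(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over the triage cascade.

    ``transform`` maps an annotation DataFrame to a calls DataFrame; the
    panel is the only parameter, so triage composes with pipelines.
    """

    def __init__(self, panel: PanelDefinition | None = None):
        self.panel = panel

    def fit(self, X=None, y=None):
        self.panel_ = self.panel or PanelDefinition()
        return self

    def transform(self, annotation: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "panel_"):
            self.fit()
        return triage_variants(annotation, self.panel_)


@dataclass
class CarrierMatrix:
    """Subjects x genes carrier grid for rare-risk variants.

    ``flags``: boolean DataFrame (carries >= 1 rare-risk variant in gene);
    ``counts``: per-subject number of distinct rare-risk variants carried.
    """

    flags: pd.DataFrame
    counts: pd.Series


def carrier_matrix(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    dosages: DosageMatrix,
    hard_call_threshold: float = 1.0,
    imputed_threshold: float = 0.5,
) -> CarrierMatrix:
    """Build the rare-risk carrier matrix.

    A subject carries a variant when its dosage reaches 1 for hard calls or
    0.5 for imputed dosages (rare variants normally arrive as sequencing
    hard calls; the imputed threshold is a config value).
    """
    rare_keys = calls.index[calls["category"] == RARE_RISK]
    rare_keys = [k for k in rare_keys if k in dosages.dosages.columns]
    subj = dosages.dosages.index
    genes = sorted(annotation.loc[rare_keys, "gene"].unique()) if rare_keys else []
    flags = pd.DataFrame(False, index=subj, columns=pd.Index(genes, name="gene"))
    counts = pd.Series(0, index=subj, name="n_rare_variants")
    if rare_keys:
        d = dosages.dosages[rare_keys]
        thr = np.where(
            dosages.provenance[rare_keys].to_numpy() == "hard_call",
            hard_call_threshold,
            imputed_threshold,
        )
        carried = (d.to_numpy() >= thr[None, :]) & np.isfinite(d.to_numpy())
        carried = pd.DataFrame(carried, index=subj, columns=rare_keys)
        counts = carried.sum(axis=1).astype(int).rename("n_rare_variants")
        gene_of = annotation.loc[rare_keys, "gene"]
        for g in genes:
            flags[g] = carried.loc[:, gene_of[gene_of == g].index].any(axis=1)
    # carrying nothing <=> zero count
    assert ((counts == 0) == (~flags.any(axis=1))).all()
    return CarrierMatrix(flags=flags, counts=counts)


def flag_monogenic_subjects(
    subjects,
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    dosages: DosageMatrix,
    panel: PanelDefinition,
) -> pd.DataFrame:
    """Flag subjects with a (likely) causal finding.

    A subject is flagged when they (a) carry a monogenic-candidate variant
    in a dominant gene, (b) carry two alleles of monogenic-candidate
    variants in a recessive gene (a single curated allele is logged, not
    flagged), (c) have a C9orf72 repeat expansion, or (d) an APP
    duplication. Returns per-subject ``monogenic`` flag and the implicated
    genes (``;``-joined).
    """
    frame = subjects if isinstance(subjects, pd.DataFrame) else None
    if frame is None:
        from .cohort_io import subjects_frame

        frame = subjects_frame(subjects)
    mono_keys = [
        k
        for k in calls.index[calls["category"] == MONOGENIC_CANDIDATE]
        if k in dosages.dosages.columns
    ]
    flagged = pd.Series(False, index=frame.index)
    genes = pd.Series("", index=frame.index, dtype=object)

    if mono_keys:
        d = dosages.dosages[mono_keys].fillna(0.0)
        gene_of = annotation.loc[mono_keys, "gene"]
        for g in sorted(gene_of.unique()):
            gkeys = gene_of[gene_of == g].index
            alleles = d[gkeys].sum(axis=1)
            if g in panel.recessive_genes:
                hit = alleles >= 2
                single = (alleles >= 1) & ~hit
                if single.any():
                    logger.info(
                        "monogenic: %d subject(s) with a single %s allele in "
                        "recessive gene %s not flagged",
                        int(single.sum()), g, g,
                    )
            else:
                hit = alleles >= 1
            flagged |= hit.reindex(frame.index, fill_value=False)
            genes[hit.reindex(frame.index, fill_value=False)] = genes[
                hit.reindex(frame.index, fill_value=False)
            ].apply(lambda s: f"{s};{g}" if s else g)

    c9 = frame["c9orf72_expansion"].astype(bool)
    app = frame["app_duplication"].astype(bool)
    for mask, g in ((c9, "C9orf72"), (app, "APP")):
        flagged |= mask
        genes[mask] = genes[mask].apply(lambda s: f"{s};{g}" if s else g)
    return pd.DataFrame({"monogenic": flagged, "genes": genes})


def gene_summary(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    dosages: DosageMatrix | None = None,
    hard_call_threshold: float = 1.0,
    imputed_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-gene rare-risk variant and carrier counts with a totals row.

    Carrier counts are per-variant carrier sums (an individual carrying two
    variants counts twice), matching how clinic panels report them. LoF and
    splice calls are grouped together against missense.
    """
    rare_keys = list(calls.index[calls["category"] == RARE_RISK])
    if not rare_keys:
        return pd.DataFrame(
            columns=["n_variants", "n_missense", "n_lof",
                     "n_lof_carriers", "n_missense_carriers"]
        )
    ann = annotation.loc[rare_keys]
    is_missense = ann["consequence"] == "missense"
    carriers_per_variant = pd.Series(0, index=pd.Index(rare_keys))
    if dosages is not None:
        avail = [k for k in rare_keys if k in dosages.dosages.columns]
        d = dosages.dosages[avail]
        thr = np.where(
            dosages.provenance[avail].to_numpy() == "hard_call",
            hard_call_threshold,
            imputed_threshold,
        )
        carried = (d.to_numpy() >= thr[None, :]) & np.isfinite(d.to_numpy())
        carriers_per_variant.loc[avail] = carried.sum(axis=0)
    per_gene = pd.DataFrame(
        {
            "n_variants": ann.groupby("gene").size(),
            "n_missense": is_missense.groupby(ann["gene"]).sum().astype(int),
            "n_lof": (~is_missense).groupby(ann["gene"]).sum().astype(int),
            "n_lof_carriers": carriers_per_variant.groupby(ann["gene"]).apply(
                lambda s: int(s[~is_missense.loc[s.index]].sum())
            ),
            "n_missense_carriers": carriers_per_variant.groupby(ann["gene"]).apply(
                lambda s: int(s[is_missense.loc[s.index]].sum())
            ),
        }
    ).sort_index()
    return summarize_gene_table(per_gene)


def summarize_gene_table(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Append a Total row and missense/LoF percentage columns (2 decimals).

    Accepts either a freshly computed per-gene table or an externally
    supplied count table with the same columns.
    """
    per_gene = per_gene.copy()
    totals = per_gene.sum(axis=0)
    out = pd.concat([per_gene, totals.to_frame("Total").T])
    n = float(totals["n_variants"]) if totals["n_variants"] else np.nan
    out["pct_missense"] = np.round(100.0 * out["n_missense"] / n, 2)
    out["pct_lof"] = np.round(100.0 * out["n_lof"] / n, 2)
    out.index.name = "gene"
    return out
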