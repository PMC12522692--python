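"""Composite genetic score: common PRS, APOE block, age-aware rare block.

The score follows the standard weighted-dosage construction: each block is
``sum_i beta_i * effective_dosage_i``, with the effective dosage counted on
the effect allele (``2 - d`` when the effect allele is the reference
allele). The three blocks are

* the common-variant AD PRS (genome-wide significant SNPs, APOE excluded),
* the APOE block, a two-marker (rs429358, rs7412) weighted dosage,
* the rare-variant block, with per-variant early/late effect sizes
  selected by the subject's age at entry (early <= 65 < late).

The combined genetic score (GS) is the standardized sum of the blocks and
is stratified into quintiles referenced on the SCD (cognitively normal)
group, mapped to the values {-1, -0.5, 0, 0.5, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort_io import DosageMatrix
from .triage import RISK_GENES

logger = logging.getLogger("memgs.scores")

QUINTILE_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def weighted_dosage_sum(
    dosages,
    betas,
    flip=None,
    missing: str = "af_impute",
    effect_af=None,
):
    """Weighted sum of effect-allele dosages over one block.

    ``flip[i]`` means the effect allele is the VCF reference allele, so the
    effective dosage is ``2 - dosages[i]``. Missing dosages (NaN) are
    handled per ``missing``: ``"exclude"`` drops the pair, ``"af_impute"``
    substitutes twice the effect-allele frequency (requires ``effect_af``).
    """
    d = np.asarray(dosages, dtype=float)
    b = np.asarray(betas, dtype=float)
    if d.shape != b.shape:
        raise ValueError(f"length mismatch: {d.shape} dosages vs {b.shape} betas")
    if flip is None:
        flip = np.zeros(d.shape, dtype=bool)
    flip = np.asarray(flip, dtype=bool)
    eff = np.where(flip, 2.0 - d, d)
    miss = ~np.isfinite(eff)
    if miss.any():
        if missing == "exclude":
            logger.info("score: excluded %d missing dosages", int(miss.sum()))
            eff = np.where(miss, 0.0, eff)
        elif missing == "af_impute":
            if effect_af is None:
                raise ValueError("af_impute requires effect_af")
            af = np.asarray(effect_af, dtype=float)
            eff = np.where(miss, 2.0 * af, eff)
            logger.info("score: AF-imputed %d missing dosages", int(miss.sum()))
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    return float(np.sum(b * eff))


@dataclass
class ApoeDiplotype:
    """APOE diplotype derived from rs429358/rs7412 genotypes."""

    diplotype: str
    e4_count: int


def apoe_diplotype(g429358, g7412) -> ApoeDiplotype:
    """Resolve the APOE diplotype from two unphased genotypes.

    Haplotype table: (rs429358, rs7412) = (T,T) -> e2; (T,C) -> e3;
    (C,C) -> e4. Inputs are genotype strings like ``"T/C"`` or allele
    counts (count of C at rs429358, count of T at rs7412). The doubly
    heterozygous case resolves to e2/e4 by convention. Missing input
    raises ValueError (the subject is excluded upstream with a log).
    """
    c4 = _allele_count(g429358, "C", "rs429358")
    t2 = _allele_count(g7412, "T", "rs7412")
    n_e4, n_e2 = c4, t2
    n_e3 = 2 - n_e4 - n_e2
    if n_e3 < 0:
        raise ValueError(
            f"inconsistent APOE genotypes (rs429358 C-count {c4}, rs7412 "
            f"T-count {t2}): implies a non-canonical haplotype"
        )
    labels = ["ε2"] * n_e2 + ["ε3"] * n_e3 + ["ε4"] * n_e4
    return ApoeDiplotype("/".join(labels), e4_count=n_e4)


def _allele_count(g, allele: str, marker: str) -> int:
    if g is None or (isinstance(g, float) and np.isnan(g)):
        raise ValueError(f"missing genotype at {marker}")
    if isinstance(g, str):
        alleles = g.replace("|", "/").split("/")
        if len(alleles) != 2 or any(a in ("", ".") for a in alleles):
            raise ValueError(f"missing/invalid genotype {g!r} at {marker}")
        return sum(1 for a in alleles if a.upper() == allele)
    n = float(g)
    if not np.isfinite(n) or n not in (0.0, 1.0, 2.0):
        raise ValueError(f"invalid allele count {g!r} at {marker}")
    return int(n)


def rare_block_score(
    dosages,
    age_years: float,
    beta_early,
    beta_late,
    age_cutoff: float = 65.0,
) -> float:
    """Age-aware weighted carrier sum over the rare-variant block.

    Uses the early-onset effect sizes when ``age_years <= age_cutoff`` and
    the late-onset ones otherwise. Age is mandatory for the GS.
    """
    if age_years is None or not np.isfinite(float(age_years)):
        raise ValueError("age is required for the rare-variant block")
    betas = np.asarray(beta_early if float(age_years) <= age_cutoff else beta_late,
                       dtype=float)
    return weighted_dosage_sum(dosages, betas, missing="exclude")


def align_weights(
    weights: pd.DataFrame,
    variants: pd.DataFrame,
    observed_af: pd.Series | None = None,
    ambiguity_tol: float = 0.1,
) -> pd.DataFrame:
    """Align a weight table to the VCF alternate alleles.

    Rows are matched on the variant key. ``flip`` marks rows whose effect
    allele is the reference allele. Rows whose effect allele matches
    neither allele are dropped with a log, as are strand-ambiguous (A/T,
    C/G) rows unless their ``effect_af`` matches the observed frequency of
    the effect allele within ``ambiguity_tol``.
    """
    out = weights.copy()
    present = out.index.intersection(variants.index)
    dropped = out.index.difference(variants.index)
    if len(dropped):
        logger.info("weights: %d rows not present in genotypes, dropped", len(dropped))
    out = out.loc[present]
    ref = variants.loc[present, "ref"]
    alt = variants.loc[present, "alt"]
    eff = out["effect_allele"] if "effect_allele" in out.columns else alt
    flip = eff == ref
    match = flip | (eff == alt)
    if not match.all():
        bad = out.index[~match].tolist()
        logger.warning("weights: effect allele matches neither REF nor ALT for %s; dropped", bad)
        out, ref, alt, eff, flip = (x[match] for x in (out, ref, alt, eff, flip))
    ambiguous = [
        k for k in out.index if (ref[k].upper(), alt[k].upper()) in AMBIGUOUS_PAIRS
    ]
    if ambiguous:
        keep = []
        for k in ambiguous:
            ok = False
            if observed_af is not None and "effect_af" in out.columns:
                af_alt = float(observed_af.get(k, np.nan))
                af_eff = af_alt if not flip[k] else 1.0 - af_alt
                ok = np.isfinite(af_eff) and abs(float(out.loc[k, "effect_af"]) - af_eff) <= ambiguity_tol
            if not ok:
                keep.append(k)
        if keep:
            logger.warning(
                "weights: rejected %d strand-ambiguous rows without a frequency match: %s",
                len(keep), keep,
            )
            out = out.drop(index=keep)
            flip = flip.drop(index=keep)
    out["flip"] = flip.astype(bool)
    n_flip = int(out["flip"].sum())
    if n_flip:
        logger.info("weights: %d rows aligned by flipping to the other allele", n_flip)
    return out


@dataclass
class QuintileBoundaries:
    """20/40/60/80th percentile cut points of the reference group."""

    cuts: np.ndarray
    reference_group: str

    def __post_init__(self):
        self.cuts = np.asarray(self.cuts, dtype=float)
        if not np.all(np.diff(self.cuts) >= 0):
            raise ValueError("quintile boundaries must be non-decreasing")


def quintile_stratify(
    gs_std: pd.Series,
    reference_mask,
    reference_group: str = "SCD",
):
    """Assign SCD-referenced quintile values to every subject.

    Boundaries are the reference group's 20/40/60/80th percentiles (linear
    interpolation between order statistics). Bins are half-open ``[lo,
    hi)`` with the lowest bin unbounded below and the top bin closed at its
    lower edge; bins 1..5 map to {-1, -0.5, 0, 0.5, 1}.
    """
    ref = gs_std[np.asarray(reference_mask, dtype=bool)]
    if len(ref) < 5:
        raise ValueError(
            f"reference group has {len(ref)} subjects; need at least 5 for quintiles"
        )
    cuts = np.percentile(ref.to_numpy(dtype=float), [20, 40, 60, 80])
    bins = np.searchsorted(cuts, gs_std.to_numpy(dtype=float), side="right")
    values = pd.Series(
        np.asarray(QUINTILE_VALUES)[bins], index=gs_std.index, name="quintile_value"
    )
    return values, QuintileBoundaries(cuts, reference_group)


class GeneticScoreModel(BaseEstimator, TransformerMixin):
    """Three-block genetic score with standardization and quintiles.

    Parameters
    ----------
    common_weights, apoe_weights, rare_weights : DataFrame
        Weight tables as produced by :func:`memgs.cohort_io.read_weight_table`.
    age_cutoff : float
        Boundary between early- and late-onset rare-variant effects.
    standardize_on : {"cohort", "scd"}
        Population whose mean/sd standardize the raw GS. "cohort" is every
        subject passed to ``fit`` (monogenic carriers are excluded by the
        pipeline beforehand).
    combine : {"standardize_sum", "sum_standardized"}
        Whether the GS is the standardized sum of raw blocks (default) or
        the (re-standardized) sum of per-block z-scores.
    five_gene_restriction : bool
        Restrict the rare block to the five established risk genes.
    missing_policy : {"af_impute", "exclude"}
        Handling of missing dosages in the common/APOE blocks.

    Fitted attributes: ``components_`` (per-subject score table), ``mean_``,
    ``sd_``, ``boundaries_``, ``apoe_diplotypes_``.
    """

    def __init__(
        self,
        common_weights=None,
        apoe_weights=None,
        rare_weights=None,
        age_cutoff: float = 65.0,
        standardize_on: str = "cohort",
        reference_group: str = "SCD",
        combine: str = "standardize_sum",
        five_gene_restriction: bool = False,
        risk_genes=RISK_GENES,
        missing_policy: str = "af_impute",
    ):
        self.common_weights = common_weights
        self.apoe_weights = apoe_weights
        self.rare_weights = rare_weights
        self.age_cutoff = age_cutoff
        self.standardize_on = standardize_on
        self.reference_group = reference_group
        self.combine = combine
        self.five_gene_restriction = five_gene_restriction
        self.risk_genes = risk_genes
        self.missing_policy = missing_policy

    # -- block computations -------------------------------------------------

    def _aligned(self, weights, variants, dosages):
        af_obs = dosages.dosages.mean(axis=0, skipna=True) / 2.0
        return align_weights(weights, variants, observed_af=af_obs)

    def _linear_block(self, w, dosages: DosageMatrix) -> pd.Series:
        """Vectorized weighted dosage sum for an aligned weight table."""
        keys = [k for k in w.index if k in dosages.dosages.columns]
        if len(keys) < len(w):
            logger.info("score: %d weight rows missing from dosages", len(w) - len(keys))
        w = w.loc[keys]
        if not len(keys):
            return pd.Series(0.0, index=dosages.dosages.index)
        d = dosages.dosages[keys].to_numpy(dtype=float)
        flip = w["flip"].to_numpy(dtype=bool)
        eff = np.where(flip[None, :], 2.0 - d, d)
        miss = ~np.isfinite(eff)
        if miss.any():
            if self.missing_policy == "af_impute":
                if "effect_af" in w.columns and w["effect_af"].notna().all():
                    af = w["effect_af"].to_numpy(dtype=float)
                else:
                    af_alt = np.nanmean(d, axis=0) / 2.0
                    af = np.where(flip, 1.0 - af_alt, af_alt)
                eff = np.where(miss, (2.0 * af)[None, :], eff)
                logger.info("score: AF-imputed %d missing dosages", int(miss.sum()))
            elif self.missing_policy == "exclude":
                eff = np.where(miss, 0.0, eff)
                logger.info("score: excluded %d missing dosages pairwise", int(miss.sum()))
            else:
                raise ValueError(f"unknown missing policy {self.missing_policy!r}")
        betas = w["beta"].to_numpy(dtype=float)
        return pd.Series(eff @ betas, index=dosages.dosages.index)

    def _rare_block(self, w, dosages: DosageMatrix, ages: pd.Series) -> pd.Series:
        if self.five_gene_restriction:
            w = w[w["gene"].isin(set(self.risk_genes))]
        keys = [k for k in w.index if k in dosages.dosages.columns]
        w = w.loc[keys]
        if ages.isna().any():
            raise ValueError("age is required for every subject entering the GS")
        if not len(keys):
            return pd.Series(0.0, index=dosages.dosages.index)
        d = np.nan_to_num(dosages.dosages[keys].to_numpy(dtype=float), nan=0.0)
        early = w["beta_early"].to_numpy(dtype=float)
        late = w["beta_late"].to_numpy(dtype=float)
        use_early = (ages.to_numpy(dtype=float) <= self.age_cutoff)[:, None]
        betas = np.where(use_early, early[None, :], late[None, :])
        return pd.Series((d * betas).sum(axis=1), index=dosages.dosages.index)

    def _components(self, variants, dosages: DosageMatrix, subjects: pd.DataFrame):
        cw = self._aligned(self.common_weights, variants, dosages)
        aw = self._aligned(self.apoe_weights, variants, dosages)
        comp = pd.DataFrame(index=dosages.dosages.index)
        comp["prs_common"] = self._linear_block(cw, dosages)
        comp["apoe_component"] = self._linear_block(aw, dosages)
        ages = subjects["age_years"].reindex(comp.index)
        comp["prs_rare"] = self._rare_block(self.rare_weights, dosages, ages)
        comp["gs_raw"] = comp["prs_common"] + comp["apoe_component"] + comp["prs_rare"]
        return comp

    def _diplotypes(self, dosages: DosageMatrix) -> pd.Series:
        """Per-subject APOE diplotype from the two marker dosages."""
        ids = {str(v).lower(): k for k, v in
               self.apoe_weights.get("rsid", pd.Series(dtype=object)).items()}
        key_429358 = ids.get("rs429358")
        key_7412 = ids.get("rs7412")
        if key_429358 is None or key_7412 is None:
            # fall back to table order: first row rs429358, second rs7412
            key_429358, key_7412 = list(self.apoe_weights.index[:2])
        out = {}
        cols = dosages.dosages.columns
        for sid in dosages.dosages.index:
            try:
                c4 = dosages.dosages.at[sid, key_429358] if key_429358 in cols else np.nan
                t2 = dosages.dosages.at[sid, key_7412] if key_7412 in cols else np.nan
                dip = apoe_diplotype(round(float(c4)), round(float(t2)))
                out[sid] = dip.diplotype
            except (ValueError, TypeError):
                out[sid] = None
        n_missing = sum(v is None for v in out.values())
        if n_missing:
            logger.info("APOE: %d subjects without a resolvable diplotype", n_missing)
        return pd.Series(out, name="apoe_diplotype")

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, subjects: pd.DataFrame):
        """Fit standardization and quintile boundaries.

        ``X`` is a ``(variants, DosageMatrix)`` pair; ``subjects`` a frame
        with ``age_years`` and ``group`` (already restricted to the
        analysis population, i.e. monogenic carriers removed).
        """
        variants, dosages = X
        subjects = subjects.loc[subjects.index.intersection(dosages.dosages.index)]
        dosages = DosageMatrix(
            dosages.dosages.loc[subjects.index], dosages.provenance
        )
        comp = self._components(variants, dosages, subjects)
        if self.combine == "sum_standardized":
            blocks = comp[["prs_common", "apoe_component", "prs_rare"]]
            z = (blocks - blocks.mean()) / blocks.std(ddof=1).replace(0.0, np.nan)
            comp["gs_raw"] = z.fillna(0.0).sum(axis=1)
            logger.info("GS combined as sum of standardized blocks")
        else:
            logger.info("GS combined as standardized sum of raw blocks")
        if self.standardize_on == "scd":
            pop = comp.loc[subjects["group"] == self.reference_group, "gs_raw"]
        else:
            pop = comp["gs_raw"]
        mean, sd = float(pop.mean()), float(pop.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("standardization population has zero variance")
        logger.info("GS standardization: mean=%.6g sd=%.6g (population=%s, n=%d)",
                    mean, sd, self.standardize_on, len(pop))
        comp["gs_std"] = (comp["gs_raw"] - mean) / sd
        ref_mask = (subjects["group"] == self.reference_group).reindex(comp.index, fill_value=False)
        comp["quintile_value"], boundaries = quintile_stratify(
            comp["gs_std"], ref_mask, self.reference_group
        )
        self.mean_, self.sd_ = mean, sd
        self.boundaries_ = boundaries
        self.components_ = comp
        self.apoe_diplotypes_ = self._diplotypes(dosages)
        return self

    def transform(self, X, subjects: pd.DataFrame) -> pd.DataFrame:
        """Score new subjects with the fitted standardization/boundaries."""
        variants, dosages = X
        comp = self._components(variants, dosages, subjects)
        comp["gs_std"] = (comp["gs_raw"] - self.mean_) / self.sd_
        bins = np.searchsorted(self.boundaries_.cuts,
                               comp["gs_std"].to_numpy(dtype=float), side="right")
        comp["quintile_value"] = np.asarray(QUINTILE_VALUES)[bins]
        return comp

    def fit_transform(self, X, subjects: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X, subjects).components_


def build_gs(variants, dosages, subjects, common_weights, apoe_weights,
             rare_weights, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`GeneticScoreModel`."""
    model = GeneticScoreModel(common_weights, apoe_weights, rare_weights, **kwargs)
    return model.fit_transform((variants, dosages), subjects)
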