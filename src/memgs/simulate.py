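"""Seeded synthetic memory-clinic cohorts.

The generator emulates the statistical structure the analysis assumes: a
four-group clinic series (SCD / MCI / AD / Other) with fixed group sizes,
group-specific age distributions, sex, APOE-e4 and rare-variant carrier
frequencies, a Hardy-Weinberg common-variant block, and an AD-vs-SCD
assignment tilted by a logistic liability on the genetic score.

Group composition is fixed by quota (a clinic series, not free-running
case/control sampling); the liability enters through which pool members
receive the AD label. Two liability modes exist:

* ``liability_on="common_prs"`` (default): the tilt acts on the
  standardized common-variant PRS, and APOE genotypes / rare carriers are
  drawn per final group so the configured per-group carrier targets are
  hit. The APOE and rare channels of AD association come from those
  targets.
* ``liability_on="gs"``: all three blocks are drawn for the SCD+AD pool
  from pooled targets first and the tilt acts on the standardized full
  genetic score — the mode for parameter-recovery studies, where the tilt
  slope is the well-defined truth.

Defaults reproduce the clinic-series composition used throughout the test
suite (n = 996-998, AD-group APOE-e4 fraction 64.6%, etc.). Rare variants
are emitted as sequencing hard calls; the common block is emitted as a
dosage (DS) field to exercise the imputed-dosage path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort_io import DosageMatrix, SubjectRecord, subjects_frame, variant_key
from .triage import PanelDefinition, RISK_GENES, CANDIDATE_GENES

GROUPS = ("SCD", "MCI", "AD", "Other")
RARE_GENES = tuple(sorted(RISK_GENES + CANDIDATE_GENES))

# Synthetic gene anchor coordinates (GRCh38-like, for plausible VCF output).
GENE_COORDS = {
    "ABCA1": ("9", 104781002), "ABCA7": ("19", 1040101), "ACE": ("17", 61554422),
    "ADAM10": ("15", 58588807), "ATP8B4": ("15", 50147784), "CLU": ("8", 27596917),
    "RIN3": ("14", 92980071), "SORL1": ("11", 121452314), "SRC": ("20", 35973088),
    "TREM2": ("6", 41126244), "ZCWPW1": ("7", 100400826),
    "APP": ("21", 25880550), "PSEN1": ("14", 73136418), "PSEN2": ("1", 226870616),
    "MAPT": ("17", 45894382), "GRN": ("17", 44345246), "C9orf72": ("9", 27546546),
    "NPC1": ("18", 23506184),
}

# Relative per-gene share of rare-risk carriers (clinic-like spectrum).
DEFAULT_GENE_WEIGHTS = {
    "ABCA1": 31, "ABCA7": 156, "ACE": 30, "ADAM10": 9, "ATP8B4": 48,
    "CLU": 21, "RIN3": 37, "SORL1": 13, "SRC": 2, "TREM2": 39, "ZCWPW1": 5,
}

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))


def _groupdict(scd, mci, ad, other):
    return {"SCD": scd, "MCI": mci, "AD": ad, "Other": other}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic clinic cohort."""

    seed: int
    n_group: dict = field(default_factory=lambda: _groupdict(219, 87, 362, 328))
    age_mean: dict = field(default_factory=lambda: _groupdict(57.8, 64.3, 65.6, 60.6))
    age_sd: dict = field(default_factory=lambda: _groupdict(9.3, 7.5, 7.2, 9.0))
    female_frac: dict = field(default_factory=lambda: _groupdict(0.416, 0.241, 0.481, 0.351))
    family_history_frac: dict = field(default_factory=lambda: _groupdict(0.384, 0.299, 0.448, 0.274))
    apoe4_target: dict = field(default_factory=lambda: _groupdict(0.370, 0.425, 0.646, 0.406))
    rare_target: dict = field(default_factory=lambda: _groupdict(0.306, 0.322, 0.359, 0.273))
    monogenic_rate: dict = field(default_factory=lambda: _groupdict(0.014, 0.046, 0.022, 0.052))
    apoe44_given_carrier: float = 0.25
    apoe24_given_het_carrier: float = 0.06
    apoe2_het_given_noncarrier: float = 0.13
    apoe22_given_noncarrier: float = 0.01
    n_common: int = 82
    common_af_range: tuple = (0.05, 0.5)
    common_beta_mean: float = 0.07
    common_beta_sd: float = 0.03
    weight_flip_frac: float = 0.1
    n_rare_per_gene: int = 3
    gene_weights: dict = field(default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS))
    beta_gs: float = 0.6
    beta_interaction: float = 0.0
    interaction_gene: str = "TREM2"
    liability_on: str = "common_prs"
    mci_amyloid_pos_frac_of_ad: float = 0.08
    age_bounds: tuple = (40.0, 95.0)
    age_cutoff: float = 65.0

    def validate(self) -> "SimConfig":
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("female_frac", "family_history_frac", "apoe4_target",
                     "rare_target", "monogenic_rate"):
            for g, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{g}]={v} is not a fraction in [0, 1]")
        if any(n < 0 for n in self.n_group.values()):
            raise ValueError("group sizes must be non-negative")
        if self.liability_on not in ("common_prs", "gs"):
            raise ValueError(f"unknown liability mode {self.liability_on!r}")
        lo, hi = self.common_af_range
        if not (0 < lo <= hi < 1):
            raise ValueError("common_af_range must lie inside (0, 1)")
        return self

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["common_af_range"] = list(self.common_af_range)
        d["age_bounds"] = list(self.age_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["common_af_range"] = tuple(d["common_af_range"])
        d["age_bounds"] = tuple(d["age_bounds"])
        return cls(**d).validate()


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort plus the generating truth."""

    config: SimConfig
    subjects: list
    variants: pd.DataFrame          # chrom/pos/ref/alt per key
    annotation: pd.DataFrame
    dosages: DosageMatrix
    weights_common: pd.DataFrame
    weights_apoe: pd.DataFrame
    weights_rare: pd.DataFrame
    truth: pd.DataFrame
    panel: PanelDefinition

    def subjects_frame(self) -> pd.DataFrame:
        return subjects_frame(self.subjects)

    def write(self, outdir) -> dict:
        """Write the standard input files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        paths = {
            "vcf": outdir / "cohort.vcf",
            "phenotypes": outdir / "phenotypes.csv",
            "annotation": outdir / "annotation.tsv",
            "weights_common": outdir / "weights_common.tsv",
            "weights_apoe": outdir / "weights_apoe.tsv",
            "weights_rare": outdir / "weights_rare.tsv",
            "truth": outdir / "truth.tsv",
            "config": outdir / "simconfig.yaml",
            "panel": outdir / "panel.yaml",
        }
        self._write_vcf(paths["vcf"])
        self._write_phenotypes(paths["phenotypes"])
        for name, df in (
            ("annotation", self.annotation), ("weights_common", self.weights_common),
            ("weights_apoe", self.weights_apoe), ("weights_rare", self.weights_rare),
            ("truth", self.truth),
        ):
            with open(paths[name], "w") as fh:
                fh.write(f"# seed={seed}\n")
                df.to_csv(fh, sep="\t", float_format="%.10g")
        self.config.to_yaml(paths["config"])
        self.panel.to_yaml(paths["panel"])
        return paths

    def _write_phenotypes(self, path) -> None:
        frame = self.subjects_frame().drop(columns=["group"]).rename(
            columns={"age_years": "age", "diagnosis_raw": "diagnosis"}
        )
        frame["c9orf72_expansion"] = frame["c9orf72_expansion"].astype(int)
        frame["app_duplication"] = frame["app_duplication"].astype(int)
        with open(path, "w") as fh:
            fh.write(f"# seed={self.config.seed}\n")
            frame.to_csv(fh, float_format="%.6g")

    def _write_vcf(self, path) -> None:
        d = self.dosages.dosages
        prov = self.dosages.provenance
        samples = list(d.index)
        order = self.variants.assign(_c=self.variants["chrom"].astype(int)).sort_values(
            ["_c", "pos", "ref", "alt"]
        ).index
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write(f"##memgs_seed={self.config.seed}\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        buf.write('##FORMAT=<ID=DS,Number=A,Type=Float,Description="Imputed dosage">\n')
        for c in sorted({v for v in self.variants["chrom"]}, key=int):
            buf.write(f"##contig=<ID={c}>\n")
        buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples) + "\n")
        for key in order:
            row = self.variants.loc[key]
            col = d[key].to_numpy(dtype=float)
            if prov[key] == "imputed_dosage":
                fmt = "GT:DS"
                cells = []
                for v in col:
                    if not np.isfinite(v):
                        cells.append("./.:.")
                    else:
                        g = int(round(v))
                        gt = ("0/0", "0/1", "1/1")[min(g, 2)]
                        cells.append(f"{gt}:{v:g}")
            else:
                fmt = "GT"
                cells = []
                for v in col:
                    if not np.isfinite(v):
                        cells.append("./.")
                    else:
                        cells.append(("0/0", "0/1", "1/1")[min(int(round(v)), 2)])
            rsid = self.annotation.loc[key, "rsid"] if "rsid" in self.annotation.columns \
                and key in self.annotation.index else "."
            rsid = rsid if isinstance(rsid, str) and rsid else "."
            buf.write(f"{row['chrom']}\t{row['pos']}\t{rsid}\t{row['ref']}\t"
                      f"{row['alt']}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")
        Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# internal draws
# ---------------------------------------------------------------------------

def _truncnorm_ages(n, mean, sd, bounds, rng):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return np.round(truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng), 1)


def _draw_apoe(n, target, cfg: SimConfig, rng):
    """Return (C-count at rs429358, T-count at rs7412) hitting the carrier target."""
    carrier = rng.random(n) < target
    hom = carrier & (rng.random(n) < cfg.apoe44_given_carrier)
    het = carrier & ~hom
    e2_partner = het & (rng.random(n) < cfg.apoe24_given_het_carrier)
    c4 = np.where(hom, 2, np.where(het, 1, 0))
    u = rng.random(n)
    t2_nc = np.where(
        u < cfg.apoe22_given_noncarrier, 2,
        np.where(u < cfg.apoe22_given_noncarrier + cfg.apoe2_het_given_noncarrier, 1, 0),
    )
    t2 = np.where(carrier, e2_partner.astype(int), t2_nc)
    return c4.astype(float), t2.astype(float)


def _draw_rare(n, target, gene_variant_idx, gene_share, rng, n_rare_cols):
    """Per-gene Bernoulli carriers; P(>=1 gene) == target by construction."""
    dos = np.zeros((n, n_rare_cols))
    for gene, idxs in gene_variant_idx.items():
        w = gene_share[gene]
        p = 1.0 - (1.0 - target) ** w
        carriers = rng.random(n) < p
        pick = rng.integers(0, len(idxs), size=n)
        rows = np.flatnonzero(carriers)
        dos[rows, np.asarray(idxs)[pick[rows]]] = 1.0
    return dos


def _quota_labels(lin, n_cases, rng):
    """Bernoulli logistic labels with the intercept solved for the quota,
    then trimmed/padded by uniformly random flips to hit it exactly."""
    n = len(lin)
    if n_cases <= 0:
        return np.zeros(n, dtype=bool)
    if n_cases >= n:
        return np.ones(n, dtype=bool)

    def excess(a):
        return expit(a + lin).sum() - n_cases

    a = brentq(excess, -40, 40)
    labels = rng.random(n) < expit(a + lin)
    diff = int(labels.sum()) - n_cases
    if diff > 0:
        flip = rng.choice(np.flatnonzero(labels), size=diff, replace=False)
        labels[flip] = False
    elif diff < 0:
        flip = rng.choice(np.flatnonzero(~labels), size=-diff, replace=False)
        labels[flip] = True
    return labels


def _standardize(x):
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# variant scaffolding
# ---------------------------------------------------------------------------

def _common_block(cfg: SimConfig, rng):
    lo, hi = cfg.common_af_range
    af = rng.uniform(lo, hi, size=cfg.n_common)
    beta_alt = np.clip(rng.normal(cfg.common_beta_mean, cfg.common_beta_sd,
                                  size=cfg.n_common), 0.01, None)
    rows = []
    for i in range(cfg.n_common):
        chrom = str((i % 22) + 1)
        pos = 1_000_000 + 13_117 * (i + 1)
        ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "gene": f"LOC{i + 1:03d}", "af": af[i], "beta_alt": beta_alt[i]})
    df = pd.DataFrame(rows)
    df.index = pd.Index(
        [variant_key(r["chrom"], r["pos"], r["ref"], r["alt"]) for _, r in df.iterrows()],
        name="variant",
    )
    flip = rng.random(cfg.n_common) < cfg.weight_flip_frac
    df["weight_flip"] = flip
    return df


def _rare_block(cfg: SimConfig, rng):
    """Rare-risk panel variants, a few decoys, and monogenic panel variants."""
    rows = []
    named = {
        "TREM2": [("6", 41129252, "C", "T", "missense", 0.77)],
        "ABCA7": [("19", 1059056, "G", "A", "missense", 0.62)],
        "RIN3": [("14", 93142861, "T", "C", "missense", 0.48)],
        "ACE": [("17", 61601584, "A", "G", "missense", 0.55)],
    }
    lof_genes = {"ABCA1", "ABCA7", "ACE", "ADAM10", "RIN3", "ZCWPW1"}
    for gene in RARE_GENES:
        chrom, start = GENE_COORDS[gene]
        fixed = named.get(gene, [])
        for j in range(cfg.n_rare_per_gene):
            if j < len(fixed):
                c, pos, ref, alt, cons, revel = fixed[j]
            else:
                c = chrom
                pos = start + 97 * (j + 1)
                ref, alt = _ALLELE_PAIRS[(start + j) % len(_ALLELE_PAIRS)]
                if j == cfg.n_rare_per_gene - 1 and gene in lof_genes:
                    cons, revel = "lof", np.nan
                else:
                    cons, revel = "missense", round(float(rng.uniform(0.3, 0.9)), 3)
            rows.append({
                "chrom": c, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
                "consequence": cons,
                "pop_af": round(float(rng.uniform(1e-4, 5e-3)), 6),
                "revel": revel if cons == "missense" else np.nan,
                "loftee": "HC" if cons == "lof" else None,
                "splice_delta": np.nan,
                "curated_class": "unclassified",
                "role": "rare_panel",
            })
    # decoys: excluded by the cascade for different reasons
    decoys = [
        ("CLU", 0, "missense", 0.05, np.nan, "revel below threshold"),
        ("ABCA1", 1, "missense", 0.65, np.nan, "common decoy"),
        ("TREM2", 2, "splice_region", np.nan, 0.12, "weak splice"),
        ("SORL1", 3, "splice_region", np.nan, 0.81, "strong splice"),
    ]
    for gene, j, cons, revel, sd, _why in decoys:
        chrom, start = GENE_COORDS[gene]
        ref, alt = _ALLELE_PAIRS[(j + 1) % len(_ALLELE_PAIRS)]
        rows.append({
            "chrom": chrom, "pos": start + 5_003 + 31 * j, "ref": ref, "alt": alt,
            "gene": gene, "consequence": cons,
            "pop_af": 0.02 if _why == "common decoy" else round(float(rng.uniform(1e-4, 5e-3)), 6),
            "revel": revel if cons == "missense" else np.nan,
            "loftee": None, "splice_delta": sd,
            "curated_class": "unclassified", "role": "decoy",
        })
    # monogenic panel variants with curated ACMG classes
    mono = [
        ("APP", "missense", "V"), ("PSEN1", "missense", "V"),
        ("GRN", "lof", "V"), ("MAPT", "missense", "IV"),
        ("PSEN2", "missense", "III"), ("SORL1", "lof", "unclassified"),
    ]
    for k, (gene, cons, klass) in enumerate(mono):
        chrom, start = GENE_COORDS[gene]
        ref, alt = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
        rows.append({
            "chrom": chrom, "pos": start + 11_213 + 53 * k, "ref": ref, "alt": alt,
            "gene": gene, "consequence": cons,
            "pop_af": round(float(rng.uniform(1e-6, 1e-4)), 8),
            "revel": 0.95 if cons == "missense" else np.nan,
            "loftee": "HC" if cons == "lof" else None,
            "splice_delta": np.nan, "curated_class": klass, "role": "monogenic_panel",
        })
    df = pd.DataFrame(rows)
    df.index = pd.Index(
        [variant_key(r["chrom"], r["pos"], r["ref"], r["alt"]) for _, r in df.iterrows()],
        name="variant",
    )
    if df.index.duplicated().any():
        raise RuntimeError("synthetic rare panel produced duplicate variant keys")
    return df


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``cfg`` (seeded, deterministic)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_scd, n_mci = cfg.n_group["SCD"], cfg.n_group["MCI"]
    n_ad, n_other = cfg.n_group["AD"], cfg.n_group["Other"]
    n_pool = n_scd + n_ad
    n_total = n_pool + n_mci + n_other
    ids = [f"S{i + 1:04d}" for i in range(n_total)]

    common = _common_block(cfg, rng)
    rare = _rare_block(cfg, rng)
    panel_rows = rare[rare["role"] == "rare_panel"]
    gene_variant_idx = {
        g: [rare.index.get_loc(k) for k in panel_rows.index[panel_rows["gene"] == g]]
        for g in RARE_GENES
    }
    total_w = sum(cfg.gene_weights.get(g, 0) for g in RARE_GENES)
    gene_share = {g: cfg.gene_weights.get(g, 0) / total_w for g in RARE_GENES}
    beta_early = np.round(rng.uniform(0.4, 1.2, size=len(rare)), 4)
    beta_late = np.round(0.6 * beta_early, 4)

    # APOE marker weights (effect alleles: C at rs429358, T at rs7412).
    b_429358, b_7412 = 1.12, -0.40

    # common genotypes for everyone (Hardy-Weinberg hard calls, emitted as DS)
    G = rng.binomial(2, common["af"].to_numpy(), size=(n_total, cfg.n_common)).astype(float)
    flip = common["weight_flip"].to_numpy()
    table_beta = np.where(flip, -common["beta_alt"].to_numpy(), common["beta_alt"].to_numpy())
    eff = np.where(flip[None, :], 2.0 - G, G)
    prs_common = eff @ table_beta

    groups = np.empty(n_total, dtype=object)
    groups[n_pool:n_pool + n_mci] = "MCI"
    groups[n_pool + n_mci:] = "Other"

    ages = np.empty(n_total)
    apoe_c4 = np.empty(n_total)
    apoe_t2 = np.empty(n_total)
    rare_dos = np.zeros((n_total, len(rare)))
    pool = slice(0, n_pool)
    z_common = np.empty(n_total)
    z_common[pool] = _standardize(prs_common[pool])

    w_scd = n_scd / n_pool
    if cfg.liability_on == "gs":
        pooled_age_mean = w_scd * cfg.age_mean["SCD"] + (1 - w_scd) * cfg.age_mean["AD"]
        pooled_age_sd = w_scd * cfg.age_sd["SCD"] + (1 - w_scd) * cfg.age_sd["AD"]
        pooled_apoe = w_scd * cfg.apoe4_target["SCD"] + (1 - w_scd) * cfg.apoe4_target["AD"]
        pooled_rare = w_scd * cfg.rare_target["SCD"] + (1 - w_scd) * cfg.rare_target["AD"]
        ages[pool] = _truncnorm_ages(n_pool, pooled_age_mean, pooled_age_sd,
                                     cfg.age_bounds, rng)
        apoe_c4[pool], apoe_t2[pool] = _draw_apoe(n_pool, pooled_apoe, cfg, rng)
        rare_dos[pool] = _draw_rare(n_pool, pooled_rare, gene_variant_idx,
                                    gene_share, rng, len(rare))
        early_mask = (ages[pool] <= cfg.age_cutoff)[:, None]
        betas = np.where(early_mask, beta_early[None, :], beta_late[None, :])
        rare_comp = (rare_dos[pool] * betas).sum(axis=1)
        apoe_comp = b_429358 * apoe_c4[pool] + b_7412 * apoe_t2[pool]
        gs_raw = prs_common[pool] + apoe_comp + rare_comp
        lin = cfg.beta_gs * _standardize(gs_raw)
        if cfg.beta_interaction:
            ig_idx = gene_variant_idx[cfg.interaction_gene]
            carrier = rare_dos[pool][:, ig_idx].sum(axis=1) > 0
            lin = lin + cfg.beta_interaction * z_common[pool] * carrier
        liability = lin
    else:
        liability = cfg.beta_gs * z_common[pool]

    is_ad = _quota_labels(liability, n_ad, rng)
    groups[pool] = np.where(is_ad, "AD", "SCD")

    for g in GROUPS:
        mask = groups == g
        if cfg.liability_on == "gs" and g in ("SCD", "AD"):
            continue  # pool demographics already drawn from pooled targets
        n_g = int(mask.sum())
        ages[mask] = _truncnorm_ages(n_g, cfg.age_mean[g], cfg.age_sd[g],
                                     cfg.age_bounds, rng)
        apoe_c4[mask], apoe_t2[mask] = _draw_apoe(n_g, cfg.apoe4_target[g], cfg, rng)
        rare_dos[mask] = _draw_rare(n_g, cfg.rare_target[g], gene_variant_idx,
                                    gene_share, rng, len(rare))

    # low-frequency decoy and monogenic-panel carriers
    for role, p in (("decoy", 0.01),):
        for k in rare.index[rare["role"] == role]:
            j = rare.index.get_loc(k)
            hits = rng.random(n_total) < p
            rare_dos[hits, j] = 1.0

    sex = np.empty(n_total, dtype=object)
    famhist = np.empty(n_total, dtype=object)
    for g in GROUPS:
        mask = groups == g
        n_g = int(mask.sum())
        sex[mask] = np.where(rng.random(n_g) < cfg.female_frac[g], "female", "male")
        famhist[mask] = np.where(rng.random(n_g) < cfg.family_history_frac[g], "yes", "no")

    # monogenic mechanisms
    mono_variants = rare.index[(rare["role"] == "monogenic_panel")
                               & rare["curated_class"].isin(("IV", "V"))].tolist()
    sorl1_lof = rare.index[(rare["role"] == "monogenic_panel")
                           & (rare["gene"] == "SORL1")].tolist()
    mech = np.full(n_total, "", dtype=object)
    c9flag = np.zeros(n_total, dtype=bool)
    appflag = np.zeros(n_total, dtype=bool)
    for g in GROUPS:
        mask = np.flatnonzero(groups == g)
        carriers = mask[rng.random(len(mask)) < cfg.monogenic_rate[g]]
        kinds = rng.choice(["curated", "sorl1_lof", "c9orf72", "app_dup"],
                           size=len(carriers), p=[0.55, 0.10, 0.20, 0.15])
        for i, kind in zip(carriers, kinds):
            mech[i] = kind
            if kind == "curated":
                key = mono_variants[int(rng.integers(0, len(mono_variants)))]
                rare_dos[i, rare.index.get_loc(key)] = 1.0
            elif kind == "sorl1_lof":
                rare_dos[i, rare.index.get_loc(sorl1_lof[0])] = 1.0
            elif kind == "c9orf72":
                c9flag[i] = True
            else:
                appflag[i] = True

    # raw diagnoses and CSF status
    diagnosis = np.empty(n_total, dtype=object)
    csf = np.full(n_total, "unknown", dtype=object)
    other_labels = ("FTD", "LBD", "VD", "PPD", "OtherDem")
    other_p = (0.35, 0.20, 0.15, 0.20, 0.10)
    csf_measured = {"SCD": 0.76, "MCI": 0.69, "AD": 0.85, "Other": 0.77}
    csf_positive = {"SCD": 0.128, "MCI": 0.0, "AD": 0.793, "Other": 0.206}
    for g in GROUPS:
        mask = np.flatnonzero(groups == g)
        n_g = len(mask)
        if g == "Other":
            diagnosis[mask] = rng.choice(other_labels, size=n_g, p=other_p)
        elif g == "AD":
            as_mci = rng.random(n_g) < cfg.mci_amyloid_pos_frac_of_ad
            diagnosis[mask] = np.where(as_mci, "MCI", "AD")
            measured = (rng.random(n_g) < csf_measured[g]) | as_mci
            pos = as_mci | (measured & (rng.random(n_g) < csf_positive[g]))
            csf[mask] = np.where(measured, np.where(pos, "positive", "negative"), "unknown")
        else:
            diagnosis[mask] = g
            measured = rng.random(n_g) < csf_measured[g]
            pos = measured & (rng.random(n_g) < csf_positive[g])
            csf[mask] = np.where(measured, np.where(pos, "positive", "negative"), "unknown")

    subjects = [
        SubjectRecord(
            subject_id=ids[i], age_years=float(ages[i]), sex=str(sex[i]),
            diagnosis_raw=str(diagnosis[i]), family_history=str(famhist[i]),
            csf_amyloid=str(csf[i]), c9orf72_expansion=bool(c9flag[i]),
            app_duplication=bool(appflag[i]),
        ).validate()
        for i in range(n_total)
    ]

    # assemble dosage matrix and variant/annotation tables
    apoe_keys = ["19:44908684:T:C", "19:44908822:C:T"]
    apoe_var = pd.DataFrame(
        {"chrom": ["19", "19"], "pos": [44908684, 44908822],
         "ref": ["T", "C"], "alt": ["C", "T"]},
        index=pd.Index(apoe_keys, name="variant"),
    )
    variants = pd.concat([
        common[["chrom", "pos", "ref", "alt"]], apoe_var,
        rare[["chrom", "pos", "ref", "alt"]],
    ])
    dos = pd.DataFrame(
        np.column_stack([G, apoe_c4, apoe_t2, rare_dos]),
        index=pd.Index(ids, name="subject_id"), columns=variants.index,
    )
    provenance = pd.Series(
        ["imputed_dosage"] * cfg.n_common + ["hard_call"] * (2 + len(rare)),
        index=variants.index, name="provenance",
    )
    dosages = DosageMatrix(dos, provenance).validate()

    annotation = pd.concat([
        pd.DataFrame({
            "chrom": common["chrom"], "pos": common["pos"], "ref": common["ref"],
            "alt": common["alt"], "gene": common["gene"], "consequence": "other",
            "pop_af": common["af"], "revel": np.nan, "loftee": None,
            "splice_delta": np.nan, "curated_class": "unclassified", "rsid": "",
        }),
        pd.DataFrame({
            "chrom": apoe_var["chrom"], "pos": apoe_var["pos"], "ref": apoe_var["ref"],
            "alt": apoe_var["alt"], "gene": "APOE", "consequence": "missense",
            "pop_af": [0.15, 0.08], "revel": np.nan, "loftee": None,
            "splice_delta": np.nan, "curated_class": "unclassified",
            "rsid": ["rs429358", "rs7412"],
        }),
        rare.drop(columns=["role"]).assign(rsid=""),
    ])
    annotation.index.name = "variant"

    weights_common = pd.DataFrame({
        "chrom": common["chrom"], "pos": common["pos"], "ref": common["ref"],
        "alt": common["alt"],
        "effect_allele": np.where(common["weight_flip"], common["ref"], common["alt"]),
        "beta": table_beta,
        "effect_af": np.where(common["weight_flip"], 1 - common["af"], common["af"]),
    }, index=common.index)
    weights_apoe = pd.DataFrame({
        "chrom": ["19", "19"], "pos": [44908684, 44908822], "ref": ["T", "C"],
        "alt": ["C", "T"], "effect_allele": ["C", "T"],
        "beta": [b_429358, b_7412], "effect_af": [0.15, 0.08],
        "rsid": ["rs429358", "rs7412"],
    }, index=pd.Index(apoe_keys, name="variant"))
    rare_weight_rows = rare[rare["role"] == "rare_panel"]
    weights_rare = pd.DataFrame({
        "chrom": rare_weight_rows["chrom"], "pos": rare_weight_rows["pos"],
        "ref": rare_weight_rows["ref"], "alt": rare_weight_rows["alt"],
        "gene": rare_weight_rows["gene"],
        "beta_early": beta_early[[rare.index.get_loc(k) for k in rare_weight_rows.index]],
        "beta_late": beta_late[[rare.index.get_loc(k) for k in rare_weight_rows.index]],
    }, index=rare_weight_rows.index)

    early_mask = (ages <= cfg.age_cutoff)[:, None]
    betas_all = np.where(early_mask, beta_early[None, :], beta_late[None, :])
    panel_idx = [rare.index.get_loc(k) for k in rare_weight_rows.index]
    rare_comp_all = (rare_dos[:, panel_idx] * betas_all[:, panel_idx]).sum(axis=1)
    apoe_comp_all = b_429358 * apoe_c4 + b_7412 * apoe_t2
    ig_idx = gene_variant_idx[cfg.interaction_gene]
    truth = pd.DataFrame({
        "group": groups, "prs_common_true": prs_common,
        "apoe_component_true": apoe_comp_all, "rare_component_true": rare_comp_all,
        "gs_true": prs_common + apoe_comp_all + rare_comp_all,
        "z_common_true": np.r_[z_common[pool], _standardize(prs_common[n_pool:])],
        "liability": np.r_[liability, np.zeros(n_mci + n_other)],
        "interaction_carrier": rare_dos[:, ig_idx].sum(axis=1) > 0,
        "monogenic_mechanism": mech,
        "beta_gs": cfg.beta_gs, "liability_on": cfg.liability_on,
    }, index=pd.Index(ids, name="subject_id"))

    panel = PanelDefinition()
    return SimulatedCohort(
        config=cfg, subjects=subjects, variants=variants, annotation=annotation,
        dosages=dosages, weights_common=weights_common, weights_apoe=weights_apoe,
        weights_rare=weights_rare, truth=truth, panel=panel,
    )


# ---------------------------------------------------------------------------
# in-print count fixtures
# ---------------------------------------------------------------------------

def make_fixture_tables() -> dict:
    """Emit the published count tables as DataFrames (idempotent).

    ``table1``: per-group demographic counts; ``table2_counts``:
    profile-category numerators/denominators; ``table3``: per-gene
    rare-variant and carrier counts; ``common_weights_dummy``: an 82-row
    placeholder common-PRS weight table; ``concordance``: a synthetic
    per-carrier table reproducing the published marginal counts (gene-class
    split 9/17/8, three SCD carriers, 16 of 31 clinical/genetic
    mismatches) — the patient-level data behind it are not public.
    """
    table1 = pd.DataFrame(
        {
            "n": [219, 87, 362, 328],
            "age_mean": [57.8, 64.3, 65.6, 60.6],
            "age_sd": [9.3, 7.5, 7.2, 9.0],
            "n_female": [91, 21, 174, 115],
            "n_family_history": [84, 26, 162, 90],
            "n_monogenic": [3, 4, 8, 17],
            "n_rare_carrier": [67, 28, 130, 90],
            "n_rare_early": [52, 15, 55, 53],
            "n_rare_late": [15, 13, 75, 37],
            "n_apoe4": [81, 37, 234, 134],
            "n_csf": [166, 60, 308, 253],
            "csf_amyloid_pos_pct": [12.8, 0.0, 79.3, 20.6],
        },
        index=pd.Index(["SCD", "MCI", "AD", "Other"], name="group"),
    )
    # printed Total column, kept verbatim: the published per-group counts do
    # not all add to it (n sums to 996 vs printed 998; females to 401 vs 402)
    table1.loc["Total"] = [998, 62.1, 8.9, 402, 363, 34, 315, 175, 140,
                           486, 787, 38.5]
    table1 = table1.astype({c: int for c in table1.columns
                            if c.startswith("n")})
    table2 = pd.DataFrame(
        {
            "count": [34, 306, 58, 473],
            "denominator": [998, 964, 964, 964],
        },
        index=pd.Index(
            ["monogenic_carriers", "rare_carrier_one_plus",
             "rare_carrier_two_plus", "apoe4_carriers"],
            name="category",
        ),
    )
    table3 = pd.DataFrame(
        {
            "n_variants": [16, 81, 14, 7, 17, 11, 13, 9, 2, 10, 4],
            "n_missense": [13, 73, 11, 4, 17, 11, 12, 9, 2, 10, 0],
            "n_lof": [3, 8, 3, 3, 0, 0, 1, 0, 0, 0, 4],
            "n_lof_carriers": [4, 10, 4, 3, 0, 0, 1, 0, 0, 0, 5],
            "n_missense_carriers": [27, 146, 26, 6, 48, 21, 36, 13, 2, 39, 0],
        },
        index=pd.Index(
            ["ABCA1", "ABCA7", "ACE", "ADAM10", "ATP8B4", "CLU",
             "RIN3", "SORL1", "SRC", "TREM2", "ZCWPW1"],
            name="gene",
        ),
    )
    dummy = pd.DataFrame({
        "chrom": [str((i % 22) + 1) for i in range(82)],
        "pos": [1_000_000 + 10_007 * (i + 1) for i in range(82)],
        "ref": ["A"] * 82, "alt": ["G"] * 82,
        "effect_allele": ["G"] * 82, "beta": [0.05] * 82,
    }, index=pd.Index(
        [f"{(i % 22) + 1}:{1_000_000 + 10_007 * (i + 1)}:A:G" for i in range(82)],
        name="variant",
    ))
    concordance = _concordance_fixture()
    return {"table1": table1, "table2_counts": table2, "table3": table3,
            "common_weights_dummy": dummy, "concordance": concordance}


def _concordance_fixture() -> pd.DataFrame:
    """Synthetic monogenic-carrier table matching the published margins."""
    rows = []
    # three SCD carriers (excluded from the mismatch denominator)
    rows += [("SCD", "PSEN1"), ("SCD", "C9orf72"), ("SCD", "GRN")]
    # AD-gene carriers (8): 5 concordant, 3 discordant
    rows += [("AD", "APP")] + [("AD", "PSEN1")] * 2 + [("AD", "SORL1")] * 2
    rows += [("FTD", "APP"), ("MCI", "PSEN1"), ("MCI", "SORL1")]
    # FTD-gene carriers (15): 8 concordant, 7 discordant
    rows += [("FTD", "MAPT")] * 2 + [("FTD", "C9orf72")] * 3 + [("FTD", "GRN")] * 2
    rows += [("FTD", "TARDBP")]
    rows += [("AD", "C9orf72")] * 2 + [("AD", "GRN"), ("MCI", "MAPT"),
                                       ("MCI", "C9orf72"), ("PPD", "C9orf72"),
                                       ("PPD", "CTSF")]
    # other-dementia-gene carriers (8): 2 concordant, 6 discordant
    rows += [("OtherDem", "HTT"), ("VD", "NOTCH3")]
    rows += [("AD", "NOTCH3"), ("AD", "PRNP"), ("FTD", "CHMP2B"),
             ("LBD", "PRNP"), ("MCI", "NPC1"), ("PPD", "HTT")]
    df = pd.DataFrame(rows, columns=["diagnosis_raw", "gene"])
    df.index = pd.Index([f"M{i + 1:03d}" for i in range(len(df))], name="subject_id")
    return df
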