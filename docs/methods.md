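# Methods

## Setting and model

The package models the genetic work-up of a consecutive memory-clinic
series. Subjects carry a raw clinical diagnosis (SCD, MCI, AD, FTD, LBD,
VD, PPD, other dementia) which is collapsed into four analysis groups:
SCD, MCI, AD (including amyloid-positive MCI, whose CSF profile places
them on the AD continuum) and Other (all non-AD dementias plus primary
psychiatric disorders, which present cognitively but are not dementias).
PPD is kept as a distinct raw label so per-diagnosis reports can list it
separately.

Genetic risk enters through four non-exclusive categories: monogenic
carriers, rare-risk carriers, the common-variant polygenic score, and
APOE. Monogenic carriers are identified first and removed from all score
analyses — a causal variant explains the phenotype outright, and leaving
such subjects in would contaminate estimates of polygenic effects.

### Variant triage

Annotated variants pass through an ordered cascade; the first matching
rule decides, and every call carries a machine-readable reason trail:

1. population allele frequency ≥ the rarity ceiling (default 1%,
   configurable up to 5%) → excluded. This rule, not a hard-coded
   exception, is what removes common coding polymorphisms such as a
   frequent TREM2 missense variant from the rare set;
2. gene outside the monogenic ∪ risk ∪ candidate panel → excluded;
3. curated ACMG class IV/V in a monogenic gene → monogenic candidate
   (curation is always an input column — the package never computes ACMG
   classes, and "unclassified" can never become a monogenic candidate);
4. *SORL1* high-confidence LoF → monogenic candidate (treated as causal;
   *SORL1* missense variants instead fall through to the rare-risk rules);
5. in a risk/candidate gene: LOFTEE HC LoF, or missense with REVEL at or
   above the per-gene threshold, or splice delta ≥ 0.5 → rare risk. A
   missense variant without a REVEL score is excluded with reason
   `missing_revel`, not an error;
6. otherwise excluded.

Per-gene REVEL thresholds default to 0.25 for every risk/candidate gene
and are overridable per gene in the panel definition. This default is a
deliberately permissive package placeholder — the original study's
per-gene thresholds live in an unavailable supplement and are **not**
reproduced here. The splice-delta cutoff of 0.5 (a variant predicted to
change splicing with ≥ 50% probability is treated as LoF-equivalent) is
likewise a package choice; no published cutoff exists for this cascade.

A subject is a monogenic carrier when they hold one monogenic-candidate
allele in a dominant gene, two alleles (two variants or one homozygous
call) in a recessive-inheritance gene, a *C9orf72* repeat expansion or an
*APP* duplication (both consumed as boolean flags; repeat and structural
assays are out of scope). A single curated allele in a recessive gene is
logged, not flagged.

Carrier status for rare-risk variants requires dosage ≥ 1 for sequencing
hard calls and ≥ 0.5 for imputed dosages (a config value; rare variants
normally arrive as hard calls). Per-gene carrier counts in the summary
table are per-variant sums, so an individual carrying two variants
counts twice — matching how clinic panels tabulate carriers.

### The genetic score

Each block is the standard weighted dosage sum Σ βᵢ·dᵢ with dosages
counted on the effect allele (2 − d when the effect allele is REF).
Weights are re-aligned to the VCF ALT allele at load time with flips
logged; strand-ambiguous rows (A/T, C/G) are rejected unless their
declared effect-allele frequency matches the observed frequency within
0.1. Missing dosages in the common/APOE blocks are handled by
effect-allele-frequency imputation by default (substituting 2·AF, the
Hardy–Weinberg expectation), with pairwise exclusion available; either
path logs its count. The rare block selects β_early when age ≤ 65 years
and β_late above, making age mandatory for the GS.

"Standardized sum" is read as standardize(sum of raw blocks); the
alternative (sum of per-block z-scores) sits behind the `combine`
parameter, and the run log names which was used. The standardization
population defaults to every subject entering the GS analysis (monogenic
carriers already removed) with an SCD-only option — the choice affects
only the per-unit odds-ratio scale, since quintile referencing is always
anchored on SCD.

Quintile boundaries are the SCD group's 20/40/60/80th percentiles using
linear interpolation between order statistics. Bins are half-open
[lo, hi): a value equal to a cut point joins the bin whose lower edge it
is, the lowest bin is unbounded below and the top bin is closed at its
lower edge. Bins 1..5 map to the values {−1, −0.5, 0, 0.5, 1}. The
reference group must contain at least five subjects.

The APOE diplotype is resolved from rs429358/rs7412 allele counts via the
haplotype table (T,T)→ε2, (T,C)→ε3, (C,C)→ε4; the doubly heterozygous
genotype resolves to ε2/ε4 (the ε1/ε3 alternative is vanishingly rare),
and a combination implying a non-canonical haplotype is an error.

### Statistics

All inference is implemented from defining formulas, with library code
used only for distribution functions and linear algebra:

* Pearson chi-square (X² = Σ(O−E)²/E, df = (R−1)(C−1)) and the pooled
  two-proportion z-test carry **no continuity corrections**, so the
  algebraic identity z² ≡ X² on 2×2 tables is an enforced contract rather
  than an approximation.
* Binary logistic regression maximizes the likelihood by IRLS
  (convergence max|score| < 1e-8 or 100 iterations); Wald standard errors
  come from the inverse observed information, intervals use the 1.96
  multiplier (matching the bracketed-OR reporting style), and collinear
  design columns are dropped via pivoted QR with a log. Coefficients
  diverging past |β| > 15 with a non-vanishing score raise a separation
  error naming the term.
* Multinomial logit (reference category fixed at zero) is fit by Newton's
  method with step halving; with two categories it reduces exactly to the
  binary fit, and per-subject probabilities always lie on the simplex.
* The AUC is the Mann–Whitney probability of correct ordering with ties
  counted half, computed from midranks in O(n log n); the O(n²)
  structural-components formulation is retained as a test oracle. The
  paired DeLong test builds the variance of the AUC difference from
  placement-value covariances; identical placements report delta 0, p 1.
* Confusion metrics (SE/SP/PPV/NPV) are percentages to two decimals;
  an undefined ratio is reported as missing, never as zero. Model-based
  classification thresholds fitted probabilities at 0.5. For the
  GS-quintile table the rule is sign-based: a negative quintile value
  predicts SCD, a positive one AD, and the zero (reference) stratum is
  excluded from the per-quintile confusion matrix.
* The gene-level interaction scan (Status ~ PRS × carrier + covariates)
  reports raw and Bonferroni-adjusted p-values (the adjustment method is
  a logged package default) and skips genes with a constant carrier
  vector or fewer than five carriers.
* The demographics surface uses chi-square for count rows; the age row
  uses a one-way ANOVA F-test, since ages are continuous and a chi-square
  on them is undefined.

## The synthetic cohort generator

No patient-level data are distributable, so the generator is first-class,
tested code that emulates the statistical structure the analysis assumes:

* **Fixed composition.** Group sizes are quotas (219/87/362/328 by
  default — a clinic series, not case/control sampling), with per-group
  truncated-normal ages on [40, 95] years, sex, family-history, APOE-ε4
  and rare-carrier fractions drawn to configured targets (defaults match
  the published clinic series).
* **Genotypes.** The 82-variant common block is drawn per variant from
  Hardy–Weinberg at frequencies uniform on [0.05, 0.5] and emitted as a
  dosage (DS) field to exercise the imputed-dosage path; effect sizes are
  N(0.07, 0.03) clipped positive, with ~10% of weight rows presented on
  the REF allele to exercise effect-allele alignment. Rare-panel variants
  (3 per gene by default, plus decoys that the cascade must exclude and a
  curated monogenic set) are hard calls; per-gene carrier probabilities
  p_g = 1 − (1 − t)^{w_g} make the probability of carrying ≥ 1 variant
  equal the group target t exactly, with gene shares w_g following a
  clinic-like spectrum.
* **Liability.** AD-vs-SCD membership inside the pooled SCD+AD block is
  assigned by a logistic tilt: Bernoulli draws from expit(α + β·z) with α
  solved so the expected case count hits the quota, then at most a few
  uniformly random flips to hit it exactly (≈2% of the pool, a negligible
  attenuation). Two modes exist because per-group APOE/rare targets and a
  full-GS liability cannot both hold for arbitrary targets:
  `liability_on="common_prs"` (default) tilts on the standardized common
  PRS and draws APOE/rare per final group, hitting the published
  per-group carrier fractions; `liability_on="gs"` draws all blocks from
  pooled targets first and tilts on the standardized full GS, giving the
  well-defined true slope needed for parameter-recovery studies. An
  optional product term β_int·z_common·carrier(gene) injects a
  gene-specific interaction in "gs" mode.
* **Determinism.** One integer-seeded NumPy generator drives every draw;
  the seed is echoed in every output header and identical seeds reproduce
  every file byte for byte.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, ancestry stratification, genotyping/imputation
error, relatedness, and the real per-gene rare-variant spectrum. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic and
calibration of its inference under the stated generative model, not
clinical performance on real cohorts.

## Validation design and problem sizes

The suite checks every statistic against an independent oracle
(closed-form 2×2 logistic, the z²≡X² identity, exhaustive pair counting
for the AUC at n ≤ 50, an independent BFGS maximization of the
multinomial likelihood, a 2000-replicate bootstrap for the DeLong
variance at n = 200) and statsmodels as an external cross-check.
Calibration experiments use 100 replicate cohorts at the default n ≈ 1000
for confidence-interval coverage of the GS slope (expected ≥ 90%; the
quota trimming and standardization-population mismatch cost a point or
two of nominal 95% coverage) and 500 null replicates for the type-I error
of the interaction and DeLong tests (accepted within three binomial
standard errors of 0.05). These sizes keep the whole suite and the
acceptance script in the tens of seconds on one CPU while leaving the
Monte-Carlo error well inside the asserted bands.

## Shipped reference tables

The count fixtures (per-group demographics, per-gene rare-variant
composition, profile-category numerators) reproduce a published clinic
series verbatim, including its internal inconsistencies (per-group sizes
summing to 996 against a printed total of 998; female counts 401 vs 402;
per-group monogenic counts 32 vs a printed 34 — two carriers evidently
sit outside the four tabulated groups). The per-carrier concordance
table is **synthetic**: the real patient-level table is not public, so a
constructed table reproduces the published margins (9/17/8 split of
carriers over AD/FTD/other-dementia genes, three SCD carriers excluded,
16 of 31 clinical/genetic mismatches). The shipped APOE, common-block
and rare-block weight tables are clearly labelled fixtures; real analyses
must supply published weight tables. The default monogenic panel
(~20 genes) and the gene→disease map are editable package defaults, not
the study's 54-gene panel.

## Known limitations

* REVEL/splice thresholds and the monogenic panel are placeholders; the
  triage cascade's *structure* is the tested contract, not its default
  parameterization.
* Wald (not profile-likelihood) intervals; small-count odds ratios
  inherit Wald's known anti-conservatism.
* The concordance denominator excludes unmappable genes rather than
  guessing a disease class for them.
* The generator's two liability modes bracket, but do not jointly
  satisfy, "hit all per-group carrier targets" and "follow a full-GS
  logistic liability"; recovery claims always cite the mode used.
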