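"""Filter cascade, carrier matrices and the per-gene summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from memgs import (DosageMatrix, PanelDefinition, carrier_matrix,
                   flag_monogenic_subjects, gene_summary, subjects_frame,
                   summarize_gene_table, triage_variant, triage_variants)
from memgs.cohort_io import SubjectRecord
from memgs.triage import EXCLUDED, MONOGENIC_CANDIDATE, RARE_RISK


def variant(gene="TREM2", consequence="missense", pop_af=1e-4, revel=0.8,
            loftee=None, splice_delta=np.nan, curated_class="unclassified"):
    return {
        "variant": "X", "gene": gene, "consequence": consequence,
        "pop_af": pop_af, "revel": revel if consequence == "missense" else np.nan,
        "loftee": loftee, "splice_delta": splice_delta,
        "curated_class": curated_class,
    }


PANEL = PanelDefinition()


class TestCascade:
    @pytest.mark.parametrize(
        "v,category,reason",
        [
            # SORL1 high-confidence LoF is treated as causal
            (variant("SORL1", "lof", 1e-4, loftee="HC"), MONOGENIC_CANDIDATE, "sorl1_lof_hc"),
            # the canonical TREM2 R47H-style missense passes the REVEL gate
            (variant("TREM2", "missense", 5e-4, revel=0.77), RARE_RISK, "revel_ge_threshold"),
            # the 1% frequency ceiling dominates everything else
            (variant("TREM2", "missense", 0.02, revel=0.99), EXCLUDED, "af_above_threshold"),
            (variant("SORL1", "lof", 0.02, loftee="HC"), EXCLUDED, "af_above_threshold"),
            # curated (likely) pathogenic in a monogenic gene
            (variant("PSEN1", "missense", 1e-5, revel=0.9, curated_class="V"),
             MONOGENIC_CANDIDATE, "curated_pathogenic"),
            # ACMG class III is not "(likely) pathogenic"
            (variant("PSEN1", "missense", 1e-5, revel=0.9, curated_class="III"),
             EXCLUDED, "monogenic_gene_not_curated"),
            # class IV/V in a non-monogenic gene does not shortcut the cascade
            (variant("ACE", "missense", 1e-4, revel=0.9, curated_class="V"),
             RARE_RISK, "revel_ge_threshold"),
            (variant("NOTAGENE"), EXCLUDED, "gene_not_in_panel"),
            (variant("CLU", "missense", 1e-4, revel=0.05), EXCLUDED, "revel_below_threshold"),
            (variant("CLU", "missense", 1e-4, revel=np.nan), EXCLUDED, "missing_revel"),
            (variant("ABCA7", "lof", 1e-4, loftee="HC"), RARE_RISK, "lof_hc"),
            (variant("ABCA7", "lof", 1e-4, loftee="LC"), EXCLUDED, "no_deleteriousness_evidence"),
            (variant("SORL1", "splice_region", 1e-4, splice_delta=0.8),
             RARE_RISK, "splice_delta_ge_threshold"),
            (variant("SORL1", "splice_region", 1e-4, splice_delta=0.1),
             EXCLUDED, "no_deleteriousness_evidence"),
        ],
    )
    def test_rules(self, v, category, reason):
        call = triage_variant(v, PANEL)
        assert call.category == category
        assert call.reasons[0] == reason

    def test_per_gene_revel_override(self):
        panel = PanelDefinition(revel_thresholds={"TREM2": 0.9})
        assert triage_variant(variant("TREM2", revel=0.8), panel).category == EXCLUDED
        assert triage_variant(variant("ABCA1", revel=0.8), panel).category == RARE_RISK

    @given(
        gene=st.sampled_from(["TREM2", "SORL1", "PSEN1", "NOTAGENE", "CLU"]),
        consequence=st.sampled_from(["missense", "lof", "splice_region", "other"]),
        pop_af=st.floats(0, 0.5, allow_nan=False),
        revel=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        loftee=st.sampled_from([None, "HC", "LC"]),
        splice=st.one_of(st.just(np.nan), st.floats(0, 1, allow_nan=False)),
        curated=st.sampled_from(["unclassified", "III", "IV", "V"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_totality_and_exclusivity(self, gene, consequence, pop_af, revel,
                                      loftee, splice, curated):
        """Every annotated variant receives exactly one category; excluded
        calls always carry a reason."""
        v = {
            "variant": "X", "gene": gene, "consequence": consequence,
            "pop_af": pop_af,
            "revel": revel if consequence == "missense" else np.nan,
            "loftee": loftee if consequence == "lof" else None,
            "splice_delta": splice, "curated_class": curated,
        }
        call = triage_variant(v, PANEL)
        assert call.category in (MONOGENIC_CANDIDATE, RARE_RISK, EXCLUDED)
        assert call.reasons

    def test_filter_monotonicity(self, cohort):
        """Raising the MAF ceiling never shrinks, and raising the REVEL
        threshold never grows, the rare-risk set."""
        ann = cohort.annotation
        base = triage_variants(ann, PanelDefinition())
        n_base = (base["category"] == RARE_RISK).sum()
        looser_maf = triage_variants(ann, PanelDefinition(maf_threshold=0.05))
        assert (looser_maf["category"] == RARE_RISK).sum() >= n_base
        stricter_revel = triage_variants(ann, PanelDefinition(revel_default=0.95))
        assert (stricter_revel["category"] == RARE_RISK).sum() <= n_base
        # rare-risk sets are nested, not merely smaller
        assert set(stricter_revel.index[stricter_revel["category"] == RARE_RISK]) \
            <= set(base.index[base["category"] == RARE_RISK])


def _toy_subjects():
    return subjects_frame([
        SubjectRecord("A", 70, "female", "AD"),
        SubjectRecord("B", 60, "male", "FTD", c9orf72_expansion=True),
        SubjectRecord("C", 65, "female", "SCD"),
        SubjectRecord("D", 72, "male", "AD", app_duplication=True),
    ])


class TestMonogenicFlags:
    def _setup(self, dosage_rows, curated_class="V", gene="PSEN1", n_var=2):
        keys = [f"1:{100 + i}:A:G" for i in range(n_var)]
        ann = pd.DataFrame({
            "chrom": "1", "pos": [100 + i for i in range(n_var)],
            "ref": "A", "alt": "G", "gene": gene, "consequence": "missense",
            "pop_af": 1e-5, "revel": 0.9, "loftee": None, "splice_delta": np.nan,
            "curated_class": curated_class,
        }, index=pd.Index(keys, name="variant"))
        calls = triage_variants(ann, PANEL)
        subj = _toy_subjects()
        dos = pd.DataFrame(dosage_rows, index=subj.index, columns=keys, dtype=float)
        dm = DosageMatrix(dos, pd.Series("hard_call", index=dos.columns))
        return subj, calls, ann, dm

    def test_c9orf72_and_app_flags(self):
        subj, calls, ann, dm = self._setup(np.zeros((4, 2)))
        flags = flag_monogenic_subjects(subj, calls, ann, dm, PANEL)
        assert flags.loc["B", "monogenic"] and flags.loc["B", "genes"] == "C9orf72"
        assert flags.loc["D", "monogenic"] and flags.loc["D", "genes"] == "APP"
        assert not flags.loc["A", "monogenic"]

    def test_curated_dominant_carrier_flagged(self):
        subj, calls, ann, dm = self._setup([[1, 0], [0, 0], [0, 0], [0, 0]])
        flags = flag_monogenic_subjects(subj, calls, ann, dm, PANEL)
        assert flags.loc["A", "monogenic"] and "PSEN1" in flags.loc["A", "genes"]

    def test_class_iii_never_flags(self):
        subj, calls, ann, dm = self._setup([[1, 1]] + [[0, 0]] * 3,
                                           curated_class="III")
        flags = flag_monogenic_subjects(subj, calls, ann, dm, PANEL)
        assert not flags.loc["A", "monogenic"]

    def test_recessive_needs_two_alleles(self):
        one = self._setup([[1, 0], [0, 0], [0, 0], [0, 0]], gene="NPC1")
        flags = flag_monogenic_subjects(*one, PANEL)
        assert not flags.loc["A", "monogenic"]
        two = self._setup([[1, 1], [2, 0], [0, 0], [0, 0]], gene="NPC1")
        flags = flag_monogenic_subjects(*two, PANEL)
        assert flags.loc["A", "monogenic"]       # two distinct alleles
        assert flags.loc["B", "monogenic"]       # homozygous counts as two


class TestCarrierMatrix:
    def test_matches_bruteforce_scan(self, cohort):
        """The vectorized carrier matrix equals a per-subject exhaustive scan."""
        calls = triage_variants(cohort.annotation, cohort.panel)
        cm = carrier_matrix(calls, cohort.annotation, cohort.dosages)
        rare_keys = calls.index[calls["category"] == RARE_RISK]
        d = cohort.dosages.dosages
        for sid in d.index[:120]:
            carried = {k for k in rare_keys if d.loc[sid, k] >= 1}
            assert cm.counts[sid] == len(carried)
            genes = {cohort.annotation.loc[k, "gene"] for k in carried}
            assert set(cm.flags.columns[cm.flags.loc[sid]]) == genes

    def test_zero_subject(self, cohort):
        calls = triage_variants(cohort.annotation, cohort.panel)
        cm = carrier_matrix(calls, cohort.annotation, cohort.dosages)
        zero = cm.counts == 0
        assert (~cm.flags.loc[zero].any(axis=1)).all()

    def test_imputed_threshold(self):
        ann = pd.DataFrame({
            "chrom": "6", "pos": [100], "ref": "C", "alt": "T", "gene": "TREM2",
            "consequence": "missense", "pop_af": 1e-4, "revel": 0.8,
            "loftee": None, "splice_delta": np.nan, "curated_class": "unclassified",
        }, index=pd.Index(["6:100:C:T"], name="variant"))
        calls = triage_variants(ann, PANEL)
        dos = pd.DataFrame([[0.6], [0.4]], index=["A", "B"], columns=["6:100:C:T"])
        dm = DosageMatrix(dos, pd.Series("imputed_dosage", index=dos.columns))
        cm = carrier_matrix(calls, ann, dm)
        assert bool(cm.flags.loc["A", "TREM2"]) and not bool(cm.flags.loc["B", "TREM2"])


class TestGeneSummary:
    def test_totals_equal_independent_sums(self, cohort):
        calls = triage_variants(cohort.annotation, cohort.panel)
        tab = gene_summary(calls, cohort.annotation, cohort.dosages)
        body = tab.drop(index="Total")
        for col in ("n_variants", "n_missense", "n_lof",
                    "n_lof_carriers", "n_missense_carriers"):
            assert tab.loc["Total", col] == body[col].sum()

    def test_published_count_fixture(self, fixtures):
        """The per-gene fixture reproduces the printed totals and shares."""
        tab = summarize_gene_table(fixtures["table3"])
        assert tab.loc["Total", "n_variants"] == 184
        assert tab.loc["Total", "n_missense"] == 162
        assert tab.loc["Total", "n_lof"] == 22
        assert tab.loc["Total", "n_lof_carriers"] == 27
        assert tab.loc["Total", "n_missense_carriers"] == 364
        assert tab.loc["Total", "pct_missense"] == 88.04
        assert tab.loc["Total", "pct_lof"] == 11.96

    def test_single_gene_single_carrier(self):
        per_gene = pd.DataFrame(
            {"n_variants": [1], "n_missense": [1], "n_lof": [0],
             "n_lof_carriers": [0], "n_missense_carriers": [1]},
            index=pd.Index(["TREM2"], name="gene"))
        tab = summarize_gene_table(per_gene)
        assert tab.loc["Total"].tolist()[:5] == [1, 1, 0, 0, 1]

    def test_empty_calls_empty_table(self, cohort):
        empty = triage_variants(cohort.annotation.iloc[:0], cohort.panel)
        tab = gene_summary(empty, cohort.annotation, cohort.dosages)
        assert tab.empty
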