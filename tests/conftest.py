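"""Shared fixtures: one synthetic cohort and one pipeline run per session."""

from __future__ import annotations

import textwrap

import pytest

from memgs import RunConfig, SimConfig, make_fixture_tables, run_pipeline, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic clinic cohort (seeded)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The same cohort written to disk in the standard formats."""
    d = tmp_path_factory.mktemp("cohort")
    paths = cohort.write(d)
    return paths


@pytest.fixture(scope="session")
def pipeline_run(cohort_dir, tmp_path_factory):
    """One full pipeline run over the session cohort."""
    out = tmp_path_factory.mktemp("report")
    cfg = RunConfig(
        vcf=str(cohort_dir["vcf"]),
        phenotypes=str(cohort_dir["phenotypes"]),
        annotation=str(cohort_dir["annotation"]),
        weights_common=str(cohort_dir["weights_common"]),
        weights_apoe=str(cohort_dir["weights_apoe"]),
        weights_rare=str(cohort_dir["weights_rare"]),
        out_dir=str(out),
        seed=11,
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def fixtures():
    """The published count tables as DataFrames."""
    return make_fixture_tables()


def write_vcf(path, body: str, samples=("S1",)) -> str:
    """Write a minimal VCF with the given record lines."""
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=DS,Number=A,Type=Float,Description="Dosage">
        """
    )
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(header + cols + "\n" + textwrap.dedent(body))
    return str(path)
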