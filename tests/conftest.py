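"""Shared fixtures: small synthetic cohorts, on disk and in memory."""

import pathlib

import pytest

import cohortaf as ca


@pytest.fixture(scope="session")
def null_fixture():
    """In-memory null cohort: every SNP drawn at its catalogue frequency."""
    return ca.generate(
        ca.FixtureSpec(n_samples=30, n_males=15, n_snps=200, seed=11)
    )


@pytest.fixture(scope="session")
def spiked_fixture_dir(tmp_path_factory) -> pathlib.Path:
    """On-disk cohort of 44 samples with one strongly spiked SNP.

    The spike mimics a fully penetrant pharmacogenomic allele: cohort
    frequency 0.5 (every sample heterozygous on average) against a
    catalogue frequency of 0.08.
    """
    outdir = tmp_path_factory.mktemp("spiked_cohort")
    spec = ca.FixtureSpec(
        n_samples=44,
        n_males=22,
        n_snps=80,
        missingness=0.05,
        seed=202,
        spikes=(
            ca.Spike(cohort_freq=0.5, catalogue_freq=0.08, consequence="missense",
                     damaging_flag=True),
        ),
    )
    ca.make_fixture(spec, outdir)
    return outdir


@pytest.fixture(scope="session")
def spiked_samples(spiked_fixture_dir):
    from cohortaf.fixtures import load_sample_manifest

    return load_sample_manifest(spiked_fixture_dir / "samples.tsv")


def write_vcf(path: pathlib.Path, records: list[str], sample_id: str = "S1") -> pathlib.Path:
    """Write a minimal single-sample VCF from pre-formatted record lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n##contig=<ID=X>\n"
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n"
    )
    path.write_text(header + "".join(r + "\n" for r in records))
    return path
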