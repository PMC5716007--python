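"""End-to-end cohort analysis: read -> sex check -> depth filter ->
frequencies -> tests -> corrections -> consequence filter.

This is the library form of the full run; the CLI's ``run`` subcommand
is a thin wrapper around :func:`run_pipeline`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import consequence as consequence_mod
from . import cohort_io, depth, frequency, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one pipeline run.

    ``catalogues`` maps a source label to a catalogue frame (already
    loaded). Independent result sets are produced per source, each with
    its own multiple-testing denominator.
    """

    declared_males: int
    declared_females: int
    alpha: float = stats.DEFAULT_ALPHA
    correct_by_catalogue: bool = False
    depth_cutoff: int = depth.DEFAULT_DEPTH_CUTOFF
    apply_depth_filter: bool = True
    absent_policy: str = cohort_io.STATUS_REF_ASSUMED
    strict_sex: bool = False
    min_x_calls: int = 50
    test_mode: str = "goodness_of_fit"
    include_all_consequences: bool = False


@dataclass
class RunResult:
    """Everything one pipeline run produces."""

    results: dict[str, pd.DataFrame]  # per catalogue source, corrected + filtered
    unfiltered: dict[str, pd.DataFrame]  # corrected, before the consequence filter
    frequencies: pd.DataFrame
    sex_report: cohort_io.SexCheckReport
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    samples: list[cohort_io.Sample],
    catalogues: dict[str, pd.DataFrame],
    config: RunConfig,
    annotations: pd.DataFrame | None = None,
) -> RunResult:
    """Run the full analysis over a cohort.

    The union of all catalogue SNPs defines the genotype table; testing
    and correction run independently per catalogue source, as two
    result sets can catch discrepancies between reference populations.
    The consequence filter applies only when annotations are given.
    """
    union = (
        pd.concat(catalogues.values(), ignore_index=True)
        .drop_duplicates(subset=["chrom", "pos", "rare_allele"])
        .reset_index(drop=True)
    )
    stage_counts = {"catalogue_snps_union": len(union), "samples": len(samples)}

    calls = cohort_io.read_cohort(
        samples, union, absent_policy=config.absent_policy, infer_sexes=False
    )
    cohort_io.infer_cohort_sexes(samples, calls, min_x_calls=config.min_x_calls)
    stage_counts["genotype_calls"] = len(calls)

    sex_report = cohort_io.verify_sex_counts(
        samples,
        config.declared_males,
        config.declared_females,
        strict=config.strict_sex,
    )

    if config.apply_depth_filter and any(s.depth_path for s in samples):
        calls, n_demoted = depth.apply_depth_filter(
            calls, samples, cutoff=config.depth_cutoff
        )
        stage_counts["calls_demoted_by_depth"] = n_demoted

    freqs = frequency.cohort_frequencies(calls, samples)
    stage_counts["snps_with_frequencies"] = len(freqs)
    stage_counts["snps_untestable"] = int(freqs["untestable"].sum())

    results: dict[str, pd.DataFrame] = {}
    unfiltered: dict[str, pd.DataFrame] = {}
    for label, cat in catalogues.items():
        tested = stats.chi2_vs_catalogue(freqs, cat, mode=config.test_mode)
        m = len(cat) if config.correct_by_catalogue else len(tested)
        corrected = stats.correct_pvalues(tested, alpha=config.alpha, m=m)
        unfiltered[label] = corrected
        stage_counts[f"tested[{label}]"] = len(tested)
        stage_counts[f"significant[{label}]"] = int(corrected["significant"].sum())
        if annotations is not None:
            corrected = consequence_mod.filter_protein_altering(
                corrected, annotations, include_all=config.include_all_consequences
            )
            stage_counts[f"after_consequence_filter[{label}]"] = len(corrected)
        results[label] = corrected

    return RunResult(
        results=results,
        unfiltered=unfiltered,
        frequencies=freqs,
        sex_report=sex_report,
        stage_counts=stage_counts,
    )


def write_run(result: RunResult, outdir: str | Path) -> None:
    """Write per-catalogue result TSVs, the frequency table and a run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frequency.write_frequencies(result.frequencies, outdir / "frequencies.tsv")
    for label, df in result.results.items():
        stats.write_results(df, outdir / f"results.{label}.tsv")
    rep = result.sex_report
    lines = [
        f"sex check: declared {rep.declared_males}M/{rep.declared_females}F, "
        f"inferred {rep.inferred_males}M/{rep.inferred_females}F/"
        f"{rep.inferred_ambiguous} ambiguous -> {'PASS' if rep.passed else 'FAIL'}"
    ]
    for sample_id, declared, inferred in rep.mismatches:
        lines.append(f"  mismatch: {sample_id} declared {declared}, inferred {inferred}")
    lines += [f"{k}: {v}" for k, v in result.stage_counts.items()]
    (outdir / "run_report.txt").write_text("\n".join(lines) + "\n")
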