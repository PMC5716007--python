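"""Per-individual VCF input and cohort sex verification.

Each cohort member contributes one post-variant-calling VCF. Genotypes
are projected onto the catalogue's SNPs: every (sample, catalogue SNP)
pair yields exactly one call with a status of

``called``
    the site appears in the sample's VCF with a usable GT;
``ref_assumed``
    the site is absent from the VCF and is imputed homozygous for the
    common allele (the usual sites-only VCF convention, later subject to
    depth checking);
``unknown``
    no usable genotype (missing/half GT, or absent under the
    ``absent-is-unknown`` policy, or demoted by the depth filter).

Sex is inferred per sample from non-pseudoautosomal X heterozygosity and
checked against the declared male/female counts, so that X-chromosome
allele totals use the correct ploidy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome

logger = logging.getLogger(__name__)

STATUS_CALLED = "called"
STATUS_REF_ASSUMED = "ref_assumed"
STATUS_UNKNOWN = "unknown"

#: Column order of a genotype-call frame.
CALL_COLUMNS = ["sample_id", "chrom", "pos", "rare_allele", "rare_count", "status", "het"]


@dataclass
class Sample:
    """One cohort member and their input files."""

    sample_id: str
    vcf_path: str | Path | None = None
    depth_path: str | Path | None = None
    declared_sex: str = genome.UNKNOWN
    inferred_sex: str | None = None

    @property
    def sex(self) -> str:
        """Working sex: the declared one when given, else the inferred one."""
        if self.declared_sex in (genome.MALE, genome.FEMALE):
            return self.declared_sex
        return self.inferred_sex or genome.AMBIGUOUS


@dataclass(frozen=True)
class SexCheckReport:
    """Outcome of checking inferred sexes against declared counts."""

    declared_males: int
    declared_females: int
    inferred_males: int
    inferred_females: int
    inferred_ambiguous: int
    passed: bool
    mismatches: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)


def _parse_genotype(gt_indices: list[int]) -> tuple[list[int], bool] | None:
    """Return (called allele indices, is_het) or None for missing/half GT."""
    alleles = [a for a in gt_indices if a is not None]
    if not alleles or any(a < 0 for a in alleles):
        return None
    het = len(alleles) >= 2 and len(set(alleles)) > 1
    return alleles, het


def read_sample_vcf(
    sample: Sample,
    catalogue: pd.DataFrame,
    *,
    absent_policy: str = STATUS_REF_ASSUMED,
) -> pd.DataFrame:
    """Project one sample's VCF onto the catalogue SNPs.

    Returns one row per catalogue SNP. VCF records at non-catalogue
    positions are ignored; a record at a catalogue site whose ALT does
    not match the catalogue rare allele still yields a ``called`` row
    (its alleles simply count as common). Genotypes with a missing or
    half call (``./.``, ``./1``) give ``unknown``; GT allele indices not
    matching the record's REF/ALT list skip the record with a warning
    count.

    Parameters
    ----------
    absent_policy
        Status assigned to catalogue SNPs absent from the VCF when no
        depth evidence has been consulted yet: ``"ref_assumed"``
        (default) or ``"unknown"``.
    """
    if absent_policy not in (STATUS_REF_ASSUMED, STATUS_UNKNOWN):
        raise ValueError(f"invalid absent_policy {absent_policy!r}")
    if sample.vcf_path is None:
        raise ValueError(f"sample {sample.sample_id} has no VCF path")

    from cyvcf2 import VCF

    try:
        vcf = VCF(str(sample.vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise OSError(
            f"cannot read VCF for sample {sample.sample_id}: {sample.vcf_path}"
        ) from exc

    n = len(catalogue)
    rare_count = np.zeros(n, dtype=np.int64)
    het = np.zeros(n, dtype=bool)
    if absent_policy == STATUS_REF_ASSUMED:
        status = np.full(n, STATUS_REF_ASSUMED, dtype=object)
    else:
        status = np.full(n, STATUS_UNKNOWN, dtype=object)

    # catalogue rows by normalised site; one site may carry several rare alleles
    site_rows: dict[tuple[str, int], list[int]] = {}
    norm_chrom = catalogue["chrom"].map(genome.normalise_chrom)
    for i, (c, p) in enumerate(zip(norm_chrom, catalogue["pos"])):
        site_rows.setdefault((c, int(p)), []).append(i)

    n_bad_gt = 0
    try:
        for variant in vcf:
            key = (genome.normalise_chrom(variant.CHROM), variant.POS)
            rows = site_rows.get(key)
            if rows is None:
                continue
            parsed = _parse_genotype(list(variant.genotypes[0][:-1]))
            if parsed is None:
                for i in rows:
                    status[i] = STATUS_UNKNOWN
                continue
            allele_idx, is_het = parsed
            seqs = [variant.REF] + list(variant.ALT)
            if any(a >= len(seqs) for a in allele_idx):
                n_bad_gt += 1
                continue
            called = [seqs[a] for a in allele_idx]
            for i in rows:
                rare = catalogue["rare_allele"].iat[i]
                rare_count[i] = sum(1 for s in called if s == rare)
                status[i] = STATUS_CALLED
                het[i] = is_het
    finally:
        vcf.close()

    if n_bad_gt:
        logger.warning(
            "sample %s: skipped %d records with GT allele index outside REF/ALT",
            sample.sample_id,
            n_bad_gt,
        )

    calls = pd.DataFrame(
        {
            "sample_id": sample.sample_id,
            "chrom": catalogue["chrom"].to_numpy(),
            "pos": catalogue["pos"].to_numpy(),
            "rare_allele": catalogue["rare_allele"].to_numpy(),
            "rare_count": rare_count,
            "status": status,
            "het": het,
        }
    )
    calls.loc[calls["status"] == STATUS_UNKNOWN, "rare_count"] = 0
    return calls[CALL_COLUMNS]


def infer_sex(
    calls: pd.DataFrame,
    *,
    min_x_calls: int = 50,
    male_max_het: float = 0.05,
    female_min_het: float = 0.20,
    par_intervals: tuple[tuple[int, int], ...] = genome.PAR_X_GRCH37,
) -> str:
    """Infer a sample's sex from non-PAR X heterozygosity.

    With at least ``min_x_calls`` called genotypes on the non-PAR X, the
    heterozygous fraction h classifies the sample: h < ``male_max_het``
    -> male, h > ``female_min_het`` -> female, otherwise ambiguous.
    Fewer calls than the minimum also give ambiguous.
    """
    on_x = calls["chrom"].map(genome.is_x)
    par = calls.apply(
        lambda r: genome.in_par(r["chrom"], r["pos"], par_intervals), axis=1
    ) if on_x.any() else pd.Series(False, index=calls.index)
    x_calls = calls[on_x & ~par & (calls["status"] == STATUS_CALLED)]
    if len(x_calls) < min_x_calls:
        return genome.AMBIGUOUS
    h = float(x_calls["het"].mean())
    if h < male_max_het:
        return genome.MALE
    if h > female_min_het:
        return genome.FEMALE
    return genome.AMBIGUOUS


def infer_cohort_sexes(samples: list[Sample], calls: pd.DataFrame, **kwargs) -> None:
    """Set ``inferred_sex`` on every sample from the pooled call frame."""
    for sample in samples:
        sample.inferred_sex = infer_sex(
            calls[calls["sample_id"] == sample.sample_id], **kwargs
        )


def verify_sex_counts(
    samples: list[Sample],
    declared_males: int,
    declared_females: int,
    *,
    strict: bool = False,
) -> SexCheckReport:
    """Check inferred sexes against the declared male/female counts.

    The declared counts must sum to the cohort size (hard error
    otherwise). A count disagreement is reported (``passed=False``) and,
    under ``strict=True``, raised as an error; per-sample mismatches
    between a determinate declared and inferred sex are listed either way.
    """
    if declared_males + declared_females != len(samples):
        raise ValueError(
            f"declared {declared_males} males + {declared_females} females "
            f"!= {len(samples)} samples"
        )
    inferred = [s.inferred_sex or genome.AMBIGUOUS for s in samples]
    n_male = inferred.count(genome.MALE)
    n_female = inferred.count(genome.FEMALE)
    n_amb = inferred.count(genome.AMBIGUOUS)
    mismatches = tuple(
        (s.sample_id, s.declared_sex, inf)
        for s, inf in zip(samples, inferred)
        if s.declared_sex in (genome.MALE, genome.FEMALE)
        and inf in (genome.MALE, genome.FEMALE)
        and s.declared_sex != inf
    )
    passed = n_male == declared_males and n_female == declared_females
    report = SexCheckReport(
        declared_males=declared_males,
        declared_females=declared_females,
        inferred_males=n_male,
        inferred_females=n_female,
        inferred_ambiguous=n_amb,
        passed=passed,
        mismatches=mismatches,
    )
    if not passed:
        msg = (
            f"sex check failed: declared {declared_males}M/{declared_females}F, "
            f"inferred {n_male}M/{n_female}F/{n_amb} ambiguous"
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return report


def read_cohort(
    samples: list[Sample],
    catalogue: pd.DataFrame,
    *,
    absent_policy: str = STATUS_REF_ASSUMED,
    infer_sexes: bool = True,
) -> pd.DataFrame:
    """Read every sample's VCF and pool the calls into one frame.

    Optionally infers each sample's sex from its X calls as a side
    effect. The result satisfies: exactly one row per (sample,
    catalogue SNP), |samples| x |catalogue| rows in total.
    """
    frames = [
        read_sample_vcf(s, catalogue, absent_policy=absent_policy) for s in samples
    ]
    calls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=CALL_COLUMNS
    )
    if infer_sexes:
        infer_cohort_sexes(samples, calls)
    return calls
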