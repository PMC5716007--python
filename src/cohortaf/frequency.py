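"""Sex-aware cohort allele frequencies with bounds under missing data.

The cohort rare-allele frequency at a SNP is the tally of rare alleles
over all usable genotypes divided by the number of presumed alleles:
two per individual on autosomes, and on sex chromosomes one (male) or
two (female) — X pseudoautosomal sites count as autosomal. Genotypes
with status ``unknown`` contribute no observed alleles; instead their
ploidy is accumulated as *unobserved* alleles, from which the extreme
frequencies are formed:

    freq_lower = rare / (observed + unobserved)      (unknowns all common)
    freq_upper = (rare + unobserved) / (observed + unobserved)  (all rare)

so the true cohort frequency always lies in [freq_lower, freq_upper].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import genome
from .cohort_io import STATUS_UNKNOWN, Sample

logger = logging.getLogger(__name__)

FREQUENCY_COLUMNS = [
    "chrom",
    "pos",
    "rare_allele",
    "rare_count",
    "allele_total",
    "n_unknown_alleles",
    "freq",
    "freq_lower",
    "freq_upper",
    "untestable",
]


def ploidy(
    sex: str,
    chrom: str,
    pos: int,
    par_intervals: tuple[tuple[int, int], ...] = genome.PAR_X_GRCH37,
) -> int:
    """Number of allele copies a sample of the given sex carries at a locus.

    Autosomes: 2. Non-PAR X: 1 for males, 2 for females. PAR X: 2.
    Y: 1 for males, 0 for females. An ambiguous sex at a sex-chromosome
    locus raises ValueError (callers count those alleles as unknown).
    """
    if genome.is_x(chrom):
        if genome.in_par(chrom, pos, par_intervals):
            return 2
        if sex == genome.MALE:
            return 1
        if sex == genome.FEMALE:
            return 2
        raise ValueError(f"ambiguous sex at X locus {chrom}:{pos}")
    if genome.is_y(chrom):
        if sex == genome.MALE:
            return 1
        if sex == genome.FEMALE:
            return 0
        raise ValueError(f"ambiguous sex at Y locus {chrom}:{pos}")
    return 2


def _ploidy_arrays(
    calls: pd.DataFrame,
    sex_by_sample: dict[str, str],
    par_intervals: tuple[tuple[int, int], ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ploidy per call row, plus an ambiguous-sex-at-sex-locus mask.

    Ambiguous rows get the maximal ploidy (2 on X, 1 on Y) and must be
    counted as unknown by the caller.
    """
    chroms = calls["chrom"].to_numpy()
    pos = calls["pos"].to_numpy()
    sexes = calls["sample_id"].map(sex_by_sample).to_numpy()

    is_x = np.array([genome.is_x(c) for c in chroms])
    is_y = np.array([genome.is_y(c) for c in chroms])
    in_par = np.array(
        [
            genome.in_par(c, p, par_intervals) if x else False
            for c, p, x in zip(chroms, pos, is_x)
        ]
    )
    male = sexes == genome.MALE
    female = sexes == genome.FEMALE

    pl = np.full(len(calls), 2, dtype=np.int64)
    pl[is_x & ~in_par & male] = 1
    pl[is_y & male] = 1
    pl[is_y & female] = 0
    pl[is_y & ~male & ~female] = 1  # ambiguous: maximal ploidy, forced unknown

    ambiguous = (~male & ~female) & ((is_x & ~in_par) | is_y)
    return pl, ambiguous


def cohort_frequencies(
    calls: pd.DataFrame,
    samples: list[Sample],
    *,
    par_intervals: tuple[tuple[int, int], ...] = genome.PAR_X_GRCH37,
) -> pd.DataFrame:
    """Tally rare-allele counts and frequencies per SNP across the cohort.

    Per SNP: ``rare_count`` sums over non-unknown calls, ``allele_total``
    sums the ploidy of samples with non-unknown calls, and
    ``n_unknown_alleles`` the ploidy of unknown calls, from which the
    point frequency and its bounds follow. Samples of ambiguous sex
    contribute their sex-chromosome loci as unknown alleles (with a
    logged warning). SNPs with no observed alleles are emitted with an
    undefined frequency and flagged ``untestable``.
    """
    sex_by_sample = {s.sample_id: s.sex for s in samples}
    missing = set(calls["sample_id"]) - set(sex_by_sample)
    if missing:
        raise ValueError(f"calls reference unknown samples: {sorted(missing)}")

    pl, ambiguous = _ploidy_arrays(calls, sex_by_sample, par_intervals)
    if ambiguous.any():
        n_samp = calls.loc[ambiguous, "sample_id"].nunique()
        logger.warning(
            "%d sample(s) of ambiguous sex: their sex-chromosome alleles "
            "are counted as unknown",
            n_samp,
        )

    unknown = (calls["status"] == STATUS_UNKNOWN).to_numpy() | ambiguous
    rare = calls["rare_count"].to_numpy().copy()
    over = ~unknown & (rare > pl)
    if over.any():
        logger.warning(
            "%d call(s) report more rare alleles than the locus ploidy; "
            "clipped (hemizygous sites called diploid?)",
            int(over.sum()),
        )
        rare = np.minimum(rare, pl)
    rare[unknown] = 0

    work = pd.DataFrame(
        {
            "chrom": calls["chrom"].to_numpy(),
            "pos": calls["pos"].to_numpy(),
            "rare_allele": calls["rare_allele"].to_numpy(),
            "rare": rare,
            "obs_alleles": np.where(unknown, 0, pl),
            "unk_alleles": np.where(unknown, pl, 0),
        }
    )
    g = (
        work.groupby(["chrom", "pos", "rare_allele"], sort=True, observed=True)
        .agg(
            rare_count=("rare", "sum"),
            allele_total=("obs_alleles", "sum"),
            n_unknown_alleles=("unk_alleles", "sum"),
        )
        .reset_index()
    )

    if (g["rare_count"] > g["allele_total"]).any():
        raise ValueError("rare_count exceeds allele_total (invariant breach)")

    total_all = g["allele_total"] + g["n_unknown_alleles"]
    with np.errstate(divide="ignore", invalid="ignore"):
        g["freq"] = np.where(
            g["allele_total"] > 0, g["rare_count"] / g["allele_total"], np.nan
        )
        g["freq_lower"] = np.where(
            total_all > 0, g["rare_count"] / total_all, np.nan
        )
        g["freq_upper"] = np.where(
            total_all > 0,
            (g["rare_count"] + g["n_unknown_alleles"]) / total_all,
            np.nan,
        )
    g["untestable"] = g["allele_total"] == 0
    return g[FREQUENCY_COLUMNS]


def write_frequencies(frequencies: pd.DataFrame, path) -> None:
    """Write the per-SNP frequency table as TSV for audit."""
    frequencies.to_csv(path, sep="\t", index=False, float_format="%.6g")
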