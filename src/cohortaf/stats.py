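"""Chi-squared testing of cohort allele frequencies against a catalogue.

Each SNP's observed rare/common allele counts are compared with the
expectation under the catalogue frequency q by a chi-squared test with
one degree of freedom and no Yates continuity correction. The upper-tail
p of the df=1 statistic already responds to deviation in either
direction, so it serves as the two-sided p; the direction (enriched or
depleted relative to q) is reported separately.

Two modes are available:

``goodness_of_fit`` (default)
    q is treated as a fixed population frequency; observed counts
    (rare, common) against expected (q*n, (1-q)*n).
``two_sample``
    the catalogue's own finite allele count enters a 2x2 allele-count
    contingency test; requires the catalogue's allele_number. As the
    catalogue grows this converges to the goodness-of-fit p.

Multiple testing is handled by Bonferroni (p * m, capped at 1) and
Benjamini-Hochberg step-up FDR over the m SNPs tested per catalogue
source; significance defaults to corrected p < 0.01. When unknown
alleles exist at a SNP, the p-value range attainable over every possible
allocation of those alleles is reported alongside the headline test.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalogue import SNP_KEY

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01

ENRICHED = "enriched"
DEPLETED = "depleted"


def chi2_goodness_of_fit(
    rare_count: np.ndarray | int,
    allele_total: np.ndarray | int,
    q: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Df=1 chi-squared of observed allele counts vs a fixed frequency q.

    Observed (rare, common) = (rare_count, allele_total - rare_count);
    expected (q*n, (1-q)*n); chi2 = sum (O-E)^2 / E, no continuity
    correction. Returns (chi2, upper-tail p). Vectorised.
    """
    rare = np.asarray(rare_count, dtype=float)
    n = np.asarray(allele_total, dtype=float)
    q = np.asarray(q, dtype=float)
    # algebraically identical to the two-cell sum (O-E)^2/E
    chi2 = (rare - q * n) ** 2 / (n * q * (1.0 - q))
    return chi2, sps.chi2.sf(chi2, df=1)


def chi2_two_sample(
    rare_a: np.ndarray | int,
    total_a: np.ndarray | int,
    rare_b: np.ndarray | int,
    total_b: np.ndarray | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Df=1 chi-squared on a 2x2 allele-count table, no Yates correction.

    Rows are the two cohorts, columns rare/common allele counts.
    Vectorised; degenerate margins give chi2 = 0, p = 1.
    """
    a = np.asarray(rare_a, dtype=float)
    b = np.asarray(total_a, dtype=float) - a
    c = np.asarray(rare_b, dtype=float)
    d = np.asarray(total_b, dtype=float) - c
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return chi2, sps.chi2.sf(chi2, df=1)


def bound_pvalues(
    rare_count: int,
    allele_total: int,
    n_unknown_alleles: int,
    q: float,
) -> tuple[float, float]:
    """Range of p-values attainable over all allocations of unknown alleles.

    Each of the ``n_unknown_alleles`` unobserved alleles could be rare
    or common; allocating j of them rare gives the table
    (rare_count + j, allele_total + n_unknown_alleles) for j = 0..u.
    The chi-squared statistic is convex in j, so the smallest p over all
    allocations occurs at an extreme (j = 0 or j = u) and the largest at
    the feasible count nearest the expectation q*(allele_total+u); the
    returned (p_lower, p_upper) therefore brackets the p-value of every
    intermediate allocation. With no unknown alleles both ends equal the
    plain test's p.
    """
    u = int(n_unknown_alleles)
    total = allele_total + u
    lo, hi = rare_count, rare_count + u
    _, p_lo = chi2_goodness_of_fit(lo, total, q)
    _, p_hi = chi2_goodness_of_fit(hi, total, q)
    p_min = float(min(p_lo, p_hi))
    # feasible integer counts nearest the expected count maximise p
    expected = q * total
    candidates = {lo, hi}
    for x in (int(np.floor(expected)), int(np.ceil(expected))):
        candidates.add(min(max(x, lo), hi))
    _, ps = chi2_goodness_of_fit(
        np.array(sorted(candidates)), total, q
    )
    p_max = float(np.max(ps))
    return p_min, p_max


def chi2_vs_catalogue(
    frequencies: pd.DataFrame,
    catalogue: pd.DataFrame,
    mode: Literal["goodness_of_fit", "two_sample"] = "goodness_of_fit",
    *,
    expected_floor: float = 1.0,
) -> pd.DataFrame:
    """Test every testable SNP's cohort frequency against the catalogue.

    SNPs are matched on (chrom, pos, rare_allele). Rows flagged
    untestable in the frequency table, and catalogue frequencies of
    exactly 0 or 1, are excluded with a logged count. Goodness-of-fit
    results whose smaller expected cell falls below ``expected_floor``
    are flagged ``low_expected`` (computed regardless; consider
    :func:`exact_binomial_check`). Where unknown alleles exist the
    attainable p-value range is reported as (p_raw_lower, p_raw_upper).

    Returns one row per tested SNP, uncorrected; feed the result to
    :func:`correct_pvalues`.
    """
    if mode not in ("goodness_of_fit", "two_sample"):
        raise ValueError(f"unknown test mode {mode!r}")
    merged = frequencies.merge(catalogue, on=SNP_KEY, how="inner")
    n_untestable = int(merged["untestable"].sum())
    degenerate = (merged["rare_freq"] <= 0.0) | (merged["rare_freq"] >= 1.0)
    n_degenerate = int((degenerate & ~merged["untestable"]).sum())
    if n_untestable or n_degenerate:
        logger.info(
            "excluded from testing: %d SNPs with no observed alleles, "
            "%d with catalogue frequency 0 or 1",
            n_untestable,
            n_degenerate,
        )
    t = merged[~merged["untestable"] & ~degenerate].reset_index(drop=True)

    rare = t["rare_count"].to_numpy()
    total = t["allele_total"].to_numpy()
    q = t["rare_freq"].to_numpy()

    if mode == "goodness_of_fit":
        chi2, p_raw = chi2_goodness_of_fit(rare, total, q)
        expected_min = np.minimum(q, 1 - q) * total
        low_expected = expected_min < expected_floor
    else:
        if t["allele_number"].isna().any():
            raise ValueError(
                "two_sample mode requires allele_number for every catalogue SNP"
            )
        an = t["allele_number"].to_numpy(dtype=float)
        cat_rare = np.rint(q * an)
        chi2, p_raw = chi2_two_sample(rare, total, cat_rare, an)
        low_expected = np.zeros(len(t), dtype=bool)

    out = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "pos": t["pos"],
            "rare_allele": t["rare_allele"],
            "snp_id": t["snp_id"],
            "source": t["source"],
            "rare_count": rare,
            "allele_total": total,
            "n_unknown_alleles": t["n_unknown_alleles"],
            "freq": t["freq"],
            "catalogue_freq": q,
            "chi2": chi2,
            "p_raw": p_raw,
            "direction": np.where(t["freq"] > q, ENRICHED, DEPLETED),
            "low_expected": low_expected,
        }
    )

    p_lower = np.full(len(out), np.nan)
    p_upper = np.full(len(out), np.nan)
    has_unknown = out["n_unknown_alleles"].to_numpy() > 0
    for i in np.flatnonzero(has_unknown):
        p_lower[i], p_upper[i] = bound_pvalues(
            int(rare[i]), int(total[i]), int(out["n_unknown_alleles"].iat[i]), float(q[i])
        )
    out["p_raw_lower"] = p_lower
    out["p_raw_upper"] = p_upper
    return out


def benjamini_hochberg(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Step-up BH adjusted values, optionally with an external test count m.

    ``m`` defaults to the number of p-values; a larger m (e.g. the full
    catalogue size when untested SNPs are charged to the budget) scales
    every adjusted value up accordingly.
    """
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m ({m}) must be >= number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def correct_pvalues(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    m: int | None = None,
) -> pd.DataFrame:
    """Apply Bonferroni and BH-FDR correction and call significance.

    ``m`` is the multiple-testing denominator: by default the number of
    SNPs actually tested for this catalogue source; pass the full
    catalogue size to charge untested SNPs to the budget as well.
    Significance is ``p_bonferroni < alpha`` (default 0.01). The result
    is sorted by raw p.
    """
    out = results.copy()
    if out.empty:
        for col in ("m", "p_bonferroni", "q_fdr", "significant"):
            out[col] = pd.Series(dtype=float if col != "significant" else bool)
        return out
    n = len(out)
    if m is None:
        m = n
    elif m != n:
        logger.info("multiple-testing denominator m=%d (tested %d SNPs)", m, n)
    p = out["p_raw"].to_numpy()
    out["m"] = m
    out["p_bonferroni"] = np.minimum(p * m, 1.0)
    out["q_fdr"] = benjamini_hochberg(p, m)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)


def exact_binomial_check(results: pd.DataFrame) -> pd.DataFrame:
    """Exact binomial two-sided p for rows flagged ``low_expected``.

    An extension beyond the chi-squared pipeline: at small expected
    counts the asymptotic test is unreliable, so flagged rows get a
    companion exact p in a ``p_exact`` column (NaN elsewhere). The
    chi-squared p remains the headline result.
    """
    out = results.copy()
    p_exact = np.full(len(out), np.nan)
    for i in np.flatnonzero(out["low_expected"].to_numpy()):
        p_exact[i] = sps.binomtest(
            int(out["rare_count"].iat[i]),
            int(out["allele_total"].iat[i]),
            float(out["catalogue_freq"].iat[i]),
        ).pvalue
    out["p_exact"] = p_exact
    return out


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-SNP results table as TSV, as produced by the pipeline."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
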