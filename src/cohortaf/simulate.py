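"""Power simulation: frequency-vs-catalogue testing against a case-control design.

The question simulated: a phenotype cohort of ``n_cohort`` exomes in
which every affected individual carries one rare allele of one of ``k``
interchangeable causative SNPs (heterozygous, dominant model) — how
often does each design flag the causative SNPs?

Generative model per replicate
------------------------------
``round(n_cohort * (1 - nongenetic_fraction))`` individuals are genetic
cases; each is causal with probability ``penetrance`` and, if causal,
is assigned uniformly at random to one of the k causative SNPs, where
it carries one rare allele. Every chromosome not carrying an assigned
causal allele draws a background rare allele independently at the
population frequency q. Non-causative catalogue SNPs are not simulated;
their multiplicity enters only through the multiple-testing denominator
``m_correction`` (default 121,000, a typical count of catalogued exome
SNPs).

Detection
---------
The frequency test applies the goodness-of-fit chi-squared against q
with Bonferroni correction over ``m_correction``; a SNP is significant
when corrected p < ``alpha_freq``. The association comparator draws an
equal-sized control cohort at frequency q and applies the 2x2
allele-count chi-squared at a genome-wide raw threshold
(``assoc_threshold``, default 1e-8). Powers are per-SNP detection
fractions over replicates; a scenario counts as *detected* when every
causative SNP's per-SNP power exceeds 0.5 (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import chi2_goodness_of_fit, chi2_two_sample

DEFAULT_M_CORRECTION = 121_000

#: Selectable scenario-detection criteria.
DETECTION_CRITERIA = ("per_snp_power", "any_snp_power", "all_in_one_replicate")


@dataclass(frozen=True)
class Scenario:
    """One simulation condition.

    Parameters
    ----------
    n_cohort
        Number of phenotype-cohort individuals.
    q
        Population rare-allele frequency of each causative SNP, (0, 0.5).
    k
        Number of interchangeable causative SNPs, >= 1.
    penetrance
        Probability a genetic case is actually caused by its SNP.
    nongenetic_fraction
        Fraction of the cohort with a non-genetic aetiology.
    m_correction
        Multiple-testing denominator for the frequency design.
    alpha_freq
        Corrected significance level for the frequency design.
    assoc_threshold
        Raw genome-wide p threshold for the association comparator.
    n_controls
        Control-cohort size for the comparator (default: n_cohort).
    replicates, seed
        Monte-Carlo settings; the seed fixes all randomness.
    """

    n_cohort: int
    q: float
    k: int
    penetrance: float = 1.0
    nongenetic_fraction: float = 0.0
    m_correction: int = DEFAULT_M_CORRECTION
    alpha_freq: float = 0.01
    assoc_threshold: float = 1e-8
    n_controls: int | None = None
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 0.5:
            raise ValueError(f"q must be in (0, 0.5), got {self.q}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        if not 0.0 <= self.nongenetic_fraction < 1.0:
            raise ValueError("nongenetic_fraction must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def controls(self) -> int:
        return self.n_cohort if self.n_controls is None else self.n_controls


@dataclass(frozen=True)
class PowerResult:
    """Detection rates for one scenario (all powers are per-replicate fractions)."""

    scenario: Scenario
    per_snp_power_freq: tuple[float, ...]
    power_all_freq: float
    power_any_freq: float
    per_snp_power_assoc: tuple[float, ...]
    power_all_assoc: float
    power_any_assoc: float
    detected_freq: bool
    detected_assoc: bool


def simulate_counts(
    scenario: Scenario, rng: np.random.Generator, n_replicates: int | None = None
) -> np.ndarray:
    """Per-SNP cohort rare-allele counts, shape (replicates, k).

    Causal carriers contribute one rare allele each at their assigned
    SNP; all remaining chromosomes (2*n_cohort minus the causal alleles
    at that SNP) carry background rare alleles as independent draws at
    frequency q.
    """
    reps = scenario.replicates if n_replicates is None else n_replicates
    n, k = scenario.n_cohort, scenario.k
    n_genetic = round(n * (1.0 - scenario.nongenetic_fraction))
    if scenario.penetrance < 1.0:
        n_causal = rng.binomial(n_genetic, scenario.penetrance, size=reps)
    else:
        n_causal = np.full(reps, n_genetic)
    pvals = np.full(k, 1.0 / k)
    causal = np.vstack([rng.multinomial(nc, pvals) for nc in n_causal])
    background = rng.binomial(2 * n - causal, scenario.q)
    return causal + background


def simulate_cohort(scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    """One replicate's per-SNP rare-allele counts, shape (k,)."""
    return simulate_counts(scenario, rng, n_replicates=1)[0]


def freq_design_detect(counts: np.ndarray, scenario: Scenario) -> np.ndarray:
    """Frequency-design significance per causative SNP.

    Goodness-of-fit chi-squared of each SNP's cohort counts against q,
    Bonferroni-corrected over ``m_correction``; significant when the
    corrected p falls below ``alpha_freq``. Works on (k,) or (R, k).
    """
    counts = np.asarray(counts)
    _, p = chi2_goodness_of_fit(counts, 2 * scenario.n_cohort, scenario.q)
    return np.minimum(p * scenario.m_correction, 1.0) < scenario.alpha_freq


def assoc_detect(
    counts: np.ndarray, scenario: Scenario, rng: np.random.Generator
) -> np.ndarray:
    """Association-comparator significance per causative SNP.

    Draws a control cohort of ``scenario.controls`` individuals with
    allele counts Binomial(2*controls, q) per SNP and applies the 2x2
    allele-count chi-squared at the raw genome-wide threshold.
    """
    if scenario.controls <= 0:
        raise ValueError("association comparator requires n_controls > 0")
    counts = np.asarray(counts)
    control_total = 2 * scenario.controls
    control_rare = rng.binomial(control_total, scenario.q, size=counts.shape)
    _, p = chi2_two_sample(
        counts, 2 * scenario.n_cohort, control_rare, control_total
    )
    return p < scenario.assoc_threshold


def _detected(per_snp: np.ndarray, power_all: float, criterion: str) -> bool:
    if criterion == "per_snp_power":
        return bool(np.all(per_snp > 0.5))
    if criterion == "any_snp_power":
        return bool(np.any(per_snp > 0.5))
    if criterion == "all_in_one_replicate":
        return power_all > 0.5
    raise ValueError(
        f"unknown detection criterion {criterion!r}; expected one of {DETECTION_CRITERIA}"
    )


def run_scenario(scenario: Scenario, detection: str = "per_snp_power") -> PowerResult:
    """Estimate detection powers for one scenario over its replicates."""
    rng = np.random.default_rng(scenario.seed)
    counts = simulate_counts(scenario, rng)
    sig_f = freq_design_detect(counts, scenario)
    sig_a = assoc_detect(counts, scenario, rng)

    per_f = sig_f.mean(axis=0)
    per_a = sig_a.mean(axis=0)
    all_f = float(sig_f.all(axis=1).mean())
    all_a = float(sig_a.all(axis=1).mean())
    return PowerResult(
        scenario=scenario,
        per_snp_power_freq=tuple(per_f),
        power_all_freq=all_f,
        power_any_freq=float(sig_f.any(axis=1).mean()),
        per_snp_power_assoc=tuple(per_a),
        power_all_assoc=all_a,
        power_any_assoc=float(sig_a.any(axis=1).mean()),
        detected_freq=_detected(per_f, all_f, detection),
        detected_assoc=_detected(per_a, all_a, detection),
    )


def run_grid(
    scenarios: Iterable[Scenario], detection: str = "per_snp_power"
) -> tuple[list[PowerResult], pd.DataFrame]:
    """Run many scenarios and summarise the detectable-k boundary.

    The summary has one row per (n_cohort, q, penetrance,
    nongenetic_fraction) condition, reporting the largest tested k for
    which the condition was detected, for both designs (0 when none).
    """
    results = [run_scenario(s, detection) for s in scenarios]
    rows = []
    for r in results:
        s = r.scenario
        rows.append(
            {
                "n_cohort": s.n_cohort,
                "q": s.q,
                "penetrance": s.penetrance,
                "nongenetic_fraction": s.nongenetic_fraction,
                "k": s.k,
                "min_per_snp_power_freq": min(r.per_snp_power_freq),
                "min_per_snp_power_assoc": min(r.per_snp_power_assoc),
                "detected_freq": r.detected_freq,
                "detected_assoc": r.detected_assoc,
            }
        )
    per_k = pd.DataFrame(rows)
    cond = ["n_cohort", "q", "penetrance", "nongenetic_fraction"]

    def _max_k(g: pd.DataFrame, col: str) -> int:
        det = g.loc[g[col], "k"]
        return int(det.max()) if len(det) else 0

    summary = (
        per_k.groupby(cond, sort=True)
        .apply(
            lambda g: pd.Series(
                {
                    "k_tested_max": int(g["k"].max()),
                    "max_k_detected_freq": _max_k(g, "detected_freq"),
                    "max_k_detected_assoc": _max_k(g, "detected_assoc"),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return results, summary


def power_table(results: Sequence[PowerResult]) -> pd.DataFrame:
    """Flat per-scenario power table (one row per scenario)."""
    rows = []
    for r in results:
        s = r.scenario
        rows.append(
            {
                "n_cohort": s.n_cohort,
                "q": s.q,
                "k": s.k,
                "penetrance": s.penetrance,
                "nongenetic_fraction": s.nongenetic_fraction,
                "replicates": s.replicates,
                "seed": s.seed,
                "min_per_snp_power_freq": min(r.per_snp_power_freq),
                "power_all_freq": r.power_all_freq,
                "power_any_freq": r.power_any_freq,
                "min_per_snp_power_assoc": min(r.per_snp_power_assoc),
                "power_all_assoc": r.power_all_assoc,
                "power_any_assoc": r.power_any_assoc,
                "detected_freq": r.detected_freq,
                "detected_assoc": r.detected_assoc,
            }
        )
    return pd.DataFrame(rows)


def scenarios_from_config(config: dict) -> list[Scenario]:
    """Expand a grid configuration into scenarios.

    ``config`` maps :class:`Scenario` field names to a value or a list
    of values; list-valued fields are expanded as a full grid. Each
    expanded scenario receives a distinct seed derived from the base
    ``seed`` entry (default 0).
    """
    base_seed = int(config.get("seed", 0))
    fields = {
        name: val
        for name, val in config.items()
        if name != "seed"
    }
    unknown = set(fields) - set(Scenario.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown scenario field(s): {sorted(unknown)}")
    lists = {
        name: (val if isinstance(val, (list, tuple)) else [val])
        for name, val in fields.items()
    }
    names = sorted(lists)
    scenarios = []
    seeds = np.random.SeedSequence(base_seed).generate_state(
        max(1, int(np.prod([len(lists[n]) for n in names])))
    ) % (2**31)
    for i, combo in enumerate(product(*(lists[n] for n in names))):
        kwargs = dict(zip(names, combo))
        scenarios.append(Scenario(seed=int(seeds[i]), **kwargs))
    return scenarios
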