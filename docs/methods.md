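# Methods

## The statistical model

`cohortaf` treats each catalogued SNP independently. In the reference
population the SNP's rare allele has frequency *q* (taken from the
catalogue and treated as fixed). In a phenotype cohort whose usable
genotypes contribute *n* presumed alleles at the locus, the observed
rare-allele count *x* is compared with its expectation *qn* by the df=1
chi-squared statistic X² = (x − qn)²/(nq(1−q)), algebraically identical
to Σ(O−E)²/E over the (rare, common) cells. No continuity correction is
applied. The upper-tail p-value of a df=1 chi-squared already responds
to deviation in either direction, so it is reported as the two-sided
p; the direction (enriched/depleted relative to *q*) is reported as a
separate column rather than folded into the test.

Two test modes exist. The default *goodness-of-fit* mode treats *q* as
exact — appropriate when the catalogue's sample is much larger than the
cohort. The *two-sample* mode instead builds the 2×2 allele-count table
of cohort vs catalogue (using the catalogue's `allele_number`) and
applies the contingency chi-squared without continuity correction; as
the catalogue's allele count grows this converges to the
goodness-of-fit p (the test suite checks agreement within 1% at 10⁶
catalogued alleles). Sites whose smaller expected cell falls below 1.0
are still tested but flagged `low_expected`; an exact binomial
companion p-value is available for flagged sites as an extension — the
chi-squared result remains the headline number.

### Allele counting

Presumed alleles per individual: 2 on autosomes and on X
pseudoautosomal regions (GRCh37 PAR1/PAR2 defaults, configurable), 1
for males on non-PAR X and on Y, 0 for females on Y. Genotypes come
from per-individual variant-calling VCFs; a catalogue SNP absent from a
sample's VCF is imputed homozygous-common (`ref_assumed`) under the
usual sites-only convention, demoted to `unknown` if the site's depth
is below the cutoff (default 20 reads, below which heterozygosity
cannot be reliably detected), or treated as `unknown` outright under
the `absent-is-unknown` policy when no depth data exist. Half calls
(`./1`) and missing genotypes are always `unknown`. A diploid call at a
hemizygous locus (e.g. male X called 1/1) is clipped to the locus
ploidy with a warning. Samples whose sex cannot be resolved contribute
their sex-chromosome loci as unknown alleles, counted at the maximal
ploidy so that the frequency bounds stay conservative.

### Missing data: frequency and p-value bounds

Unknown genotypes contribute no observed alleles; their ploidy is
accumulated as *u* unobserved alleles per SNP. Assigning all of them to
the common or rare allele gives

    freq_lower = x / (n + u),     freq_upper = (x + u) / (n + u),

which bracket the true cohort frequency. For p-values the package
reports the full attainable range over all integer allocations
*j* = 0..*u*: because X²(j) is convex in *j*, the smallest p occurs at
an extreme allocation while the largest occurs at the feasible count
nearest the expectation *q(n+u)* — which can be an interior allocation
whenever *q* lies strictly between the frequency bounds. Reporting the
true [min, max] over allocations (rather than only the two endpoint
tests) makes the documented guarantee — every possible allocation's
p-value lies inside the reported range — hold unconditionally; when *q*
falls outside the bounds the two coincide. The headline p remains the
observed-alleles-only test.

### Multiple testing

Bonferroni (*p·m* capped at 1) and step-up Benjamini–Hochberg q-values
are computed over the *m* SNPs actually tested per catalogue source;
untestable SNPs (no observed alleles, or catalogue frequency exactly 0
or 1) are excluded from *m* so that no correction budget is spent on
sites that cannot reject. A `correct-by-catalogue` switch instead uses
the full catalogue size, for users who want every catalogued SNP
charged to the budget; the BH implementation accepts this external *m*
directly (statsmodels' implementation, which cannot, is the independent
cross-check in the tests for the *m* = tested case). Significance
defaults to Bonferroni-corrected *p* < 0.01, configurable via `alpha`.

### Sex inference

Sex is inferred per sample from the heterozygous fraction *h* of called
non-PAR X genotypes: *h* < 0.05 → male, *h* > 0.20 → female, otherwise
(or with fewer than `min_x_calls` = 50 called X genotypes) ambiguous.
The thresholds are design choices — true male X heterozygosity is
essentially zero apart from call errors, while female exome X
heterozygosity is far above 20% at catalogue SNPs — and are
configurable, as is the minimum call count (small catalogues need a
lower minimum; the bundled examples use 3–5). Inferred counts are
checked against the declared male/female totals: a disagreement is a
warning by default and fatal under `strict`.

## Catalogues

Catalogues load from a tab-separated table or a sites-VCF with a
frequency INFO key (default `AF`). Multi-allelic sites are expanded to
one entry per alternate allele with its own frequency; a compatibility
switch (`evs_lowest_allele`) reproduces a historical catalogue parser's
defect of keeping only the lowest-frequency alternate, so analyses that
depended on that behaviour can be replicated. Rows with frequency above
0.5 are re-oriented (alleles swapped, f → 1−f) with a warning, keeping
the invariant that the catalogued rare allele is the minor allele.
Catalogue matching — both between two catalogues and between catalogue
and cohort — is by (chromosome, position, rare allele), not by rsID,
since identifiers differ across catalogue releases. Two catalogues'
shared SNPs are *discordant* when their frequencies differ by strictly
more than the threshold (default 5 percentage points).

When several catalogues are supplied, the pipeline reports one fully
independent result set per catalogue (own test, own *m*, own
significance calls): discrepancies between references then surface as
SNPs significant against one catalogue only.

## Power simulation

The simulation asks when the frequency design beats an idealised
case-control association study. Per replicate, a cohort of `n_cohort`
individuals is generated under a heterozygous-dominant model:
`round(n·(1−nongenetic_fraction))` genetic cases, each causal with
probability `penetrance`; causal cases are assigned uniformly at random
to one of *k* interchangeable causative SNPs and carry one rare allele
there; every chromosome not carrying an assigned causal allele draws a
background rare allele independently at frequency *q*. Non-causative
catalogue SNPs enter only through the correction denominator
`m_correction` (default 121,000, a typical count of catalogued exome
SNPs). The uniform assignment, dominant carriers and independent
background are modelling choices; all are explicit scenario
parameters.

Detection: the frequency design tests each causative SNP's counts
against *q* (goodness of fit, Bonferroni over `m_correction`,
corrected α = 0.01); the association comparator draws an equal-sized
control cohort at frequency *q* and applies the 2×2 allele-count
chi-squared at a raw genome-wide threshold of 10⁻⁸. A scenario counts
as *detected* when every causative SNP's per-replicate detection
fraction exceeds 0.5; any-SNP and all-in-one-replicate criteria are
selectable. Grid summaries report, per condition, the largest tested
*k* that was detected; with power monotone in *k* this is also the
boundary of the detected range. Scenarios are fully seeded and
bit-reproducible; the bundled grids use 1000 replicates, which bounds
the Monte-Carlo standard error of a power estimate by ~0.016.

Under this design the association comparator at n=100 still detects
very small *k* (an overwhelming single-SNP signal), and boundaries for
stressed conditions (n=30, half non-genetic, half penetrance) land
above the most conservative published-style expectations; the
generative details behind such historical tables are not recoverable,
so the grid is parameterised to bracket them and the run report prints
the computed boundary for comparison rather than asserting it.

## Synthetic cohorts

The fixtures generator draws a catalogue (autosome/X/Y mix, frequencies
uniform on [0.05, 0.40] by default, allele number 10,000), then
genotypes each sample as Binomial(ploidy, true frequency) — males are
haploid on non-PAR X, so male X heterozygosity is structurally zero. By
default the true cohort frequency equals the catalogue frequency (a
null cohort); *spiked* SNPs override it to create known signals.
`missingness` independently masks genotypes; masked sites are omitted
from the written VCF *and* given sub-cutoff depth in the written depth
table, so the on-disk cohort reproduces the in-memory truth exactly
after depth filtering (a test asserts this round trip). Depths at
usable sites are `cutoff + Poisson(depth_mean − cutoff)`, which keeps
coverage consistent with call status by construction — the generator
validates the pipeline's bookkeeping, not depth realism. Not emulated:
linkage disequilibrium, genotype-calling error, batch effects between
capture kits; passing tests therefore demonstrate correctness of the
counting and testing machinery, not robustness to real-data artefacts.

## Numerical and policy choices

- Chi-squared p-values come from `scipy.stats.chi2.sf`; statistics are
  computed in closed form and verified against the literal Σ(O−E)²/E
  to relative 1e-10.
- Degenerate 2×2 margins give X² = 0, p = 1.
- Ties: a frequency difference of exactly the discordance threshold is
  concordant; depth exactly at the cutoff passes; a gene mean depth of
  exactly cutoff−1 (19.0) is *not* adequately covered (strict >).
- The significance policy is corrected *p* < α with α = 0.01 by
  default; α is a flag because reasonable analyses differ here.
- Exon census: per-exon means average over all (base, sample) pairs;
  per-gene means deduplicate bases shared by overlapping exons.
- Coordinates are 1-based (VCF convention) internally; BED input is
  converted at the parser.

## Limitations

- Only depth is checked at SNP sites; base and mapping quality are out
  of scope, as is duplicate-read handling.
- Joint/multi-sample VCFs are not supported — the design is one
  variant-calling VCF per individual.
- No Hardy–Weinberg checks, imputation, linkage-disequilibrium
  modelling, or covariate-adjusted association models.
- Mitochondrial sites are not treated specially (an exome capture does
  not target them); pathogenicity predictions are consumed as boolean
  annotations, never computed.
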