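"""Power comparison: frequency-vs-catalogue testing against a
case-control association design.

Simulates cohorts in which k interchangeable causative SNPs (each at
population frequency q) fully explain the phenotype, and asks up to
which k each design still detects every causative SNP (per-SNP power
above 0.5). The frequency design tests the cohort against the
catalogue frequency with Bonferroni correction over 121,000 SNPs at
corrected alpha 0.01; the association design tests the cohort against
an equal-sized simulated control group at a raw genome-wide threshold
of 1e-8.
"""

import cohortaf as ca

for n_cohort, q in ((100, 0.005), (100, 0.01), (3000, 0.01)):
    scenarios = [
        ca.Scenario(n_cohort=n_cohort, q=q, k=k, replicates=500, seed=40 + k)
        for k in range(1, 11)
    ]
    _, summary = ca.run_grid(scenarios)
    row = summary.iloc[0]
    print(
        f"n={n_cohort:5d} q={q}: frequency design detects k<="
        f"{int(row['max_k_detected_freq'])}, association detects k<="
        f"{int(row['max_k_detected_assoc'])} (of k<=10 tested)"
    )
# The frequency design keeps its power at small cohort sizes because it
# needs no control group: the catalogue supplies the expectation. The
# association comparator requires thousands of samples to reach its
# genome-wide threshold once the signal is split across several SNPs.
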