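"""Comparing two reference catalogues.

Reference populations disagree: different sampling, different
ancestries, occasionally different variant processing. Before testing
a cohort it is worth knowing how far two candidate catalogues diverge.
This example builds two overlapping catalogues and counts SNPs whose
rare-allele frequencies differ by more than 5 percentage points.
"""

import numpy as np
import pandas as pd

import cohortaf as ca

rng = np.random.default_rng(2)
n = 200


def build(freqs, label):
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "snp_id": [f"rs{i}" for i in range(n)],
            "ref_allele": "A",
            "rare_allele": "G",
            "rare_freq": freqs,
            "allele_number": 10_000,
            "source": label,
        }
    )


base = rng.uniform(0.02, 0.45, size=n)
# most SNPs agree within sampling noise; a minority diverge strongly
noise = rng.normal(0.0, 0.01, size=n)
divergent = rng.random(n) < 0.15
noise[divergent] += rng.choice([-1, 1], divergent.sum()) * rng.uniform(
    0.06, 0.15, divergent.sum()
)
other = np.clip(base + noise, 0.001, 0.499)

comparison = ca.compare_catalogues(build(base, "popA"), build(other, "popB"),
                                   threshold=0.05)
print(f"shared SNPs: {comparison.n_shared}")
print(f"discordant (|freq difference| > {comparison.threshold:.0%}): "
      f"{comparison.n_discordant} ({comparison.discordant_fraction:.1%})")
print(f"first discordant IDs: {list(comparison.discordant_ids[:5])}")
# Testing a cohort against both catalogues and reporting two result
# sets surfaces findings that depend on the choice of reference.
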