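"""Estimate the number of (female) founders from mtDNA haplotype counts.

Draws N founders with replacement from the source haplotype distribution
and tabulates the probability that exactly k haplotypes (the number seen
in the introduced population) are represented, for N = 2..20. The exact
inclusion-exclusion values are attached alongside the simulation.
"""

import numpy as np

from founderflow import (SimulationScenario, mito_founder_estimate,
                         sample_dataset)

table, hapset, truth = sample_dataset(SimulationScenario(seed=1))
src = truth["true_source"]
k_obs = int(np.sum(hapset.counts["INTRO"] > 0))
print(f"haplotypes observed in the introduced population: {k_obs}")

result = mito_founder_estimate(hapset.counts[src], k_observed=k_obs,
                               founder_range=range(2, 21),
                               trials=100_000, seed=3,
                               source_label=src)
for N, sim, exact in zip(result.founder_range, result.prob_k,
                         result.exact_prob_k):
    print(f"N={N:2d}  simulated={sim:.4f}  exact={exact:.4f}")
print(f"\nmost supported founder number: {result.mle_N} "
      f"({result.metadata['interpretation']})")
print("The curve peaks where N founders most plausibly carry exactly "
      f"{k_obs} haplotypes; mtDNA underestimates the census founder count "
      "because only maternal lineages are counted and post-founding drift "
      "is ignored.")
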