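"""Estimate the effective founder number from microsatellite data.

Profiles the Monte Carlo likelihood of the introduced sample over
candidate founder numbers N0 under a founding-bottleneck +
logistic-growth Wright-Fisher model, then sweeps the assumed demography
(carrying capacity K, growth rate r) to show how the assumption about
early growth shifts the estimate.
"""

from founderflow import (SimulationScenario, demographic_sweep,
                         founder_grid_likelihood, sample_dataset)
from founderflow.founder_nuclear import sample_allele_counts

scenario = SimulationScenario(seed=1, nuclear_sample_sizes=(70,) * 10)
table, _, truth = sample_dataset(scenario)
src = sample_allele_counts(table, truth["true_source"])
intro = sample_allele_counts(table, "INTRO")

est = founder_grid_likelihood(src, intro, K=2000, r=1.5, t=10,
                              grid=range(2, 41), M=1000, seed=1)
print(f"true N0 = {truth['true_N0']}")
print(f"MLE = {est.mle}, 2-log-likelihood support limits = "
      f"{est.support_limits}")

sweep = demographic_sweep({truth["true_source"]: src}, intro,
                          K_values=[500, 2000, 8000],
                          r_values=[0.5, 1.0, 2.0], t=10,
                          grid=range(2, 41), M=1000, seed=2)
print("\nestimate vs assumed demography:")
print(sweep.table().to_string(index=False))
print("Slow assumed growth (r=0.5) attributes more drift to the "
      "post-founding generations and therefore yields a larger founder "
      "estimate; at r >= 1 the estimate settles near the true value.")
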