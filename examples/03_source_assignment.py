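"""Identify the source population of the introduced sample.

Pairwise Weir-Cockerham theta ranks candidate sources by genetic
similarity; a neighbor-joining tree on Cavalli-Sforza chord distances
(with locus-bootstrap support) shows the same structure as a tree.
"""

from founderflow import (SimulationScenario, assign_source, fst_matrix,
                         neighbor_joining_with_bootstrap, sample_dataset)

table, _, truth = sample_dataset(SimulationScenario(seed=1))

fst = fst_matrix(table)
ranking = assign_source(fst, "INTRO")
print(ranking.to_string(index=False))
print(f"\ntrue source was {truth['true_source']}; "
      f"top-ranked: {ranking.iloc[0]['population']} "
      f"(theta = {ranking.iloc[0]['theta']:.4f})")

tree = neighbor_joining_with_bootstrap(table, reps=200, seed=0)
print("\nNJ tree (bootstrap % on internal branches):")
print(tree.newick)
print("Low theta against INTRO and shared tree position both point at the "
      "source; other candidates sit at theta ~ 0.2-0.5.")
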