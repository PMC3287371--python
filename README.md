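# founderflow

Invasion-genetics analysis for introduced populations: identify the most
likely source population and estimate the effective number of founding
individuals from microsatellite genotypes and mtDNA haplotypes.

When a population is established by a handful of colonists, the founding
bottleneck leaves a characteristic genetic signature: allelic and haplotype
richness drop sharply while heterozygosity barely moves, and the new
population drifts away from its source. `founderflow` quantifies that
signature and inverts it:

- **Diversity summaries** per population: proportion of polymorphic loci
  *P*, mean alleles per locus *A*, rarefied allelic richness *A*<sub>R</sub>
  and private allelic richness *A*<sub>p</sub> standardized to *g* gene
  copies (default 26), observed and Nei unbiased expected heterozygosity
  *H*<sub>O</sub>/*H*<sub>E</sub>; haplotype diversity *h* and nucleotide
  diversity π for mtDNA, plus between-population mean pairwise nucleotide
  differences.
- **Source assignment**: pairwise Weir–Cockerham θ (FST) with
  genotype-permutation significance tests, Cavalli-Sforza chord distances,
  unrooted neighbor-joining trees with locus-bootstrap support, and a
  ranking of candidate sources by similarity to the introduced population.
- **Nuclear founder-number MLE**: the likelihood of the introduced sample
  under a model in which *N*<sub>0</sub> diploid founders are drawn from
  the source, and allele frequencies then drift by Wright–Fisher
  resampling along a logistic growth trajectory
  *N*(*g*) = *K N*<sub>0</sub>e<sup>*rg*</sup>/(*K* + *N*<sub>0</sub>(e<sup>*rg*</sup> − 1))
  for *t* generations. The likelihood is profiled over a grid of
  *N*<sub>0</sub> (Monte Carlo, importance-sampled), with support limits at
  2 log-likelihood units, and swept over the assumed demography
  (*K* ∈ {500…16,000}, *r* ∈ {0.5…3.0}).
- **Mitochondrial founder simulation**: the probability that *N* founders
  drawn with replacement from the source haplotype distribution carry
  exactly *k* haplotypes (the number observed in the introduced
  population), tabulated for *N* = 2..20 by simulation (100,000 trials) and
  by exact inclusion–exclusion.
- **Synthetic data**: a generator producing source panels
  (Balding–Nichols divergence) plus a founded population with known ground
  truth, so every estimator is testable by parameter recovery.

## Worked example

```python
from founderflow import (SimulationScenario, sample_dataset, fst_matrix,
                         assign_source, founder_grid_likelihood)
from founderflow.founder_nuclear import sample_allele_counts

# a synthetic study: 9 candidate sources, 7 microsatellite loci, one
# population founded from S1 by 10 individuals, 10 generations ago
table, hapset, truth = sample_dataset(
    SimulationScenario(seed=1, nuclear_sample_sizes=(70,) * 10))

ranking = assign_source(fst_matrix(table), "INTRO")
print(ranking.head(3)[["population", "theta"]])
#   population     theta
# 0         S1  0.027375
# 1         S3  0.259734
# 2         S2  0.281377

est = founder_grid_likelihood(
    sample_allele_counts(table, "S1"),
    sample_allele_counts(table, "INTRO"),
    K=2000, r=1.5, t=10, grid=range(2, 41), M=1000, seed=1)
print(est.mle, est.support_limits)
# 8 (6, 11)
```

The θ ranking puts the true source (θ ≈ 0.03) far below every other
candidate (θ ≈ 0.26–0.36), and the founder-number profile likelihood peaks
at 8 with 2-log-likelihood support limits (6, 11), covering the true
founder number of 10.
Longer narrative walkthroughs — one per capability — live in `examples/`.

A thin CLI wraps the same functions:

```sh
founderflow simulate --seed 1 --outdir data/
founderflow diversity data/genepop.txt data/haps.fasta data/popmap.tsv -o table.csv
founderflow differentiate data/genepop.txt --introduced INTRO -o out/
founderflow founders-nuclear data/genepop.txt --source S1 --introduced INTRO -o sweep.csv
founderflow founders-mito data/haps.fasta data/popmap.tsv --source S1 --introduced INTRO -o curve.csv
founderflow run --genepop data/genepop.txt --introduced INTRO --outdir report/
```

## Layout

- `src/founderflow/io_formats.py` — Genepop / FASTA+popmap / CSV / JSON /
  Newick readers and writers, core containers, run configuration
- `src/founderflow/synthetic.py` — ground-truth dataset generator
- `src/founderflow/diversity.py` — nuclear and mtDNA diversity statistics
- `src/founderflow/differentiation.py` — θ, permutation tests, chord
  distances, NJ + bootstrap, source ranking
- `src/founderflow/founder_nuclear.py` — bottleneck + logistic-growth
  likelihood, demographic sweep
- `src/founderflow/founder_mito.py` — haplotype founder-draw simulation
  and exact pmf
- `src/founderflow/pipeline.py` — end-to-end orchestration and reports
- `docs/methods.md` — model assumptions, numerical choices, limitations
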