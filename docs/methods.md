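# Methods

## The inference problem

An introduced population was founded from one of several candidate source
populations by an unknown number of colonists, some generations ago. Given
diploid microsatellite genotypes from the introduced population and the
candidates, plus aligned mtDNA haplotype sequences, the package answers
three questions: which candidate is the source, how severe was the founding
bottleneck (diversity loss), and how many effective founders were there.

## Diversity statistics

Per population and locus, with n the number of individuals scored:

- Observed heterozygosity Ho = fraction of heterozygous genotypes.
- Expected heterozygosity He = (2n/(2n−1))(1 − Σ p²), Nei's unbiased
  small-sample form (the convention of the standard population-genetics
  packages this mirrors).
- Rarefied allelic richness A_R at g gene copies: Σ_a [1 − C(N−N_a, g)/C(N, g)],
  the expected allele count of a random g-gene subsample, computed with
  log-gamma arithmetic. Default g = 26 genes (13 diploids), matching the
  smallest sample in the emulated study design; loci/populations with fewer
  than g genes are excluded from the mean with a logged warning rather than
  failing, since partial tables are still useful.
- Private allelic richness A_p: for each allele, the probability it appears
  in the focal population's g-gene subsample times the probability it is
  absent from every other population's g-gene subsample (independent
  hypergeometric draws), summed over alleles and averaged over loci. This
  is the rarefied ("standardized") private-allele quantity; raw private
  allele counts are sample-size-biased in exactly the way rarefaction
  removes.
- Haplotype diversity h = (n/(n−1))(1 − Σ p²) with Nei's variance formula
  for its SD. Nucleotide diversity π = (n/(n−1)) Σ p_i p_j d_ij / L, per
  site; its SD uses the total variance including the stochastic
  (evolutionary) term. Between-population differences Σ p_i^A p_j^B d_ij
  are reported raw (not per site), so within- and between-population
  quantities sit on the two scales practitioners expect from paired
  diversity/distance tables.
- A_R/A_p means use across-locus SDs; Ho/He SDs are across loci as well.

## Differentiation and source assignment

FST is the Weir & Cockerham (1984) θ: per locus and allele the variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from allele frequencies, sample
sizes and heterozygote frequencies; the multi-locus estimate is
Σa / Σ(a+b+c) with components summed over alleles and loci (ratio of sums,
not mean of ratios — the convention of FSTAT-style software). Loci
monomorphic across the pair are skipped; a pair with no usable locus gets
NaN, never 0. Significance is by permuting whole multilocus genotypes
between the two samples (individual-level permutation; allele-level
permutation would break within-individual correlation) with
p = (1 + #{θ* ≥ θ}) / (reps + 1), so p is never exactly zero.

The chord distance per locus is d_l = 1 − Σ_a √(x_a y_a), averaged over
loci. Any positive scalar multiple of this quantity leaves neighbor-joining
topology unchanged, so the constant is fixed at 1. Trees are Saitou–Nei NJ
(via scikit-bio) with negative branch lengths clamped to zero; bootstrap
support resamples loci with replacement (the natural resampling unit for a
multilocus distance), rebuilds the tree, and scores each internal
bipartition of the point-estimate tree. With 7 loci the support granularity
is necessarily coarse — documented, not hidden.

Source ranking orders candidates by ascending θ against the introduced
population, breaking exact ties by mtDNA mean pairwise differences when
available; NaN entries rank last and residual ties share a rank.

## Nuclear founder-number likelihood

Model: N0 diploid founders contribute 2·N0 gene copies drawn multinomially
from the source allele frequencies; the population then follows the
continuous-logistic size trajectory N(g) = K·N0·e^{rg}/(K + N0(e^{rg}−1)),
rounded to integers, and allele frequencies drift by multinomial
Wright–Fisher resampling of 2·N(g) copies each generation g = 1..t.
The continuous solution is used rather than a discrete Ricker update
because the discrete map oscillates for r near 3, which the demographic
sweep must cover; the continuous form is monotone for all r > 0. Mutation
is ignored: at t ≈ 10 generations microsatellite mutation contributes
negligibly. K, r and t are inputs, not estimands — the sweep over
K ∈ {500, 1000, 2000, 4000, 8000, 16000} and r ∈ {0.5, 1.0, 1.5, 2.0, 3.0}
at t = 10 exposes how the demographic assumption moves the estimate.

Source frequencies are estimated from the source sample counts with an
unobserved-allele rule: an allele present in the introduced sample but
missing from the source sample receives one pseudo-copy, since a zero
source frequency would make the data impossible by source sampling error
alone. Loci monomorphic across both samples are excluded (they carry no
founder-number information).

The per-locus likelihood P(introduced counts | N0) is an expectation over
founder draws and drift paths of the multinomial probability of the
observed counts given the final frequencies. A naive forward simulation
estimates this expectation with variance spanning tens of log-units,
because the multinomial weight is exponentially peaked in the distance
between simulated and observed frequencies. The estimator therefore uses
guided importance sampling, which is unbiased for the identical
expectation:

- founder pools are proposed from a 0.7/0.3 mixture of the observed
  introduced frequencies and the source frequencies, reweighted by the
  exact multinomial density ratio;
- each drift generation proposes from a bridge q = (1−λ_g)·f + λ_g·p_obs,
  where λ_g is generation g's share 1/(2N(g)) of the drift-plus-sampling
  variance remaining, again with exact reweighting;
- the same per-locus random streams are reused across the N0 grid (common
  random numbers), so the shape of the profile is smoother than its level.

With M = 1000 replicates per (locus, N0) the log-likelihood noise is below
about one unit (measured), versus 2–10 units for the naive estimator.
Replicates that lose an allele the observation requires get exactly zero
weight; N0 values whose 2·N0 gene copies cannot carry all observed alleles
have a structural zero likelihood and are reported as −inf.

The MLE is the grid argmax (default grid N0 = 2..40, covering the plausible
range with headroom) and support limits are the extreme grid values within
2 log-likelihood units of the maximum — the conventional likelihood-support
definition. A boundary MLE is flagged.

## Mitochondrial founder simulation

N founder individuals are drawn with replacement from the source haplotype
distribution; the statistic is P(exactly k distinct haplotypes), with k the
haplotype count observed in the introduced population, profiled over
N = 2..20 (100,000 trials per N by default). The exact value
Σ_{|S|=k} Σ_{T⊆S} (−1)^{k−|T|}(Σ_{i∈T} p_i)^N is attached whenever the
source carries ≤ 20 haplotypes and serves as a permanent cross-check on
the simulation pathway. A pooled-source mode sums several populations'
count vectors to absorb haplotype sampling error in any single candidate.

Interpretation caveats, recorded in the result metadata: the estimate
counts female-equivalent founders (maternal inheritance), and post-founding
drift is deliberately not modeled, so haplotypes present at founding but
later lost are not accounted for — both biases push the mtDNA estimate
below the nuclear one, which is the expected ordering, not a
contradiction.

## Synthetic data generator

The generator's defaults emulate a realistic field design of this kind: nine
source populations plus one introduced population, seven microsatellite
loci with 6–48 alleles each, nuclear sample sizes (28, 27, 68, 59, 71, 15,
33, 124, 66, 71) and mtDNA sample sizes (16, 24, 15, 16, 16, 15, 23, 31,
15, 15), a 759-bp mtDNA alignment, and a founding event of N0 = 10
individuals t = 10 generations ago with r = 1.5, K = 2000.

Source allele frequencies follow the Balding–Nichols model: per locus an
ancestral vector from a symmetric Dirichlet(1), then per population a
Dirichlet draw with mean the ancestral vector and concentration (1−F)/F.
The drift parameter F equals the expected pairwise Weir–Cockerham θ
between sources (verified by simulation); the default F = 0.3 places
between-source θ in the 0.2–0.5 band typical of strongly structured
freshwater fishes, while the founded population sits at θ ≈ 0.03–0.08 from
its true source — the regime in which source assignment is informative but
not trivial. Genotypes are assembled from two independent gene copies
(Hardy–Weinberg); no missing data are simulated.

mtDNA haplotype pools are shallow clades: each source population's
haplotypes differ from a population seed sequence by 1–3 substitutions,
and the seeds differ from a common ancestral sequence by 15–30, giving
small within-population and large between-population pairwise differences.
The introduced population's haplotype distribution is the realized founder
draw itself (no post-founding mtDNA drift), matching the assumption of the
mito estimator.

What the generator does not emulate: null alleles, allele dropout and
scoring error; missing genotypes; microsatellite mutation; migration among
sources; age structure or overlapping generations; selection. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to these real-data complications.

## Numerical choices and degenerate inputs

- Rarefaction uses log-gamma binomials; g > N excludes the locus (logged).
- Permutation p-values use the +1 correction; a ≥ comparison with a 1e-12
  slack avoids float-equality artifacts on degenerate relabelings.
- NJ negative branch lengths are clamped to zero (logged by scikit-bio's
  convention); 3-taxon inputs return the unique unrooted topology.
- The likelihood grid reports −inf for structurally impossible N0 rather
  than dropping the grid point.
- All Monte Carlo stages accept either an integer seed or a numpy
  Generator; the pipeline derives independent child streams per stage from
  one master seed, so whole-report runs are reproducible bit-for-bit.
- Test and acceptance problem sizes (20 recovery replicates at M = 1000;
  50 ranking replicates; 100,000 mtDNA trials) were chosen as the smallest
  sizes at which the Monte Carlo error is clearly below the effect sizes
  being checked.

## Known limitations

- The nuclear likelihood conditions on the point estimate of source
  frequencies (plus the pseudo-count rule) rather than integrating over
  source-frequency uncertainty; with source samples of ~70 individuals
  this is a second-order effect, but with very small source samples the
  support limits will be anti-conservative.
- Support limits come from a Monte Carlo profile; residual noise of up to
  ~1 log-unit can shift the limits by a grid step or two.
- The bootstrap on 7 loci has coarse support granularity.
- The mtDNA estimator ignores post-founding drift by construction and
  estimates female-equivalent founders.
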