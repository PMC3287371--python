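"""Maximum-likelihood founder-number estimation from nuclear genotypes.

Model: an introduced population is founded by N0 diploid individuals drawn
from a source population, then grows deterministically along a logistic
trajectory toward carrying capacity K at intrinsic rate r while allele
frequencies drift by Wright-Fisher resampling each generation. The
likelihood of the observed introduced-population sample is estimated by
forward Monte Carlo: simulate the founding + t generations of drift many
times and average the multinomial probability of the observed allele counts
over replicates. The log-likelihood is summed over loci and profiled over a
grid of candidate N0; support limits are the extreme grid values within two
log-likelihood units of the maximum.

Mutation is ignored (the post-founding horizon is ~10 generations) and K,
r and t are inputs, not estimands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


@dataclass
class DemographicModel:
    """Founding-bottleneck + logistic-growth demography."""

    N0: int
    K: int
    r: float
    t: int

    def __post_init__(self) -> None:
        if not (1 <= self.N0 <= self.K):
            raise ValueError("require 1 <= N0 <= K")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.t < 0:
            raise ValueError("t must be non-negative")


@dataclass
class FounderEstimate:
    """Profile log-likelihood over candidate founder numbers."""

    grid: list[int]
    loglik: np.ndarray
    mle: int
    support_limits: tuple[int, int]
    excluded_loci: list[str] = field(default_factory=list)
    at_boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "grid": list(self.grid),
            "loglik": [float(x) for x in self.loglik],
            "mle": int(self.mle),
            "support_limits": [int(x) for x in self.support_limits],
            "excluded_loci": list(self.excluded_loci),
            "at_boundary": bool(self.at_boundary),
        }


def logistic_trajectory(model: DemographicModel) -> np.ndarray:
    """Per-generation effective sizes N(0..t).

    The continuous logistic solution N(g) = K N0 e^{rg} / (K + N0(e^{rg}-1))
    evaluated at integer generations and rounded; monotone non-decreasing
    and bounded by K for every r (unlike a discrete Ricker update, which
    oscillates for r near 3).
    """
    g = np.arange(model.t + 1)
    e = np.exp(model.r * g)
    N = model.K * model.N0 * e / (model.K + model.N0 * (e - 1.0))
    N = np.round(N).astype(int)
    N[0] = model.N0
    return np.minimum.accumulate(np.maximum.accumulate(N)[::-1])[::-1]


def simulate_post_founding_freqs(source_freqs: np.ndarray,
                                 model: DemographicModel,
                                 rng: np.random.Generator,
                                 n_reps: int = 1) -> np.ndarray:
    """Simulate final-generation allele frequencies at one locus.

    Founder pool: multinomial draw of 2*N0 gene copies from the source
    frequencies; then each generation g = 1..t resamples 2*N(g) copies from
    the previous generation's frequencies. Returns an (n_reps, n_alleles)
    array of final frequencies.
    """
    traj = logistic_trajectory(model)
    p = np.broadcast_to(np.asarray(source_freqs, dtype=float),
                        (n_reps, len(source_freqs)))
    counts = rng.multinomial(2 * model.N0, p)
    freqs = counts / (2.0 * model.N0)
    for g in range(1, model.t + 1):
        genes = int(2 * traj[g])
        counts = rng.multinomial(genes, freqs)
        freqs = counts / genes
    return freqs


def _source_frequencies(source_counts: Mapping[int, int],
                        introduced_counts: Mapping[int, int],
                        locus: str = "?") -> tuple[list[int], np.ndarray]:
    """Source allele frequencies with the unobserved-allele pseudocount.

    An allele seen in the introduced sample but absent from the source
    sample gets one pseudo-copy in the source counts before normalization;
    otherwise a single unlucky source sample would force a zero likelihood.
    """
    alleles = sorted(set(source_counts) | set(introduced_counts))
    counts = np.array([source_counts.get(a, 0) for a in alleles], dtype=float)
    missing = [a for a, c in zip(alleles, counts)
               if c == 0 and introduced_counts.get(a, 0) > 0]
    if missing:
        logger.info("locus %s: alleles %s absent from source; one pseudo-copy "
                    "each added", locus, missing)
        for a in missing:
            counts[alleles.index(a)] = 1.0
    return alleles, counts / counts.sum()


def _multinomial_logpmf(obs: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """log P(obs | freqs) for each row of freqs; -inf where impossible."""
    n = int(obs.sum())
    log_coef = gammaln(n + 1) - float(gammaln(obs + 1).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = obs * np.log(freqs)
    lp = np.where(obs == 0, 0.0, lp)
    return log_coef + lp.sum(axis=1)


def _locus_loglik_guided(p: np.ndarray, obs: np.ndarray, N0: int,
                         traj: np.ndarray, M: int,
                         rng: np.random.Generator,
                         founder_mix: float = 0.7) -> float:
    """Guided (importance-sampled) Monte Carlo estimate of
    log P(obs | N0, trajectory) for one locus.

    The estimand is the expectation, over founder draws and Wright-Fisher
    drift, of the multinomial probability of the observed allele counts
    given the final-generation frequencies. A naive forward simulation
    estimates it with enormous variance (the multinomial weight spans tens
    of log-units across drift paths), so replicates are simulated from a
    guided proposal and reweighted exactly, which leaves the estimator
    unbiased for the same quantity:

    * founder pools are drawn from a mixture of the source frequencies and
      the observed introduced frequencies (``founder_mix`` on the latter);
    * each drift generation resamples from a bridge that pulls frequencies
      toward the observation in proportion to that generation's share
      1/(2 N_g) of the drift variance remaining before sampling.

    Replicates that lose an allele required by the observation get zero
    weight automatically. Returns -inf when no replicate is compatible
    (e.g. 2*N0 gene copies cannot carry all observed alleles — a structural
    zero of the model).
    """
    t = len(traj) - 1
    n_obs = obs.sum()
    p_obs = obs / n_obs
    q0 = founder_mix * p_obs + (1.0 - founder_mix) * p
    counts = rng.multinomial(2 * N0, np.broadcast_to(q0, (M, len(p))))
    with np.errstate(divide="ignore", invalid="ignore"):
        lw = counts @ (np.log(p) - np.log(q0))
    freqs = counts / (2.0 * N0)
    step_var = [1.0 / (2.0 * traj[g]) for g in range(1, t + 1)]
    for g in range(1, t + 1):
        genes = int(2 * traj[g])
        remaining = sum(step_var[g - 1:]) + 1.0 / n_obs
        lam = step_var[g - 1] / remaining
        q = (1.0 - lam) * freqs + lam * p_obs
        q /= q.sum(axis=1, keepdims=True)
        c = rng.multinomial(genes, q)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(c > 0, c * (np.log(freqs) - np.log(q)), 0.0)
        lw = lw + inc.sum(axis=1)
        freqs = c / genes
    lp = _multinomial_logpmf(obs, freqs)
    val = logsumexp(lw + lp) - math.log(M)
    return float(val) if np.isfinite(val) else -np.inf


def founder_grid_likelihood(source_sample: Mapping[str, Mapping[int, int]],
                            introduced_sample: Mapping[str, Mapping[int, int]],
                            K: int, r: float, t: int,
                            grid: Sequence[int] | None = None,
                            M: int = 1000,
                            seed: int | np.random.Generator = 0
                            ) -> FounderEstimate:
    """Monte Carlo profile likelihood of the founder number N0.

    ``source_sample`` and ``introduced_sample`` map locus id -> allele
    gene-copy counts. For each candidate N0, each locus's sampling
    probability is the probability of the observed introduced counts under
    founder sampling + logistic-growth Wright-Fisher drift, estimated by
    guided Monte Carlo over M replicates (see :func:`_locus_loglik_guided`);
    the log-likelihood sums over loci. Loci monomorphic across both samples
    carry no founder-number information and are excluded. The same
    per-locus random streams are reused across grid points (common random
    numbers), so the profile's shape is less noisy than its level.
    """
    if M < 100:
        raise ValueError("M must be >= 100")
    grid = list(grid) if grid is not None else list(range(2, 41))
    if not grid:
        raise ValueError("empty candidate grid")
    if isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(int(seed.integers(2 ** 31)))
    else:
        ss = np.random.SeedSequence(seed)

    excluded: list[str] = []
    usable: list[tuple[str, np.ndarray, np.ndarray]] = []
    for locus in source_sample:
        src = source_sample[locus]
        intro = introduced_sample.get(locus, {})
        alleles = sorted(set(src) | set(intro))
        observed = {a for a in alleles
                    if src.get(a, 0) > 0 or intro.get(a, 0) > 0}
        obs = np.array([intro.get(a, 0) for a in alleles], dtype=float)
        if len(observed) < 2 or obs.sum() == 0:
            excluded.append(locus)
            logger.info("locus %s uninformative (monomorphic or no introduced "
                        "data); excluded", locus)
            continue
        _, p = _source_frequencies(src, intro, locus)
        usable.append((locus, p, obs))
    if not usable:
        raise ValueError("no informative locus")
    locus_seeds = dict(zip((loc for loc, _, _ in usable),
                           ss.spawn(len(usable))))

    loglik = np.zeros(len(grid))
    for gi, N0 in enumerate(grid):
        model = DemographicModel(N0=N0, K=K, r=r, t=t)
        traj = logistic_trajectory(model)
        total = 0.0
        for locus, p, obs in usable:
            rng = np.random.default_rng(locus_seeds[locus])
            ll = _locus_loglik_guided(p, obs, N0, traj, M, rng)
            if ll == -np.inf:
                logger.debug("locus %s: zero likelihood at N0=%d", locus, N0)
                total = -np.inf
                break
            total += ll
        loglik[gi] = total

    if not np.any(np.isfinite(loglik)):
        raise ValueError("likelihood vanished on the whole grid")
    best = int(np.nanargmax(loglik))
    inside = [g for g, ll in zip(grid, loglik) if ll >= loglik[best] - 2.0]
    est = FounderEstimate(
        grid=grid,
        loglik=loglik,
        mle=grid[best],
        support_limits=(min(inside), max(inside)),
        excluded_loci=excluded,
        at_boundary=best in (0, len(grid) - 1),
    )
    if est.at_boundary:
        logger.warning("founder MLE at grid boundary (N0=%d)", est.mle)
    return est


@dataclass
class SweepResult:
    """Founder estimates over the (source, K, r) cross-product at fixed t."""

    t: int
    cells: dict[tuple[str, int, float], FounderEstimate | None]

    def table(self) -> "object":
        import pandas as pd

        rows = []
        for (source, K, r), est in self.cells.items():
            if est is None:
                rows.append({"source": source, "K": K, "r": r,
                             "mle": None, "lo": None, "hi": None})
            else:
                rows.append({"source": source, "K": K, "r": r, "mle": est.mle,
                             "lo": est.support_limits[0],
                             "hi": est.support_limits[1]})
        return pd.DataFrame(rows)


def demographic_sweep(samples_by_source: Mapping[str, Mapping[str, Mapping[int, int]]],
                      introduced_sample: Mapping[str, Mapping[int, int]],
                      K_values: Sequence[int], r_values: Sequence[float],
                      t: int, grid: Sequence[int] | None = None,
                      M: int = 1000,
                      seed: int | np.random.Generator = 0) -> SweepResult:
    """Run founder_grid_likelihood over every (source, K, r) combination.

    Failed cells are recorded as None and the sweep continues.
    """
    if not K_values or not r_values or not samples_by_source:
        raise ValueError("empty sweep axes")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.Generator) \
        else np.random.SeedSequence(int(seed.integers(2 ** 31)))
    cells: dict[tuple[str, int, float], FounderEstimate | None] = {}
    children = iter(ss.spawn(len(samples_by_source) * len(K_values) * len(r_values)))
    for source, src_sample in samples_by_source.items():
        for K in K_values:
            for r in r_values:
                child = np.random.default_rng(next(children))
                try:
                    cells[(source, K, r)] = founder_grid_likelihood(
                        src_sample, introduced_sample, K=K, r=r, t=t,
                        grid=grid, M=M, seed=child)
                except ValueError as exc:
                    logger.warning("sweep cell (%s, K=%d, r=%.2f) failed: %s",
                                   source, K, r, exc)
                    cells[(source, K, r)] = None
    return SweepResult(t=t, cells=cells)


def sample_allele_counts(table, pop: str) -> dict[str, dict[int, int]]:
    """Per-locus allele gene-copy counts for one population of a GenotypeTable."""
    return {locus: dict(table.allele_counts(pop, locus))
            for locus in table.locus_ids}
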