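"""Per-population diversity statistics for nuclear and mitochondrial data.

Nuclear: proportion of polymorphic loci (P), mean alleles per locus (A),
rarefied allelic richness (A_R) and rarefied private allelic richness (A_p)
standardized to a fixed number of gene copies, observed heterozygosity (Ho)
and Nei's unbiased expected heterozygosity (He).

Mitochondrial: haplotype counts, private haplotypes, haplotype diversity h
and per-site nucleotide diversity pi, plus mean pairwise nucleotide
differences between populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import GenotypeTable, HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class DiversitySummary:
    """Nuclear diversity bundle for one population."""

    population: str
    n: int
    P: float
    A: float
    A_sd: float
    A_R: float
    A_p: float
    Ho: float
    Ho_sd: float
    He: float
    He_sd: float


@dataclass
class MitoDiversitySummary:
    """Mitochondrial diversity bundle for one population."""

    population: str
    n: int
    n_H: int
    n_pH: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _log_choose(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _prob_absent(N: int, N_a: int, g: int) -> float:
    """Hypergeometric probability that an allele with N_a of N gene copies
    is absent from a subsample of g copies: C(N-N_a, g) / C(N, g)."""
    if N - N_a < g:
        return 0.0
    return math.exp(_log_choose(N - N_a, g) - _log_choose(N, g))


def rarefied_allelic_richness(allele_counts: Sequence[int], g: int) -> float:
    """Expected number of distinct alleles in a random subsample of g genes.

    ``allele_counts`` are the per-allele gene counts at one locus; the
    expectation is the sum over alleles of their hypergeometric inclusion
    probabilities (the standard rarefaction estimator).
    """
    counts = [int(c) for c in allele_counts if c > 0]
    N = sum(counts)
    if g > N:
        raise ValueError(f"subsample of {g} genes exceeds total {N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    return float(sum(1.0 - _prob_absent(N, c, g) for c in counts))


def private_allelic_richness(all_pops_counts: dict[str, dict[int, int]],
                             focal: str, g: int) -> float:
    """Expected number of alleles private to ``focal`` in g-gene subsamples.

    Every population is rarefied to g genes; an allele contributes the
    probability that it appears in the focal subsample and in no other
    population's subsample (independent hypergeometric draws).
    """
    totals = {p: sum(c.values()) for p, c in all_pops_counts.items()}
    if g > totals[focal]:
        raise ValueError("g exceeds the focal population's gene count")
    for p, N in totals.items():
        if g > N:
            raise ValueError(f"g exceeds gene count of population {p}")
    alleles = set()
    for c in all_pops_counts.values():
        alleles.update(a for a, k in c.items() if k > 0)
    total = 0.0
    focal_counts = all_pops_counts[focal]
    for a in alleles:
        p_in_focal = 1.0 - _prob_absent(totals[focal], focal_counts.get(a, 0), g)
        if p_in_focal == 0.0:
            continue
        p_absent_elsewhere = 1.0
        for p, c in all_pops_counts.items():
            if p == focal:
                continue
            p_absent_elsewhere *= _prob_absent(totals[p], c.get(a, 0), g)
        total += p_in_focal * p_absent_elsewhere
    return total


# ---------------------------------------------------------------------------
# Heterozygosity and nuclear summaries
# ---------------------------------------------------------------------------

def heterozygosity_stats(table: GenotypeTable, population: str) -> dict:
    """Per-locus and mean Ho, He, P and A for one population.

    He is Nei's unbiased estimator ``(2n/(2n-1)) (1 - sum p_i^2)`` with n the
    number of non-missing individuals at the locus. Loci with no data are
    excluded (and logged).
    """
    per_locus: dict[str, dict] = {}
    for locus in table.locus_ids:
        genos = table.locus_genotypes(population, locus)
        if not genos:
            logger.warning("locus %s all-missing in %s; excluded", locus, population)
            continue
        n = len(genos)
        counts = table.allele_counts(population, locus)
        freqs = np.array(list(counts.values())) / (2 * n)
        ho = sum(1 for a, b in genos if a != b) / n
        he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(freqs ** 2)))
        per_locus[locus] = {
            "n": n, "A": len(counts), "Ho": ho, "He": he,
            "polymorphic": len(counts) > 1,
        }
    if not per_locus:
        raise ValueError(f"population {population} has no scorable locus")
    A = np.array([v["A"] for v in per_locus.values()], dtype=float)
    Ho = np.array([v["Ho"] for v in per_locus.values()])
    He = np.array([v["He"] for v in per_locus.values()])
    return {
        "per_locus": per_locus,
        "P": float(np.mean([v["polymorphic"] for v in per_locus.values()])),
        "A": float(A.mean()), "A_sd": float(A.std(ddof=1)) if len(A) > 1 else 0.0,
        "Ho": float(Ho.mean()), "Ho_sd": float(Ho.std(ddof=1)) if len(Ho) > 1 else 0.0,
        "He": float(He.mean()), "He_sd": float(He.std(ddof=1)) if len(He) > 1 else 0.0,
    }


def nuclear_diversity(table: GenotypeTable, g: int = 26) -> list[DiversitySummary]:
    """Full nuclear diversity table, one row per population.

    A_R and A_p are rarefied to ``g`` gene copies; loci where any relevant
    population has fewer than ``g`` genes are excluded from the rarefied
    means with a logged warning.
    """
    summaries = []
    for pop in table.population_ids:
        het = heterozygosity_stats(table, pop)
        ar_vals, ap_vals = [], []
        for locus in table.locus_ids:
            counts = table.allele_counts(pop, locus)
            N = sum(counts.values())
            if N < g:
                logger.warning(
                    "locus %s in %s has %d genes < g=%d; excluded from A_R",
                    locus, pop, N, g)
            elif N > 0:
                ar_vals.append(rarefied_allelic_richness(list(counts.values()), g))
            all_counts = {p: dict(table.allele_counts(p, locus))
                          for p in table.population_ids}
            totals = {p: sum(c.values()) for p, c in all_counts.items()}
            if all(t >= g for t in totals.values()):
                ap_vals.append(private_allelic_richness(all_counts, pop, g))
            else:
                logger.warning(
                    "locus %s skipped for A_p: some population has < %d genes",
                    locus, g)
        summaries.append(DiversitySummary(
            population=pop,
            n=table.sample_sizes[pop],
            P=het["P"], A=het["A"], A_sd=het["A_sd"],
            A_R=float(np.mean(ar_vals)) if ar_vals else float("nan"),
            A_p=float(np.mean(ap_vals)) if ap_vals else float("nan"),
            Ho=het["Ho"], Ho_sd=het["Ho_sd"],
            He=het["He"], He_sd=het["He_sd"],
        ))
    return summaries


# ---------------------------------------------------------------------------
# Mitochondrial diversity
# ---------------------------------------------------------------------------

def mito_diversity(hapset: HaplotypeSet, population: str) -> MitoDiversitySummary:
    """Haplotype diversity h and per-site nucleotide diversity pi.

    h uses the n/(n-1) small-sample correction; pi is the corrected mean
    pairwise difference divided by the alignment length. Standard deviations
    follow Nei's variance formulas (for pi, the total variance including the
    stochastic term).
    """
    n = hapset.sample_size(population)
    if n < 2:
        raise ValueError(f"need >= 2 sequences in {population}, have {n}")
    p = hapset.frequencies(population)
    sum_p2 = float(np.sum(p ** 2))
    h = (n / (n - 1)) * (1.0 - sum_p2)
    sum_p3 = float(np.sum(p ** 3))
    var_h = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2 ** 2) + sum_p2 - sum_p2 ** 2
    )
    h_sd = math.sqrt(max(var_h, 0.0))

    L = hapset.seq_length
    if L is None:
        raise ValueError("HaplotypeSet has no sequence length for per-site pi")
    d = hapset.diff_matrix
    mean_diff = (n / (n - 1)) * float(p @ d @ p)
    pi = mean_diff / L
    var_pi = ((n + 1) / (3.0 * (n - 1))) * pi / L \
        + (2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))) * pi ** 2
    pi_sd = math.sqrt(max(var_pi, 0.0))

    present = hapset.counts[population] > 0
    others = np.zeros(len(hapset.haplotype_ids), dtype=bool)
    for pop in hapset.population_ids:
        if pop != population:
            others |= hapset.counts[pop] > 0
    return MitoDiversitySummary(
        population=population,
        n=n,
        n_H=int(present.sum()),
        n_pH=int((present & ~others).sum()),
        h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd,
    )


def between_population_differences(hapset: HaplotypeSet,
                                   popA: str, popB: str) -> float:
    """Mean pairwise nucleotide differences between two populations (raw,
    not per site): sum_ij p_i^A p_j^B d_ij."""
    pA = hapset.frequencies(popA)
    pB = hapset.frequencies(popB)
    return float(pA @ hapset.diff_matrix @ pB)


def mito_difference_matrix(hapset: HaplotypeSet) -> tuple[list[str], np.ndarray]:
    pops = hapset.population_ids
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = between_population_differences(hapset, pops[i], pops[j])
    return pops, m


def diversity_table(nuclear: list[DiversitySummary],
                    mito: list[MitoDiversitySummary] | None = None) -> pd.DataFrame:
    """Assemble the per-population summary table (nuclear columns first,
    mitochondrial columns appended when available)."""
    rows = []
    mito_by_pop = {m.population: m for m in (mito or [])}
    for s in nuclear:
        row = {
            "population": s.population, "n": s.n, "P": round(s.P, 2),
            "A_p": round(s.A_p, 1) if not math.isnan(s.A_p) else "",
            "A_R": round(s.A_R, 1) if not math.isnan(s.A_R) else "",
            "A": round(s.A, 1), "A_sd": round(s.A_sd, 1),
            "Ho": round(s.Ho, 2), "Ho_sd": round(s.Ho_sd, 2),
            "He": round(s.He, 2), "He_sd": round(s.He_sd, 2),
        }
        m = mito_by_pop.get(s.population)
        if m is not None:
            row.update({
                "mt_n": m.n, "n_H": m.n_H, "n_pH": m.n_pH,
                "h": round(m.h, 2), "h_sd": round(m.h_sd, 2),
                "pi": round(m.pi, 4), "pi_sd": round(m.pi_sd, 4),
            })
        rows.append(row)
    return pd.DataFrame(rows)
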