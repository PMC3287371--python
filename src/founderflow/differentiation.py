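"""Population differentiation and source assignment.

Pairwise Weir & Cockerham (1984) theta with genotype-permutation tests,
Cavalli-Sforza chord distances, neighbor-joining trees with locus-bootstrap
branch support, and ranking of candidate source populations for an
introduced population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from .io_formats import GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix (kind: fst, chord or mtdna_diff)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "fst"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class SupportTree:
    """Unrooted NJ tree with bootstrap support on internal bipartitions."""

    newick: str
    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(table: GenotypeTable, pops: Sequence[str],
                   locus: str) -> tuple[float, float, float]:
    """Summed per-allele variance components (a, b, c) for one locus.

    Direct implementation of the Weir & Cockerham (1984) analysis of
    variance: a = among populations, b = among individuals within
    populations, c = within individuals.
    """
    genos = {p: table.locus_genotypes(p, locus) for p in pops}
    sizes = np.array([len(genos[p]) for p in pops], dtype=float)
    use = sizes >= 1
    if use.sum() < 2:
        return 0.0, 0.0, 0.0
    pops = [p for p, u in zip(pops, use) if u]
    n = sizes[use]
    r = len(pops)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1)

    alleles = table.alleles_at(locus, pops)
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0

    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([
            sum((g[0] == allele) + (g[1] == allele) for g in genos[pop]) / (2 * ni)
            for pop, ni in zip(pops, n)
        ])
        h_i = np.array([
            sum(g[0] != g[1] and allele in g for g in genos[pop]) / ni
            for pop, ni in zip(pops, n)
        ])
        pbar = float(np.sum(n * p_i) / (r * nbar))
        s2 = float(np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n * h_i) / (r * nbar))
        if nbar <= 1:
            continue
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0
            )
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def pairwise_fst(table: GenotypeTable, popA: str, popB: str) -> float:
    """Multi-locus Weir & Cockerham theta between two populations.

    Variance components are summed over alleles and loci before forming the
    ratio (the FSTAT convention). Loci monomorphic across both populations
    contribute nothing. Returns NaN when no locus is usable.
    """
    num = den = 0.0
    for locus in table.locus_ids:
        a, b, c = _wc_components(table, [popA, popB], locus)
        num += a
        den += a + b + c
    if den == 0.0:
        logger.warning("theta undefined for %s vs %s (no usable locus)", popA, popB)
        return float("nan")
    return num / den


def fst_matrix(table: GenotypeTable) -> DistanceMatrix:
    pops = table.population_ids
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_fst(table, pops[i], pops[j])
    return DistanceMatrix(list(pops), m, kind="fst")


def fst_permutation_test(table: GenotypeTable, popA: str, popB: str,
                         reps: int = 999,
                         seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for theta between two populations.

    Whole multilocus genotypes are shuffled between the two samples
    (individual-level permutation); p = (1 + #{theta_perm >= theta_obs})
    / (reps + 1).
    """
    if reps < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    obs = pairwise_fst(table, popA, popB)
    pool = list(table.genotypes[popA]) + list(table.genotypes[popB])
    nA = len(table.genotypes[popA])
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(len(pool))
        permuted = GenotypeTable(
            population_ids=[popA, popB],
            locus_ids=table.locus_ids,
            genotypes={
                popA: [pool[i] for i in perm[:nA]],
                popB: [pool[i] for i in perm[nA:]],
            },
        )
        if pairwise_fst(permuted, popA, popB) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (reps + 1)


# ---------------------------------------------------------------------------
# Chord distance and neighbor joining
# ---------------------------------------------------------------------------

def _locus_chord(table: GenotypeTable, popA: str, popB: str,
                 locus: str) -> Optional[float]:
    cA = table.allele_counts(popA, locus)
    cB = table.allele_counts(popB, locus)
    nA, nB = sum(cA.values()), sum(cB.values())
    if nA == 0 or nB == 0:
        return None
    alleles = set(cA) | set(cB)
    s = sum(np.sqrt((cA.get(a, 0) / nA) * (cB.get(a, 0) / nB)) for a in alleles)
    return 1.0 - float(s)


def chord_distance_matrix(table: GenotypeTable,
                          loci: Sequence[str] | None = None) -> DistanceMatrix:
    """Cavalli-Sforza chord distances averaged over loci.

    Per locus d_l = 1 - sum_a sqrt(x_a y_a); the pairwise distance is the
    mean of d_l over loci scorable in both populations (loci missing in one
    member of a pair are dropped for that pair, with a log note).
    """
    loci = list(loci) if loci is not None else table.locus_ids
    pops = table.population_ids
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for locus in loci:
                d = _locus_chord(table, pops[i], pops[j], locus)
                if d is None:
                    logger.warning("locus %s dropped for pair (%s, %s)",
                                   locus, pops[i], pops[j])
                else:
                    vals.append(d)
            if not vals:
                raise ValueError(f"no scorable locus for pair {pops[i]}, {pops[j]}")
            m[i, j] = m[j, i] = float(np.mean(vals))
    return DistanceMatrix(list(pops), m, kind="chord")


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    sk = _SkbioDM(dm.values, ids=dm.labels)
    tree = nj(sk, neg_as_zero=True)
    return tree


def _bipartitions(tree: TreeNode, taxa: frozenset) -> dict[frozenset, "TreeNode"]:
    """Non-trivial bipartitions of an unrooted tree, keyed canonically.

    Each internal edge splits the taxa in two; the split is represented by
    whichever side does not contain the alphabetically first taxon, so the
    key is invariant to the arbitrary rooting of the TreeNode.
    """
    ref = min(taxa)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out[side] = node
    return out


def neighbor_joining_with_bootstrap(table: GenotypeTable, reps: int = 1000,
                                    seed: int | np.random.Generator = 0
                                    ) -> SupportTree:
    """NJ tree on chord distances with locus-bootstrap branch support.

    Bootstrap pseudoreplicates resample loci with replacement, rebuild the
    tree, and each internal bipartition of the point-estimate tree is
    annotated with the percentage of pseudoreplicates containing it. With
    few loci the support granularity is necessarily coarse.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    point = nj_tree(chord_distance_matrix(table))
    taxa = frozenset(t.name for t in point.tips())
    target = _bipartitions(point, taxa)
    counts = {bp: 0 for bp in target}
    loci = table.locus_ids
    for _ in range(reps):
        resampled = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        boot = nj_tree(chord_distance_matrix(table, loci=resampled))
        boot_bps = _bipartitions(boot, taxa)
        for bp in counts:
            if bp in boot_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / reps for bp, c in counts.items()}
    for bp, node in target.items():
        node.name = f"{supports[bp]:.0f}"
    newick = str(point).strip()
    return SupportTree(newick=newick, tree=point, supports=supports)


# ---------------------------------------------------------------------------
# Source ranking
# ---------------------------------------------------------------------------

def assign_source(fst: DistanceMatrix, introduced: str,
                  mito_diffs: DistanceMatrix | None = None) -> pd.DataFrame:
    """Rank candidate source populations by ascending theta to ``introduced``.

    Exact theta ties are broken by mtDNA mean pairwise differences when a
    mito matrix is supplied; residual ties share a rank (reported via the
    ``tied`` column). Undefined (NaN) theta entries rank last.
    """
    if introduced not in fst.labels:
        raise ValueError(f"{introduced} not in distance matrix")
    rows = []
    for pop in fst.labels:
        if pop == introduced:
            continue
        theta = fst.get(pop, introduced)
        mito = mito_diffs.get(pop, introduced) if mito_diffs is not None \
            else float("nan")
        rows.append({"population": pop, "theta": theta, "mito_diff": mito})
    df = pd.DataFrame(rows)
    sort_key = df.assign(
        _nan=df["theta"].isna(),
        _mito=df["mito_diff"].fillna(np.inf),
    ).sort_values(["_nan", "theta", "_mito", "population"])
    df = df.loc[sort_key.index].reset_index(drop=True)
    # shared ranks for exact ties on (theta, mito_diff); NaN as a sentinel
    key = list(zip(df["theta"].fillna(np.inf).round(12),
                   df["mito_diff"].fillna(np.inf).round(12)))
    ranks, tied = [], []
    for i, k in enumerate(key):
        ranks.append(ranks[i - 1] if i > 0 and k == key[i - 1] else i + 1)
    for i, k in enumerate(key):
        tied.append(key.count(k) > 1)
    df["rank"] = ranks
    df["tied"] = tied
    return df
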