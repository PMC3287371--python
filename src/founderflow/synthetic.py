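"""Synthetic microsatellite + mtDNA datasets with known ground truth.

The generator emulates a field study of one introduced population and a
panel of candidate source populations: several diverged source populations
(Balding-Nichols allele-frequency model around a common ancestral pool),
one of which founds the introduced population with a known number of
founders, followed by logistic growth with Wright-Fisher drift. Samples of
diploid genotypes (Genepop) and mtDNA haplotypes (FASTA + popmap) are drawn
from the resulting frequencies, and the ground truth is recorded in a
sidecar JSON so downstream estimators can be tested by parameter recovery.

Defaults mirror the study design this package targets: nine candidate
sources plus one introduced population, seven microsatellite loci with 6-48
alleles each, nuclear sample sizes between 15 and 124, a 759-bp mtDNA
locus, and a founding event of 10 individuals 10 generations ago.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .founder_nuclear import DemographicModel, logistic_trajectory
from .io_formats import (GenotypeTable, HaplotypeSet, write_fasta_haplotypes,
                         write_genepop, _pairwise_differences)

NUCLEOTIDES = np.array(list("ACGT"))

#: nuclear / mtDNA sample sizes for the nine sources + introduced population
DEFAULT_NUCLEAR_N = (28, 27, 68, 59, 71, 15, 33, 124, 66, 71)
DEFAULT_MITO_N = (16, 24, 15, 16, 16, 15, 23, 31, 15, 15)


@dataclass
class SimulationScenario:
    """Ground-truth parameters for one synthetic dataset."""

    n_source_pops: int = 9
    n_loci: int = 7
    alleles_per_locus: tuple[int, int] = (6, 48)
    divergence_F: float = 0.3
    true_source: str = "S1"
    true_N0: int = 10
    r: float = 1.5
    K: int = 2000
    t: int = 10
    seq_length: int = 759
    haplotypes_per_pop: int = 8
    nuclear_sample_sizes: tuple[int, ...] = DEFAULT_NUCLEAR_N
    mito_sample_sizes: tuple[int, ...] = DEFAULT_MITO_N
    introduced_label: str = "INTRO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_N0 < 1:
            raise ValueError("true_N0 must be >= 1")
        if not (0.0 < self.divergence_F < 1.0):
            raise ValueError("divergence_F must lie in (0, 1)")
        if self.t < 0 or self.r <= 0:
            raise ValueError("t must be >= 0 and r > 0")
        if self.K < self.true_N0:
            raise ValueError("K must be >= true_N0")
        if len(self.nuclear_sample_sizes) != self.n_source_pops + 1:
            raise ValueError("need one nuclear sample size per population "
                             "(sources + introduced)")
        if len(self.mito_sample_sizes) != self.n_source_pops + 1:
            raise ValueError("need one mtDNA sample size per population")
        if any(n <= 0 for n in self.nuclear_sample_sizes + self.mito_sample_sizes):
            raise ValueError("sample sizes must be positive")

    @property
    def source_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_source_pops)]

    @property
    def population_labels(self) -> list[str]:
        return self.source_labels + [self.introduced_label]


def generate_source_metapopulation(scenario: SimulationScenario,
                                   rng: np.random.Generator | None = None
                                   ) -> dict[str, list[np.ndarray]]:
    """Per-population, per-locus allele frequencies for the source panel.

    Each locus gets an ancestral frequency vector from a symmetric
    Dirichlet(1); each population's vector is a Balding-Nichols draw,
    Dirichlet with mean the ancestral vector and concentration (1-F)/F, so
    the drift parameter F sets the expected differentiation among sources.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    lo, hi = scenario.alleles_per_locus
    n_alleles = rng.integers(lo, hi + 1, size=scenario.n_loci)
    F = scenario.divergence_F
    conc = (1.0 - F) / F
    freqs: dict[str, list[np.ndarray]] = {p: [] for p in scenario.source_labels}
    for A in n_alleles:
        ancestral = rng.dirichlet(np.ones(A))
        for pop in scenario.source_labels:
            freqs[pop].append(rng.dirichlet(conc * ancestral))
    return freqs


def simulate_introduction(source_freqs: list[np.ndarray],
                          scenario: SimulationScenario,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[np.ndarray], np.ndarray]:
    """Found the introduced population and let it drift for t generations.

    The founder gene pool is 2*N0 copies per locus drawn multinomially from
    the source frequencies; subsequent generations resample along the
    logistic size trajectory. Returns the final per-locus frequencies and
    the trajectory.
    """
    if scenario.true_N0 > scenario.K:
        raise ValueError("true_N0 exceeds K")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    model = DemographicModel(N0=scenario.true_N0, K=scenario.K,
                             r=scenario.r, t=scenario.t)
    traj = logistic_trajectory(model)
    finals = []
    for p in source_freqs:
        counts = rng.multinomial(2 * model.N0, p)
        f = counts / (2.0 * model.N0)
        for g in range(1, scenario.t + 1):
            genes = int(2 * traj[g])
            f = rng.multinomial(genes, f) / genes
        finals.append(f)
    return finals, traj


def _mutate(seq: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    sites = rng.choice(len(seq), size=n_subs, replace=False)
    for s in sites:
        choices = [b for b in "ACGT" if b != out[s]]
        out[s] = choices[rng.integers(0, 3)]
    return out


def _generate_mtdna_pool(scenario: SimulationScenario,
                         rng: np.random.Generator
                         ) -> tuple[list[str], dict[str, np.ndarray]]:
    """Haplotype sequences and per-source frequency vectors.

    Each source population is a shallow clade: its haplotypes differ from a
    population-specific seed sequence by 1-3 substitutions, while the seeds
    themselves differ from a common ancestral sequence by many more, so
    within-clade pairwise distances are small and between-clade distances
    large (the pattern of deeply structured mtDNA among basins).
    """
    L = scenario.seq_length
    ancestral = NUCLEOTIDES[rng.integers(0, 4, size=L)]
    sequences: list[str] = []
    seq_index: dict[str, int] = {}
    pop_freqs: dict[str, np.ndarray] = {}
    per_pop_haps: dict[str, list[int]] = {}
    for pop in scenario.source_labels:
        seed_seq = _mutate(ancestral, rng.integers(15, 31), rng)
        hap_ids = []
        for _ in range(scenario.haplotypes_per_pop):
            hap = _mutate(seed_seq, rng.integers(1, 4), rng)
            s = "".join(hap)
            if s not in seq_index:
                seq_index[s] = len(sequences)
                sequences.append(s)
            hap_ids.append(seq_index[s])
        per_pop_haps[pop] = hap_ids
    H = len(sequences)
    for pop in scenario.source_labels:
        f = np.zeros(H)
        weights = rng.dirichlet(np.ones(len(per_pop_haps[pop])) * 1.0)
        for hid, w in zip(per_pop_haps[pop], weights):
            f[hid] += w
        pop_freqs[pop] = f
    return sequences, pop_freqs


def sample_dataset(scenario: SimulationScenario,
                   outdir: str | Path | None = None
                   ) -> tuple[GenotypeTable, HaplotypeSet, dict]:
    """Draw a full synthetic dataset and (optionally) write it to disk.

    Returns the GenotypeTable, the HaplotypeSet and the ground-truth
    sidecar dict; with ``outdir`` set, also writes genepop.txt, haps.fasta,
    popmap.tsv and truth.json. Fully deterministic given the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    source_freqs = generate_source_metapopulation(scenario, rng)
    intro_freqs, traj = simulate_introduction(
        source_freqs[scenario.true_source], scenario, rng)
    all_freqs = dict(source_freqs)
    all_freqs[scenario.introduced_label] = intro_freqs

    # diploid genotypes: two independent gene copies per locus (HWE assembly)
    genotypes: dict[str, list] = {}
    for pop, n in zip(scenario.population_labels, scenario.nuclear_sample_sizes):
        inds = []
        for _ in range(n):
            row = []
            for freqs in all_freqs[pop]:
                # allele labels are sizes 101, 103, ... (3-digit Genepop codes)
                a1, a2 = rng.choice(len(freqs), size=2, p=freqs) * 2 + 101
                row.append((int(min(a1, a2)), int(max(a1, a2))))
            inds.append(row)
        genotypes[pop] = inds
    locus_ids = [f"Loc{i + 1}" for i in range(scenario.n_loci)]
    table = GenotypeTable(scenario.population_labels, locus_ids, genotypes)

    # mtDNA: source pool frequencies; the introduced population's haplotype
    # distribution is the realized founder draw (maternal lineages sampled
    # once at founding; no post-founding drift is applied to mtDNA)
    sequences, mito_freqs = _generate_mtdna_pool(scenario, rng)
    founder_draw = rng.multinomial(scenario.true_N0,
                                   mito_freqs[scenario.true_source])
    mito_freqs[scenario.introduced_label] = founder_draw / scenario.true_N0
    counts = {}
    for pop, n in zip(scenario.population_labels, scenario.mito_sample_sizes):
        counts[pop] = rng.multinomial(n, mito_freqs[pop])
    hapset = HaplotypeSet(
        haplotype_ids=[f"H{i + 1}" for i in range(len(sequences))],
        counts=counts,
        diff_matrix=_pairwise_differences(sequences),
        sequences=sequences,
        seq_length=scenario.seq_length,
    )

    truth = {
        "scenario": asdict(scenario),
        "true_source": scenario.true_source,
        "true_N0": scenario.true_N0,
        "trajectory": traj.tolist(),
        "founder_mito_draw": founder_draw.tolist(),
        "introduced_label": scenario.introduced_label,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(table, outdir / "genepop.txt")
        write_fasta_haplotypes(hapset, outdir / "haps.fasta",
                               outdir / "popmap.tsv")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return table, hapset, truth
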