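"""Readers, writers and core containers for the pipeline's file formats.

Nuclear genotypes travel as Genepop files (both the 2-digit and 3-digit
allele-code dialects), mitochondrial haplotypes as aligned FASTA plus a
two-column population map, and results as CSV / JSON / Newick.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: allele code meaning "missing" (any width)
MISSING = 0

Genotype = Optional[tuple[int, int]]


class GenepopParseError(ValueError):
    """Raised when a Genepop file violates the dialect."""


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes for several populations.

    ``genotypes[pop]`` is a list over individuals; each individual is a list
    over loci holding an unordered allele pair ``(a1, a2)`` (stored sorted)
    or ``None`` for missing. A genotype with any missing allele is treated
    as wholly missing for that locus.
    """

    population_ids: list[str]
    locus_ids: list[str]
    genotypes: dict[str, list[list[Genotype]]]
    individual_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in self.population_ids:
            inds = self.genotypes[pop]
            for ind in inds:
                if len(ind) != len(self.locus_ids):
                    raise ValueError(
                        f"individual in {pop} has {len(ind)} loci, "
                        f"expected {len(self.locus_ids)}"
                    )
            if pop not in self.individual_ids:
                self.individual_ids[pop] = [
                    f"{pop}_{i + 1}" for i in range(len(inds))
                ]

    @property
    def sample_sizes(self) -> dict[str, int]:
        return {p: len(self.genotypes[p]) for p in self.population_ids}

    def locus_index(self, locus: str) -> int:
        return self.locus_ids.index(locus)

    def allele_counts(self, pop: str, locus: str) -> Counter:
        """Gene (allele-copy) counts at one locus in one population."""
        j = self.locus_index(locus)
        counts: Counter = Counter()
        for ind in self.genotypes[pop]:
            g = ind[j]
            if g is not None:
                counts[g[0]] += 1
                counts[g[1]] += 1
        return counts

    def gene_count(self, pop: str, locus: str) -> int:
        j = self.locus_index(locus)
        return 2 * sum(1 for ind in self.genotypes[pop] if ind[j] is not None)

    def locus_genotypes(self, pop: str, locus: str) -> list[tuple[int, int]]:
        """Non-missing genotypes at one locus."""
        j = self.locus_index(locus)
        return [ind[j] for ind in self.genotypes[pop] if ind[j] is not None]

    def alleles_at(self, locus: str, pops: Sequence[str] | None = None) -> list[int]:
        """Sorted union of allele labels observed at a locus."""
        pops = list(pops) if pops is not None else self.population_ids
        alleles: set[int] = set()
        for p in pops:
            alleles.update(self.allele_counts(p, locus))
        return sorted(alleles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.population_ids == other.population_ids
            and self.locus_ids == other.locus_ids
            and self.genotypes == other.genotypes
        )


@dataclass
class HaplotypeSet:
    """mtDNA haplotypes: sequences, per-population counts, difference matrix.

    ``counts[pop]`` is an integer vector aligned with ``haplotype_ids``;
    ``diff_matrix[i, j]`` is the number of mismatching aligned positions
    between haplotypes i and j.
    """

    haplotype_ids: list[str]
    counts: dict[str, np.ndarray]
    diff_matrix: np.ndarray
    sequences: Optional[list[str]] = None
    seq_length: Optional[int] = None

    def __post_init__(self) -> None:
        H = len(self.haplotype_ids)
        self.diff_matrix = np.asarray(self.diff_matrix)
        if self.diff_matrix.shape != (H, H):
            raise ValueError("diff_matrix shape does not match haplotype count")
        if not np.array_equal(self.diff_matrix, self.diff_matrix.T):
            raise ValueError("diff_matrix must be symmetric")
        if np.any(np.diag(self.diff_matrix) != 0):
            raise ValueError("diff_matrix diagonal must be zero")
        if self.sequences is not None:
            if self.seq_length is None:
                self.seq_length = len(self.sequences[0])
            if any(len(s) != self.seq_length for s in self.sequences):
                raise ValueError("sequences must share one length")
        for pop, c in self.counts.items():
            self.counts[pop] = np.asarray(c, dtype=int)
            if len(self.counts[pop]) != H:
                raise ValueError(f"count vector for {pop} has wrong length")

    @property
    def population_ids(self) -> list[str]:
        return list(self.counts)

    def sample_size(self, pop: str) -> int:
        return int(self.counts[pop].sum())

    def frequencies(self, pop: str) -> np.ndarray:
        n = self.sample_size(pop)
        if n == 0:
            raise ValueError(f"population {pop} has no mtDNA sample")
        return self.counts[pop] / n


@dataclass
class RunConfig:
    """Knobs shared across pipeline stages, with the study defaults."""

    rarefaction_genes: int = 26
    bootstrap_reps: int = 1000
    permutation_reps: int = 999
    mito_trials: int = 100_000
    founder_grid: tuple[int, int] = (2, 40)
    r_values: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)
    K_values: tuple[int, ...] = (500, 1000, 2000, 4000, 8000, 16000)
    t: int = 10
    mc_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rarefaction_genes", "bootstrap_reps", "permutation_reps",
                     "mito_trials", "t", "mc_reps"):
            if getattr(self, name) < 0 or (name != "t" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.founder_grid[0] < 1 or self.founder_grid[1] < self.founder_grid[0]:
            raise ValueError("founder_grid must be an increasing range with min >= 1")

    @property
    def founder_candidates(self) -> list[int]:
        lo, hi = self.founder_grid
        return list(range(lo, hi + 1))


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _detect_width(token: str, line_no: int) -> int:
    if len(token) == 4:
        return 2
    if len(token) == 6:
        return 3
    raise GenepopParseError(
        f"line {line_no}: genotype token '{token}' is neither 4 nor 6 digits"
    )


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Accepts 2- and 3-digit allele codes (auto-detected; mixing widths in one
    file is an error). Allele code 00/000 marks a missing allele; a genotype
    with any missing allele is recorded as missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be Genepop")
    # locus names: everything between the title line and the first 'pop'
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                locus_ids.append(name)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'pop' line found")

    population_ids: list[str] = []
    genotypes: dict[str, list[list[Genotype]]] = OrderedDict()
    individual_ids: dict[str, list[str]] = {}
    width: Optional[int] = None
    current: Optional[str] = None

    for line_no, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            current = f"pop{len(population_ids) + 1}"
            population_ids.append(current)
            genotypes[current] = []
            individual_ids[current] = []
            continue
        if "," not in line:
            raise GenepopParseError(f"line {line_no}: expected 'id , genotypes'")
        ind_id, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_ids):
            raise GenepopParseError(
                f"line {line_no}: {len(tokens)} genotypes for {len(locus_ids)} loci"
            )
        row: list[Genotype] = []
        for tok in tokens:
            w = _detect_width(tok, line_no)
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"line {line_no}: mixed {width}- and {w}-digit allele codes"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if a1 == MISSING or a2 == MISSING:
                row.append(None)
            else:
                row.append((min(a1, a2), max(a1, a2)))
        genotypes[current].append(row)
        individual_ids[current].append(ind_id.strip())

    # Genepop's convention: the last individual id of each pop often names it.
    named = [individual_ids[p][-1] if individual_ids[p] else p for p in population_ids]
    if len(set(named)) == len(named):
        genotypes = OrderedDict(
            (new, genotypes[old]) for new, old in zip(named, population_ids)
        )
        individual_ids = {
            new: individual_ids[old] for new, old in zip(named, population_ids)
        }
        population_ids = named

    return GenotypeTable(population_ids, locus_ids, genotypes, individual_ids)


def write_genepop(table: GenotypeTable, path: str | Path,
                  title: str = "founderflow export", width: int = 3) -> None:
    """Write a :class:`GenotypeTable` as a Genepop file."""
    if width not in (2, 3):
        raise ValueError("allele code width must be 2 or 3")
    out = [title]
    out.extend(table.locus_ids)
    for pop in table.population_ids:
        out.append("pop")
        ids = table.individual_ids.get(pop)
        for k, ind in enumerate(table.genotypes[pop]):
            label = ids[k] if ids else f"{pop}_{k + 1}"
            # the pop is identified by its last individual's label prefix
            if k == len(table.genotypes[pop]) - 1:
                label = pop
            toks = []
            for g in ind:
                if g is None:
                    toks.append("0" * (2 * width))
                else:
                    if max(g) >= 10 ** width:
                        raise ValueError(
                            f"allele label {max(g)} does not fit {width} digits"
                        )
                    toks.append(f"{g[0]:0{width}d}{g[1]:0{width}d}")
            out.append(f"{label} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA haplotypes
# ---------------------------------------------------------------------------

def _pairwise_differences(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    H = len(seqs)
    d = np.zeros((H, H), dtype=int)
    for i in range(H):
        d[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
    return d + d.T


AMBIGUITY = set("RYSWKMBDHVN-")


def read_fasta_haplotypes(fasta: str | Path, popmap: str | Path) -> HaplotypeSet:
    """Collapse aligned FASTA records into haplotypes with per-population counts.

    ``popmap`` is a two-column TSV mapping record id to population. Identical
    sequences collapse to one haplotype; the difference matrix is the
    position-wise mismatch count (gaps and ambiguity codes count as
    mismatches against any different character, and are flagged in the log).
    """
    pop_of: dict[str, str] = {}
    for line in Path(popmap).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"popmap line not two columns: {line!r}")
        pop_of[parts[0]] = parts[1]

    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ValueError("empty FASTA")
    L = len(records[0].seq)
    seq_to_idx: dict[str, int] = {}
    haplotype_ids: list[str] = []
    sequences: list[str] = []
    pops_seen: list[str] = []
    per_pop: dict[str, Counter] = OrderedDict()
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) != L:
            raise ValueError(
                f"record {rec.id}: length {len(seq)} != alignment length {L}"
            )
        if rec.id not in pop_of:
            raise ValueError(f"record {rec.id} missing from popmap")
        if AMBIGUITY & set(seq):
            logger.warning("record %s contains gap/ambiguity characters", rec.id)
        if seq not in seq_to_idx:
            seq_to_idx[seq] = len(sequences)
            haplotype_ids.append(f"H{len(sequences) + 1}")
            sequences.append(seq)
        pop = pop_of[rec.id]
        if pop not in per_pop:
            per_pop[pop] = Counter()
            pops_seen.append(pop)
        per_pop[pop][seq_to_idx[seq]] += 1

    H = len(sequences)
    counts = {
        pop: np.array([per_pop[pop].get(i, 0) for i in range(H)])
        for pop in pops_seen
    }
    return HaplotypeSet(
        haplotype_ids=haplotype_ids,
        counts=counts,
        diff_matrix=_pairwise_differences(sequences),
        sequences=sequences,
        seq_length=L,
    )


def write_fasta_haplotypes(hapset: HaplotypeSet, fasta: str | Path,
                           popmap: str | Path) -> None:
    """Expand a HaplotypeSet back to one FASTA record per sampled sequence."""
    if hapset.sequences is None:
        raise ValueError("HaplotypeSet carries no sequences")
    fa_lines, pm_lines = [], []
    k = 0
    for pop in hapset.population_ids:
        for h, c in enumerate(hapset.counts[pop]):
            for _ in range(int(c)):
                k += 1
                rid = f"{pop}_seq{k}"
                fa_lines.append(f">{rid}\n{hapset.sequences[h]}")
                pm_lines.append(f"{rid}\t{pop}")
    Path(fasta).write_text("\n".join(fa_lines) + "\n")
    Path(popmap).write_text("\n".join(pm_lines) + "\n")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_distance_csv(labels: Sequence[str], below: np.ndarray,
                       path: str | Path,
                       above: np.ndarray | None = None) -> None:
    """Write a matrix CSV: `below` under the diagonal, optional `above` over it.

    Mirrors the paired presentation of nuclear FST below / mtDNA mean
    differences above one diagonal. Diagonal cells are left blank.
    """
    n = len(labels)
    cells = [["" for _ in range(n)] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i > j:
                cells[i][j] = f"{below[i, j]:.6g}"
            elif i < j and above is not None:
                cells[i][j] = f"{above[i, j]:.6g}"
            elif i < j:
                cells[i][j] = f"{below[i, j]:.6g}"
    df = pd.DataFrame(cells, index=list(labels), columns=list(labels))
    df.to_csv(path)
    logger.info("wrote distance matrix to %s", path)


def write_summary_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
    logger.info("wrote summary table to %s", path)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.strip() + "\n")
    logger.info("wrote tree to %s", path)


def write_founder_json(estimate: Mapping, path: str | Path) -> None:
    """Serialize a founder estimate (grid + log-likelihoods) as JSON."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(estimate, indent=2, default=_default) + "\n")
    logger.info("wrote founder estimate to %s", path)


def read_founder_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
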