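"""End-to-end analysis: diversity -> differentiation -> founder estimation.

One call runs the whole study design on a Genepop file (plus optional
mtDNA inputs), ranks candidate sources for a designated introduced
population, and estimates the founder number from both marker classes
using the top-ranked sources. Everything is a pure function of
(inputs, config, seed); a report directory with CSV/JSON/Newick outputs
and a provenance block is written when requested.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .differentiation import (DistanceMatrix, assign_source,
                              fst_matrix, neighbor_joining_with_bootstrap)
from .diversity import (diversity_table, mito_difference_matrix,
                        mito_diversity, nuclear_diversity)
from .founder_mito import MitoFounderResult, mito_founder_estimate
from .founder_nuclear import (SweepResult, demographic_sweep,
                              sample_allele_counts)
from .io_formats import (GenotypeTable, HaplotypeSet, RunConfig,
                         read_fasta_haplotypes, read_genepop,
                         write_distance_csv, write_founder_json,
                         write_newick, write_summary_csv)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    """All pipeline outputs; sections left as None were skipped."""

    diversity: pd.DataFrame
    fst: DistanceMatrix
    tree_newick: str
    source_ranking: pd.DataFrame
    mito_diffs: Optional[DistanceMatrix]
    nuclear_sweep: Optional[SweepResult]
    mito_founder: Optional[MitoFounderResult]
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _provenance(config: RunConfig, inputs: dict[str, str]) -> dict:
    blob = json.dumps({"config": config.__dict__, "inputs": inputs},
                      sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": config.seed,
        "founderflow_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "inputs": inputs,
    }


def run_full_analysis(genepop: str | Path | GenotypeTable,
                      introduced: str,
                      config: RunConfig | None = None,
                      fasta: str | Path | None = None,
                      popmap: str | Path | None = None,
                      hapset: HaplotypeSet | None = None,
                      n_top_sources: int = 3,
                      outdir: str | Path | None = None) -> AnalysisReport:
    """Run the full analysis for one introduced population.

    Stages: per-population diversity summaries; pairwise theta with a
    chord-distance NJ tree (locus bootstrap); source ranking; then the
    nuclear demographic-sweep founder likelihood and the mtDNA founder-draw
    curve, both using the ``n_top_sources`` best-ranked candidate sources.
    Stage failures are recorded in ``report.skipped`` and dependent stages
    are skipped rather than aborting the run.
    """
    config = config or RunConfig()
    inputs = {"genepop": str(genepop) if not isinstance(genepop, GenotypeTable)
              else "<in-memory>", "fasta": str(fasta), "popmap": str(popmap)}
    table = genepop if isinstance(genepop, GenotypeTable) \
        else read_genepop(genepop)
    if introduced not in table.population_ids:
        raise ValueError(f"introduced population {introduced!r} not in data")
    if hapset is None and fasta is not None and popmap is not None:
        hapset = read_fasta_haplotypes(fasta, popmap)

    skipped: dict[str, str] = {}
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(child) for name, child in
             zip(["bootstrap", "sweep", "mito"], ss.spawn(3))}

    logger.info("stage: diversity")
    nuclear = nuclear_diversity(table, g=config.rarefaction_genes)
    mito_summaries = None
    mito_dm = None
    if hapset is not None:
        mito_summaries = [mito_diversity(hapset, p)
                          for p in hapset.population_ids
                          if hapset.sample_size(p) >= 2]
        pops, m = mito_difference_matrix(hapset)
        mito_dm = DistanceMatrix(pops, m, kind="mtdna_diff")
    else:
        skipped["mito_diversity"] = "no mtDNA input supplied"
    div_table = diversity_table(nuclear, mito_summaries)

    logger.info("stage: differentiation")
    fst = fst_matrix(table)
    tree = neighbor_joining_with_bootstrap(
        table, reps=config.bootstrap_reps, seed=seeds["bootstrap"])
    ranking = assign_source(fst, introduced, mito_diffs=mito_dm)
    top = [p for p in ranking["population"].head(n_top_sources)]
    logger.info("top-ranked sources: %s", top)

    logger.info("stage: nuclear founder sweep")
    sweep = None
    try:
        intro_counts = sample_allele_counts(table, introduced)
        samples_by_source = {s: sample_allele_counts(table, s) for s in top}
        sweep = demographic_sweep(
            samples_by_source, intro_counts,
            K_values=config.K_values, r_values=config.r_values,
            t=config.t, grid=config.founder_candidates, M=config.mc_reps,
            seed=seeds["sweep"])
    except ValueError as exc:
        skipped["nuclear_sweep"] = str(exc)

    logger.info("stage: mtDNA founder curve")
    mito_founder = None
    if hapset is None:
        skipped["mito_founder"] = "no mtDNA input supplied"
    else:
        try:
            k_obs = int(np.sum(hapset.counts[introduced] > 0))
            pool = {s: hapset.counts[s] for s in top if s in hapset.counts}
            mito_founder = mito_founder_estimate(
                pool, k_observed=k_obs,
                founder_range=list(range(2, 21)),
                trials=config.mito_trials, seed=seeds["mito"])
        except (KeyError, ValueError) as exc:
            skipped["mito_founder"] = str(exc)

    report = AnalysisReport(
        diversity=div_table, fst=fst, tree_newick=tree.newick,
        source_ranking=ranking, mito_diffs=mito_dm,
        nuclear_sweep=sweep, mito_founder=mito_founder,
        skipped=skipped, provenance=_provenance(config, inputs),
    )
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary_csv(report.diversity, outdir / "diversity.csv")
    above = report.mito_diffs.values if report.mito_diffs is not None else None
    labels = report.fst.labels
    if above is not None and report.mito_diffs.labels != labels:
        # align mito labels to the nuclear ordering where possible
        idx = [report.mito_diffs.labels.index(l) for l in labels
               if l in report.mito_diffs.labels]
        if len(idx) == len(labels):
            above = report.mito_diffs.values[np.ix_(idx, idx)]
        else:
            above = None
    write_distance_csv(labels, report.fst.values,
                       outdir / "differentiation_matrix.csv", above=above)
    write_newick(report.tree_newick, outdir / "nj_tree.nwk")
    write_summary_csv(report.source_ranking, outdir / "source_ranking.csv")
    if report.nuclear_sweep is not None:
        report.nuclear_sweep.table().to_csv(outdir / "founder_sweep.csv",
                                            index=False)
        write_founder_json(
            {f"{s}|K={K}|r={r}": (est.to_dict() if est else None)
             for (s, K, r), est in report.nuclear_sweep.cells.items()},
            outdir / "founder_sweep.json")
    if report.mito_founder is not None:
        write_founder_json(report.mito_founder.to_dict(),
                           outdir / "founder_mito.json")
        pd.DataFrame({
            "N": report.mito_founder.founder_range,
            "prob_k": report.mito_founder.prob_k,
        }).to_csv(outdir / "founder_mito_curve.csv", index=False)
    summary = {
        "skipped": report.skipped,
        "provenance": report.provenance,
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("report written to %s", outdir)
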