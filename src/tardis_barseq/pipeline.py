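"""End-to-end runner: simulate → process → cluster → stats.

A single call executes every stage from one :class:`RunConfig`, writes all
artifacts (pool snapshots, FASTQ, count tables, cluster map, statistics
JSON) under ``config.out_dir``, and returns a :class:`RunSummary` whose
conservation ledgers tie every stage's inputs to its outputs.  Re-running
with the same config and seed reproduces byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cluster import cluster_barcodes
from .config import RunConfig
from .fastq import read_fastq
from .process import (
    deduplicate,
    extract_umis,
    filter_and_crop,
    fixed_base_conformity,
    trim_to_barcode,
)
from .simulate import (
    AmpliconLayout,
    MoleculePool,
    draw_integrants,
    form_array,
    generate_reads,
    sample_library,
    simulate_pcr,
    stage_rngs,
)
from .stats import (
    SampleProfile,
    fit_zt_poisson,
    jackpot_report,
    position_probabilities,
    select_threshold,
    summarize_diversity,
)
from .template import BarcodeTemplate

log = logging.getLogger("tardis_barseq")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunSummary:
    """Conservation ledger plus all computed statistics for one run."""

    seed: int
    version: str
    config: dict
    tallies: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "config": self.config,
            "tallies": self.tallies,
            "stats": self.stats,
        }


REQUIRED_SUMMARY_KEYS = ("seed", "version", "config", "tallies", "stats")


def validate_summary(summary: dict) -> None:
    """Schema and conservation checks for a run summary."""
    for key in REQUIRED_SUMMARY_KEYS:
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
    filt = summary["tallies"].get("filter", {})
    if filt:
        discards = sum(v for k, v in filt.items() if k.startswith("discard_"))
        if filt.get("input", 0) != filt.get("kept", 0) + discards:
            raise ValueError("filter tally violates conservation")
    umi = summary["tallies"].get("umi", {})
    if umi and umi.get("input", 0) != umi.get("kept", 0) + umi.get("umi_unmatched", 0):
        raise ValueError("umi tally violates conservation")


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True, default=str) + "\n")


def _write_counts(counts: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tcount\n")
        for barcode in sorted(counts, key=lambda b: (-counts[b], b)):
            fh.write(f"{barcode}\t{counts[barcode]}\n")


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full pipeline described by ``config``.

    Stages run in order (simulation optional); any failure raises
    :class:`PipelineError` naming the stage, with conservation tallies up
    to that point attached to the exception.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=config.seed, version=__version__, config=config.to_dict())
    rngs = stage_rngs(config.seed, 5)
    stage = "setup"
    try:
        # ---------------- simulate ----------------
        if config.simulate.enabled:
            stage = "simulate"
            sim = config.simulate
            template = BarcodeTemplate(sim.template)
            library = sample_library(template, sim.n_library_molecules, rngs[0])
            mix = simulate_pcr(
                library,
                sim.pcr_cycles,
                efficiency_beta=(sim.pcr_efficiency_a, sim.pcr_efficiency_b),
                seed=rngs[1],
            )
            array = form_array(
                mix,
                sim.n_founders,
                sim.copy_lambda,
                sim.jackpot_prob,
                sim.jackpot_factor_log_sd,
                seed=rngs[2],
            )
            integrants = draw_integrants(array, sim.n_integrants, seed=rngs[3])
            layout = AmpliconLayout(
                read_length=sim.read_length,
                error_rate=sim.error_rate,
                duplicate_rate=sim.duplicate_rate,
                quality_model=(sim.quality_mean, sim.quality_sd, sim.quality_low_tail_prob),
            )
            fastq_path = out_dir / "simulated.fastq"
            n_reads = generate_reads(
                array, layout, sim.depth, fastq_path, out_dir / "sidecar.tsv", rngs[4]
            )
            for pool, name in (
                (library, "library"),
                (mix, "injection_mix"),
                (array, "array"),
                (integrants, "integrants"),
            ):
                pool.to_tsv(out_dir / f"pool_{name}.tsv")
            summary.tallies["simulate"] = {
                "library_unique": library.n_unique,
                "mix_unique": mix.n_unique,
                "array_unique": array.n_unique,
                "integrant_unique": integrants.n_unique,
                "reads_written": n_reads,
            }
            log.info("stage=simulate reads=%d array_unique=%d", n_reads, array.n_unique)
        else:
            stage = "input"
            if not config.fastq:
                raise ValueError("simulate disabled and no input fastq given")
            fastq_path = Path(config.fastq)

        # ---------------- process ----------------
        stage = "process"
        kept, filter_tally = filter_and_crop(read_fastq(fastq_path), config.process)
        pairs, umi_tally = extract_umis(kept, config.process)
        dedup = deduplicate(pairs)
        raw_counts, trim_tally = trim_to_barcode(dedup, config.process.barcode_length)
        summary.tallies["filter"] = filter_tally
        summary.tallies["umi"] = umi_tally
        summary.tallies["dedup"] = {
            "input": dedup.n_reads, "unique_molecules": dedup.n_unique,
        }
        summary.tallies["trim"] = trim_tally
        _write_counts(dict(raw_counts), out_dir / "raw_counts.tsv")
        log.info(
            "stage=process kept=%d unique_molecules=%d raw_barcodes=%d",
            filter_tally.get("kept", 0), dedup.n_unique, len(raw_counts),
        )

        # ---------------- cluster ----------------
        stage = "cluster"
        result = cluster_barcodes(dict(raw_counts), config.cluster)
        _write_counts(result.centroids, out_dir / "corrected_counts.tsv")
        with open(out_dir / "cluster_map.tsv", "w") as fh:
            fh.write("member\tcentroid\tcount\n")
            for member in sorted(result.assignments):
                fh.write(f"{member}\t{result.assignments[member]}\t{raw_counts[member]}\n")
        summary.tallies["cluster"] = {
            "raw_unique": len(raw_counts),
            "centroids": len(result.centroids),
            "dropped_wrong_length": len(result.dropped),
            "mass_in": int(sum(raw_counts.values())),
            "mass_out": int(result.total),
        }
        log.info("stage=cluster centroids=%d", len(result.centroids))

        # ---------------- stats ----------------
        stage = "stats"
        # plateau threshold is selected on raw counts, where the low-count
        # error tail that creates the plateau still exists, then applied to
        # the corrected table
        threshold, fallback = select_threshold(dict(raw_counts), config.stats)
        profile = SampleProfile.from_counts("sample", result.centroids, threshold)
        diversity = summarize_diversity(profile)
        jackpots, reads_frac, unique_frac = jackpot_report(
            result.centroids, config.stats.jackpot_cutoff
        )
        logo = position_probabilities(profile.counts, config.stats.logo_weighting)
        logo.to_csv(out_dir / "logo_matrix.tsv", sep="\t")
        # copy numbers are only known when this run simulated the array
        ztp = None
        if config.simulate.enabled:
            ztp = fit_zt_poisson([int(round(c)) for c in array.entries.values()])
        summary.stats = {
            "threshold": threshold,
            "threshold_fallback_used": fallback,
            "diversity": diversity,
            "jackpot": {
                "cutoff": config.stats.jackpot_cutoff,
                "n_jackpots": len(jackpots),
                "reads_fraction": reads_frac,
                "unique_fraction": unique_frac,
            },
            "fixed_base_conformity": fixed_base_conformity(profile.counts),
            "zt_poisson": ztp,
        }
        _write_json(summary.stats, out_dir / "stats.json")
        _write_json(summary.to_dict(), out_dir / "summary.json")
        validate_summary(summary.to_dict())
        log.info("stage=stats threshold=%d n_unique=%d", threshold, diversity["n_unique"])
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed: {exc}; tallies so far: {summary.tallies}"
        ) from exc
    return summary
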