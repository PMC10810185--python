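"""End-to-end orchestration: simulate -> process -> filter -> profile -> quantify.

A single TOML config drives the whole run; every knob that resolves a
methodological fork elsewhere in the package (trim anchor, dipyrimidine
window reading, overlap fraction, fit method) is a named config key so
alternatives are testable.  The run emits a machine-readable stage report
(read counts surviving every stage, output paths with sha256 checksums) and
is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import composition, damage_filter, metagene, read_processing, spikein_quant
from .io_formats import (RawRead, write_bed6_genes, write_bed6_reads,
                         write_fasta, write_profile_tsv)
from .read_processing import GenomeIndex, LengthRange
from .synthetic_data import SimulationParams, make_genes, make_genome, \
    make_spikein_series, simulate_library

#: Per-species analysis presets: length range and gene-selection thresholds.
SPECIES_PRESETS = {
    "human": {"length_range": (24, 30), "gene_min_length": 5_000,
              "gene_min_distance": 5_000},
    "worm": {"length_range": (20, 28), "gene_min_length": 1_000,
             "gene_min_distance": 500},
    "fly": {"length_range": (25, 30), "gene_min_length": 1_000,
            "gene_min_distance": 100},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


@dataclass
class PipelineConfig:
    seed: int = 0
    species_preset: str = "worm"
    sample_species: str = "worm"
    spike_species: str = "fly"
    # simulation of the sample-species experiment
    sample_sim: dict[str, Any] = field(default_factory=dict)
    spike_sim: dict[str, Any] = field(default_factory=dict)
    dilutions: list[float] = field(
        default_factory=lambda: [1.0, 0.1, 0.01, 1e-3, 1e-4])
    spike_reads: int = 1_000
    #: true relative repair of the simulated "mutant" and background libraries
    mutant_relative: float = 0.01
    background_relative: float = 1e-3
    mutant_input_scale: float = 1.0
    # analysis switches
    window: tuple[int, int] = (4, 10)
    require_both_in_window: bool = True
    trim_k: int = 20
    trim_anchor: str = "three_prime"
    length_range: str | tuple[int, int] = "preset"
    min_overlap_fraction: float = 0.5
    top_n_genes: int = 5_000
    fit_method: str = "origin"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config field {key!r}")
            setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.species_preset not in SPECIES_PRESETS:
            raise ConfigError(
                f"species_preset: unknown preset {self.species_preset!r}")
        for name in ("sample_sim", "spike_sim"):
            sim = getattr(self, name)
            for path_key in ("genome_path", "genes_path", "reads_path"):
                p = sim.get(path_key)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{name}.{path_key}: no such file {p!r}")
        if not self.dilutions:
            raise ConfigError("dilutions: must list at least one dilution")

    def resolved_length_range(self) -> LengthRange:
        if self.length_range == "preset":
            return LengthRange(*SPECIES_PRESETS[self.species_preset]["length_range"])
        return LengthRange(*self.length_range)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_params(overrides: Mapping[str, Any], seed: int) -> SimulationParams:
    kwargs = {k: v for k, v in overrides.items()
              if k not in ("genome_path", "genes_path", "reads_path")}
    if "gene_length_range" in kwargs:
        kwargs["gene_length_range"] = tuple(kwargs["gene_length_range"])
    return SimulationParams(seed=seed, **kwargs)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline and write outputs + a stage report.

    Stages: simulate (sample + spike libraries, dilution series, mutant and
    background libraries) -> process (trim, dedup, align, length filter,
    3'-anchored trim) -> damage filter -> composition -> metagene ->
    spike-in quantification.  Fails fast with the first stage's error.
    Returns the report dict (also written as ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "outputs": {}}
    preset = SPECIES_PRESETS[config.species_preset]

    # --- simulate -----------------------------------------------------------
    sample_params = _sim_params(config.sample_sim, config.seed)
    spike_defaults = {"genome_sizes": {"chrS": 40_000}, "n_genes": 6,
                      "mito_fraction": 0.0}
    spike_params = _sim_params({**spike_defaults, **config.spike_sim},
                               config.seed + 1)
    genome = make_genome(sample_params, rngs[0])
    genes = make_genes(genome, sample_params, rngs[0])
    spike_genome = make_genome(spike_params, rngs[1])
    spike_genes = make_genes(spike_genome, spike_params, rngs[1])

    base = simulate_library(genome, genes, sample_params, rngs[2], "wt")
    spike_lib = simulate_library(spike_genome, spike_genes, spike_params,
                                 rngs[3], "spike")
    series = make_spikein_series(base, spike_lib, config.dilutions,
                                 config.spike_reads, rngs[4])
    extra = make_spikein_series(
        base, spike_lib, [config.mutant_relative, config.background_relative],
        config.spike_reads, rngs[5])
    mutant, background = extra
    mutant.sample_id, background.sample_id = "mutant", "background"

    write_fasta(genome.items(), outdir / "genome.fa")
    write_fasta(spike_genome.items(), outdir / "spike_genome.fa")
    write_bed6_genes(genes, outdir / "genes.bed")
    base.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    report["stages"]["simulate"] = {
        "sample_reads": len(base.raw), "spike_reads": len(spike_lib.raw),
        "series": [lib.sample_id for lib in series]}

    # --- process the undiluted sample library -------------------------------
    index = GenomeIndex(genome)
    spike_index = GenomeIndex(spike_genome)
    length_range = config.resolved_length_range()
    processed = read_processing.process_library(
        base.raw, index, sample_params.adaptor, length_range,
        k=config.trim_k, sample_id="wt")
    window = damage_filter.DipyrimidineWindow(*config.window)
    damaged, dmg_stats = damage_filter.filter_damage(
        processed.reads, window, config.require_both_in_window)
    write_bed6_reads(damaged, outdir / "wt.filtered.bed")
    counts_report = dict(processed.report)
    counts_report["damage_filtered"] = dmg_stats["kept"]
    stage_counts = list(processed.report) + [("damage_filtered",
                                             dmg_stats["kept"])]
    report["stages"]["process"] = counts_report
    # count monotonicity is a pipeline invariant; enforce, do not assume
    surv = [n for _, n in stage_counts]
    if any(b > a for a, b in zip(surv, surv[1:])):
        raise RuntimeError(f"stage survivor counts increased: {stage_counts}")

    # --- composition (pre-damage-filter: the mitochondrial specificity
    # control must not be conditioned on carrying a dipyrimidine) ------------
    profiles = composition.compartment_profiles(processed.reads, k=config.trim_k)
    for name, prof in profiles.items():
        write_profile_tsv(prof.to_frame(), outdir / f"dinucleotide.{name}.tsv")
    report["stages"]["composition"] = {
        name: {"n_reads": prof.n_reads,
               "pyrimidine_peak": composition.pyrimidine_peak(prof)}
        for name, prof in profiles.items()}

    # --- metagene -----------------------------------------------------------
    sel_params = metagene.GeneSelectionParams(
        preset["gene_min_length"], preset["gene_min_distance"])
    contig_lengths = {c: len(s) for c, s in genome.items()}
    selection = metagene.select_genes(genes, sel_params, contig_lengths)
    binned = metagene.bin_genes(selection.kept, contig_lengths)
    counts = metagene.assign_reads(damaged, binned,
                                   config.min_overlap_fraction)
    top = metagene.rank_genes_ts_nts(counts, config.top_n_genes)
    profile = metagene.profile_rpkm(counts, len(damaged), top)
    write_profile_tsv(profile, outdir / "metagene.tsv")
    report["stages"]["metagene"] = {
        "genes_selected": len(selection.kept), "genes_profiled": len(top),
        "body_ts_nts_ratio": metagene.body_ts_nts_ratio(profile)}

    # --- spike-in quantification -------------------------------------------
    def _library_counts(lib, dilution=None, input_scale=1.0):
        trimmed, _ = read_processing.trim_adaptors(lib.raw,
                                                   sample_params.adaptor)
        unique = read_processing.dedup(trimmed)
        sample_seqs, spike_seqs, _ = spikein_quant.partition_by_species(
            (r.sequence for r in unique), index, spike_index)

        def _filtered_count(seqs, idx, rng_lengths):
            aligned, _ = read_processing.align_exact(
                [RawRead(f"q{i}", s) for i, s in enumerate(seqs)], idx)
            kept = read_processing.filter_length(aligned, rng_lengths)
            kept = read_processing.trim_5prime_to(kept, config.trim_k,
                                                  config.trim_anchor)
            kept, _ = damage_filter.filter_damage(kept, window,
                                                  config.require_both_in_window)
            return len(kept)

        spike_range = LengthRange(*SPECIES_PRESETS.get(
            config.spike_species, {"length_range": (19, 30)})["length_range"])
        return spikein_quant.LibraryCounts(
            lib.sample_id,
            _filtered_count(sample_seqs, index, length_range),
            _filtered_count(spike_seqs, spike_index, spike_range),
            dilution=dilution, input_scale=input_scale)

    series_counts = [_library_counts(lib, dilution=lib.true_amount)
                     for lib in series]
    fit = spikein_quant.fit_dilution_curve(series_counts, config.fit_method)
    mutant_counts = _library_counts(mutant,
                                    input_scale=config.mutant_input_scale)
    background_counts = _library_counts(background)
    q_mutant = spikein_quant.percent_of_wt(mutant_counts, fit)
    q_background = spikein_quant.percent_of_wt(background_counts, fit)
    if q_background.percent_of_wt > 0:
        q_mutant.fold_over_background = spikein_quant.fold_over_background(
            q_mutant, q_background)

    quant = pd.DataFrame([
        {"sample": c.sample_id, "n_sample": c.n_sample, "n_spike": c.n_spike,
         "ratio": spikein_quant.ratio(c), "dilution": c.dilution}
        for c in series_counts] + [
        {"sample": q.sample_id, "n_sample": c.n_sample, "n_spike": c.n_spike,
         "ratio": q.ratio, "percent_of_wt": q.percent_of_wt,
         "fold_over_background": q.fold_over_background}
        for q, c in [(q_mutant, mutant_counts),
                     (q_background, background_counts)]])
    quant.to_csv(outdir / "quant.tsv", sep="\t", index=False)
    report["stages"]["quantify"] = {
        "slope": fit.slope, "r_squared": fit.r_squared,
        "mutant_percent_of_wt": q_mutant.percent_of_wt,
        "mutant_fold_over_background": q_mutant.fold_over_background}

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "report.json":
            report["outputs"][path.name] = _sha256(path)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
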