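"""End-to-end pipeline: simulate -> call -> annotate -> validate.

``run_pipeline`` wires the synthetic generator (or, stage-wise, external
inputs via the CLI) through DMR calling, consensus rules, regulatory
annotation, and cohort validation, writing every stage's table to a run
directory plus a machine-readable ``summary.json`` stamped with the seed
and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate, calling, cohort, simulate, summary
from .io import write_dmr_table

logger = logging.getLogger("methdual")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    window: int = 500
    q_cutoff: float = 1e-5
    min_support: int = 2
    validation_q: float = 0.05
    validation_dmc: float = 0.05
    density_bin: int = 5_000
    profile_bin: int = 500_000
    fold_threshold: float = 2.0
    seed: int = 0
    genome: simulate.GenomeConfig = field(default_factory=simulate.GenomeConfig)
    design: simulate.DMRDesign = field(default_factory=simulate.DMRDesign)
    depth: simulate.DepthConfig = field(default_factory=simulate.DepthConfig)
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    n_cell_lines: int = 2

    def __post_init__(self) -> None:
        for name in ("q_cutoff", "validation_q", "validation_dmc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for b in (self.density_bin, self.profile_bin):
            if b % self.window != 0:
                raise ValueError("window width must divide every bin width")
        self.genome.window = self.window

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sensitivity(truth: simulate.TruthSet,
                 eac_cons: list, upsc_cons: list) -> tuple[float, float]:
    """Recovery of planted focal windows and direction accuracy among recovered.

    A shared planted window counts recovered iff it is consensus in both
    types; a type-specific window iff consensus in its own type. Direction
    accuracy is measured over the recovered windows' consensus directions.
    """
    eac = {d.window_index: d.direction for d in eac_cons}
    upsc = {d.window_index: d.direction for d in upsc_cons}
    n = hit = dir_ok = 0
    for p in truth.planted:
        n += 1
        if p.affected == "shared":
            got = p.window_index in eac and p.window_index in upsc
            direction = eac.get(p.window_index)
        elif p.affected == "EAC":
            got = p.window_index in eac
            direction = eac.get(p.window_index)
        else:
            got = p.window_index in upsc
            direction = upsc.get(p.window_index)
        if got:
            hit += 1
            if direction == p.direction:
                dir_ok += 1
    sens = hit / n if n else float("nan")
    dir_acc = dir_ok / hit if hit else float("nan")
    return sens, dir_acc


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Run every stage on synthetic data and return the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    logger.addHandler(log_handler)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    rng_seed = config.seed
    logger.info("simulating genome (seed %d)", rng_seed)
    genome = simulate.generate_genome(config.genome, seed=rng_seed)
    latent, truth = simulate.plant_methylomes(genome, config.design, seed=rng_seed + 1)
    tracks = simulate.simulate_counts(latent, genome, config.depth, seed=rng_seed + 2)
    chromhmm = simulate.simulate_chromhmm(genome, config.n_cell_lines, seed=rng_seed + 3)
    beta_cohort = simulate.simulate_probe_cohort(
        latent, genome, truth, config.cohort, seed=rng_seed + 4)

    logger.info("pairwise DMR calling at q < %g", config.q_cutoff)
    normal = tracks["NE"]
    eac_calls = [calling.call_pairwise_dmrs(normal, tracks[s], config.q_cutoff)
                 for s in simulate.EAC_SAMPLES]
    upsc_calls = [calling.call_pairwise_dmrs(normal, tracks[s], config.q_cutoff)
                  for s in simulate.UPSC_SAMPLES]
    h1_calls = calling.call_pairwise_dmrs(normal, tracks["H1"], config.q_cutoff)

    frame = genome.frame
    eac_cons = calling.consensus_dmrs(eac_calls, "EAC", frame, config.min_support)
    upsc_cons = calling.consensus_dmrs(upsc_calls, "UPSC", frame, config.min_support)
    shared = calling.shared_dmrs(eac_cons, upsc_cons)
    eac_tp, upsc_tp = calling.type_preferred_dmrs(eac_calls, upsc_calls, frame)

    catalog = annotate.FeatureCatalog.from_genome(genome)
    state_map = simulate.default_state_map()
    all_cons = eac_cons + upsc_cons
    h1_dirs = {c.window_index: c.direction for c in h1_calls}
    h1_map = annotate.h1_comparison_of_windows(h1_dirs, [d.window_index for d in all_cons])
    patterns = {d.window_index: annotate.methylation_pattern(d.direction, h1_map[d.window_index])
                for d in all_cons}
    reg_class = annotate.regulatory_class_of_windows(
        [d.interval for d in all_cons], chromhmm, state_map)

    contexts = [annotate.classify_context(d.interval, catalog) for d in all_cons]
    te_fracs, te_table = annotate.te_enrichment_report(all_cons, genome.te_catalog, frame)
    profile = annotate.binned_rpkm_profile(
        normal, [tracks[s] for s in simulate.UPSC_SAMPLES], "medip", config.profile_bin)
    density = annotate.global_density_shift(
        normal, [tracks[s] for s in simulate.TUMOR_SAMPLES],
        config.density_bin, config.fold_threshold)

    logger.info("validating %d shared DMRs against the probe cohort", len(shared))
    val_records = cohort.validate_dmrs(
        [d.interval for d in shared], beta_cohort,
        [d.direction for d in shared], "EAC-like", "normal",
        config.validation_q, config.validation_dmc)
    tested = [r for r in val_records if r.testable]
    validated_frac = (sum(r.validated for r in tested) / len(tested)) if tested else float("nan")

    sens, dir_acc = _sensitivity(truth, eac_cons, upsc_cons)

    # --- write stage outputs ---
    write_dmr_table(eac_cons, out / "dmrs_eac.bed")
    write_dmr_table(upsc_cons, out / "dmrs_upsc.bed")
    write_dmr_table(shared, out / "dmrs_shared.bed")
    write_dmr_table(eac_tp + upsc_tp, out / "dmrs_type_preferred.bed")
    te_table.to_csv(out / "te_enrichment.tsv", sep="\t", index=False)
    profile.to_csv(out / "profile_500kb.tsv", sep="\t", index=False)
    density.to_csv(out / "global_density.tsv", sep="\t", index=False)
    cohort.validation_table(val_records).to_csv(out / "validation.tsv", sep="\t", index=False)

    pattern_counts: dict[str, int] = {}
    for pat in patterns.values():
        key = pat if pat is not None else "undefined"
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
    context_counts: dict[str, int] = {}
    for c in contexts:
        context_counts[c["context"]] = context_counts.get(c["context"], 0) + 1
    reg_counts: dict[str, int] = {}
    for r in reg_class:
        reg_counts[r] = reg_counts.get(r, 0) + 1

    result = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_windows": len(frame),
        "dmr_counts": summary.class_summary({
            "EAC": eac_cons, "UPSC": upsc_cons, "EC-shared": shared,
            "EAC-tp": eac_tp, "UPSC-tp": upsc_tp,
        }),
        "planted_sensitivity": sens,
        "direction_accuracy": dir_acc,
        "context_counts": context_counts,
        "pattern_counts": pattern_counts,
        "regulatory_class_counts": reg_counts,
        "te_fractions": te_fracs.to_dict(orient="records"),
        "validated_fraction": validated_frac,
        "n_validated": int(sum(r.validated for r in tested)),
        "n_testable": len(tested),
        "global_density_mean": density[density["sample"] == "mean"]
            .drop(columns="sample").iloc[0].to_dict(),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(result, fh, indent=2, default=float)
    return result
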