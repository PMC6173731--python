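"""End-to-end orchestration: simulate -> classify -> normalize -> gate scan
-> kinetics -> limiting dilution -> scRNA QC, emitting a report bundle
with a checksum manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .flow_readout import call_colony, call_engraftment, summarize_colonies
from .gates import scan_gates
from .indexsort import batch_correct, pca_markers, transform_table
from .kinetics import build_cumulative, ess_f_test, fit_first_division
from .lda import compare_frequencies, fit_single_hit
from .scqc import qc_filter, select_hvgs, size_factors
from .synthetic import (
    CountsSimConfig,
    GradientConfig,
    LDASimConfig,
    plant_gate_outcomes,
    simulate_counts,
    simulate_indexsort,
    simulate_lda,
)

__all__ = ["ReportBundle", "run_demo"]

logger = logging.getLogger("clonotrace")


@dataclass
class ReportBundle:
    """Emitted files plus a run manifest (versions, seed, checksums)."""

    out_dir: Path
    files: dict = field(default_factory=dict)  # name -> path
    manifest_path: Path | None = None

    def register(self, name: str, path: Path) -> None:
        self.files[name] = Path(path)

    def write_manifest(self, config: PipelineConfig, seed: int, timings: dict) -> None:
        checksums = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in sorted(self.files.items())
        }
        config_hash = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()
        manifest = {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash,
            "files": {name: str(p) for name, p in sorted(self.files.items())},
            "checksums": checksums,
            "timings_s": timings,
        }
        self.manifest_path = self.out_dir / "manifest.json"
        io.write_json(manifest, self.manifest_path)


def _stage(name):
    logger.info("[%s] starting", name)
    return time.time()


def run_demo(config: PipelineConfig, out_dir) -> ReportBundle:
    """Run every stage on synthetic data; deterministic given the seed."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                       format="%(name)s %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    seed = config.seed
    rng_seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    timings: dict[str, float] = {}

    # -- simulate index sort + colonies -------------------------------------
    t0 = _stage("simulate")
    sim = simulate_indexsort(GradientConfig(n_cells=config.sim_n_cells,
                                            seed=int(rng_seeds[0])))
    io.write_indexsort_csv(sim.table, out / "indexsort.csv")
    bundle.register("indexsort_csv", out / "indexsort.csv")
    readouts = io.read_colony_counts_csv
    sim.readouts.to_csv(out / "colony_counts.csv", index=False)
    bundle.register("colony_counts_csv", out / "colony_counts.csv")
    timings["simulate"] = time.time() - t0

    # -- classify colonies ---------------------------------------------------
    t0 = _stage("classify-colonies")
    readouts = io.read_colony_counts_csv(out / "colony_counts.csv")
    calls = [call_colony(r, threshold=config.colony_cell_threshold) for r in readouts]
    io.write_colony_calls_csv(calls, out / "colony_calls.csv")
    bundle.register("colony_calls_csv", out / "colony_calls.csv")
    summary = summarize_colonies(calls)
    summary.to_csv(out / "colony_summary.csv", index=False)
    bundle.register("colony_summary_csv", out / "colony_summary.csv")
    timings["classify"] = time.time() - t0

    # -- normalize index data ------------------------------------------------
    t0 = _stage("normalize-index")
    markers = [c for c in sim.table.columns if c not in ("cell_id", "well", "sort_batch")]
    norm = transform_table(sim.table, markers, m=config.logicle_m)
    lgcl_cols = [m + ".lgcl" for m in markers]
    corrected = batch_correct(norm[lgcl_cols].to_numpy(), norm["sort_batch"].to_numpy())
    norm[lgcl_cols] = corrected
    io.write_indexsort_csv(norm, out / "indexsort_normalized.csv")
    bundle.register("indexsort_normalized_csv", out / "indexsort_normalized.csv")
    pca = pca_markers(corrected, markers=markers)
    io.write_json(
        {
            "variance_explained": pca.variance_explained,
            "loadings": {m: pca.loadings[i].tolist() for i, m in enumerate(markers)},
        },
        out / "pca.json",
    )
    bundle.register("pca_json", out / "pca.json")
    timings["normalize"] = time.time() - t0

    # -- gate scan on planted labels ----------------------------------------
    t0 = _stage("optimize-gates")
    x = norm[config.gate_marker_x + ".lgcl"].to_numpy()
    y = norm[config.gate_marker_y + ".lgcl"].to_numpy()
    planted = pd.DataFrame({config.gate_marker_x: x, config.gate_marker_y: y})
    target, qx, qy = plant_gate_outcomes(
        planted, marker_x=config.gate_marker_x, marker_y=config.gate_marker_y
    )
    scan = scan_gates(
        x, y, target,
        orientation=config.gate_orientation,
        min_occupancy=config.gate_min_occupancy,
        marker_x=config.gate_marker_x,
        marker_y=config.gate_marker_y,
    )
    report = scan.to_dict()
    report["planted_threshold_x"] = qx
    report["planted_threshold_y"] = qy
    io.write_json(report, out / "gates.json")
    bundle.register("gates_json", out / "gates.json")
    scan.grid.to_csv(out / "gate_grid.csv", index=False)
    bundle.register("gate_grid_csv", out / "gate_grid.csv")
    timings["gates"] = time.time() - t0

    # -- division kinetics by gate membership --------------------------------
    t0 = _stage("fit-kinetics")
    in_gate = scan.best_gate.contains(x, y)
    nonempty = sim.true_outcome != "none"
    records = pd.DataFrame(
        {"well_id": sim.table["well"], "time_hours": sim.true_division_time}
    )
    io.write_division_csv(records[nonempty], out / "division_times.csv")
    bundle.register("division_times_csv", out / "division_times.csv")
    curve_in = build_cumulative(records[nonempty & in_gate])
    curve_out = build_cumulative(records[nonempty & ~in_gate])
    fit_in = fit_first_division(curve_in)
    fit_out = fit_first_division(curve_out)
    F, p = ess_f_test(curve_in, curve_out)
    io.write_json(
        {
            "gate_population": fit_in.to_dict(),
            "rest_of_compartment": fit_out.to_dict(),
            "extra_sum_of_squares_F": F,
            "p_value": p,
        },
        out / "kinetics.json",
    )
    bundle.register("kinetics_json", out / "kinetics.json")
    timings["kinetics"] = time.time() - t0

    # -- limiting dilution ----------------------------------------------------
    t0 = _stage("lda")
    cohort_a = simulate_lda(LDASimConfig(
        true_frequency=1 / 13, doses=[1, 3, 10], mice_per_dose=[8, 8, 8],
        group="Subset1", seed=int(rng_seeds[1]),
    ))
    cohort_b = simulate_lda(LDASimConfig(
        true_frequency=1 / 685, doses=[100, 300, 1000], mice_per_dose=[7, 7, 7],
        group="Subset2", seed=int(rng_seeds[2]),
    ))
    io.write_lda_csv([cohort_a, cohort_b], out / "lda_cohorts.csv")
    bundle.register("lda_cohorts_csv", out / "lda_cohorts.csv")
    fit_a = fit_single_hit(cohort_a, level=config.lda_level)
    fit_b = fit_single_hit(cohort_b, level=config.lda_level)
    chi2, p_lda, fold = compare_frequencies(cohort_a, cohort_b)
    io.write_json(
        {
            "Subset1": fit_a.to_dict(),
            "Subset2": fit_b.to_dict(),
            "comparison": {"chi2": chi2, "p": p_lda, "fold": fold},
        },
        out / "lda.json",
    )
    bundle.register("lda_json", out / "lda.json")
    timings["lda"] = time.time() - t0

    # -- scRNA-seq QC ----------------------------------------------------------
    t0 = _stage("scqc")
    matrix, truth = simulate_counts(CountsSimConfig(seed=int(rng_seeds[3])))
    qc = qc_filter(
        matrix,
        min_gene_reads=config.qc_min_gene_reads,
        min_mapping_fraction=config.qc_min_mapping_fraction,
        max_mito_fraction=config.qc_max_mito_fraction,
    )
    factors = size_factors(matrix)
    hvg = select_hvgs(
        matrix, factors,
        mean_for_fit=config.hvg_mean_for_fit, margin=config.hvg_margin,
    )
    truth_hvg = set(truth["is_hvg"][truth["is_hvg"]].index)
    recovered = truth_hvg & set(hvg.hvg_genes)
    io.write_json(
        {
            "n_cells": matrix.counts.shape[1],
            "kept_cells": len(qc.kept_cells),
            "dropped_cells": len(qc.dropped_cells),
            "thresholds": qc.thresholds,
            "n_hvg": len(hvg.hvg_genes),
            "planted_hvg_sensitivity": len(recovered) / max(len(truth_hvg), 1),
            "hvg_fit_coefficients": hvg.coefficients,
        },
        out / "scqc.json",
    )
    bundle.register("scqc_json", out / "scqc.json")
    timings["scqc"] = time.time() - t0

    bundle.write_manifest(config, seed, timings)
    logger.info("bundle written to %s", out)
    return bundle
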