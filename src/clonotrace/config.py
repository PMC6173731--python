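"""Pipeline configuration: YAML loading, defaulting and validation.

The config houses every fixed analysis constant in one place: logicle
decades m = 5.1, the 30-cell colony rule, the 20-cell graft-lineage rule,
the 0.01% engraftment threshold, MeanForFit = 10 for HVG selection, the
gate-scan occupancy floor and the QC thresholds.  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    # logicle / normalization
    logicle_m: float = 5.1
    # classification thresholds
    colony_cell_threshold: int = 30
    graft_lineage_threshold: int = 20
    engraftment_pct_threshold: float = 0.01
    engraftment_min_cells: int = 30
    # gate scan
    gate_min_occupancy: float = 0.10
    gate_orientation: str = "x_hi_y_lo"
    gate_marker_x: str = "CLEC9A"
    gate_marker_y: str = "CD34"
    # kinetics
    kinetics_grid_hours: float = 12.0
    kinetics_censor_hours: float = 96.0
    # limiting dilution
    lda_level: float = 0.95
    # scRNA-seq QC
    qc_min_gene_reads: float = 2e5
    qc_min_mapping_fraction: float = 0.20
    qc_max_mito_fraction: float = 0.20
    hvg_mean_for_fit: float = 10.0
    hvg_margin: float = 0.0
    # simulation sizes for demo mode
    sim_n_cells: int = 400
    # optional input paths (simulation mode when absent)
    indexsort_csv: str | None = None
    colony_counts_csv: str | None = None
    division_csv: str | None = None
    lda_csv: str | None = None
    engraftment_csv: str | None = None
    counts_tsv: str | None = None

    def validate(self) -> "PipelineConfig":
        positive = [
            ("logicle_m", self.logicle_m),
            ("colony_cell_threshold", self.colony_cell_threshold),
            ("graft_lineage_threshold", self.graft_lineage_threshold),
            ("engraftment_pct_threshold", self.engraftment_pct_threshold),
            ("engraftment_min_cells", self.engraftment_min_cells),
            ("kinetics_grid_hours", self.kinetics_grid_hours),
            ("qc_min_gene_reads", self.qc_min_gene_reads),
            ("hvg_mean_for_fit", self.hvg_mean_for_fit),
            ("sim_n_cells", self.sim_n_cells),
        ]
        for name, value in positive:
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for name, value in [
            ("gate_min_occupancy", self.gate_min_occupancy),
            ("lda_level", self.lda_level),
            ("qc_min_mapping_fraction", self.qc_min_mapping_fraction),
            ("qc_max_mito_fraction", self.qc_max_mito_fraction),
        ]:
            if not (0 < value <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {value}")
        for name in (
            "indexsort_csv", "colony_counts_csv", "division_csv",
            "lda_csv", "engraftment_csv", "counts_tsv",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} references a missing file: {path}")
        return self


def validate_config(path) -> PipelineConfig:
    """Load a YAML config, apply defaults, reject unknown keys, validate."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    return PipelineConfig(**raw).validate()
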