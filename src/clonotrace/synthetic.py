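"""Synthetic data generators with planted ground truth.

Every input type the analysis consumes can be generated here with the
statistical structure the analysis assumes, alongside its truth record:

* index-sort tables on a 1-D latent differentiation gradient with
  anti-correlated CLEC9A/CD34 log-intensities, gradient-dependent colony
  outcome probabilities and division times, and per-well gated colony
  counts;
* limiting-dilution cohorts under the single-hit Poisson model;
* negative-binomial gene x cell count matrices with constant spike-ins,
  planted batch shifts and planted high-dispersion (HVG) genes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lda import LDACohort

__all__ = [
    "GradientConfig",
    "SyntheticIndexSort",
    "simulate_indexsort",
    "plant_gate_outcomes",
    "LDASimConfig",
    "simulate_lda",
    "CountsSimConfig",
    "simulate_counts",
]

MARKER_NAMES = [
    "CD19", "CD34", "CD38", "CD45RA", "CD90", "CD49f", "CD10", "CLEC9A", "CD117",
]

#: baseline log10 intensity per marker (arbitrary instrument units);
#: non-gradient channels sit clear of the near-zero linear zone so the
#: CLEC9A/CD34 gradient, not background noise, carries the PCA structure
_MARKER_BASE = {
    "CD19": 2.0, "CD34": 3.0, "CD38": 2.2, "CD45RA": 2.2, "CD90": 2.5,
    "CD49f": 2.5, "CD10": 2.0, "CLEC9A": 3.0, "CD117": 2.3,
}

#: outcome classes with (intercept, slope) logits on centred latent state
_DEFAULT_OUTCOME_LOGITS = {
    "My": (1.0, 0.0),
    "My/Ery": (0.5, -2.5),
    "My/NK": (0.5, 2.5),
    "My/NK/Ery": (-0.5, 0.0),
    "Ery": (-1.2, -2.5),
    "NK": (-1.2, 2.5),
    "none": (-0.2, 0.0),
}

#: median hours to first division per fate class (Ery-containing slowest)
_DEFAULT_DIVISION_MEDIANS = {"ery": 66.0, "nk": 42.0, "my": 54.0, "multi": 60.0}


@dataclass
class GradientConfig:
    """Parameters of the latent-gradient index-sort generator.

    The latent state s ~ Uniform(0,1) orders cells along the
    differentiation continuum: CLEC9A log-intensity falls and CD34 rises
    linearly in s (Gaussian noise on the log scale), all other markers are
    pure noise.  Colony outcomes follow a softmax of per-class linear
    logits in (s - 1/2); division times are lognormal around a fate-class
    median, censored at 96 h on the 12 h grid; per-well gated counts are
    Poisson around ``colony_count_means`` for present lineages.
    """

    n_cells: int = 800
    marker_names: list[str] = field(default_factory=lambda: list(MARKER_NAMES))
    clec9a_slope: float = -1.2   # log10 intensity per unit latent state
    cd34_slope: float = 1.2
    noise_sd: float = 0.25       # log10 intensity SD
    outcome_logit_params: dict = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_LOGITS)
    )
    division_time_medians: dict = field(
        default_factory=lambda: dict(_DEFAULT_DIVISION_MEDIANS)
    )
    division_sigma: float = 0.35  # lognormal sigma of division times
    division_plateau: float = 0.9
    colony_count_means: float = 120.0
    background_sd: float = 8.0    # additive instrument noise (raw units)
    batch_log_shifts: tuple = (0.0, 0.15)
    censor_hours: float = 96.0
    grid_hours: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 < self.division_plateau <= 1):
            raise ValueError("division_plateau must be in (0, 1]")
        for v in (self.clec9a_slope, self.cd34_slope):
            if not np.isfinite(v):
                raise ValueError("slopes must be finite")


@dataclass
class SyntheticIndexSort:
    """Generated index-sort table plus its ground truth."""

    table: pd.DataFrame           # cell_id, well, sort_batch, marker columns
    latent_state: np.ndarray      # per-cell s in [0, 1]
    true_outcome: np.ndarray      # per-cell colony-type label
    true_division_time: np.ndarray  # hours, NaN = censored / never divided
    readouts: pd.DataFrame        # per-well gated counts (ColonyReadout rows)
    config: GradientConfig


def _fate_class(outcome: str) -> str:
    has_ery = "Ery" in outcome
    has_nk = "NK" in outcome
    if has_ery and has_nk:
        return "multi"
    if has_ery:
        return "ery"
    if has_nk:
        return "nk"
    return "my"


def simulate_indexsort(config: GradientConfig) -> SyntheticIndexSort:
    """Generate an index-sort experiment along the latent gradient."""
    cfg = config
    for name, (a, b) in cfg.outcome_logit_params.items():
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError(f"non-finite logit parameters for {name!r}")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    s = rng.uniform(0.0, 1.0, size=n)
    batches = np.array(
        [f"batch{i % len(cfg.batch_log_shifts) + 1}" for i in range(n)]
    )
    shifts = np.array([cfg.batch_log_shifts[i % len(cfg.batch_log_shifts)] for i in range(n)])

    intensities = {}
    for marker in cfg.marker_names:
        base = _MARKER_BASE.get(marker, 2.0)
        if marker == "CLEC9A":
            logi = base + cfg.clec9a_slope * (s - 0.5)
        elif marker == "CD34":
            logi = base + cfg.cd34_slope * (s - 0.5)
        else:
            logi = np.full(n, base)
        logi = logi + shifts + rng.normal(0.0, cfg.noise_sd, size=n)
        raw = 10.0**logi + rng.normal(0.0, cfg.background_sd, size=n)
        intensities[marker] = raw

    # colony outcome: softmax of linear logits in centred s
    classes = list(cfg.outcome_logit_params)
    logits = np.stack(
        [
            a + b * (s - 0.5)
            for a, b in (cfg.outcome_logit_params[c] for c in classes)
        ],
        axis=1,
    )
    prob = np.exp(logits - logits.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    cum = np.cumsum(prob, axis=1)
    draws = rng.uniform(size=n)
    outcome_idx = (draws[:, None] > cum).sum(axis=1)
    outcomes = np.array([classes[i] for i in outcome_idx])

    # first-division times: lognormal around fate-class median, 12 h grid
    med = np.array(
        [
            cfg.division_time_medians[_fate_class(o)] if o != "none" else np.nan
            for o in outcomes
        ]
    )
    raw_t = np.exp(np.log(med) + rng.normal(0.0, cfg.division_sigma, size=n))
    divides = rng.uniform(size=n) < cfg.division_plateau
    t = np.where(divides & (outcomes != "none"), raw_t, np.nan)
    snapped = np.ceil(t / cfg.grid_hours) * cfg.grid_hours
    snapped = np.where(snapped < cfg.grid_hours, cfg.grid_hours, snapped)
    division_time = np.where(snapped <= cfg.censor_hours, snapped, np.nan)

    # per-well gated counts: Poisson around the per-lineage mean
    mu = cfg.colony_count_means
    readout_rows = []
    my_split = rng.integers(0, 3, size=n)  # 0 = Mono, 1 = Gran, 2 = MonoGran
    for i, o in enumerate(outcomes):
        row = {
            "well_id": f"well{i:05d}",
            "assay": "MS5_multilineage",
            "GlyA_pos": 0, "CD41_pos": 0, "CD45_CD14": 0, "CD45_CD15": 0,
            "CD45_CD56": 0, "CD45_CD19": 0, "CD45_CD11b": 0, "CD45_total": 0,
        }
        if o != "none":
            if "My" in o.split("/"):
                if my_split[i] == 0:
                    row["CD45_CD14"] = int(rng.poisson(mu))
                elif my_split[i] == 1:
                    row["CD45_CD15"] = int(rng.poisson(mu))
                else:
                    row["CD45_CD14"] = int(rng.poisson(mu / 2))
                    row["CD45_CD15"] = int(rng.poisson(mu / 2))
            if "NK" in o.split("/"):
                row["CD45_CD56"] = int(rng.poisson(mu))
            if "Ery" in o.split("/"):
                row["GlyA_pos"] = int(rng.poisson(mu))
            row["CD45_total"] = (
                row["CD45_CD14"] + row["CD45_CD15"] + row["CD45_CD56"]
                + row["CD45_CD19"] + row["CD45_CD11b"]
            )
        readout_rows.append(row)
    readouts = pd.DataFrame(readout_rows)

    table = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n)],
            "well": [f"well{i:05d}" for i in range(n)],
            "sort_batch": batches,
            **intensities,
        }
    )
    return SyntheticIndexSort(
        table=table,
        latent_state=s,
        true_outcome=outcomes,
        true_division_time=division_time,
        readouts=readouts,
        config=cfg,
    )


def plant_gate_outcomes(
    table: pd.DataFrame,
    marker_x: str = "CLEC9A",
    marker_y: str = "CD34",
    x_percentile: float = 70.0,
    y_percentile: float = 30.0,
) -> tuple[np.ndarray, float, float]:
    """Deterministic planted gate labels for gate-recovery tests.

    A cell is target-positive iff its ``marker_x`` value lies strictly
    above that marker's ``x_percentile`` and its ``marker_y`` value
    strictly below ``y_percentile``.  Returns (labels, qx, qy) where qx/qy
    are the planted percentile thresholds.
    """
    x = table[marker_x].to_numpy(dtype=float)
    y = table[marker_y].to_numpy(dtype=float)
    qx = float(np.percentile(x, x_percentile))
    qy = float(np.percentile(y, y_percentile))
    return (x > qx) & (y < qy), qx, qy


# ---------------------------------------------------------------------------
# limiting dilution
# ---------------------------------------------------------------------------


@dataclass
class LDASimConfig:
    """Single-hit engraftment cohort generator parameters."""

    true_frequency: float        # repopulating cells per cell transplanted
    doses: list[int] = field(default_factory=lambda: [30, 100, 300])
    mice_per_dose: list[int] = field(default_factory=lambda: [8, 8, 8])
    group: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_frequency < 0:
            raise ValueError("frequency must be non-negative")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if len(self.doses) != len(self.mice_per_dose):
            raise ValueError("doses and mice_per_dose must align")


def simulate_lda(config: LDASimConfig) -> LDACohort:
    """Each mouse engrafts independently with P = 1 - exp(-f * dose)."""
    rng = np.random.default_rng(config.seed)
    f = config.true_frequency
    k = [
        int(rng.binomial(n, 1.0 - np.exp(-f * d)))
        for d, n in zip(config.doses, config.mice_per_dose)
    ]
    return LDACohort(
        group=config.group,
        dose=np.array(config.doses, dtype=float),
        n=np.array(config.mice_per_dose, dtype=int),
        k_engrafted=np.array(k, dtype=int),
    )


# ---------------------------------------------------------------------------
# counts matrices
# ---------------------------------------------------------------------------


@dataclass
class CountsSimConfig:
    """Negative-binomial counts generator parameters.

    Endogenous gene g in cell j has mean mu_g * depth_j * batch_shift and
    NB dispersion phi_g = a / mu_g + b (variance mu + phi * mu^2).
    Spike-ins share one expected value across all cells (no depth or batch
    scaling).  ``n_hvg`` planted genes (chosen among genes with mean above
    the HVG fit window) get dispersion scaled by ``hvg_dispersion_scale``;
    mito gene means are rescaled so they hold ~``mito_fraction`` of
    endogenous reads in expectation.
    """

    n_genes: int = 2000
    n_cells: int = 200
    n_spikeins: int = 50
    mean_log_mu: float = float(np.log(100.0))
    sd_log_mu: float = 1.2
    dispersion_a: float = 0.5
    dispersion_b: float = 0.05
    mito_fraction: float = 0.05
    n_mito: int = 13
    n_hvg: int = 100
    hvg_dispersion_scale: float = 8.0
    batch_shifts: list[float] = field(default_factory=lambda: [0.0, 0.2])
    depth_sd: float = 0.2        # lognormal sd of per-cell depth
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mito_fraction < 1):
            raise ValueError("mito_fraction must be in (0, 1)")
        if self.dispersion_a < 0 or self.dispersion_b <= 0:
            raise ValueError("invalid dispersion parameters (need a >= 0, b > 0)")
        if min(self.n_genes, self.n_cells, self.n_spikeins) < 1:
            raise ValueError("sizes must be positive")


def simulate_counts(config: CountsSimConfig):
    """Generate a CountsMatrix with planted truth.

    Returns (matrix, truth) where truth is a dict holding per-gene means,
    the planted HVG flags, per-cell depth, batch labels and the spike-in
    expected values.
    """
    from .scqc import CountsMatrix

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_g, n_c = cfg.n_genes, cfg.n_cells

    mu = np.exp(rng.normal(cfg.mean_log_mu, cfg.sd_log_mu, size=n_g))
    # mito genes: rescale to hold the configured read share in expectation
    mito_idx = rng.choice(n_g, size=min(cfg.n_mito, n_g), replace=False)
    is_mito = np.zeros(n_g, dtype=bool)
    is_mito[mito_idx] = True
    non_mito_total = mu[~is_mito].sum()
    target_mito_total = cfg.mito_fraction / (1.0 - cfg.mito_fraction) * non_mito_total
    mu[is_mito] *= target_mito_total / mu[is_mito].sum()

    # planted HVGs among genes with mean comfortably above the fit window
    eligible = np.where((mu > 20.0) & ~is_mito)[0]
    hvg_idx = rng.choice(eligible, size=min(cfg.n_hvg, len(eligible)), replace=False)
    is_hvg = np.zeros(n_g, dtype=bool)
    is_hvg[hvg_idx] = True

    phi = cfg.dispersion_a / mu + cfg.dispersion_b
    phi = phi * np.where(is_hvg, cfg.hvg_dispersion_scale, 1.0)

    depth = np.exp(rng.normal(0.0, cfg.depth_sd, size=n_c))
    batch_labels = np.array(
        [f"batch{j % len(cfg.batch_shifts) + 1}" for j in range(n_c)]
    )
    shift = np.exp(
        np.array([cfg.batch_shifts[j % len(cfg.batch_shifts)] for j in range(n_c)])
    )

    mean_mat = mu[:, None] * depth[None, :] * shift[None, :]
    r = 1.0 / phi  # NB size parameter
    p = r[:, None] / (r[:, None] + mean_mat)
    endo_counts = rng.negative_binomial(r[:, None], p)

    spike_mu = np.exp(rng.uniform(np.log(2.0), np.log(2000.0), size=cfg.n_spikeins))
    phi_s = cfg.dispersion_a / spike_mu + cfg.dispersion_b
    r_s = 1.0 / phi_s
    p_s = r_s[:, None] / (r_s[:, None] + spike_mu[:, None])
    spike_counts = rng.negative_binomial(np.broadcast_to(r_s[:, None], (cfg.n_spikeins, n_c)), p_s)

    gene_ids = [
        f"MT-G{i:04d}" if is_mito[i] else f"G{i:04d}" for i in range(n_g)
    ]
    spike_ids = [f"ERCC-{i:05d}" for i in range(cfg.n_spikeins)]
    cell_ids = [f"cell{j:04d}" for j in range(n_c)]
    counts = pd.DataFrame(
        np.vstack([endo_counts, spike_counts]),
        index=gene_ids + spike_ids,
        columns=cell_ids,
    )

    reads_in_genes = counts.loc[gene_ids].sum(axis=0)
    total_reads = (reads_in_genes / rng.uniform(0.4, 0.7, size=n_c)).astype(int)
    cell_meta = pd.DataFrame(
        {
            "total_reads": total_reads,
            "reads_in_genes": reads_in_genes,
            "batch": batch_labels,
        },
        index=cell_ids,
    )
    matrix = CountsMatrix.from_counts(counts, cell_meta=cell_meta)
    truth = {
        "gene_means": pd.Series(mu, index=gene_ids),
        "is_hvg": pd.Series(is_hvg, index=gene_ids),
        "is_mito": pd.Series(is_mito, index=gene_ids),
        "spike_means": pd.Series(spike_mu, index=spike_ids),
        "depth": pd.Series(depth, index=cell_ids),
        "batch": pd.Series(batch_labels, index=cell_ids),
        "dispersion": pd.Series(phi, index=gene_ids),
    }
    return matrix, truth
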