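"""Exhaustive in-silico scan of two-marker sorting-gate thresholds.

Given index-sorted cells with known colony outcomes, the scan evaluates
every axis-aligned rectangular gate whose thresholds sit at observed
marker values and returns the gate maximizing enrichment of a target
outcome, subject to a minimum occupancy (fraction of the compartment
inside the gate).  This is the procedure that derives CLEC9A/CD34 sorting
gates (CLEC9A-hi/CD34-lo vs CLEC9A-lo/CD34-hi) from single-cell outcome
data.

Gate membership, by orientation:

* ``x_hi_y_lo`` — x >= threshold_x and y <= threshold_y
* ``x_lo_y_hi`` — x <= threshold_x and y >= threshold_y

Membership uses order comparisons only, so the scan is invariant to any
strictly increasing transform applied jointly to data and thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GateSpec", "GateScanResult", "scan_gates", "evaluate_gate"]

ORIENTATIONS = ("x_hi_y_lo", "x_lo_y_hi")


@dataclass(frozen=True)
class GateSpec:
    """Axis-aligned rectangular gate in a two-marker plane."""

    marker_x: str = "CLEC9A"
    marker_y: str = "CD34"
    threshold_x: float = 0.0
    threshold_y: float = 0.0
    orientation: str = "x_hi_y_lo"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation: {self.orientation!r}")
        if not (np.isfinite(self.threshold_x) and np.isfinite(self.threshold_y)):
            raise ValueError("thresholds must be finite")

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.orientation == "x_hi_y_lo":
            return (x >= self.threshold_x) & (y <= self.threshold_y)
        return (x <= self.threshold_x) & (y >= self.threshold_y)


@dataclass
class GateScanResult:
    """Best gate plus the full evaluated grid."""

    best_gate: GateSpec
    enrichment: float
    occupancy: float
    grid: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "marker_x": self.best_gate.marker_x,
            "marker_y": self.best_gate.marker_y,
            "threshold_x": self.best_gate.threshold_x,
            "threshold_y": self.best_gate.threshold_y,
            "orientation": self.best_gate.orientation,
            "enrichment": self.enrichment,
            "occupancy": self.occupancy,
        }


def scan_gates(
    x,
    y,
    target,
    orientation: str = "x_hi_y_lo",
    min_occupancy: float = 0.10,
    marker_x: str = "CLEC9A",
    marker_y: str = "CD34",
) -> GateScanResult:
    """Scan all threshold pairs and maximize target enrichment.

    Parameters
    ----------
    x, y : arrays of float
        Normalized marker values per cell (colony-forming cells only).
    target : boolean array
        Whether each cell's outcome matches the target predicate.
    orientation : str
        Which corner of the plane is inside the gate.
    min_occupancy : float
        Smallest admissible fraction of cells inside the gate.

    Candidate thresholds are all observed values of each marker.  Ties on
    enrichment break toward larger occupancy, then smaller threshold_x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    target = np.asarray(target, dtype=bool)
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 cells with outcomes")
    if not (len(y) == n == len(target)):
        raise ValueError("x, y and target must have equal length")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation: {orientation!r}")

    ux = np.unique(x)
    uy = np.unique(y)
    ix = np.searchsorted(ux, x)
    iy = np.searchsorted(uy, y)
    H = np.zeros((len(ux), len(uy)))
    Ht = np.zeros_like(H)
    np.add.at(H, (ix, iy), 1.0)
    np.add.at(Ht, (ix, iy), target.astype(float))

    if orientation == "x_hi_y_lo":
        # gate count for (tx=ux[i], ty=uy[j]) = cells with x >= ux[i], y <= uy[j]
        cx = np.cumsum(H[::-1], axis=0)[::-1]
        cnt = np.cumsum(cx, axis=1)
        cxt = np.cumsum(Ht[::-1], axis=0)[::-1]
        cnt_t = np.cumsum(cxt, axis=1)
    else:
        cx = np.cumsum(H, axis=0)
        cnt = np.cumsum(cx[:, ::-1], axis=1)[:, ::-1]
        cxt = np.cumsum(Ht, axis=0)
        cnt_t = np.cumsum(cxt[:, ::-1], axis=1)[:, ::-1]

    occ = cnt / n
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = np.where(cnt > 0, cnt_t / np.maximum(cnt, 1), np.nan)

    ok = occ >= min_occupancy - 1e-12
    if not ok.any():
        raise ValueError("no gate satisfies the occupancy constraint")

    enr_ok = np.where(ok, enr, -np.inf)
    best_e = enr_ok.max()
    cand = np.argwhere(np.isclose(enr_ok, best_e, rtol=0, atol=1e-12))
    # tie-break: larger occupancy, then smaller threshold_x
    occ_c = occ[cand[:, 0], cand[:, 1]]
    keep = cand[np.isclose(occ_c, occ_c.max(), atol=1e-12)]
    tx_c = ux[keep[:, 0]]
    best = keep[np.argmin(tx_c)]

    # report the tightest threshold pair describing the selected cell set:
    # threshold values inside empty gaps are non-identifiable, so snap to
    # the extreme member values (preserves membership exactly)
    probe = GateSpec(
        marker_x=marker_x, marker_y=marker_y,
        threshold_x=float(ux[best[0]]), threshold_y=float(uy[best[1]]),
        orientation=orientation,
    )
    members = probe.contains(x, y)
    if orientation == "x_hi_y_lo":
        tight_x, tight_y = x[members].min(), y[members].max()
    else:
        tight_x, tight_y = x[members].max(), y[members].min()
    gate = GateSpec(
        marker_x=marker_x,
        marker_y=marker_y,
        threshold_x=float(tight_x),
        threshold_y=float(tight_y),
        orientation=orientation,
    )
    gx, gy = np.meshgrid(np.arange(len(ux)), np.arange(len(uy)), indexing="ij")
    grid = pd.DataFrame(
        {
            "threshold_x": ux[gx.ravel()],
            "threshold_y": uy[gy.ravel()],
            "enrichment": enr.ravel(),
            "occupancy": occ.ravel(),
        }
    )
    return GateScanResult(
        best_gate=gate,
        enrichment=float(enr[best[0], best[1]]),
        occupancy=float(occ[best[0], best[1]]),
        grid=grid,
    )


def threshold_step_distance(
    gate: GateSpec, x, y, planted_x: float, planted_y: float
) -> tuple[int, int]:
    """Grid-step distance between a recovered gate and planted thresholds.

    A threshold value is identifiable only up to the cells that would
    change gate membership, so distance is counted in *gate-relevant*
    cells: for the x axis, cells on the gate's y side lying strictly
    between the recovered and planted x thresholds (and symmetrically for
    y).  (0, 0) means the recovered thresholds are the nearest admissible
    candidates to the planted values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo_x, hi_x = sorted((gate.threshold_x, planted_x))
    lo_y, hi_y = sorted((gate.threshold_y, planted_y))
    if gate.orientation == "x_hi_y_lo":
        relevant_x = y <= gate.threshold_y
        relevant_y = x >= gate.threshold_x
    else:
        relevant_x = y >= gate.threshold_y
        relevant_y = x <= gate.threshold_x
    dx = int(np.sum(relevant_x & (x > lo_x) & (x < hi_x)))
    dy = int(np.sum(relevant_y & (y > lo_y) & (y < hi_y)))
    return dx, dy


def evaluate_gate(gate: GateSpec, x, y, outcomes) -> dict:
    """Outcome composition inside a gate.

    Returns per-outcome fractions over the cells inside the gate (summing
    to 1) and the gate occupancy.  Raises on an empty gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    outcomes = np.asarray(outcomes)
    inside = gate.contains(x, y)
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError("gate contains no cells")
    vals, counts = np.unique(outcomes[inside], return_counts=True)
    return {
        "composition": {str(v): c / n_in for v, c in zip(vals, counts)},
        "occupancy": n_in / len(x),
        "n_cells": n_in,
    }
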