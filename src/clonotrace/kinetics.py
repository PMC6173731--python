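"""Quiescence-exit kinetics from single-cell first-division times.

Wells are inspected on a 12 h grid for 4 days; each well either shows a
first division at some grid time or is censored at 96 h.  The cumulative
fraction divided by time t (censored wells count in the denominator only)
is summarized by a Hill-type sigmoid in linear time,

    F(t) = plateau / (1 + (ec50 / t)^hill),        bottom fixed at 0,

fitted by ordinary (unweighted) least squares.  ``ec50`` is the mean time
to first division; ``plateau`` absorbs wells that never divide.  Two
curves are compared with the extra-sum-of-squares F-test (all three
parameters shared vs free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OBSERVATION_GRID",
    "build_cumulative",
    "FirstDivisionModel",
    "FirstDivisionResults",
    "fit_first_division",
    "ess_f_test",
]

#: 12 h observation grid over 4 days
OBSERVATION_GRID = np.arange(12.0, 97.0, 12.0)


def build_cumulative(
    records: pd.DataFrame, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Cumulative first-division curve from per-well records.

    Parameters
    ----------
    records : DataFrame
        Columns ``well_id`` and ``time_hours``; NaN time means the well was
        censored (no division by the end of observation).  Empty wells are
        excluded upstream and never appear here.
    grid : array of float, optional
        Observation times; defaults to 12..96 h every 12 h.

    Returns
    -------
    DataFrame with columns ``t`` and ``fraction``; the denominator is all
    wells (censored wells never enter the numerator), so the curve is
    non-decreasing by construction.
    """
    if len(records) == 0:
        raise ValueError("no well records")
    if grid is None:
        grid = OBSERVATION_GRID
    times = records["time_hours"].to_numpy(dtype=float)
    n = len(times)
    observed = times[~np.isnan(times)]
    frac = np.array([(observed <= t).sum() / n for t in grid])
    return pd.DataFrame({"t": np.asarray(grid, dtype=float), "fraction": frac})


def _hill(t, ec50, hill, plateau):
    return plateau / (1.0 + (ec50 / t) ** hill)


class FirstDivisionModel:
    """Sigmoid model of a cumulative first-division curve.

    Parameters
    ----------
    t : array of float
        Observation times (hours); must be positive.
    fraction : array of float
        Cumulative fraction of wells divided by each time.
    """

    def __init__(self, t, fraction):
        self.t = np.asarray(t, dtype=float)
        self.fraction = np.asarray(fraction, dtype=float)
        if len(self.t) != len(self.fraction):
            raise ValueError("t and fraction must have equal length")
        if np.any(self.t <= 0):
            raise ValueError("times must be positive")
        if len(self.t) < 4:
            raise ValueError("need at least 4 curve points for a 3-parameter fit")
        if np.count_nonzero(np.unique(self.fraction[self.fraction > 0])) < 2:
            raise ValueError("degenerate curve: fewer than 2 distinct nonzero fractions")

    @classmethod
    def from_records(cls, records: pd.DataFrame, grid=None) -> "FirstDivisionModel":
        curve = build_cumulative(records, grid=grid)
        return cls(curve["t"], curve["fraction"])

    from_dataframe = from_records

    def fit(self) -> "FirstDivisionResults":
        """Ordinary least squares with multi-start initialization.

        Fitting runs on time rescaled by max(t) and the fitted ec50 is
        mapped back, so rescaling the time axis (hours -> minutes) rescales
        ec50 exactly and leaves hill and plateau bit-identical.
        """
        scale = float(self.t.max())
        ts = self.t / scale
        y = self.fraction

        # ec50 starts: quantiles of time weighted by curve increments
        inc = np.diff(np.concatenate([[0.0], y]))
        inc = np.clip(inc, 0.0, None)
        if inc.sum() > 0:
            order = np.argsort(ts)
            cw = np.cumsum(inc[order]) / inc.sum()
            ec50_starts = [
                float(ts[order][np.searchsorted(cw, q)]) for q in (0.25, 0.5, 0.75)
            ]
        else:
            ec50_starts = [float(np.median(ts))]
        plateau0 = float(np.clip(y.max(), 1e-3, 1.0))

        best = None
        lower = [1e-6, 0.05, 1e-6]
        upper = [1e3, 60.0, 1.0]
        for e0 in dict.fromkeys(ec50_starts):
            for h0 in (1.0, 2.0, 4.0):
                p0 = [np.clip(e0, lower[0], upper[0]), h0, plateau0]
                try:
                    popt, _ = optimize.curve_fit(
                        _hill, ts, y, p0=p0, bounds=(lower, upper),
                        maxfev=20000, method="trf",
                    )
                except RuntimeError:
                    continue
                rss = float(np.sum((y - _hill(ts, *popt)) ** 2))
                if best is None or rss < best[1]:
                    best = (popt, rss)
        if best is None:
            raise RuntimeError("sigmoid fit did not converge from any start")
        (ec50s, hill, plateau), rss = best
        return FirstDivisionResults(
            model=self,
            ec50=float(ec50s * scale),
            hill=float(hill),
            plateau=float(plateau),
            rss=rss,
            df=len(self.t) - 3,
            n_points=len(self.t),
        )


@dataclass
class FirstDivisionResults:
    """Fitted sigmoid: ec50 (hours), hill slope, plateau, residual SS."""

    model: FirstDivisionModel
    ec50: float
    hill: float
    plateau: float
    rss: float
    df: int
    n_points: int

    def predict(self, t) -> np.ndarray:
        return _hill(np.asarray(t, dtype=float), self.ec50, self.hill, self.plateau)

    def summary(self) -> str:
        return "\n".join(
            [
                "First-division sigmoid fit",
                "==========================",
                f"ec50 (h):   {self.ec50:.3f}",
                f"hill slope: {self.hill:.3f}",
                f"plateau:    {self.plateau:.4f}",
                f"RSS:        {self.rss:.6g}  (df = {self.df}, n = {self.n_points})",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "ec50": self.ec50,
            "hill": self.hill,
            "plateau": self.plateau,
            "rss": self.rss,
            "df": self.df,
            "n_points": self.n_points,
        }

    def plot(self, ax=None, **kwargs):
        """Plot the curve points and the fitted sigmoid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.t, m.fraction, "o", **kwargs)
        tt = np.linspace(m.t.min() / 2, m.t.max(), 200)
        ax.plot(tt, self.predict(tt), "-")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cumulative fraction divided")
        return ax


def fit_first_division(curve: pd.DataFrame) -> FirstDivisionResults:
    """Fit the sigmoid to a (t, fraction) curve table."""
    return FirstDivisionModel(curve["t"], curve["fraction"]).fit()


def ess_f_test(
    curve_a: pd.DataFrame, curve_b: pd.DataFrame
) -> tuple[float, float]:
    """Extra-sum-of-squares F-test comparing two first-division curves.

    Null: one 3-parameter sigmoid for the pooled points
    (df0 = n_a + n_b - 3); alternative: separate sigmoids
    (df1 = n_a + n_b - 6).  F = ((RSS0 - RSS1)/3) / (RSS1/df1), referred to
    the F(3, df1) distribution.
    """
    fit_a = fit_first_division(curve_a)
    fit_b = fit_first_division(curve_b)
    pooled = pd.DataFrame(
        {
            "t": np.concatenate([np.asarray(curve_a["t"]), np.asarray(curve_b["t"])]),
            "fraction": np.concatenate(
                [np.asarray(curve_a["fraction"]), np.asarray(curve_b["fraction"])]
            ),
        }
    )
    fit_0 = fit_first_division(pooled)
    rss1 = fit_a.rss + fit_b.rss
    df1 = fit_a.n_points + fit_b.n_points - 6
    if df1 <= 0:
        raise ValueError("not enough points for separate fits (df1 <= 0)")
    rss0 = fit_0.rss
    F = max(rss0 - rss1, 0.0) / 3.0 / (rss1 / df1)
    p = float(stats.f.sf(F, 3, df1))
    return float(F), p
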