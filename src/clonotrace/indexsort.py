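"""Normalization and analysis of index-sorted flow-cytometry intensities.

Index sorting records every sorted single cell's full marker intensity
vector.  Raw instrument intensities span decades and can be negative near
zero, so channels are put on the logicle (biexponential) scale — linear
near zero, logarithmic at high intensity — with per-channel parameters
estimated from the data.  Multi-day sorts are then harmonized with a
parametric empirical-Bayes location/scale batch adjustment, and the
normalized marker matrix is summarized by PCA with loadings.

The forward biexponential with A = 0 is

    B(y) = T * 10^-(M-W) * (10^(y-W) - p^2 * 10^-((y-W)/p) + p^2 - 1)

for y >= W, extended odd-symmetrically about y = W, where p solves
W = 2 p log10(p) / (p + 1).  ``logicle`` inverts B by monotone bracketed
root-finding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LogicleParams",
    "estimate_logicle_params",
    "biexponential",
    "logicle",
    "batch_correct",
    "PCAResult",
    "pca_markers",
    "median_shift",
    "group_tests",
]


# ---------------------------------------------------------------------------
# logicle transform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicleParams:
    """Logicle scale parameters.

    T : top of scale (instrument units); M : total decades;
    W : linearization width (decades); A : additional negative decades
    (0 here); p : auxiliary root of W = 2 p log10(p) / (p + 1).
    """

    T: float
    M: float
    W: float
    A: float = 0.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0 or self.M <= 0:
            raise ValueError("T and M must be positive")
        if not (0 <= self.W < self.M / 2):
            raise ValueError("W must satisfy 0 <= W < M/2")


def _solve_p(W: float) -> float:
    """p > 1 solving W = 2 p log10(p) / (p + 1); p = 1 when W = 0."""
    if W == 0:
        return 1.0
    f = lambda p: 2.0 * p * np.log10(p) / (p + 1.0) - W
    return float(optimize.brentq(f, 1.0 + 1e-12, 1e6, xtol=1e-14))


def make_logicle_params(T: float, M: float, W: float, A: float = 0.0) -> LogicleParams:
    return LogicleParams(T=T, M=M, W=W, A=A, p=_solve_p(W))


def estimate_logicle_params(
    x, m: float = 5.1, T: float | None = None
) -> LogicleParams:
    """Data-driven logicle parameters for one channel.

    T defaults to the channel maximum; W is set from the 5th percentile r
    of the negative events as W = max(0, (m - log10(T/|r|)) / 2), and 0
    when there are no negative events.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("channel data must be non-empty and finite")
    if m <= 0:
        raise ValueError("decades m must be positive")
    if T is None:
        T = float(np.max(x))
    if T <= 0:
        raise ValueError("top of scale must be positive (all values <= 0?)")
    neg = x[x < 0]
    if neg.size == 0:
        W = 0.0
    else:
        r = np.percentile(neg, 5)
        W = max(0.0, (m - np.log10(T / abs(r))) / 2.0)
    return make_logicle_params(T=T, M=m, W=W)


def biexponential(y, params: LogicleParams) -> np.ndarray:
    """Forward map from logicle decades y to instrument intensity."""
    y = np.asarray(y, dtype=float)
    T, M, W, p = params.T, params.M, params.W, params.p
    d = y - W
    s = np.sign(d)
    a = np.abs(d)
    core = 10.0**a - p**2 * 10.0 ** (-a / p) + p**2 - 1.0
    return T * 10.0 ** (-(M - W)) * s * core


def logicle(x, params: LogicleParams) -> np.ndarray:
    """Inverse of the biexponential: decades y with B(y) = x, y in [0, M].

    Strictly increasing; |B(y) - x| <= 1e-8 * max(1, |x|).
    """
    x = np.asarray(x, dtype=float)
    lo_val = biexponential(0.0, params)
    if np.any(x < lo_val - 1e-9 * max(1.0, abs(lo_val))) or np.any(
        x > params.T * (1 + 1e-12)
    ):
        raise ValueError("intensity outside the representable range [B(0), T]")

    def invert(v: float) -> float:
        hi = params.M
        # B(M) can undershoot T by ~T*10^(-2M); widen the bracket minimally
        while biexponential(hi, params) < v and hi < params.M + 2.0:
            hi += 0.25
        return optimize.brentq(
            lambda y: biexponential(y, params) - v, 0.0, hi, xtol=1e-13
        )

    out = np.array([invert(float(v)) for v in np.atleast_1d(x)])
    return out if x.ndim else float(out[0])


def transform_table(
    table: pd.DataFrame, markers: list[str], m: float = 5.1, suffix: str = ".lgcl"
) -> pd.DataFrame:
    """Logicle-transform marker columns; adds ``<marker><suffix>`` columns.

    Values outside the representable range [B(0), T] — e.g. the most
    negative events below the W-estimation percentile — are clamped to the
    range edge before transforming, as flow display tools do.
    """
    out = table.copy()
    for marker in markers:
        vals = out[marker].to_numpy(dtype=float)
        params = estimate_logicle_params(vals, m=m)
        lo = biexponential(0.0, params)
        out[marker + suffix] = logicle(np.clip(vals, lo, params.T), params)
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction (parametric location/scale adjustment)
# ---------------------------------------------------------------------------


def batch_correct(
    matrix, batches, tol: float = 1e-4, max_iter: int = 200
) -> np.ndarray:
    """Remove per-batch location/scale effects (parametric empirical Bayes).

    Features are standardized, per-batch means (gamma) and variances
    (delta^2) get moment-matched normal and inverse-gamma priors, posterior
    estimates are iterated to convergence, and the adjusted data are
    restored to the original scale.  Each feature's grand mean is then
    recentred exactly to its input value.  Zero-variance features pass
    through unchanged; a single batch returns the input unchanged.

    Parameters
    ----------
    matrix : (cells x features) array
    batches : length-cells labels
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (cells x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    batches = np.asarray(batches)
    if len(batches) != X.shape[0]:
        raise ValueError("batch labels must match the number of cells")
    labels, batch_idx = np.unique(batches, return_inverse=True)
    n_batches = len(labels)
    counts = np.bincount(batch_idx)
    if np.any(counts < 2):
        raise ValueError("every batch needs at least 2 cells")
    if n_batches == 1:
        return X.copy()

    n_cells, n_feat = X.shape
    grand_mean_in = X.mean(axis=0)
    col_var = X.var(axis=0)
    active = col_var > 0
    out = X.copy()
    Xa = X[:, active]
    if Xa.shape[1] == 0:
        return out

    # batch-structure fit: per-batch, per-feature means
    batch_means = np.vstack([Xa[batch_idx == i].mean(axis=0) for i in range(n_batches)])
    weights = counts / n_cells
    stand_mean = weights @ batch_means  # per-feature
    resid = Xa - batch_means[batch_idx]
    var_pooled = (resid**2).sum(axis=0) / n_cells
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    Z = (Xa - stand_mean) / np.sqrt(var_pooled)

    adjusted = np.empty_like(Z)
    for i in range(n_batches):
        Zi = Z[batch_idx == i]
        ni = counts[i]
        gamma_hat = Zi.mean(axis=0)
        delta_hat = Zi.var(axis=0, ddof=1)
        # hyperpriors by method of moments
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if len(gamma_hat) > 1 else 0.0
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1) if len(delta_hat) > 1 else 0.0
        if d_var > 0:
            a_prior = (2.0 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
        else:
            a_prior = b_prior = None

        gamma_star = gamma_hat.copy()
        delta_star = np.where(delta_hat > 0, delta_hat, 1.0)
        if tau2 > 0 and a_prior is not None:
            sum_sq0 = ((Zi - gamma_star) ** 2).sum(axis=0)
            for _ in range(max_iter):
                g_new = (ni * tau2 * gamma_hat + delta_star * gamma_bar) / (
                    ni * tau2 + delta_star
                )
                sum_sq = ((Zi - g_new) ** 2).sum(axis=0)
                d_new = (b_prior + 0.5 * sum_sq) / (ni / 2.0 + a_prior - 1.0)
                change = max(
                    np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-12)),
                    np.max(np.abs(d_new - delta_star) / np.maximum(np.abs(delta_star), 1e-12)),
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
            del sum_sq0
        else:
            # degenerate hyperprior (e.g. identical features): no shrinkage
            gamma_star = np.full_like(gamma_hat, gamma_bar) if tau2 == 0 else gamma_hat

        adjusted[batch_idx == i] = (Zi - gamma_star) / np.sqrt(delta_star)

    result = adjusted * np.sqrt(var_pooled) + stand_mean
    # exact grand-mean restoration per feature
    result += grand_mean_in[active] - result.mean(axis=0)
    out[:, active] = result
    return out


# ---------------------------------------------------------------------------
# PCA with loadings
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Scores (cells x comps), unit-norm loadings (markers x comps),
    per-component variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    markers: list[str] | None = None

    def top_loadings(self, component: int = 0, k: int = 3) -> pd.Series:
        """Markers with the largest absolute loadings on one component."""
        lo = pd.Series(
            self.loadings[:, component],
            index=self.markers
            if self.markers is not None
            else range(self.loadings.shape[0]),
        )
        return lo.reindex(lo.abs().sort_values(ascending=False).index).head(k)


def pca_markers(matrix, markers: list[str] | None = None, scale: bool = False) -> PCAResult:
    """PCA of a cells x markers matrix via SVD.

    Columns are mean-centered (variance-scaled only if ``scale``).  Sign
    convention: within each component the loading of largest magnitude is
    positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 markers")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention
    for j in range(Vt.shape[0]):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s**2
    return PCAResult(
        scores=scores,
        loadings=Vt.T,
        variance_explained=var / var.sum(),
        markers=markers,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def median_shift(values_a, values_b) -> float:
    """Percent shift of group a's median relative to reference group b,
    on raw (untransformed) intensities: 100 * (med_a - med_b) / med_b."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = np.median(b)
    if mb == 0:
        raise ValueError("reference median is zero")
    return float(100.0 * (np.median(a) - mb) / mb)


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn z-tests on pooled ranks with Bonferroni adjustment."""
    groups = np.unique(labels)
    N = len(values)
    ranks = stats.rankdata(values)
    # tie correction
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {"group_1": g1, "group_2": g2, "statistic": z, "p": p,
             "p_adjusted": min(1.0, p * len(pairs))}
        )
    return pd.DataFrame(rows)


def group_tests(values, labels, design: str = "kruskal"):
    """Group comparisons, dispatched to standard implementations.

    design:
      * ``"kruskal"``      — Kruskal–Wallis omnibus + Dunn/Bonferroni pairs
      * ``"anova"``        — one-way ANOVA + Tukey HSD pairs
      * ``"mannwhitney"``  — two-group Mann–Whitney U
      * ``"paired_t"``     — two-group paired t-test
      * ``"fisher"``       — 2x2 Fisher exact test; ``values`` is the table

    Returns a dict with ``statistic``, ``p`` and, for omnibus designs, a
    ``pairwise`` DataFrame with adjusted p-values.
    """
    if design == "fisher":
        table = np.asarray(values)
        if table.shape != (2, 2):
            raise ValueError("fisher design needs a 2x2 table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return {"design": design, "statistic": float(odds), "p": float(p)}

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    samples = [values[labels == g] for g in groups]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")

    if design in ("kruskal", "anova"):
        if len(groups) < 2:
            raise ValueError("omnibus tests need at least 2 groups")
        if design == "kruskal":
            if all(np.all(s == samples[0][0]) for s in samples):
                stat, p = 0.0, 1.0  # scipy raises on all-identical input
            else:
                stat, p = stats.kruskal(*samples)
            pairwise = _dunn_posthoc(values, labels)
        else:
            stat, p = stats.f_oneway(*samples)
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            tk = pairwise_tukeyhsd(values, labels)
            pairwise = pd.DataFrame(
                data=tk.summary().data[1:], columns=tk.summary().data[0]
            ).rename(columns={"p-adj": "p_adjusted"})
        return {
            "design": design,
            "statistic": float(stat),
            "p": float(p),
            "pairwise": pairwise,
        }

    if len(groups) != 2:
        raise ValueError(f"{design} needs exactly 2 groups")
    a, b = samples
    if design == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif design == "paired_t":
        if len(a) != len(b):
            raise ValueError("paired design needs equal group sizes")
        stat, p = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown design: {design!r}")
    return {"design": design, "statistic": float(stat), "p": float(p)}
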