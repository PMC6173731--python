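"""Limiting-dilution analysis under the single-hit Poisson model.

A transplant of ``d`` cells engrafts iff it contains at least one
repopulating cell.  If repopulating cells occur at frequency ``f`` per cell
transplanted, the number of such cells in a graft is Poisson(f*d) and

    P(mouse negative at dose d) = exp(-f * d).

Given cohort rows (dose d_i, n_i mice transplanted, k_i engrafted) the
log-likelihood is

    l(f) = sum_i [ (n_i - k_i) * (-f * d_i) + k_i * log(1 - exp(-f * d_i)) ]

which is strictly concave in f whenever any mouse engrafted.  The MLE is
found by root-finding on the score; cohorts with 0% or 100% response sit on
the boundary of the parameter space and are handled with one-sided
profile-likelihood bounds, in the spirit of extreme limiting dilution
analysis (ELDA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LDACohort",
    "SingleHitModel",
    "SingleHitResults",
    "fit_single_hit",
    "frequency_ci",
    "compare_frequencies",
]


@dataclass
class LDACohort:
    """Dose-response rows for one transplanted population.

    Parameters
    ----------
    group : str
        Population label (e.g. ``"Subset1"``).
    dose : array-like of float
        Cells transplanted per mouse, one entry per dose level.
    n : array-like of int
        Mice transplanted at each dose.
    k_engrafted : array-like of int
        Mice engrafted at each dose.
    """

    group: str
    dose: np.ndarray
    n: np.ndarray
    k_engrafted: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.k_engrafted = np.asarray(self.k_engrafted, dtype=int)
        if self.dose.ndim != 1 or len(self.dose) == 0:
            raise ValueError("cohort needs at least one dose row")
        if not (len(self.dose) == len(self.n) == len(self.k_engrafted)):
            raise ValueError("dose, n and k_engrafted must have equal length")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if np.any(self.n <= 0):
            raise ValueError("mice counts must be positive")
        if np.any(self.k_engrafted < 0) or np.any(self.k_engrafted > self.n):
            raise ValueError("k_engrafted must satisfy 0 <= k <= n")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group: str | None = None) -> "LDACohort":
        """Build a cohort from a table with columns group, dose, n, k_engrafted."""
        if group is not None:
            df = df[df["group"] == group]
            label = group
        else:
            labels = df["group"].unique() if "group" in df else ["cohort"]
            if len(labels) > 1:
                raise ValueError(
                    "table holds multiple groups; pass group= to select one"
                )
            label = str(labels[0])
        return cls(
            group=label,
            dose=df["dose"].to_numpy(),
            n=df["n"].to_numpy(),
            k_engrafted=df["k_engrafted"].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "dose": self.dose,
                "n": self.n,
                "k_engrafted": self.k_engrafted,
            }
        )


class SingleHitModel:
    """Single-hit Poisson dose-response model for one cohort.

    ``fit()`` returns a :class:`SingleHitResults` carrying the frequency
    estimate, its confidence interval and the maximized log-likelihood.
    """

    def __init__(self, cohort: LDACohort):
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group: str | None = None) -> "SingleHitModel":
        return cls(LDACohort.from_dataframe(df, group=group))

    # -- likelihood ---------------------------------------------------------

    def loglike(self, f: float) -> float:
        """Log-likelihood at frequency ``f`` (repopulating cells per cell)."""
        d, n, k = self.cohort.dose, self.cohort.n, self.cohort.k_engrafted
        if f < 0:
            raise ValueError("frequency must be non-negative")
        if f == 0:
            return 0.0 if np.all(k == 0) else -np.inf
        neg = (n - k) * (-f * d)
        with np.errstate(divide="ignore"):
            # log(1 - exp(-fd)) via expm1 for accuracy at small fd
            pos = k * np.log(-np.expm1(-f * d))
        return float(np.sum(neg + pos))

    def score(self, f: float) -> float:
        """First derivative of the log-likelihood with respect to f."""
        d, n, k = self.cohort.dose, self.cohort.n, self.cohort.k_engrafted
        e = np.exp(-f * d)
        return float(np.sum(-(n - k) * d + k * d * e / (1.0 - e)))

    def information(self, f: float) -> float:
        """Observed (= expected, given k) information about f."""
        d, k = self.cohort.dose, self.cohort.k_engrafted
        e = np.exp(-f * d)
        return float(np.sum(k * d**2 * e / (1.0 - e) ** 2))

    # -- fitting ------------------------------------------------------------

    def fit(self, level: float = 0.95) -> "SingleHitResults":
        d, n, k = self.cohort.dose, self.cohort.n, self.cohort.k_engrafted
        total_k, total_n = int(k.sum()), int(n.sum())

        if total_k == 0:
            # all-negative boundary: MLE at f = 0
            f_up = _profile_upper_all_negative(d, n, level)
            return SingleHitResults(
                self, f_hat=0.0, ci_low=0.0, ci_high=f_up,
                loglik=0.0, boundary="all_negative", level=level,
            )
        if total_k == total_n:
            # all-positive boundary: likelihood increases without bound
            f_lo = _profile_lower_all_positive(d, n, level)
            return SingleHitResults(
                self, f_hat=np.inf, ci_low=f_lo, ci_high=np.inf,
                loglik=0.0, boundary="all_positive", level=level,
            )

        f_hat = self._mle()
        ll = self.loglike(f_hat)
        info = self.information(f_hat)
        # Wald interval on log f, exp-transformed back
        se_logf = 1.0 / (f_hat * np.sqrt(info))
        z = stats.norm.ppf(0.5 + level / 2.0)
        ci_low = f_hat * np.exp(-z * se_logf)
        ci_high = f_hat * np.exp(z * se_logf)
        return SingleHitResults(
            self, f_hat=f_hat, ci_low=ci_low, ci_high=ci_high,
            loglik=ll, boundary="interior", level=level, se_logf=se_logf,
        )

    def _mle(self) -> float:
        """Root of the score; the likelihood is strictly concave in f."""
        d = self.cohort.dose
        lo = 1e-12 / d.max()
        hi = 1.0 / d.min()
        # expand upward until the score goes negative
        for _ in range(200):
            if self.score(hi) < 0:
                break
            hi *= 2.0
        else:  # pragma: no cover - unreachable for interior cohorts
            raise RuntimeError("could not bracket the MLE")
        return float(optimize.brentq(self.score, lo, hi, xtol=1e-300, rtol=1e-15))


def _profile_upper_all_negative(d, n, level: float) -> float:
    """One-sided profile-likelihood upper bound when no mouse engrafted.

    l(0) - l(f) = f * sum(n*d); the bound solves 2*(l(0)-l(f)) = chi2_1(level).
    """
    chi = stats.chi2.ppf(level, df=1)
    return float(chi / 2.0 / np.sum(n * d))


def _profile_lower_all_positive(d, n, level: float) -> float:
    """One-sided profile lower bound when every mouse engrafted."""
    chi = stats.chi2.ppf(level, df=1)

    def gap(logf):
        f = np.exp(logf)
        with np.errstate(divide="ignore"):
            ll = np.sum(n * np.log(-np.expm1(-f * d)))
        return -2.0 * ll - chi  # l(sup) = 0

    lo, hi = np.log(1e-12 / d.max()), np.log(1e3 / d.min())
    return float(np.exp(optimize.brentq(gap, lo, hi, xtol=1e-12)))


@dataclass
class SingleHitResults:
    """Fitted repopulating-cell frequency with uncertainty.

    Attributes
    ----------
    f_hat : float
        MLE of the frequency (repopulating cells per cell transplanted).
    one_in : float
        1 / f_hat, the "1 in N" form figures usually print.
    ci_low, ci_high : float
        Confidence bounds on f at ``level``.
    boundary : str
        "interior", "all_negative" or "all_positive".
    """

    model: SingleHitModel
    f_hat: float
    ci_low: float
    ci_high: float
    loglik: float
    boundary: str
    level: float
    se_logf: float = field(default=np.nan)

    @property
    def one_in(self) -> float:
        return 1.0 / self.f_hat if self.f_hat > 0 else np.inf

    def summary(self) -> str:
        c = self.model.cohort
        lines = [
            "Single-hit limiting dilution fit",
            "================================",
            f"group:                 {c.group}",
            f"dose levels:           {len(c.dose)}",
            f"mice (engrafted/total): {int(c.k_engrafted.sum())}/{int(c.n.sum())}",
            f"frequency f:           {self.f_hat:.6g}",
            f"1 in N:                {self.one_in:.4g}",
            f"{int(self.level*100)}% CI on 1/f:        "
            f"[{1.0/self.ci_high if self.ci_high > 0 else np.inf:.4g}, "
            f"{1.0/self.ci_low if self.ci_low > 0 else np.inf:.4g}]",
            f"log-likelihood:        {self.loglik:.4f}",
            f"boundary:              {self.boundary}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "group": self.model.cohort.group,
            "f_hat": self.f_hat,
            "one_in": self.one_in,
            "ci_low_f": self.ci_low,
            "ci_high_f": self.ci_high,
            "ci_one_in": [
                1.0 / self.ci_high if self.ci_high > 0 else np.inf,
                1.0 / self.ci_low if self.ci_low > 0 else np.inf,
            ],
            "loglik": self.loglik,
            "boundary": self.boundary,
            "level": self.level,
        }


# -- functional surface ------------------------------------------------------


def fit_single_hit(cohort: LDACohort, level: float = 0.95) -> SingleHitResults:
    """Fit the single-hit model to one cohort."""
    return SingleHitModel(cohort).fit(level=level)


def frequency_ci(fit: SingleHitResults, level: float | None = None) -> tuple[float, float]:
    """Confidence bounds on f from a fitted cohort (refit if level differs)."""
    if level is None or level == fit.level:
        return fit.ci_low, fit.ci_high
    refit = fit.model.fit(level=level)
    return refit.ci_low, refit.ci_high


def compare_frequencies(
    cohort_a: LDACohort, cohort_b: LDACohort
) -> tuple[float, float, float]:
    """Likelihood-ratio comparison of two cohorts' frequencies.

    The null model shares one frequency across both cohorts; the alternative
    fits each freely.  Returns ``(chi2, p, fold)`` with
    ``fold = f_hat_a / f_hat_b``, tested against chi-square with 1 df.
    """
    fit_a = fit_single_hit(cohort_a)
    fit_b = fit_single_hit(cohort_b)
    if fit_a.boundary == "all_negative" or fit_b.boundary == "all_negative":
        raise ValueError(
            "fold ratio undefined for an all-negative cohort; "
            "report its profile upper bound instead"
        )
    pooled = LDACohort(
        group=f"{cohort_a.group}+{cohort_b.group}",
        dose=np.concatenate([cohort_a.dose, cohort_b.dose]),
        n=np.concatenate([cohort_a.n, cohort_b.n]),
        k_engrafted=np.concatenate([cohort_a.k_engrafted, cohort_b.k_engrafted]),
    )
    fit_p = fit_single_hit(pooled)
    chi2 = 2.0 * (fit_a.loglik + fit_b.loglik - fit_p.loglik)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    fold = fit_a.f_hat / fit_b.f_hat
    return chi2, p, fold
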