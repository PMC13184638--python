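"""Stage two: random-effects pooling of county log-IRRs.

County-specific log incidence-rate ratios y_i with standard errors s_i
are combined under the additive random-effects model

    y_i ~ N(mu, s_i^2 + tau^2),

with the between-county variance tau^2 estimated by REML (default) or
DerSimonian–Laird, and mu by the inverse-variance weighted mean at the
estimated tau^2.  Confidence intervals are normal-theory Wald intervals
on the log scale, exponentiated to the IRR scale.

Inclusion mirrors the published analysis: estimates with a standard
error above 2 (log-IRR scale) are excluded as unstable; an alternative
population threshold supports the sensitivity analysis.  Pooled effects
are labelled by whether they represent more than 85% of eligible
counties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = [
    "MetaResult",
    "PooledEffect",
    "filter_estimates",
    "pool_random_effects",
    "coverage_label",
    "pool_by_category",
    "RandomEffectsMeta",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MetaResult:
    mu: float          # pooled log-IRR
    se: float          # standard error of mu
    tau2: float        # between-county variance (log scale)
    irr: float
    ci_low: float
    ci_high: float
    k: int             # number of pooled estimates
    method: str


@dataclass
class PooledEffect:
    outcome: str
    stratum: str
    category: str
    irr: float
    ci_low: float
    ci_high: float
    tau2: float
    n_included: int
    n_eligible: int
    coverage: float
    coverage_flag: str


def filter_estimates(estimates: pd.DataFrame, se_max: float = 2.0,
                     population_min: float | None = None):
    """Apply the stability inclusion rule; returns (included, report).

    Default rule keeps rows with ``se <= se_max`` on the log-IRR scale
    (the published "standard error greater than 2" exclusion, boundary
    inclusive).  Passing ``population_min`` switches to the sensitivity
    rule keeping counties with population at or above the threshold
    (which then requires a ``population`` column).  The report profiles
    the excluded counties: count, median population and median share of
    drought-labelled time when those columns are present.
    """
    df = estimates
    if population_min is not None:
        if "population" not in df.columns:
            raise ValueError("population threshold rule requires a 'population' column")
        mask = df["population"] >= population_min
    else:
        mask = df["se"].notna() & (df["se"] <= se_max)
    included = df[mask].copy()
    excluded = df[~mask]
    report = {
        "rule": "population" if population_min is not None else "se",
        "threshold": population_min if population_min is not None else se_max,
        "n_included": int(mask.sum()),
        "n_excluded": int((~mask).sum()),
        "excluded_median_population": (float(excluded["population"].median())
                                       if "population" in df.columns and len(excluded) else np.nan),
        "excluded_median_drought_share": (float(excluded["drought_share"].median())
                                          if "drought_share" in df.columns and len(excluded) else np.nan),
    }
    return included, report


def _reml_negll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                  + np.sum(w * (y - mu) ** 2))


def _tau2_reml(y: np.ndarray, v: np.ndarray) -> float:
    upper = max(float(np.ptp(y)) ** 2 + 10.0 * float(v.max(initial=0.0)), 1e-4)
    opt = minimize_scalar(_reml_negll, args=(y, v), bounds=(0.0, upper),
                          method="bounded", options={"xatol": 1e-10})
    tau2 = float(opt.x)
    if _reml_negll(0.0, y, v) <= opt.fun:  # boundary check
        tau2 = 0.0
    return tau2


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu_f = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_f) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (len(y) - 1)) / denom)


def pool_random_effects(log_irr, se, method: str = "reml") -> MetaResult:
    """Pool county log-IRRs under the random-effects model.

    A single estimate passes through unchanged (with a warning, since no
    heterogeneity can be estimated).  Degenerate input where every
    estimate is identical with zero standard error reduces to that exact
    value with tau^2 = 0.
    """
    y = np.asarray(log_irr, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    if y.size == 0:
        raise ValueError("nothing to pool")
    if y.size != v.size:
        raise ValueError("log_irr and se lengths differ")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("estimates must be finite with non-negative se")
    if method not in ("reml", "dl"):
        raise ValueError("method must be 'reml' or 'dl'")
    if y.size == 1:
        warnings.warn("pooling a single estimate: returning it unchanged", stacklevel=2)
        mu, se_mu, tau2 = float(y[0]), float(np.sqrt(v[0])), 0.0
    elif np.all(v == 0) and np.ptp(y) == 0:
        mu, se_mu, tau2 = float(y[0]), 0.0, 0.0
    else:
        if method == "reml":
            tau2 = _tau2_reml(y, v)
        else:
            if np.all(v == 0):
                tau2 = float(np.var(y, ddof=1))
            else:
                tau2 = _tau2_dl(y, np.where(v == 0, 1e-12, v))
        w = 1.0 / (v + tau2) if tau2 > 0 or np.all(v > 0) else 1.0 / np.maximum(v, 1e-12)
        mu = float(np.sum(w * y) / np.sum(w))
        se_mu = float(np.sqrt(1.0 / np.sum(w)))
    return MetaResult(mu=mu, se=se_mu, tau2=tau2, irr=float(np.exp(mu)),
                      ci_low=float(np.exp(mu - Z95 * se_mu)),
                      ci_high=float(np.exp(mu + Z95 * se_mu)),
                      k=int(y.size), method=method)


def coverage_label(n_included: int, n_eligible: int) -> str:
    """'over85' iff strictly more than 85% of eligible counties are pooled."""
    if n_eligible <= 0:
        raise ValueError("n_eligible must be positive")
    return "over85" if n_included / n_eligible > 0.85 else "under85"


def pool_by_category(estimates: pd.DataFrame, n_eligible: int,
                     se_max: float = 2.0, population_min: float | None = None,
                     method: str = "reml") -> tuple[pd.DataFrame, list[dict]]:
    """Filter then pool each (outcome, stratum, category) group.

    ``n_eligible`` is the denominator for the coverage label — by
    default every county present in the input panel.  Categories whose
    included set is empty are skipped with a report entry rather than
    aborting the whole run.
    """
    rows, reports = [], []
    est = estimates[estimates["converged"] & estimates["category"].notna()]
    for (outcome, stratum, cat), grp in est.groupby(["outcome", "stratum", "category"],
                                                    sort=True):
        included, report = filter_estimates(grp, se_max=se_max, population_min=population_min)
        report.update({"outcome": outcome, "stratum": stratum, "category": cat})
        reports.append(report)
        if len(included) == 0:
            report["pooled"] = False
            continue
        report["pooled"] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pool_random_effects(included["log_irr"].to_numpy(),
                                      included["se"].to_numpy(), method=method)
        n_inc = len(included)
        rows.append(PooledEffect(
            outcome=outcome, stratum=stratum, category=cat, irr=res.irr,
            ci_low=res.ci_low, ci_high=res.ci_high, tau2=res.tau2,
            n_included=n_inc, n_eligible=n_eligible,
            coverage=n_inc / n_eligible,
            coverage_flag=coverage_label(n_inc, n_eligible)).__dict__)
    return pd.DataFrame(rows), reports


class RandomEffectsMeta(BaseEstimator):
    """Sklearn-style estimator for the second-stage pooling.

    ``fit(X)`` expects the first-stage estimates table (columns
    county_id, outcome, stratum, category, log_irr, se, converged);
    fitted attributes hold the pooled-effects table and exclusion
    reports.
    """

    def __init__(self, se_max: float = 2.0, population_min: float | None = None,
                 method: str = "reml"):
        self.se_max = se_max
        self.population_min = population_min
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        required = {"county_id", "outcome", "stratum", "category", "log_irr", "se", "converged"}
        missing = sorted(required - set(X.columns))
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        n_eligible = X["county_id"].nunique()
        self.pooled_, self.exclusion_reports_ = pool_by_category(
            X, n_eligible=n_eligible, se_max=self.se_max,
            population_min=self.population_min, method=self.method)
        self.n_eligible_ = n_eligible
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "pooled_"):
            self.fit(X)
        return self.pooled_
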