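"""Absolute risk differences from pooled incidence rate ratios.

The absolute risk difference converts a relative effect into additional
cases per million persons per month:

    ARD = alpha * (IRR - 1) / IRR

where alpha is the baseline rate — deaths per million persons per month
over the stratum's person-time spent in the NONE (no drought) reference
exposure.  The map is strictly increasing in IRR for alpha > 0, so the
95% interval endpoints of the IRR transform directly into ARD bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ARDResult", "baseline_rate", "ard_from_irr", "irr_from_ard"]

PER_MILLION = 1e6


@dataclass
class ARDResult:
    alpha: float      # baseline rate, deaths per million persons per month
    ard: float        # additional cases per million persons per month
    ard_low: float
    ard_high: float


def baseline_rate(panel: pd.DataFrame, death_col: str,
                  population_col: str = "population",
                  label_col: str = "exposure_label") -> float:
    """Baseline rate alpha over NONE-exposure person-time.

    alpha = 1e6 * (deaths in NONE months) / (person-months in NONE
    months).  Doubling both numerator and denominator leaves it
    unchanged; a stratum with no NONE person-time has no defined
    baseline and raises.
    """
    none = panel[panel[label_col] == "NONE"]
    if len(none) == 0:
        raise ValueError("no NONE-exposure months in this stratum")
    person_months = float(none[population_col].sum())
    if person_months <= 0:
        raise ValueError("zero person-months of NONE exposure")
    return PER_MILLION * float(none[death_col].sum()) / person_months


def ard_from_irr(alpha: float, irr: float, ci_low: float, ci_high: float) -> ARDResult:
    """ARD with endpoint-propagated 95% bounds.

    ARD = alpha*(IRR-1)/IRR is monotone increasing in IRR, so the bounds
    are the same map evaluated at the interval endpoints; ordering is
    preserved for any valid interval.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 < ci_low <= irr <= ci_high):
        raise ValueError("require 0 < ci_low <= irr <= ci_high")
    f = lambda r: alpha * (r - 1.0) / r
    return ARDResult(alpha=alpha, ard=f(irr), ard_low=f(ci_low), ard_high=f(ci_high))


def irr_from_ard(ard: float, alpha: float) -> float:
    """Inverse of the ARD map: IRR = alpha / (alpha - ARD)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if ard >= alpha:
        raise ValueError("ard must be below alpha (IRR would be infinite)")
    return alpha / (alpha - ard)


def ard_table(pooled: pd.DataFrame, alphas: dict) -> pd.DataFrame:
    """Join pooled IRRs with stratum baseline rates into the effects table.

    ``alphas`` maps (outcome, stratum) to the baseline rate.  Rows
    without a baseline (no NONE person-time) are dropped.
    """
    rows = []
    for _, r in pooled.iterrows():
        key = (r["outcome"], r["stratum"])
        if key not in alphas:
            continue
        res = ard_from_irr(alphas[key], r["irr"], r["ci_low"], r["ci_high"])
        row = dict(r)
        row.update({"alpha": res.alpha, "ard": res.ard,
                    "ard_low": res.ard_low, "ard_high": res.ard_high})
        rows.append(row)
    return pd.DataFrame(rows)
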