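"""Descriptive summary of a labeled panel (deaths and county-months by
drought exposure, plus person-based strata).

Percentage conventions deliberately mirror the published national
baseline table:

* person-based rows (age, sex, urbanicity) use the outcome's death
  total within that variable as the denominator;
* exposure-based death rows use the sum of the six exposure-category
  death counts as the denominator (in the source data a small number of
  deaths fall outside the categorised set, so this differs from the
  printed outcome total);
* county-month frequency rows use total county-months.

Percentages are rounded to two decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exposure import EXPOSURE_LEVELS

__all__ = ["summarize_counts", "descriptive_summary", "load_us_descriptive_counts"]

PERSON_VARIABLES = {"age": ("age2064", "age65p"), "sex": ("male", "female")}


def load_us_descriptive_counts() -> pd.DataFrame:
    """Published national descriptive counts (contiguous US, 2000–2018,
    12-month timescale): suicide deaths by stratum and drought exposure
    category, and county-month frequencies."""
    ref = resources.files("droughtmeta.data") / "us_2000_2018_descriptive_counts.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach percentages to a tidy counts table.

    ``counts`` has columns section (person | exposure | frequency),
    variable, level, outcome and count; the returned copy gains a
    ``percent`` column computed with the section-specific denominator
    conventions described in the module docstring.
    """
    required = {"section", "variable", "level", "outcome", "count"}
    missing = sorted(required - set(counts.columns))
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(counts) == 0:
        raise ValueError("empty counts table")
    out = counts.copy()
    denom = pd.Series(index=out.index, dtype=float)
    person = out["section"] == "person"
    denom[person] = out[person].groupby(["outcome", "variable"])["count"].transform("sum")
    exposure = out["section"] == "exposure"
    denom[exposure] = out[exposure].groupby("outcome")["count"].transform("sum")
    freq = out["section"] == "frequency"
    denom[freq] = out.loc[freq, "count"].sum()
    unknown = ~(person | exposure | freq)
    if unknown.any():
        raise ValueError(f"unknown section(s): {sorted(out.loc[unknown, 'section'].unique())}")
    out["percent"] = (100.0 * out["count"] / denom).round(2)
    return out


def _panel_counts(panel: pd.DataFrame, outcomes) -> pd.DataFrame:
    rows = []
    lab = panel["exposure_label"]
    for lev in EXPOSURE_LEVELS:
        rows.append({"section": "frequency", "variable": "drought", "level": lev,
                     "outcome": "county_months", "count": int((lab == lev).sum())})
    for outcome in outcomes:
        col = f"deaths_{outcome}"
        if col not in panel.columns:
            continue
        for lev in EXPOSURE_LEVELS:
            rows.append({"section": "exposure", "variable": "drought", "level": lev,
                         "outcome": outcome, "count": int(panel.loc[lab == lev, col].sum())})
        for variable, levels in PERSON_VARIABLES.items():
            cols = [f"deaths_{outcome}_{s}" for s in levels]
            if all(c in panel.columns for c in cols):
                for s, c in zip(levels, cols):
                    rows.append({"section": "person", "variable": variable, "level": s,
                                 "outcome": outcome, "count": int(panel[c].sum())})
        if "urbanicity" in panel.columns:
            for s in ("metro", "nonmetro"):
                rows.append({"section": "person", "variable": "urbanicity", "level": s,
                             "outcome": outcome,
                             "count": int(panel.loc[panel["urbanicity"] == s, col].sum())})
    return pd.DataFrame(rows)


def descriptive_summary(panel: pd.DataFrame, outcomes=("firearm", "nonfirearm")) -> pd.DataFrame:
    """Baseline-characteristics table for a labeled county-month panel.

    Emits county-month frequencies per exposure category, death counts
    per category and outcome, and person-based rows where stratum death
    columns (``deaths_<outcome>_<level>``) or an ``urbanicity`` column
    are present.  Raises on an empty panel or unlabeled rows.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    if "exposure_label" not in panel.columns:
        raise ValueError("panel has no exposure_label column; run the labeler first")
    lab = panel["exposure_label"]
    if lab.isna().any() or (lab == "").any() or not set(lab.unique()) <= set(EXPOSURE_LEVELS):
        raise ValueError("panel contains unlabeled or unknown exposure rows")
    return summarize_counts(_panel_counts(panel, outcomes))
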