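"""End-to-end orchestration: panel in, IRR/ARD tables out.

`TwoStageDroughtAnalysis` is the composite estimator: given a
county-month panel it labels exposures (if needed), fits the per-county
negative-binomial additive models, pools the county log-IRRs by
random-effects meta-analysis per outcome/stratum/exposure category, and
derives absolute risk differences from stratum baseline rates.
`run_pipeline` wraps it with file I/O: simulate or ingest a panel CSV,
run the analysis, and write every artifact (labels, county estimates,
pooled effects, ARD table, descriptive summary, exclusion report, modal
knot diagnostic, run manifest) to an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .effects import ard_table, baseline_rate
from .exposure import DroughtExposureLabeler
from .meta import pool_by_category
from .simulate import SimConfig, default_strata, simulate_panel
from .stage1 import (TEMP_KNOT_GRID, TIME_KNOT_GRID, estimates_to_frame,
                     fit_all_counties, national_modal_knots)
from .summary import descriptive_summary

__all__ = ["RunConfig", "SchemaError", "TwoStageDroughtAnalysis",
           "run_pipeline", "load_panel_csv"]

logger = logging.getLogger("droughtmeta")

#: Minimum columns of an ingested panel CSV (plus one deaths_<outcome>
#: column per requested outcome).
REQUIRED_PANEL_COLUMNS = ("county_id", "year", "month", "percentile",
                          "temperature", "population")

KNOWN_STRATA = ("total", "age2064", "age65p", "male", "female", "metro", "nonmetro")

#: Default FIPS recodes applied at ingest to keep county series contiguous
#: across jurisdictional changes (Shannon County SD -> Oglala Lakota
#: County SD; Bedford city VA merged into Bedford County VA).
DEFAULT_FIPS_RECODES = {"46113": "46102", "51515": "51019"}


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "simulate"              # "simulate" | "csv"
    input_path: str | None = None       # required in csv mode
    out_dir: str = "droughtmeta_run"
    seed: int = 0
    n_counties: int = 50                # simulate mode
    n_months: int = 228                 # simulate mode
    simulate_strata: bool = False
    timescale: int = 12
    outcomes: tuple = ("firearm", "nonfirearm")
    strata: tuple = ("total",)
    temp_grid: tuple = TEMP_KNOT_GRID
    time_grid: tuple = TIME_KNOT_GRID
    fixed_knots: tuple | None = None    # e.g. (4, 4) for the national modal pair
    se_max: float = 2.0
    population_min: float | None = None
    meta_method: str = "reml"
    bins: tuple | None = None
    min_duration: int = 2
    fips_recodes: dict = field(default_factory=lambda: dict(DEFAULT_FIPS_RECODES))

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "csv"):
            raise ValueError("mode must be 'simulate' or 'csv'")
        if self.mode == "csv" and not self.input_path:
            raise ValueError("csv mode requires input_path")
        if self.timescale not in (6, 12):
            raise ValueError("timescale must be 6 or 12")
        unknown = set(self.strata) - set(KNOWN_STRATA)
        if unknown:
            raise ValueError(f"unknown strata: {sorted(unknown)}")
        if self.fixed_knots is not None and len(self.fixed_knots) != 2:
            raise ValueError("fixed_knots must be a (k_temp, k_time) pair")
        if self.meta_method not in ("reml", "dl"):
            raise ValueError("meta_method must be 'reml' or 'dl'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("outcomes", "strata", "temp_grid", "time_grid", "fixed_knots"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_panel_csv(path, outcomes=("firearm", "nonfirearm"),
                   fips_recodes: dict | None = DEFAULT_FIPS_RECODES) -> pd.DataFrame:
    """Read and validate a panel CSV; adds month_index and season.

    Raises :class:`SchemaError` naming the first missing column.  The
    FIPS recode table (pass ``None`` or ``{}`` to disable) is applied to
    ``county_id`` before the density check so harmonised counties form
    contiguous series; rows merged by a recode have their deaths and
    populations summed and other numeric fields averaged.
    """
    df = pd.read_csv(path, dtype={"county_id": str})
    for col in REQUIRED_PANEL_COLUMNS + tuple(f"deaths_{o}" for o in outcomes):
        if col not in df.columns:
            raise SchemaError(f"panel is missing required column {col!r}")
    if fips_recodes:
        df["county_id"] = df["county_id"].replace(fips_recodes)
        group_cols = [c for c in df.columns if c not in
                      {"county_id", "year", "month"} and pd.api.types.is_numeric_dtype(df[c])]
        agg = {c: ("sum" if c.startswith("deaths_") or c in ("population",) else "mean")
               for c in group_cols}
        nongroup = [c for c in df.columns if c not in group_cols]
        first = {c: "first" for c in nongroup if c not in ("county_id", "year", "month")}
        df = (df.groupby(["county_id", "year", "month"], as_index=False)
                .agg({**agg, **first}))
    y0 = int(df["year"].min())
    m0 = int(df.loc[df["year"] == y0, "month"].min())
    df["month_index"] = (df["year"] - y0) * 12 + (df["month"] - m0) + 1
    for county, grp in df.groupby("county_id"):
        mi = np.sort(grp["month_index"].to_numpy())
        if not np.array_equal(mi, np.arange(mi[0], mi[0] + len(mi))):
            raise SchemaError(f"county {county} has gaps in its monthly series")
    if "season" not in df.columns:
        names = np.array(["DJF", "MAM", "JJA", "SON"], dtype=object)
        df["season"] = names[(df["month"].to_numpy() % 12) // 3]
    return df.sort_values(["county_id", "month_index"], ignore_index=True)


def _stratum_view(panel: pd.DataFrame, outcome: str, stratum: str):
    """(sub-panel, count column, population column) for one stratum."""
    if stratum == "total":
        return panel, f"deaths_{outcome}", "population"
    if stratum in ("metro", "nonmetro"):
        if "urbanicity" not in panel.columns:
            raise SchemaError("urbanicity strata require an 'urbanicity' column")
        return panel[panel["urbanicity"] == stratum], f"deaths_{outcome}", "population"
    ccol, pcol = f"deaths_{outcome}_{stratum}", f"population_{stratum}"
    for col in (ccol, pcol):
        if col not in panel.columns:
            raise SchemaError(f"stratum {stratum!r} requires column {col!r}")
    return panel, ccol, pcol


class TwoStageDroughtAnalysis(BaseEstimator):
    """Composite estimator for the full two-stage analysis.

    ``fit(X)`` takes a county-month panel (labeled or not); fitted
    attributes hold every intermediate and final table:

    - ``labeled_panel_`` — panel with exposure labels;
    - ``county_estimates_`` — first-stage log-IRRs per county/category;
    - ``modal_knots_``, ``knot_table_`` — national knot diagnostic;
    - ``pooled_`` — random-effects pooled IRRs with CIs, tau2, coverage;
    - ``ard_`` — pooled effects joined with baseline rates and ARDs;
    - ``summary_`` — descriptive baseline table;
    - ``exclusion_reports_`` — per-category filtering reports.
    """

    def __init__(self, outcomes=("firearm", "nonfirearm"), strata=("total",),
                 temp_grid=TEMP_KNOT_GRID, time_grid=TIME_KNOT_GRID,
                 se_max: float = 2.0, population_min: float | None = None,
                 meta_method: str = "reml", bins=None, min_duration: int = 2):
        self.outcomes = outcomes
        self.strata = strata
        self.temp_grid = temp_grid
        self.time_grid = time_grid
        self.se_max = se_max
        self.population_min = population_min
        self.meta_method = meta_method
        self.bins = bins
        self.min_duration = min_duration

    def fit(self, X: pd.DataFrame, y=None):
        panel = X
        if "exposure_label" not in panel.columns:
            labeler = DroughtExposureLabeler(bins=self.bins, min_duration=self.min_duration)
            panel = labeler.fit(panel).transform(panel)
        self.labeled_panel_ = panel
        drought = panel["exposure_label"].isin(
            ["M2SD_WRS", "S2ED_WRS", "S2ED_IMP", "M2SD_IMP"])
        county_profile = (panel.assign(_d=drought)
                          .groupby("county_id")
                          .agg(population=("population", "median"),
                               drought_share=("_d", "mean")))
        all_estimates = []
        frames = []
        alphas = {}
        for outcome in self.outcomes:
            for stratum in self.strata:
                sub, ccol, pcol = _stratum_view(panel, outcome, stratum)
                ests = fit_all_counties(sub, ccol, outcome=outcome, stratum=stratum,
                                        temp_grid=self.temp_grid, time_grid=self.time_grid,
                                        population_col=pcol)
                all_estimates.extend(ests)
                frame = estimates_to_frame(ests)
                frame = frame.merge(county_profile, on="county_id", how="left")
                frames.append(frame)
                try:
                    alphas[(outcome, stratum)] = baseline_rate(sub, ccol, population_col=pcol)
                except ValueError:
                    logger.warning("no baseline rate for %s/%s", outcome, stratum)
        est_df = pd.concat(frames, ignore_index=True)
        self.county_estimates_ = est_df
        self.modal_knots_, self.knot_table_ = national_modal_knots(all_estimates)
        pooled_frames, reports = [], []
        for (outcome, stratum), grp in est_df.groupby(
                ["outcome", "stratum"], sort=True):
            n_eligible = grp["county_id"].nunique()
            pooled, rep = pool_by_category(grp, n_eligible=n_eligible,
                                           se_max=self.se_max,
                                           population_min=self.population_min,
                                           method=self.meta_method)
            pooled_frames.append(pooled)
            reports.extend(rep)
        nonempty = [f for f in pooled_frames if len(f)]
        if not nonempty:
            raise RuntimeError("no category could be pooled (no convergent counties)")
        self.pooled_ = pd.concat(nonempty, ignore_index=True)
        self.exclusion_reports_ = reports
        self.alphas_ = alphas
        self.ard_ = ard_table(self.pooled_, alphas)
        self.summary_ = descriptive_summary(panel, outcomes=self.outcomes)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "ard_"):
            self.fit(X)
        return self.ard_


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and write artifacts; returns paths by name.

    Deterministic for a fixed config (including seed): rerunning into a
    fresh directory reproduces byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths = {}
    try:
        if config.mode == "simulate":
            sim = SimConfig(n_counties=config.n_counties, n_months=config.n_months,
                            seed=config.seed, min_duration=config.min_duration,
                            strata=default_strata() if config.simulate_strata else None,
                            **({"bins": tuple(config.bins)} if config.bins else {}))
            panel = simulate_panel(sim)
            paths["panel"] = out / "panel.csv"
            panel.to_csv(paths["panel"], index=False)
            paths["truth"] = out / "truth.json"
            paths["truth"].write_text(sim.to_json())
            logger.info("simulated %d counties x %d months", sim.n_counties, sim.n_months)
        else:
            panel = load_panel_csv(config.input_path, outcomes=config.outcomes,
                                   fips_recodes=config.fips_recodes)
            labeler = DroughtExposureLabeler(bins=config.bins,
                                            min_duration=config.min_duration,
                                            timescale=config.timescale)
            panel = labeler.fit(panel).transform(panel)
        temp_grid = (config.fixed_knots[:1] if config.fixed_knots else config.temp_grid)
        time_grid = (config.fixed_knots[1:] if config.fixed_knots else config.time_grid)
        model = TwoStageDroughtAnalysis(
            outcomes=config.outcomes, strata=config.strata,
            temp_grid=tuple(temp_grid), time_grid=tuple(time_grid),
            se_max=config.se_max, population_min=config.population_min,
            meta_method=config.meta_method, bins=config.bins,
            min_duration=config.min_duration)
        model.fit(panel)
        label_cols = ["county_id", "year", "month", "category", "event_id",
                      "phase", "exposure_label"]
        writes = {
            "exposure_labels": model.labeled_panel_[
                [c for c in label_cols if c in model.labeled_panel_.columns]],
            "county_estimates": model.county_estimates_,
            "pooled_effects": model.pooled_,
            "ard_table": model.ard_,
            "descriptive_summary": model.summary_,
            "exclusion_report": pd.DataFrame(model.exclusion_reports_),
            "knot_frequencies": model.knot_table_,
        }
        for name, df in writes.items():
            paths[name] = out / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        n_failed = int((~model.county_estimates_["converged"]).sum())
        if n_failed:
            logger.info("%d county fits did not converge (excluded)", n_failed)
        manifest = {"config": _jsonable(config.to_dict()),
                    "modal_knots": [list(p) for p in model.modal_knots_],
                    "n_counties": int(panel["county_id"].nunique()),
                    "n_rows": int(len(panel)),
                    "outputs": {k: str(v) for k, v in paths.items()}}
        paths["manifest"] = out / "run_manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2))
        logger.info("run complete; outputs in %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {k: str(v) for k, v in paths.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
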