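"""Drought exposure construction from monthly dryness percentiles.

This module turns a county's monthly drought-index percentiles into the
six-level exposure classification used by the downstream count models:

1. bin dryness percentiles into US Drought Monitor style categories
   (D0–D4 dry, W0–W4 wet, NEUTRAL in between);
2. detect drought *events* — maximal runs of D1–D4 lasting at least two
   consecutive months (shorter anomalies are ignored as noise);
3. accumulate Cumulative Drought Intensity (CDI) within each event
   (severity score 1–4 per month, running sum, reset at event end);
4. split each event where cumulative CDI reaches 50% of the event total:
   months at or below the half-way point are the *worsening* phase, the
   rest the *improving* phase;
5. label every month: phase × contemporaneous severity bucket inside
   events (D1–D2 → moderate-to-severe, D3–D4 → severe-to-exceptional),
   WET for wet-category months outside events, NONE otherwise.

Percentiles are *dryness* percentiles: 100 = driest month on record
relative to climatology, 0 = wettest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CATEGORIES",
    "EXPOSURE_LEVELS",
    "DEFAULT_BINS",
    "DroughtEvent",
    "categorize_percentile",
    "detect_events",
    "compute_cdi",
    "split_phases",
    "label_months",
    "label_panel",
    "rank_to_percentile",
    "DroughtExposureLabeler",
]

# Wettest to driest.
CATEGORIES = (
    "W4", "W3", "W2", "W1", "W0",
    "NEUTRAL",
    "D0", "D1", "D2", "D3", "D4",
)

WET_CATEGORIES = frozenset({"W0", "W1", "W2", "W3", "W4"})
EVENT_CATEGORIES = frozenset({"D1", "D2", "D3", "D4"})

#: Severity score per event-eligible category (D1=1 … D4=4).
SEVERITY = {"D1": 1, "D2": 2, "D3": 3, "D4": 4}

#: Exposure levels in modeling order; NONE is always the reference.
EXPOSURE_LEVELS = ("NONE", "M2SD_WRS", "S2ED_WRS", "S2ED_IMP", "M2SD_IMP", "WET")

# Dryness-percentile bin edges following the USDM percentile convention:
# D4 is the driest 2% of months, D3 the 95th–98th percentile, and so on,
# with the wet categories mirrored at the other tail.  Half-open
# [lower, upper) intervals; the last interval includes 100.
DEFAULT_BINS = (
    (0.0, 2.0, "W4"),
    (2.0, 5.0, "W3"),
    (5.0, 10.0, "W2"),
    (10.0, 20.0, "W1"),
    (20.0, 30.0, "W0"),
    (30.0, 70.0, "NEUTRAL"),
    (70.0, 80.0, "D0"),
    (80.0, 90.0, "D1"),
    (90.0, 95.0, "D2"),
    (95.0, 98.0, "D3"),
    (98.0, 100.0, "D4"),
)


class BinConfigError(ValueError):
    """Raised when a category bin table has gaps, overlaps, or bad order."""


def _validate_bins(bins: Sequence[tuple[float, float, str]]) -> None:
    if not bins:
        raise BinConfigError("empty bin table")
    lo0 = bins[0][0]
    if lo0 != 0.0:
        raise BinConfigError(f"bins must start at 0, got {lo0}")
    prev_hi = 0.0
    for lo, hi, cat in bins:
        if cat not in CATEGORIES:
            raise BinConfigError(f"unknown category {cat!r}")
        if lo != prev_hi:
            raise BinConfigError(f"gap or overlap at percentile {lo} (expected {prev_hi})")
        if hi <= lo:
            raise BinConfigError(f"non-increasing bin ({lo}, {hi})")
        prev_hi = hi
    if prev_hi != 100.0:
        raise BinConfigError(f"bins must end at 100, got {prev_hi}")
    # Monotone: driest percentiles must map to the driest categories.
    order = [CATEGORIES.index(cat) for _, _, cat in bins]
    if order != sorted(order):
        raise BinConfigError("bin categories must run from wettest to driest")


def categorize_percentile(percentile, bins: Sequence[tuple[float, float, str]] | None = None):
    """Map dryness percentile(s) in [0, 100] to a drought category.

    Scalar input returns a category string; array input returns an
    object-dtype ndarray of category strings.  Higher percentile (drier)
    never maps to a wetter category.
    """
    if bins is None:
        bins = DEFAULT_BINS
    _validate_bins(bins)
    p = np.asarray(percentile, dtype=float)
    if np.any(p < 0) or np.any(p > 100) or np.any(~np.isfinite(p)):
        raise ValueError("percentile must lie in [0, 100]")
    edges = np.array([b[1] for b in bins[:-1]])  # internal upper edges
    cats = np.array([b[2] for b in bins], dtype=object)
    idx = np.searchsorted(edges, p, side="right")
    if p.ndim == 0:
        return str(cats[int(idx)])
    return cats[idx]


@dataclass
class DroughtEvent:
    """A contiguous run of D1–D4 months lasting >= min_duration.

    ``start``/``end`` are inclusive panel-relative month indices;
    ``severities`` holds one score in {1..4} per event month.  CDI fields
    are filled by :func:`compute_cdi`, the phase split by
    :func:`split_phases` (``split_after`` = 1-based index of the last
    worsening month).
    """

    county_id: str
    start: int
    end: int
    severities: list[int]
    cdi_cumulative: list[int] = field(default_factory=list)
    total_cdi: int | None = None
    split_after: int | None = None

    def __post_init__(self) -> None:
        if len(self.severities) < 2:
            raise ValueError("a drought event requires at least two consecutive months")
        if self.end - self.start + 1 != len(self.severities):
            raise ValueError("event span does not match severity sequence length")
        if any(s not in (1, 2, 3, 4) for s in self.severities):
            raise ValueError("severities must be integers in {1, 2, 3, 4}")

    @property
    def duration(self) -> int:
        return len(self.severities)


def detect_events(categories: Sequence[str], county_id: str = "", min_duration: int = 2) -> list[DroughtEvent]:
    """Find maximal D1–D4 runs of length >= ``min_duration``.

    ``categories`` is the time-ordered category sequence for one county
    (month 1 is the first element).  D0 and wet/neutral months break
    contiguity; runs shorter than ``min_duration`` yield no event.
    Returned events carry CDI and phase-split fields already computed.
    """
    if min_duration < 2:
        raise ValueError("min_duration must be >= 2 (an event needs persistence)")
    events: list[DroughtEvent] = []
    run_start = None
    for i, cat in enumerate(list(categories) + [None]):  # sentinel flush
        in_run = cat in EVENT_CATEGORIES
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            if i - run_start >= min_duration:
                sev = [SEVERITY[c] for c in categories[run_start:i]]
                ev = DroughtEvent(county_id=county_id, start=run_start + 1, end=i, severities=sev)
                split_phases(compute_cdi(ev))
                events.append(ev)
            run_start = None
    return events


def compute_cdi(event: DroughtEvent) -> DroughtEvent:
    """Fill the running CDI sum and event total (in place; returns event).

    CDI is event-scoped: it starts from the first event month and is
    never carried across events.
    """
    if not event.severities:
        raise ValueError("event has no severities")
    event.cdi_cumulative = list(np.cumsum(event.severities))
    event.total_cdi = int(event.cdi_cumulative[-1])
    return event


def split_phases(event: DroughtEvent) -> DroughtEvent:
    """Split the event where cumulative CDI reaches half the total.

    Worsening months are those whose running CDI is <= 50% of the event
    total (inclusive at exact equality, so palindromic profiles split at
    the midpoint).  If the first month alone already exceeds half the
    total it is still assigned to the worsening phase, keeping both
    phases non-empty for any event of length >= 2.
    """
    if not event.cdi_cumulative or event.total_cdi is None:
        raise RuntimeError("split_phases requires compute_cdi to have run")
    half = event.total_cdi / 2.0
    eligible = [i + 1 for i, c in enumerate(event.cdi_cumulative) if c <= half]
    event.split_after = max(eligible) if eligible else 1
    return event


def _severity_bucket(severity: int) -> str:
    return "M2SD" if severity <= 2 else "S2ED"


def label_months(categories: Sequence[str], events: Sequence[DroughtEvent] | None = None,
                 county_id: str = "") -> list[str]:
    """Assign exactly one exposure label to every month of a county series.

    Within an event the label crosses the event phase (worsening if the
    month index is <= split_after, improving otherwise) with the month's
    own severity bucket.  Wet-category months outside events are WET;
    everything else (NEUTRAL, D0, and sub-threshold D1–D4 runs) is NONE.
    """
    if events is None:
        events = detect_events(categories, county_id=county_id)
    labels = []
    for cat in categories:
        labels.append("WET" if cat in WET_CATEGORIES else "NONE")
    covered = [False] * len(labels)
    for ev in events:
        if ev.split_after is None:
            split_phases(compute_cdi(ev))
        for j, sev in enumerate(ev.severities):
            pos = ev.start - 1 + j
            if covered[pos]:
                raise RuntimeError("month covered by two events; event detection is broken")
            covered[pos] = True
            phase = "WRS" if (j + 1) <= ev.split_after else "IMP"
            labels[pos] = f"{_severity_bucket(sev)}_{phase}"
    return labels


def rank_to_percentile(df: pd.DataFrame, value_col: str = "eddi",
                       county_col: str = "county_id", month_col: str = "month") -> pd.Series:
    """Empirical dryness percentile of a raw drought index.

    Ranks the index within each (county, calendar-month) climatology cell
    — mid-ranks for ties — and rescales to (0, 100) via (rank − 0.5)/n.
    Higher index values must mean drier conditions (positive anomalies of
    evaporative demand do).
    """
    grp = df.groupby([county_col, month_col])[value_col]
    rank = grp.rank(method="average")
    n = grp.transform("count")
    return 100.0 * (rank - 0.5) / n


def label_panel(df: pd.DataFrame, percentile_col: str = "percentile",
                county_col: str = "county_id", bins=None, min_duration: int = 2) -> pd.DataFrame:
    """Label a multi-county panel; returns a copy with exposure columns.

    The frame must be dense in time within each county and sorted (it is
    sorted here by county and appearance order).  Adds ``category``,
    ``event_id`` (empty string outside events), ``phase`` and
    ``exposure_label`` columns.
    """
    out = df.copy()
    out["category"] = categorize_percentile(out[percentile_col].to_numpy(), bins=bins)
    out["event_id"] = ""
    out["phase"] = ""
    out["exposure_label"] = ""
    for county, idx in out.groupby(county_col, sort=False).groups.items():
        cats = list(out.loc[idx, "category"])
        events = detect_events(cats, county_id=str(county), min_duration=min_duration)
        labels = label_months(cats, events, county_id=str(county))
        out.loc[idx, "exposure_label"] = labels
        pos_index = list(idx)
        for k, ev in enumerate(events, start=1):
            for j in range(ev.duration):
                row = pos_index[ev.start - 1 + j]
                out.loc[row, "event_id"] = f"{county}-{k}"
                out.loc[row, "phase"] = "worsening" if (j + 1) <= ev.split_after else "improving"
    return out


class DroughtExposureLabeler(TransformerMixin, BaseEstimator):
    """Transformer mapping a county-month panel to exposure labels.

    Parameters
    ----------
    bins : sequence of (low, high, category), optional
        Dryness-percentile bin table; defaults to the USDM convention.
    min_duration : int, default 2
        Minimum consecutive D1–D4 months for a run to count as an event.
    source : {"percentile", "rank"}, default "percentile"
        "percentile" reads ``percentile_col`` directly; "rank" derives
        dryness percentiles from a raw index column by per-county,
        per-calendar-month empirical ranking.
    timescale : int, default 12
        Aggregation window (months) of the drought index; metadata only —
        the labeling algorithm is timescale-agnostic.
    """

    def __init__(self, bins=None, min_duration: int = 2, source: str = "percentile",
                 percentile_col: str = "percentile", index_col: str = "eddi",
                 county_col: str = "county_id", month_col: str = "month",
                 timescale: int = 12):
        self.bins = bins
        self.min_duration = min_duration
        self.source = source
        self.percentile_col = percentile_col
        self.index_col = index_col
        self.county_col = county_col
        self.month_col = month_col
        self.timescale = timescale

    def fit(self, X: pd.DataFrame, y=None):
        if self.source not in ("percentile", "rank"):
            raise ValueError("source must be 'percentile' or 'rank'")
        if self.timescale not in (6, 12):
            raise ValueError("timescale must be 6 or 12 months")
        bins = DEFAULT_BINS if self.bins is None else tuple(self.bins)
        _validate_bins(bins)
        self.bins_ = bins
        col = self.percentile_col if self.source == "percentile" else self.index_col
        if col not in X.columns:
            raise ValueError(f"missing required column {col!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "bins_"):
            self.fit(X)
        df = X
        pcol = self.percentile_col
        if self.source == "rank":
            df = X.copy()
            pcol = "_dryness_percentile"
            df[pcol] = rank_to_percentile(df, value_col=self.index_col,
                                          county_col=self.county_col, month_col=self.month_col)
        out = label_panel(df, percentile_col=pcol, county_col=self.county_col,
                          bins=self.bins_, min_duration=self.min_duration)
        if pcol == "_dryness_percentile":
            out = out.rename(columns={pcol: "percentile"})
        return out
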