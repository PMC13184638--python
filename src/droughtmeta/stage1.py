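"""Stage one: per-county negative-binomial additive count models.

Each county-outcome series of monthly death counts is modelled as

    deaths_t ~ NegBin(mu_t, alpha),
    log mu_t = log(population_t) + beta0 + exposure_t' gamma
               + season_t' delta + f_temp(T_t) + f_time(t)

with NONE as the reference exposure, a 4-level meteorological-season
factor, and unpenalised B-spline smooths for monthly mean temperature
and the panel time index (1..T).  Smooth complexity is chosen per county
by AIC over the grid k_temp in {2,3,4,5} x k_time in {3,4,5,6} (16
candidate fits); the exponentiated exposure coefficients are the
county-specific incidence rate ratios fed to the second-stage
meta-analysis.

Dispersion is estimated by profile likelihood: for each candidate alpha
the remaining coefficients are fitted by IRLS (statsmodels GLM with the
negative-binomial family), and the scalar profile is maximised over
log(alpha).  This is robust at the Poisson boundary (alpha -> 0), where
joint Newton iterations have a singular information matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .exposure import EXPOSURE_LEVELS

__all__ = [
    "spline_basis",
    "build_design",
    "fit_nb_gam",
    "select_knots",
    "national_modal_knots",
    "fit_all_counties",
    "CountyNBGAM",
    "CountyEstimate",
    "NBFit",
    "TEMP_KNOT_GRID",
    "TIME_KNOT_GRID",
]

TEMP_KNOT_GRID = (2, 3, 4, 5)
TIME_KNOT_GRID = (3, 4, 5, 6)

SEASONS = ("DJF", "MAM", "JJA", "SON")  # DJF is the reference

#: Dispersion search window (NB2 alpha); the lower end is effectively
#: the Poisson limit, the upper end caps boundary drift.
ALPHA_BOUNDS = (1e-8, 50.0)


def spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Unpenalised B-spline basis with exactly ``df`` columns.

    Degree min(3, df); interior knots at quantiles; the first basis
    column is dropped so the returned columns are identifiable next to
    an intercept.  A (numerically) constant ``x`` collapses the basis to
    zero columns — the caller drops it and records the degeneracy.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("spline df must be >= 1")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-10:
        return np.empty((x.size, 0))
    if df == 1:
        return ((x - lo) / (hi - lo))[:, None]
    degree = min(3, df)
    n_interior = df - degree
    interior = np.quantile(x, [(i + 1) / (n_interior + 1) for i in range(n_interior)])
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    return B[:, 1:]


@dataclass
class Design:
    X: np.ndarray
    colnames: list[str]
    offset: np.ndarray
    exposure_cols: dict  # label -> column index
    excluded_categories: list[str]
    dropped_collinear: list[str]


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Greedy earliest-first column selection to full rank."""
    keep, dropped = [], []
    Q: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        r = v.copy()
        for q in Q:
            r = r - (q @ v) * q
        norm0 = np.linalg.norm(v)
        if norm0 > 0 and np.linalg.norm(r) > tol * max(1.0, norm0):
            Q.append(r / np.linalg.norm(r))
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def build_design(panel: pd.DataFrame, temp_knots: int, time_knots: int,
                 exposure_levels=EXPOSURE_LEVELS, population_col: str = "population") -> Design:
    """Model matrix + log-population offset for one county's series.

    Columns: intercept, exposure dummies (reference NONE, only levels
    present in the county — absent levels are recorded in
    ``excluded_categories``), three season dummies, temperature spline
    (df = temp_knots), time spline on the 1..T index (df = time_knots).
    Collinear columns (e.g. from a constant temperature series) are
    dropped and reported.
    """
    n = len(panel)
    if n == 0:
        raise ValueError("empty county panel")
    pop = panel[population_col].to_numpy(dtype=float)
    if np.any(pop <= 0):
        raise ValueError("populations must be positive")
    cols = [np.ones(n)]
    names = ["intercept"]
    present = set(panel["exposure_label"].unique())
    exposure_cols = {}
    excluded = []
    for lev in exposure_levels:
        if lev == "NONE":
            continue
        if lev in present:
            cols.append((panel["exposure_label"] == lev).to_numpy(dtype=float))
            names.append(f"exposure[{lev}]")
        else:
            excluded.append(lev)
    for s in SEASONS[1:]:
        cols.append((panel["season"] == s).to_numpy(dtype=float))
        names.append(f"season[{s}]")
    collapsed = []
    Bt = spline_basis(panel["temperature"].to_numpy(), temp_knots)
    if Bt.shape[1] == 0:
        collapsed.append("s(temperature)")
    for j in range(Bt.shape[1]):
        cols.append(Bt[:, j])
        names.append(f"s(temperature).{j + 1}")
    Bx = spline_basis(panel["month_index"].to_numpy(dtype=float), time_knots)
    if Bx.shape[1] == 0:
        collapsed.append("s(time)")
    for j in range(Bx.shape[1]):
        cols.append(Bx[:, j])
        names.append(f"s(time).{j + 1}")
    X = np.column_stack(cols)
    X, names, dropped = _drop_collinear(X, names)
    dropped = collapsed + dropped
    for lev in list(exposure_levels):
        if f"exposure[{lev}]" in names:
            exposure_cols[lev] = names.index(f"exposure[{lev}]")
    return Design(X=X, colnames=names, offset=np.log(pop),
                  exposure_cols=exposure_cols, excluded_categories=excluded,
                  dropped_collinear=dropped)


@dataclass
class NBFit:
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    llf: float
    aic: float
    alpha: float
    converged: bool
    n_params: int  # regression coefficients + 1 for dispersion


def fit_nb_gam(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
               alpha_bounds: tuple = ALPHA_BOUNDS) -> NBFit:
    """Maximum-likelihood NB2 regression with log link and offset.

    Profile likelihood over log(alpha) with GLM-IRLS inner fits;
    coefficient covariance is the GLM observed-information covariance at
    the profiled alpha.  AIC counts every regression coefficient plus
    one dispersion parameter.  All-zero counts (rate MLE at -inf) and
    IRLS failures return ``converged=False``.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    p = X.shape[1]
    bad = NBFit(params=np.full(p, np.nan), bse=np.full(p, np.nan),
                cov=np.full((p, p), np.nan), llf=np.nan, aic=np.nan,
                alpha=np.nan, converged=False, n_params=p + 1)
    if y.sum() == 0:
        return bad
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(maxiter=100)
    except Exception:
        return bad
    start = pois.params

    def profile_negll(log_a: float) -> float:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=np.exp(log_a)),
                             offset=offset).fit(start_params=start, maxiter=100)
            return -res.llf if np.isfinite(res.llf) else 1e12
        except Exception:
            return 1e12

    lo, hi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    opt = minimize_scalar(profile_negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    if not np.isfinite(opt.fun) or opt.fun >= 1e12:
        return bad
    alpha = float(np.exp(opt.x))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=offset).fit(start_params=start, maxiter=200)
    except Exception:
        return bad
    cov = np.asarray(res.cov_params())
    bse = np.sqrt(np.diag(cov))
    converged = bool(res.converged) and np.all(np.isfinite(bse))
    llf = float(res.llf)
    n_params = p + 1
    return NBFit(params=np.asarray(res.params), bse=bse, cov=cov, llf=llf,
                 aic=-2.0 * llf + 2.0 * n_params, alpha=alpha,
                 converged=converged, n_params=n_params)


@dataclass
class CountyEstimate:
    """AIC-best first-stage fit for one county-outcome(-stratum) series."""

    county_id: str
    outcome: str
    stratum: str
    estimates: dict  # exposure label -> (log_irr, se)
    aic: float
    chosen_knots: tuple
    converged: bool
    excluded_categories: list[str] = field(default_factory=list)
    dispersion: float = np.nan
    n_fits: int = 0
    n_converged: int = 0
    aic_table: dict = field(default_factory=dict)  # (k_temp, k_time) -> aic


def select_knots(panel: pd.DataFrame, count_col: str,
                 temp_grid=TEMP_KNOT_GRID, time_grid=TIME_KNOT_GRID,
                 county_id: str = "", outcome: str = "", stratum: str = "total",
                 exposure_levels=EXPOSURE_LEVELS,
                 population_col: str = "population") -> CountyEstimate:
    """Fit every knot combination for one county; keep the lowest AIC.

    Ties are broken deterministically: smaller k_temp + k_time, then
    smaller k_temp.  A county where no combination converges is returned
    with ``converged=False`` and no estimates.
    """
    y = panel[count_col].to_numpy()
    best = None
    best_key = None
    aic_table = {}
    n_fits = n_conv = 0
    for kt in temp_grid:
        for kx in time_grid:
            design = build_design(panel, kt, kx, exposure_levels=exposure_levels,
                                  population_col=population_col)
            fit = fit_nb_gam(design.X, y, design.offset)
            n_fits += 1
            if not fit.converged:
                continue
            n_conv += 1
            aic_table[(kt, kx)] = fit.aic
            key = (fit.aic, kt + kx, kt)
            if best_key is None or key < best_key:
                best_key = key
                best = (design, fit, (kt, kx))
    if best is None:
        return CountyEstimate(county_id=county_id, outcome=outcome, stratum=stratum,
                              estimates={}, aic=np.nan, chosen_knots=(np.nan, np.nan),
                              converged=False, n_fits=n_fits, n_converged=0,
                              aic_table=aic_table)
    design, fit, knots = best
    est = {lev: (float(fit.params[j]), float(fit.bse[j]))
           for lev, j in design.exposure_cols.items()}
    return CountyEstimate(county_id=county_id, outcome=outcome, stratum=stratum,
                          estimates=est, aic=float(fit.aic), chosen_knots=knots,
                          converged=True, excluded_categories=design.excluded_categories,
                          dispersion=fit.alpha, n_fits=n_fits, n_converged=n_conv,
                          aic_table=aic_table)


def national_modal_knots(estimates: list[CountyEstimate]):
    """Modal chosen knot pair across converged counties (diagnostic only).

    Returns ``(modal_pairs, frequency_table)`` where ``modal_pairs``
    lists every pair tied for the mode and the table is a DataFrame with
    columns k_temp, k_time, n_counties.
    """
    pairs = [e.chosen_knots for e in estimates if e.converged]
    if not pairs:
        raise ValueError("no converged counties")
    tab = (pd.Series(pairs).value_counts().rename_axis("pair")
           .reset_index(name="n_counties"))
    top = tab["n_counties"].max()
    modal = sorted(tab.loc[tab["n_counties"] == top, "pair"])
    tab[["k_temp", "k_time"]] = pd.DataFrame(tab["pair"].tolist(), index=tab.index)
    return modal, tab[["k_temp", "k_time", "n_counties"]]


def estimates_to_frame(estimates: list[CountyEstimate]) -> pd.DataFrame:
    """Long per-county-category table (one row per estimated category)."""
    rows = []
    for e in estimates:
        if not e.converged:
            rows.append({"county_id": e.county_id, "outcome": e.outcome,
                         "stratum": e.stratum, "category": None, "log_irr": np.nan,
                         "se": np.nan, "aic": np.nan, "k_temp": np.nan,
                         "k_time": np.nan, "converged": False})
            continue
        for lev, (b, se) in e.estimates.items():
            rows.append({"county_id": e.county_id, "outcome": e.outcome,
                         "stratum": e.stratum, "category": lev, "log_irr": b,
                         "se": se, "aic": e.aic, "k_temp": e.chosen_knots[0],
                         "k_time": e.chosen_knots[1], "converged": True})
    return pd.DataFrame(rows)


def fit_all_counties(panel: pd.DataFrame, count_col: str, outcome: str = "",
                     stratum: str = "total", temp_grid=TEMP_KNOT_GRID,
                     time_grid=TIME_KNOT_GRID, county_col: str = "county_id",
                     population_col: str = "population") -> list[CountyEstimate]:
    """Run knot selection for every county in a labeled panel.

    Individual county failures never abort the run; they come back as
    non-converged estimates for the caller's exclusion log.
    """
    out = []
    for county, grp in panel.groupby(county_col, sort=True):
        try:
            est = select_knots(grp, count_col, temp_grid=temp_grid, time_grid=time_grid,
                               county_id=str(county), outcome=outcome, stratum=stratum,
                               population_col=population_col)
        except Exception:
            est = CountyEstimate(county_id=str(county), outcome=outcome, stratum=stratum,
                                 estimates={}, aic=np.nan, chosen_knots=(np.nan, np.nan),
                                 converged=False)
        out.append(est)
    return out


class CountyNBGAM(BaseEstimator):
    """Sklearn-style wrapper for the single-county NB-GAM with AIC knot search.

    ``fit(X)`` takes one county's panel (a DataFrame with season,
    temperature, month_index, population and exposure_label columns) and
    the count column named by ``count_col``; fitted attributes expose
    the AIC-best estimate.

    Parameters
    ----------
    count_col : str
        Column holding the monthly death counts.
    temp_grid, time_grid : sequences of int
        Knot grids searched for the temperature and time smooths; pass
        single-element grids to pin the combination (e.g. the national
        modal 4-4 pair).
    """

    def __init__(self, count_col: str = "deaths_firearm",
                 temp_grid=TEMP_KNOT_GRID, time_grid=TIME_KNOT_GRID,
                 exposure_levels=EXPOSURE_LEVELS, population_col: str = "population"):
        self.count_col = count_col
        self.temp_grid = temp_grid
        self.time_grid = time_grid
        self.exposure_levels = exposure_levels
        self.population_col = population_col

    def fit(self, X: pd.DataFrame, y=None):
        required = {"season", "temperature", "month_index", "exposure_label",
                    self.population_col, self.count_col}
        missing = sorted(required - set(X.columns))
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        est = select_knots(X, self.count_col, temp_grid=self.temp_grid,
                           time_grid=self.time_grid,
                           county_id=str(X["county_id"].iloc[0]) if "county_id" in X else "",
                           exposure_levels=self.exposure_levels,
                           population_col=self.population_col)
        self.estimate_ = est
        self.coef_ = {lev: b for lev, (b, _) in est.estimates.items()}
        self.aic_ = est.aic
        self.chosen_knots_ = est.chosen_knots
        self.converged_ = est.converged
        self.dispersion_ = est.dispersion
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Model-implied IRR vs NONE for each row's exposure label."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("CountyNBGAM is not fitted")
        return np.exp(X["exposure_label"].map(lambda s: self.coef_.get(s, 0.0)).to_numpy())
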