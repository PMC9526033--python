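"""Habitat-suitability-index (HSI) modelling of overwintering grounds.

The HSI framework relates standardized abundance (catch scaled to [0, 1])
to environmental predictors through per-variable suitability-index (SI)
curves combined across variables by an arithmetic mean (AM) or geometric
mean (GM).  Two SI families are supported:

* *fitting-based*: a unimodal Gaussian curve ``SI(x) = exp(-(x-mu)^2 / (2 sigma^2))``,
  initialised from the binned upper envelope of the abundance scatter and,
  at the model level, jointly calibrated across variables against the
  observed standardized abundance;
* *regression-based*: a polynomial (default cubic) OLS fit, clipped to
  [0, 1] and renormalized over the observed domain.

Candidate models (variable subset x SI family x combiner) are trained on one
period and validated on a held-out period by regressing observed on
predicted suitability; R-squared and small-sample AICc select the winner,
which is then refit on the full period.  Predicted HSI fields are classed
into optimal (>= 0.7), average (>= 0.3) and poor habitat, areas are
cosine-latitude weighted, and decadal differences are tested by one-way
ANOVA with Scheffe pairwise contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize, stats

from .errors import ComputationError, ValidationError

__all__ = [
    "EnvironmentalGrid",
    "SICurve",
    "HSIModel",
    "HSIValidation",
    "SelectionResult",
    "DecadalHabitatStats",
    "AnovaResult",
    "TrendResult",
    "standardize_abundance",
    "aicc",
    "fit_si_fitting_based",
    "fit_si_regression_based",
    "combine_hsi",
    "validate_and_select",
    "winter_mean",
    "build_winter_table",
    "classify_and_area",
    "decadal_anova",
    "winter_sst_trend",
    "HabitatSuitabilityModel",
    "HabitatResults",
]

VARIABLES = ("depth", "sst", "sss")
_VAR_COLUMNS = {"depth": "depth_m", "sst": "sst_c", "sss": "sss"}
WINTER_MONTHS = (12, 1, 2)


@dataclass
class EnvironmentalGrid:
    """Gridded monthly environment plus per-cell annual winter catch.

    Wraps an :class:`xarray.Dataset` with coordinates ``lon``, ``lat`` (cell
    centres, uniform step), calendar ``year`` and ``month`` (12, 1, 2), and
    variables ``depth_m(lat, lon)``, ``sst_c(year, month, lat, lon)``,
    ``sss(year, month, lat, lon)``, plus per *winter* year (labelled by its
    December) ``catch_t(wyear, lat, lon)`` and optionally the generator's
    ``true_hsi(wyear, lat, lon)``.
    """

    ds: xr.Dataset

    def __post_init__(self):
        for name in ("depth_m", "sst_c", "sss"):
            if name not in self.ds:
                raise ValidationError(f"grid is missing variable {name!r}")
        lon = self.ds["lon"].values
        lat = self.ds["lat"].values
        if lon.size != np.unique(lon).size or lat.size != np.unique(lat).size:
            raise ValidationError("grid cells must be unique")

    @property
    def resolution_deg(self) -> float:
        lon = self.ds["lon"].values
        return float(lon[1] - lon[0]) if lon.size > 1 else float("nan")

    @property
    def winter_years(self) -> np.ndarray:
        if "catch_t" in self.ds:
            return self.ds["wyear"].values
        return self.ds["year"].values[:-1]

    @property
    def n_cells(self) -> int:
        return self.ds["lon"].size * self.ds["lat"].size

    def winter_mean(self, year: int) -> xr.Dataset:
        return winter_mean(self, year)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (lon, lat, year, month) with the
        winter catch attached to the December row of its winter year."""
        rows = (
            self.ds[["sst_c", "sss"]]
            .to_dataframe()
            .reset_index()
            .dropna(subset=["sst_c", "sss"], how="all")
        )
        depth = self.ds["depth_m"].to_dataframe().reset_index()
        rows = rows.merge(depth, on=["lat", "lon"])
        if "catch_t" in self.ds:
            catch = (
                self.ds["catch_t"].to_dataframe().reset_index()
                .rename(columns={"wyear": "year"})
            )
            catch["month"] = 12
            rows = rows.merge(catch, on=["lon", "lat", "year", "month"], how="left")
        else:
            rows["catch_t"] = np.nan
        cols = ["lon", "lat", "year", "month", "depth_m", "sst_c", "sss", "catch_t"]
        return rows[cols].sort_values(["year", "month", "lat", "lon"]).reset_index(drop=True)


def winter_mean(grid: EnvironmentalGrid, year: int) -> xr.Dataset:
    """Per-cell winter means for the winter labelled ``year``.

    Winter ``year`` spans December of ``year`` and January/February of
    ``year + 1``.  Raises naming the missing month if any of the three is
    absent or not finite.
    """
    ds = grid.ds
    fields = {}
    parts = []
    for month, cal_year in ((12, year), (1, year + 1), (2, year + 1)):
        if cal_year not in ds["year"].values or month not in ds["month"].values:
            raise ValidationError(f"winter {year}: month {month} of {cal_year} missing from grid")
        sel = ds[["sst_c", "sss"]].sel(year=cal_year, month=month)
        if bool(sel["sst_c"].isnull().all()):
            raise ValidationError(f"winter {year}: month {month} of {cal_year} missing from grid")
        parts.append(sel)
    stacked = xr.concat(parts, dim="wm")
    fields["sst_c"] = stacked["sst_c"].mean(dim="wm")
    fields["sss"] = stacked["sss"].mean(dim="wm")
    fields["depth_m"] = ds["depth_m"]
    return xr.Dataset(fields)


def standardize_abundance(catch: Sequence[float]) -> np.ndarray:
    """Standardized abundance SI_obs = catch / max(catch), in [0, 1]."""
    c = np.asarray(catch, dtype=float)
    if c.size == 0 or np.nanmax(c) <= 0:
        raise ValidationError("cannot standardize: no positive catch")
    return c / np.nanmax(c)


def _gaussian(x, mu, sigma):
    return np.exp(-((np.asarray(x, float) - mu) ** 2) / (2.0 * sigma**2))


@dataclass(frozen=True)
class SICurve:
    """A per-variable suitability curve with values in [0, 1].

    ``params`` holds the form-specific coefficients: ``{"mu", "sigma"}`` for
    the fitting-based Gaussian, ``{"coeffs", "norm", "p_value"}`` (highest
    degree first) for the regression-based polynomial.  ``optimal_range`` is
    the interval where SI exceeds the configured threshold (default 0.8).
    """

    variable: str
    form: str
    params: dict
    optimal_range: tuple[float, float]
    domain: tuple[float, float]

    def __call__(self, x):
        return self.evaluate(x)

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "fitting_based":
            return _gaussian(x, self.params["mu"], self.params["sigma"])
        coeffs = np.asarray(self.params["coeffs"])
        raw = np.polyval(coeffs, x) / self.params["norm"]
        return np.clip(raw, 0.0, 1.0)


def _optimal_range_from_curve(evaluate, domain, threshold=0.8, n_grid=2001):
    xx = np.linspace(domain[0], domain[1], n_grid)
    ok = evaluate(xx) >= threshold
    if not ok.any():
        return (float("nan"), float("nan"))
    return (float(xx[ok].min()), float(xx[ok].max()))


def fit_si_fitting_based(
    variable_values: Sequence[float],
    si_observations: Sequence[float],
    variable: str = "x",
    n_bins: int = 10,
    range_threshold: float = 0.8,
) -> SICurve:
    """Fit a Gaussian SI curve to the binned upper envelope of the scatter.

    The variable is cut into ``n_bins`` equal-width bins; within each
    non-empty bin the observation with the largest standardized abundance is
    kept (at its actual x value, not the bin centre), and a scaled Gaussian
    ``A * exp(-(x-mu)^2 / (2 sigma^2))`` is least-squares fitted to those
    envelope points.  The amplitude is then dropped so the returned curve
    has maximum 1 at ``mu``.
    """
    x = np.asarray(variable_values, dtype=float)
    y = np.asarray(si_observations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("variable values and SI observations must match in shape")
    if np.unique(x).size < 5:
        raise ValidationError("need at least 5 distinct variable values")
    if np.nanstd(y) == 0:
        raise ValidationError("degenerate SI observations (constant)")
    lo, hi = float(x.min()), float(x.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    ex, ey = [], []
    for b in range(n_bins):
        members = np.flatnonzero(idx == b)
        if members.size:
            best = members[np.argmax(y[members])]
            ex.append(x[best])
            ey.append(y[best])
    ex, ey = np.asarray(ex), np.asarray(ey)
    if np.std(ex) == 0:
        raise ValidationError("degenerate variance in envelope points")
    mu0 = float(ex[np.argmax(ey)])
    sigma0 = max(float(np.std(ex)), 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, A, mu, sig: A * _gaussian(xx, mu, sig),
            ex, ey, p0=(float(ey.max()), mu0, sigma0),
            bounds=([1e-6, lo - (hi - lo), 1e-9], [10.0, hi + (hi - lo), 10.0 * (hi - lo)]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological data
        raise ComputationError(f"Gaussian SI fit failed: {err}") from err
    _, mu, sigma = map(float, popt)
    half = sigma * np.sqrt(2.0 * np.log(1.0 / range_threshold))
    return SICurve(
        variable=variable,
        form="fitting_based",
        params={"mu": mu, "sigma": sigma},
        optimal_range=(mu - half, mu + half),
        domain=(lo, hi),
    )


def fit_si_regression_based(
    variable_values: Sequence[float],
    si_observations: Sequence[float],
    variable: str = "x",
    degree: int = 3,
    range_threshold: float = 0.8,
) -> SICurve:
    """Fit a polynomial SI curve by OLS, clipped to [0, 1].

    Predictions are divided by the polynomial's maximum over the observed
    domain (so the curve attains 1) and clipped to [0, 1].  The overall
    regression F-test p-value is stored in ``params["p_value"]``.
    """
    x = np.asarray(variable_values, dtype=float)
    y = np.asarray(si_observations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("variable values and SI observations must match in shape")
    n = x.size
    if n < degree + 2:
        raise ValidationError(f"need at least degree + 2 = {degree + 2} points")
    if np.unique(x).size <= degree:
        raise ValidationError("rank-deficient design: too few distinct variable values")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0 and n > degree + 1:
        r2 = 1.0 - rss / tss
        dfm, dfe = degree, n - degree - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = (r2 / dfm) / max((1.0 - r2) / dfe, 1e-300)
        p_value = float(stats.f.sf(f_stat, dfm, dfe))
    else:
        p_value = float("nan")
    lo, hi = float(x.min()), float(x.max())
    xx = np.linspace(lo, hi, 2001)
    norm = float(np.polyval(coeffs, xx).max())
    if norm <= 0:
        raise ComputationError("regression SI has no positive values on the domain")
    curve = SICurve(
        variable=variable,
        form="regression_based",
        params={"coeffs": tuple(map(float, coeffs)), "norm": norm, "p_value": p_value},
        optimal_range=(float("nan"), float("nan")),
        domain=(lo, hi),
    )
    rng_ = _optimal_range_from_curve(curve.evaluate, (lo, hi), range_threshold)
    return SICurve(curve.variable, curve.form, curve.params, rng_, curve.domain)


@dataclass(frozen=True)
class HSIModel:
    """Per-variable SI curves and their combiner.

    ``combiner`` is ``"am"`` (arithmetic mean) or ``"gm"`` (geometric mean);
    the geometric mean never exceeds the arithmetic mean, so GM models are
    the more precautionary habitat map.
    """

    si_curves: Mapping[str, SICurve]
    combiner: str

    def __post_init__(self):
        if not self.si_curves:
            raise ValidationError("an HSI model needs at least one variable")
        if self.combiner not in ("am", "gm"):
            raise ValidationError("combiner must be 'am' or 'gm'")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(sorted(self.si_curves))

    def predict(self, values: Mapping[str, Sequence[float]]) -> np.ndarray:
        """HSI per cell from per-variable value arrays; cells with any
        missing (NaN) variable yield NaN."""
        sis = []
        for var in self.variables:
            if var not in values:
                raise ValidationError(f"missing variable {var!r} in prediction input")
            sis.append(self.si_curves[var].evaluate(np.asarray(values[var], dtype=float)))
        return combine_hsi(self.combiner, np.stack(sis, axis=0))


def combine_hsi(combiner: str, si_stack: np.ndarray) -> np.ndarray:
    """Combine an (n_vars, ...) stack of SI values into HSI.

    AM is the mean across variables, GM the n-th root of the product; both
    stay in [0, 1] and GM <= AM (AM-GM inequality).
    """
    si_stack = np.asarray(si_stack, dtype=float)
    if combiner == "am":
        return si_stack.mean(axis=0)
    if combiner == "gm":
        return np.prod(si_stack, axis=0) ** (1.0 / si_stack.shape[0])
    raise ValidationError("combiner must be 'am' or 'gm'")


@dataclass(frozen=True)
class HSIValidation:
    """Out-of-sample validation of one candidate HSI model: R-squared and
    AICc of the observed-on-predicted suitability regression."""

    r2: float
    aicc: float
    n_test: int
    train_years: tuple[int, ...]
    test_years: tuple[int, ...]


def aicc(rss: float, n: int, k: int = 3) -> float:
    """Gaussian-likelihood AICc with k counting intercept, slope and the
    residual variance: n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined: n={n} <= k+1={k + 1}")
    rss = max(rss, 1e-300)
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def build_winter_table(grid: EnvironmentalGrid, years: Sequence[int]) -> pd.DataFrame:
    """One row per (cell, winter year) with winter-mean depth/SST/SSS and,
    when present, the winter catch."""
    frames = []
    for y in years:
        wm = winter_mean(grid, int(y))
        df = wm.to_dataframe().reset_index()
        df["year"] = int(y)
        if "catch_t" in grid.ds and y in grid.ds["wyear"].values:
            catch = grid.ds["catch_t"].sel(wyear=int(y)).to_dataframe().reset_index()
            df = df.merge(catch[["lat", "lon", "catch_t"]], on=["lat", "lon"], how="left")
        else:
            df["catch_t"] = np.nan
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"depth_m": "depth", "sst_c": "sst"})
    return out[["lon", "lat", "year", "depth", "sst", "sss", "catch_t"]]


def _fit_candidate(train: pd.DataFrame, si_obs: np.ndarray, variables, form, combiner,
                   n_bins=10, degree=3, range_threshold=0.8) -> HSIModel:
    curves = {}
    for var in variables:
        x = train[var].to_numpy()
        if form == "fitting_based":
            curves[var] = fit_si_fitting_based(x, si_obs, var, n_bins, range_threshold)
        else:
            curves[var] = fit_si_regression_based(x, si_obs, var, degree, range_threshold)
    if form == "fitting_based":
        curves = _joint_refine_gaussians(train, si_obs, curves, combiner, range_threshold)
    return HSIModel(si_curves=curves, combiner=combiner)


def _joint_refine_gaussians(train, si_obs, curves, combiner, range_threshold=0.8):
    """Jointly calibrate all Gaussian SI parameters (plus one scale factor)
    against the standardized abundance by nonlinear least squares.

    The per-variable envelope fits are good initial guesses but each sees the
    other variables' influence as noise; refining (mu_v, sigma_v) of every
    curve together against SI_obs removes that bias, and at zero noise the
    refined model reproduces the generating surface exactly.  The scale
    factor absorbs the standardization of abundance by its maximum and is
    dropped afterwards (curves stay max-1 normalized).
    """
    variables = sorted(curves)
    xdata = {v: train[v].to_numpy() for v in variables}
    spans = {v: max(xdata[v].max() - xdata[v].min(), 1e-9) for v in variables}

    def unpack(theta):
        out = {}
        for i, v in enumerate(variables):
            out[v] = (theta[2 * i], np.exp(theta[2 * i + 1]))
        return out, np.exp(theta[-1])

    def residuals(theta):
        pars, scale = unpack(theta)
        stack = np.stack([_gaussian(xdata[v], *pars[v]) for v in variables])
        return scale * combine_hsi(combiner, stack) - si_obs

    theta0 = []
    for v in variables:
        theta0.extend([curves[v].params["mu"], np.log(curves[v].params["sigma"])])
    theta0.append(0.0)  # log scale
    lo_b, hi_b = [], []
    for v in variables:
        lo_b.extend([xdata[v].min() - 2 * spans[v], np.log(1e-4 * spans[v])])
        hi_b.extend([xdata[v].max() + 2 * spans[v], np.log(10 * spans[v])])
    lo_b.append(np.log(1e-3))
    hi_b.append(np.log(1e3))
    sol = optimize.least_squares(
        residuals, np.asarray(theta0), bounds=(lo_b, hi_b),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
    )
    pars, _ = unpack(sol.x)
    refined = {}
    for v in variables:
        mu, sigma = float(pars[v][0]), float(pars[v][1])
        half = sigma * np.sqrt(2.0 * np.log(1.0 / range_threshold))
        refined[v] = SICurve(
            variable=v, form="fitting_based",
            params={"mu": mu, "sigma": sigma},
            optimal_range=(mu - half, mu + half),
            domain=curves[v].domain,
        )
    return refined


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of HSI model selection: the winning model refit on the full
    period, its held-out validation, and the full candidate table."""

    best_model: HSIModel
    best_form: str
    validation: HSIValidation
    table: pd.DataFrame = field(repr=False)


def validate_and_select(
    grid: EnvironmentalGrid,
    train_years: Sequence[int],
    test_years: Sequence[int],
    si_forms: Sequence[str] = ("fitting_based", "regression_based"),
    combiners: Sequence[str] = ("am", "gm"),
    variables: Sequence[str] = VARIABLES,
    n_bins: int = 10,
    degree: int = 3,
    range_threshold: float = 0.8,
) -> SelectionResult:
    """Enumerate candidate HSI models, validate out of sample, pick the best.

    Candidates are every non-empty subset of ``variables`` crossed with the
    SI families and combiners (28 with the defaults).  Each is fitted on the
    training winters, predicts HSI for the test winters, and is scored by
    OLS of observed test suitability on predicted HSI: R-squared (higher
    better) then AICc (k = 3).  Because AICc at fixed n and k is a monotone
    transform of the residual sum of squares, genuine ties are resolved by
    parsimony: fewer variables, then fitting-based before regression-based,
    then AM before GM.  The winner is refit on train + test years.
    """
    train_years = tuple(int(y) for y in train_years)
    test_years = tuple(int(y) for y in test_years)
    if not train_years or not test_years:
        raise ValidationError("train and test year lists must be non-empty")
    train = build_winter_table(grid, train_years).dropna(subset=["catch_t"])
    test = build_winter_table(grid, test_years).dropna(subset=["catch_t"])
    if train.empty or test.empty:
        raise ValidationError("no catch records in train or test period")
    cmax = float(np.nanmax(np.concatenate([train["catch_t"], test["catch_t"]])))
    if cmax <= 0:
        raise ValidationError("cannot standardize: no positive catch")
    y_train = train["catch_t"].to_numpy() / cmax
    y_test = test["catch_t"].to_numpy() / cmax
    if y_test.size <= 4:
        raise ValidationError("test set too small for the validation regression")
    subsets = [
        combo
        for r in range(1, len(variables) + 1)
        for combo in itertools.combinations(sorted(variables), r)
    ]
    rows = []
    fitted = {}
    for form, combiner, subset in itertools.product(si_forms, combiners, subsets):
        model = _fit_candidate(train, y_train, subset, form, combiner,
                               n_bins, degree, range_threshold)
        pred = model.predict({v: test[v].to_numpy() for v in subset})
        res = stats.linregress(pred, y_test)
        resid = y_test - (res.intercept + res.slope * pred)
        rss = float(np.sum(resid**2))
        r2 = float(res.rvalue**2)
        aicc_val = aicc(rss, y_test.size)
        key = (form, combiner, subset)
        fitted[key] = model
        rows.append({
            "form": form, "combiner": combiner,
            "variables": "+".join(subset), "n_vars": len(subset),
            "r2": r2, "aicc": aicc_val, "n_test": int(y_test.size),
        })
    table = pd.DataFrame(rows)
    form_rank = {f: i for i, f in enumerate(("fitting_based", "regression_based"))}
    comb_rank = {c: i for i, c in enumerate(("am", "gm"))}

    def sort_key(row):
        return (
            -np.round(row["r2"], 9),
            np.round(row["aicc"], 6),
            row["n_vars"],
            form_rank.get(row["form"], 99),
            comb_rank.get(row["combiner"], 99),
        )

    order = sorted(range(len(rows)), key=lambda i: sort_key(rows[i]))
    best_i = order[0]
    best = rows[best_i]
    table = table.iloc[order].reset_index(drop=True)
    subset = tuple(best["variables"].split("+"))
    # refit the winner on the full train + test period
    full = pd.concat([train, test], ignore_index=True)
    y_full = full["catch_t"].to_numpy() / cmax
    final = _fit_candidate(full, y_full, subset, best["form"], best["combiner"],
                           n_bins, degree, range_threshold)
    return SelectionResult(
        best_model=final,
        best_form=best["form"],
        validation=HSIValidation(
            r2=best["r2"], aicc=best["aicc"], n_test=best["n_test"],
            train_years=train_years, test_years=test_years,
        ),
        table=table,
    )


@dataclass(frozen=True)
class DecadalHabitatStats:
    """Habitat-class area percentages for one decade (with per-year areas)."""

    decade: str
    pct_optimal: float
    pct_average: float
    pct_poor: float
    per_year: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        total = self.pct_optimal + self.pct_average + self.pct_poor
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"class percentages must sum to 100, got {total}")


def classify_and_area(
    hsi: Sequence[float],
    lat: Sequence[float],
    thresholds: tuple[float, float] = (0.7, 0.3),
) -> dict:
    """Class percentages of water area from per-cell HSI values.

    Cells with HSI >= ``thresholds[0]`` are optimal, >= ``thresholds[1]``
    average, below poor (closed-upper boundary rule: exactly 0.7 is optimal,
    exactly 0.3 average).  Cell areas are weighted by cos(latitude) since
    fixed-degree cells shrink poleward; NaN cells are excluded.
    """
    hsi = np.asarray(hsi, dtype=float)
    lat = np.asarray(lat, dtype=float)
    ok = np.isfinite(hsi)
    if not ok.any():
        raise ValidationError("no defined HSI cells to classify")
    hsi, lat = hsi[ok], lat[ok]
    hi, lo = thresholds
    w = np.cos(np.deg2rad(lat))
    total = w.sum()
    a_opt = float(w[hsi >= hi].sum())
    a_avg = float(w[(hsi >= lo) & (hsi < hi)].sum())
    a_poor = float(w[hsi < lo].sum())
    pct = {
        "pct_optimal": 100.0 * a_opt / total,
        "pct_average": 100.0 * a_avg / total,
        "pct_poor": 100.0 * a_poor / total,
    }
    # force exact closure against float rounding
    drift = 100.0 - sum(pct.values())
    pct["pct_poor"] += drift
    pct.update(area_optimal=a_opt, area_average=a_avg, area_poor=a_poor, area_total=float(total))
    return pct


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA across decade groups with Scheffe
    simultaneous pairwise contrasts."""

    f_stat: float
    p_value: float
    scheffe: pd.DataFrame = field(repr=False, default=None)


def decadal_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Test for differences in yearly habitat area between decades.

    Standard one-way ANOVA F and p over the decade groups, followed by
    Scheffe pairwise contrasts (conservative, valid for all contrasts
    simultaneously): for groups i, j the statistic
    ``(mean_i - mean_j)^2 / (MSW (1/n_i + 1/n_j) (g - 1))`` is referred to
    an F(g-1, N-g) distribution.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(data) < 2:
        raise ValidationError("need at least 2 decade groups")
    if any(d.size < 2 for d in data):
        raise ValidationError("every decade group needs at least 2 yearly observations")
    f_stat, p_value = stats.f_oneway(*data)
    g = len(data)
    n_total = sum(d.size for d in data)
    grand = np.concatenate(data)
    ssw = sum(np.sum((d - d.mean()) ** 2) for d in data)
    msw = ssw / (n_total - g)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(data), 2):
        diff = a.mean() - b.mean()
        if msw > 0:
            t2 = diff**2 / (msw * (1.0 / a.size + 1.0 / b.size))
            f_s = t2 / (g - 1)
            p_s = float(stats.f.sf(f_s, g - 1, n_total - g))
        else:
            p_s = 1.0 if diff == 0 else 0.0
        rows.append({
            "group_a": names[i], "group_b": names[j],
            "mean_diff": float(diff), "p_scheffe": p_s,
        })
    if np.var(grand) == 0:
        f_stat, p_value = 0.0, 1.0
    return AnovaResult(float(f_stat), float(p_value), pd.DataFrame(rows))


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of a yearly series: slope per year, r-squared, p-value.
    ``constant`` flags a degenerate (flat) input series."""

    slope: float
    r2: float
    p_value: float
    constant: bool = False


def winter_sst_trend(years: Sequence[int], sst: Sequence[float]) -> TrendResult:
    """OLS regression of area-mean winter SST on calendar year."""
    years = np.asarray(years, dtype=float)
    sst = np.asarray(sst, dtype=float)
    if years.size < 3:
        raise ValidationError("need at least 3 yearly values for a trend")
    if np.all(sst == sst[0]):
        return TrendResult(slope=0.0, r2=float("nan"), p_value=float("nan"), constant=True)
    res = stats.linregress(years, sst)
    return TrendResult(slope=float(res.slope), r2=float(res.rvalue**2),
                       p_value=float(res.pvalue), constant=False)


class HabitatSuitabilityModel:
    """Habitat-suitability analysis over an environmental grid,
    statsmodels style: construct with the data and periods, call ``fit``.

    Parameters
    ----------
    grid : EnvironmentalGrid
        Environment plus per-cell winter catch.
    train_years, test_years : sequences of int
        Winter years (labelled by their December) used for training and
        held-out validation.
    """

    def __init__(self, grid: EnvironmentalGrid, train_years: Sequence[int],
                 test_years: Sequence[int], **select_kwargs):
        self.grid = grid
        self.train_years = tuple(int(y) for y in train_years)
        self.test_years = tuple(int(y) for y in test_years)
        self.select_kwargs = select_kwargs

    def fit(self) -> "HabitatResults":
        sel = validate_and_select(self.grid, self.train_years, self.test_years,
                                  **self.select_kwargs)
        return HabitatResults(self, sel)


class HabitatResults:
    """Fitted habitat model: prediction, classification, decadal statistics
    and summary reporting hang off this object."""

    def __init__(self, model: HabitatSuitabilityModel, selection: SelectionResult):
        self.model = model
        self.selection = selection
        self.best_model = selection.best_model
        self.validation = selection.validation

    def predict_year(self, year: int) -> pd.DataFrame:
        """Winter-mean HSI per cell for one winter year."""
        wm = build_winter_table(self.model.grid, [year])
        hsi = self.best_model.predict(
            {v: wm[v].to_numpy() for v in self.best_model.variables})
        out = wm[["lon", "lat", "year"]].copy()
        out["hsi"] = hsi
        return out

    def classify_year(self, year: int, thresholds=(0.7, 0.3)) -> dict:
        df = self.predict_year(year)
        return classify_and_area(df["hsi"], df["lat"], thresholds)

    def decadal_stats(self, decades: Mapping[str, Sequence[int]],
                      thresholds=(0.7, 0.3)) -> tuple[list[DecadalHabitatStats], dict]:
        """Per-decade habitat-class percentages plus ANOVA/Scheffe tests of
        yearly optimal and average areas across decades."""
        stats_out = []
        opt_groups, avg_groups = {}, {}
        for label, years in decades.items():
            per_year = []
            for y in years:
                c = self.classify_year(int(y), thresholds)
                c["year"] = int(y)
                per_year.append(c)
            df = pd.DataFrame(per_year)
            stats_out.append(DecadalHabitatStats(
                decade=label,
                pct_optimal=float(df["pct_optimal"].mean()),
                pct_average=float(df["pct_average"].mean()),
                pct_poor=float(100.0 - df["pct_optimal"].mean() - df["pct_average"].mean()),
                per_year=df,
            ))
            opt_groups[label] = df["area_optimal"].to_numpy()
            avg_groups[label] = df["area_average"].to_numpy()
        tests = {
            "optimal": decadal_anova(opt_groups),
            "average": decadal_anova(avg_groups),
        }
        return stats_out, tests

    def winter_sst_trend(self, years: Sequence[int]) -> TrendResult:
        """Trend of the area-mean winter SST over the given winter years."""
        means = []
        for y in years:
            wm = winter_mean(self.model.grid, int(y))
            means.append(float(wm["sst_c"].mean()))
        return winter_sst_trend_series(np.asarray(years), np.asarray(means))

    def summary(self) -> str:
        v = self.validation
        m = self.best_model
        lines = [
            "Habitat suitability model selection",
            "-" * 44,
            f"  best model    {self.selection.best_form} / "
            f"{m.combiner.upper()} / {'+'.join(m.variables)}",
            f"  test R^2      {v.r2:8.4f}   (train {v.train_years[0]}-{v.train_years[-1]},"
            f" test {v.test_years[0]}-{v.test_years[-1]}, n={v.n_test})",
            f"  test AICc     {v.aicc:8.2f}",
            "  SI curves (refit on full period):",
        ]
        for var in m.variables:
            c = m.si_curves[var]
            lo, hi = c.optimal_range
            if c.form == "fitting_based":
                lines.append(
                    f"    {var:6s} Gaussian mu={c.params['mu']:.3f} "
                    f"sigma={c.params['sigma']:.3f} optimal [{lo:.2f}, {hi:.2f}]"
                )
            else:
                lines.append(f"    {var:6s} polynomial, optimal [{lo:.2f}, {hi:.2f}]")
        return "\n".join(lines)

    def plot_si_curves(self, ax=None):
        import matplotlib.pyplot as plt

        m = self.best_model
        if ax is None:
            _, axes = plt.subplots(1, len(m.variables), figsize=(4 * len(m.variables), 3))
        else:
            axes = ax
        axes = np.atleast_1d(axes)
        for a, var in zip(axes, m.variables):
            c = m.si_curves[var]
            xx = np.linspace(c.domain[0], c.domain[1], 300)
            a.plot(xx, c.evaluate(xx))
            a.set_xlabel(var)
            a.set_ylabel("SI")
            a.set_ylim(0, 1.05)
        return axes


# module-level alias so HabitatResults.winter_sst_trend can shadow the name
winter_sst_trend_series = winter_sst_trend
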