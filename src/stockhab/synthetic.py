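"""Synthetic fishery and environment generators with known ground truth.

Every downstream stage (ELEFAN growth fitting, catch-curve mortality, HSI
selection) is validated by parameter recovery: these generators build data
from a fully specified population or habitat, record the truth, and let the
tests check that the estimators get it back.

The population generator draws individual fish from an equilibrium age
structure (constant recruitment, constant total mortality Z, so cohort
abundance decays as exp(-Z age)), maps cohort age to mean length through
the seasonalized von Bertalanffy curve, adds Gaussian individual variation,
and thins by logistic gear selectivity.  The habitat generator lays down
smooth depth/SST/SSS fields on a regular grid and makes expected winter
catch proportional to a known true HSI built from unimodal Gaussian
suitability curves, with optional lognormal observation noise and a linear
SST trend.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import xarray as xr

from .errors import ValidationError
from .growth import VBGFParams, length_at_time
from .habitat import EnvironmentalGrid
from .lfq import LengthFrequencyData, bin_lengths, decimal_year

__all__ = [
    "PopulationScenario",
    "HabitatScenario",
    "LengthSamples",
    "simulate_length_frequencies",
    "simulate_environment_and_catch",
    "DEFAULT_SI_TRUE",
]

WINTER_MONTHS_ORDER = (12, 1, 2)

# survey cruise dates emulated by the default scenario (quasi-seasonal
# coverage over one year)
_DEFAULT_DATES = (
    _dt.date(2018, 11, 18),
    _dt.date(2019, 1, 20),
    _dt.date(2019, 4, 18),
    _dt.date(2019, 7, 17),
    _dt.date(2019, 9, 28),
    _dt.date(2019, 11, 18),
)


@dataclass(frozen=True)
class PopulationScenario:
    """Ground-truth population for length-frequency simulation.

    Defaults describe a heavily exploited, fast-growing sciaenid-like stock:
    Linf = 434 mm, K = 0.43 /yr, t0 = -0.06 yr, total mortality Z = 1.87 /yr,
    logistic gear selectivity with L50/L95 at the lengths a 0.37/0.49-yr-old
    fish reaches, one recruitment pulse per year, six quasi-seasonal survey
    dates with ~346 fish each (about 2074 in total), and 8% individual
    length variation.
    """

    linf_mm: float = 434.0
    k_per_yr: float = 0.43
    t0_yr: float = -0.06
    c_amp: float = 0.0
    ts_yr: float = 0.0
    z_per_yr: float = 1.87
    sel_l50_mm: float = 73.0
    sel_l95_mm: float = 92.0
    recruit_pulses_per_yr: int = 1
    sample_dates: tuple = _DEFAULT_DATES
    n_per_sample: int = 346
    cv_length: float = 0.08
    seed: int = 0

    def __post_init__(self):
        numeric = (
            self.linf_mm, self.k_per_yr, self.t0_yr, self.c_amp, self.ts_yr,
            self.z_per_yr, self.sel_l50_mm, self.sel_l95_mm, self.cv_length,
        )
        if not all(np.isfinite(v) for v in numeric):
            raise ValidationError("scenario parameters must be finite")
        if self.linf_mm <= 0 or self.k_per_yr <= 0 or self.z_per_yr <= 0:
            raise ValidationError("linf_mm, k_per_yr and z_per_yr must be positive")
        if not 0.0 <= self.c_amp <= 1.0:
            raise ValidationError("c_amp must lie in [0, 1]")
        if not self.sel_l95_mm > self.sel_l50_mm:
            raise ValidationError("sel_l95_mm must exceed sel_l50_mm")
        if self.recruit_pulses_per_yr not in (1, 2):
            raise ValidationError("recruit_pulses_per_yr must be 1 or 2")
        if self.n_per_sample < 1:
            raise ValidationError("n_per_sample must be >= 1")
        if self.cv_length < 0:
            raise ValidationError("cv_length must be non-negative")
        if not self.sample_dates:
            raise ValidationError("at least one sample date is required")

    @property
    def growth(self) -> VBGFParams:
        return VBGFParams(
            linf_mm=self.linf_mm, k_per_yr=self.k_per_yr,
            c_amp=self.c_amp, ts_yr=self.ts_yr, t0_yr=self.t0_yr,
        )


@dataclass(frozen=True)
class LengthSamples:
    """Raw per-date measured lengths produced by the simulator.

    ``samples`` maps each sample date (as given in the scenario) to the
    vector of retained lengths (mm); ``cohort_ages`` holds, per date, the
    relative age of each retained fish's cohort (truth for recovery tests).
    """

    samples: Mapping[object, np.ndarray]
    cohort_ages: Mapping[object, np.ndarray]
    scenario: PopulationScenario

    @property
    def total_count(self) -> int:
        return int(sum(v.size for v in self.samples.values()))

    def to_lfq(self, bin_mm: float) -> LengthFrequencyData:
        return bin_lengths(self.samples, bin_mm)


def _logistic_selectivity(length_mm, l50, l95):
    slope = np.log(19.0) / (l95 - l50)
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(length_mm, float) - l50)))


def simulate_length_frequencies(scenario: PopulationScenario) -> LengthSamples:
    """Draw length samples from the scenario's equilibrium population.

    For each sample date: cohorts are recruitment pulses (1 or 2 per year,
    at year start and mid-year) young enough that survival exp(-Z age)
    exceeds 1e-4; a fish's cohort is drawn with probability proportional to
    survival, its mean length follows the seasonal VBGF phased to the
    calendar (zero length at pulse time + t0), Gaussian individual scatter
    with sd = cv_length * mean length is added (redrawn while non-positive),
    and the fish is retained with logistic selectivity probability.
    Rejection sampling continues until exactly ``n_per_sample`` fish are
    retained per date.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    growth = scenario.growth
    max_age = np.log(1e4) / scenario.z_per_yr
    offsets = (0.0,) if scenario.recruit_pulses_per_yr == 1 else (0.0, 0.5)
    out: dict = {}
    ages_out: dict = {}
    for key in scenario.sample_dates:
        d = decimal_year(key) if isinstance(key, _dt.date) else float(key)
        pulses = []
        for year in range(int(np.floor(d - max_age)), int(np.floor(d)) + 1):
            for off in offsets:
                p = year + off
                age = d - p
                if 0.0 < age <= max_age:
                    pulses.append(p)
        pulses = np.asarray(pulses)
        ages = d - pulses
        mean_len = np.array([
            length_at_time(growth, p + scenario.t0_yr, d) for p in pulses
        ])
        viable = mean_len > 0
        if not viable.any():
            raise ValidationError(f"no recruited cohort has positive length at {key!r}")
        pulses, ages, mean_len = pulses[viable], ages[viable], mean_len[viable]
        weights = np.exp(-scenario.z_per_yr * ages)
        weights = weights / weights.sum()
        kept_len: list[np.ndarray] = []
        kept_age: list[np.ndarray] = []
        n_kept = 0
        while n_kept < scenario.n_per_sample:
            batch = max(4 * (scenario.n_per_sample - n_kept), 64)
            ci = rng.choice(pulses.size, size=batch, p=weights)
            L = mean_len[ci].astype(float)
            if scenario.cv_length > 0:
                L = L + rng.normal(0.0, scenario.cv_length * mean_len[ci])
                bad = L <= 0
                while bad.any():  # truncate individual variation at zero length
                    L[bad] = mean_len[ci][bad] + rng.normal(
                        0.0, scenario.cv_length * mean_len[ci][bad])
                    bad = L <= 0
            p_sel = _logistic_selectivity(L, scenario.sel_l50_mm, scenario.sel_l95_mm)
            keep = rng.random(batch) < p_sel
            kept_len.append(L[keep])
            kept_age.append(ages[ci[keep]])
            n_kept += int(keep.sum())
        lengths = np.concatenate(kept_len)[: scenario.n_per_sample]
        cohort_ages = np.concatenate(kept_age)[: scenario.n_per_sample]
        out[key] = lengths
        ages_out[key] = cohort_ages
    return LengthSamples(samples=out, cohort_ages=ages_out, scenario=scenario)


# Gaussian SI truth: modes at the centre of each optimal range, widths such
# that SI = 0.8 at the range edges (depth 36-72 m, SST 18.2-20.5 C,
# SSS 33.89-34.27)
_W08 = np.sqrt(2.0 * np.log(1.0 / 0.8))
DEFAULT_SI_TRUE: dict[str, tuple[float, float]] = {
    "depth": (54.0, 18.0 / _W08),
    "sst": (19.35, 1.15 / _W08),
}


@dataclass(frozen=True)
class HabitatScenario:
    """Ground-truth habitat world for the HSI pipeline.

    A 0.5-degree grid over a shelf-sea domain; depth is static and deepens
    offshore, SST carries a meridional gradient, fixed per-cell spatial
    structure, small month effects and a linear trend (default -0.028 C/yr,
    a multi-decadal winter cooling), SSS a zonal gradient.  Expected winter
    catch is ``catch_scale_t`` times the true HSI (arithmetic mean of the
    Gaussian SIs in ``si_true`` evaluated on winter-mean fields), observed
    catch multiplies in mean-one lognormal noise with CV ``catch_noise_cv``.
    """

    lon_range: tuple[float, float] = (120.0, 126.0)
    lat_range: tuple[float, float] = (24.0, 30.0)
    resolution_deg: float = 0.5
    years: tuple = tuple(range(1971, 1983))
    si_true: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SI_TRUE))
    catch_noise_cv: float = 0.3
    sst_trend_per_yr: float = -0.028
    catch_scale_t: float = 1000.0
    sst_cell_sd: float = 0.6
    sss_cell_sd: float = 0.05
    sss_interannual_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.resolution_deg <= 0:
            raise ValidationError("resolution_deg must be positive")
        if self.catch_noise_cv < 0:
            raise ValidationError("catch_noise_cv must be non-negative")
        if not self.years:
            raise ValidationError("year list must be non-empty")
        for var, (mode, width) in self.si_true.items():
            if width <= 0:
                raise ValidationError(f"si_true width for {var!r} must be positive")
            if var not in ("depth", "sst", "sss"):
                raise ValidationError(f"unknown si_true variable {var!r}")


def _gaussian(x, mu, sigma):
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def simulate_environment_and_catch(scenario: HabitatScenario) -> EnvironmentalGrid:
    """Build the gridded environment and winter catch for the scenario.

    Monthly SST/SSS are stored by *calendar* year and month (12, 1, 2), so
    the winter labelled y uses December y plus January/February y+1; the
    months of winter y share the trend offset ``sst_trend_per_yr * (y - y0)``
    and fixed per-cell spatial noise, which makes the winter-mean trend
    exactly linear and estimable.  Per-cell expected catch is proportional
    to the true HSI, which is stored as ``true_hsi`` for recovery tests.
    """
    rng = np.random.default_rng(scenario.seed)
    res = scenario.resolution_deg
    lon = np.arange(scenario.lon_range[0] + res / 2, scenario.lon_range[1], res)
    lat = np.arange(scenario.lat_range[0] + res / 2, scenario.lat_range[1], res)
    if lon.size == 0 or lat.size == 0:
        raise ValidationError("empty grid: check lon/lat ranges and resolution")
    fx = (lon[None, :] - scenario.lon_range[0]) / (scenario.lon_range[1] - scenario.lon_range[0])
    fy = (lat[:, None] - scenario.lat_range[0]) / (scenario.lat_range[1] - scenario.lat_range[0])
    depth = 15.0 + 100.0 * fx + 15.0 * fy  # deepens offshore (east) and north
    sst_base = 22.0 - 6.0 * fy + 0.0 * fx
    # saddle-shaped salinity: spatially structured but uncorrelated with the
    # zonal depth and meridional SST gradients, so predictors are separable
    sss_base = 34.10 + 0.25 * (2.0 * fx - 1.0) * (2.0 * fy - 1.0)
    sst_cell = rng.normal(0.0, scenario.sst_cell_sd, size=(lat.size, lon.size))
    sss_cell = rng.normal(0.0, scenario.sss_cell_sd, size=(lat.size, lon.size))
    month_delta_sst = {12: 0.6, 1: -0.4, 2: -0.2}
    month_delta_sss = {12: 0.02, 1: -0.01, 2: -0.01}

    wyears = np.asarray(sorted(int(y) for y in scenario.years))
    y0 = wyears[0]
    cal_years = np.arange(wyears[0], wyears[-1] + 2)
    months = np.array(WINTER_MONTHS_ORDER)
    sst = np.full((cal_years.size, months.size, lat.size, lon.size), np.nan)
    sss = np.full_like(sst, np.nan)
    for wy in wyears:
        trend = scenario.sst_trend_per_yr * (wy - y0)
        # interannual salinity anomaly per cell, shared by the winter's months
        sss_anom = rng.normal(0.0, scenario.sss_interannual_sd, size=(lat.size, lon.size))
        for month, cal in ((12, wy), (1, wy + 1), (2, wy + 1)):
            iy = int(np.searchsorted(cal_years, cal))
            im = int(np.flatnonzero(months == month)[0])
            sst[iy, im] = sst_base + sst_cell + month_delta_sst[month] + trend
            sss[iy, im] = sss_base + sss_cell + month_delta_sss[month] + sss_anom

    sigma_ln = np.sqrt(np.log(1.0 + scenario.catch_noise_cv**2))
    catch = np.empty((wyears.size, lat.size, lon.size))
    true_hsi = np.empty_like(catch)
    for i, wy in enumerate(wyears):
        winter_sst = np.nanmean(
            [sst[int(np.searchsorted(cal_years, cy)), int(np.flatnonzero(months == m)[0])]
             for m, cy in ((12, wy), (1, wy + 1), (2, wy + 1))], axis=0)
        winter_sss = np.nanmean(
            [sss[int(np.searchsorted(cal_years, cy)), int(np.flatnonzero(months == m)[0])]
             for m, cy in ((12, wy), (1, wy + 1), (2, wy + 1))], axis=0)
        fields = {"depth": depth, "sst": winter_sst, "sss": winter_sss}
        sis = [
            _gaussian(fields[var], mode, width)
            for var, (mode, width) in scenario.si_true.items()
        ]
        hsi = np.mean(sis, axis=0)
        true_hsi[i] = hsi
        expected = scenario.catch_scale_t * hsi
        if scenario.catch_noise_cv > 0:
            mult = np.exp(rng.normal(-sigma_ln**2 / 2.0, sigma_ln, size=hsi.shape))
        else:
            mult = 1.0
        catch[i] = expected * mult

    ds = xr.Dataset(
        {
            "depth_m": (("lat", "lon"), np.broadcast_to(depth, (lat.size, lon.size)).copy()),
            "sst_c": (("year", "month", "lat", "lon"), sst),
            "sss": (("year", "month", "lat", "lon"), sss),
            "catch_t": (("wyear", "lat", "lon"), catch),
            "true_hsi": (("wyear", "lat", "lon"), true_hsi),
        },
        coords={
            "lat": lat, "lon": lon,
            "year": cal_years, "month": months,
            "wyear": wyears,
        },
        attrs={"seed": scenario.seed},
    )
    return EnvironmentalGrid(ds)
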