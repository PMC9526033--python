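"""Mortality, exploitation, gear selectivity, and length-weight fits.

Given an accepted growth curve, the length-converted catch curve pools the
length-frequency samples, converts length bins to relative ages via the
inverse von Bertalanffy function, and regresses ln(N/dt) on relative age
over the descending (fully selected) limb; the negative slope estimates the
total mortality rate Z (1/yr).  Natural mortality M comes from empirical
estimators (or is supplied directly), fishing mortality is F = Z - M, and
the exploitation rate is E = F/Z.  The ascending limb, under-represented
because small fish escape the gear, yields the capture-probability ogive
(t50, t95) by comparing observed with back-extrapolated expected counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ComputationError, ValidationError
from .growth import VBGFParams, inverse_vbgf_age, seasonal_vbgf_length
from .lfq import LengthFrequencyData

__all__ = [
    "CatchCurveResult",
    "MortalityEstimates",
    "SelectivityOgive",
    "LengthWeightFit",
    "length_converted_catch_curve",
    "natural_mortality",
    "exploitation",
    "catch_probability_ogive",
    "fit_length_weight",
]


@dataclass(frozen=True)
class CatchCurveResult:
    """Length-converted catch-curve regression output.

    ``t_mid``/``log_n_dt`` cover every bin with a defined point; ``used``
    flags the descending-limb points entering the regression.  The intercept
    and slope allow back-extrapolation of expected counts for the
    selectivity ogive.
    """

    z_per_yr: float
    z_se: float
    slope: float
    intercept: float
    t_mid: np.ndarray
    dt: np.ndarray
    log_n_dt: np.ndarray
    counts: np.ndarray
    used: np.ndarray
    peak_index: int


@dataclass(frozen=True)
class MortalityEstimates:
    """Total (Z), natural (M) and fishing (F) mortality with exploitation
    rate E = F/Z.  The identities F = Z - M and E = F/Z hold exactly."""

    z_per_yr: float
    m_per_yr: float
    f_per_yr: float
    e_ratio: float
    z_se: float | None = None
    m_method: str = "user"

    def __post_init__(self):
        if self.z_per_yr < 0:
            raise ValidationError("Z must be non-negative")
        if not np.isclose(self.f_per_yr, self.z_per_yr - self.m_per_yr):
            raise ValidationError("identity F = Z - M violated")
        if self.z_per_yr > 0 and not np.isclose(self.e_ratio, self.f_per_yr / self.z_per_yr):
            raise ValidationError("identity E = F/Z violated")

    def rounded(self, ndigits: int = 2) -> dict:
        """Values rounded for reporting; rounding happens only here, never
        inside the computation."""
        return {
            "z_per_yr": round(self.z_per_yr, ndigits),
            "m_per_yr": round(self.m_per_yr, ndigits),
            "f_per_yr": round(self.f_per_yr, ndigits),
            "e_ratio": round(self.e_ratio, ndigits),
        }

    def summary(self) -> str:
        se = f" (SE {self.z_se:.3f})" if self.z_se is not None else ""
        return "\n".join([
            "Mortality and exploitation",
            "-" * 32,
            f"  Z  total mortality    {self.z_per_yr:7.3f} /yr{se}",
            f"  M  natural mortality  {self.m_per_yr:7.3f} /yr  [{self.m_method}]",
            f"  F  fishing mortality  {self.f_per_yr:7.3f} /yr",
            f"  E  exploitation rate  {self.e_ratio:7.3f}",
        ])


@dataclass(frozen=True)
class SelectivityOgive:
    """Logistic capture-probability ogive in relative age, with lengths at
    50% and 95% capture obtained through the growth curve."""

    t50_yr: float
    t95_yr: float
    l50_mm: float
    l95_mm: float

    def __post_init__(self):
        if not self.t95_yr > self.t50_yr:
            raise ValidationError("t95 must exceed t50")

    def probability(self, t) -> np.ndarray:
        """Capture probability at relative age t (0.5 at t50, 0.95 at t95)."""
        slope = np.log(19.0) / (self.t95_yr - self.t50_yr)
        return 1.0 / (1.0 + np.exp(-slope * (np.asarray(t, float) - self.t50_yr)))


@dataclass(frozen=True)
class LengthWeightFit:
    """Allometric length-weight relationship w = a * L^b (L in mm, w in g)."""

    a_coeff: float
    b_exp: float
    n_fit: int
    r2: float

    def __post_init__(self):
        if self.a_coeff <= 0 or self.b_exp <= 0:
            raise ValidationError("a and b must be positive")

    def predict(self, length_mm) -> np.ndarray:
        return self.a_coeff * np.asarray(length_mm, float) ** self.b_exp


def length_converted_catch_curve(
    lfq: LengthFrequencyData,
    growth: VBGFParams,
    point_selection: str | np.ndarray = "auto",
    min_count: int = 5,
) -> CatchCurveResult:
    """Estimate Z from pooled length frequencies and a growth curve.

    Bins are converted to relative ages at their edges via the non-seasonal
    inverse VBGF; points are ``ln(count / dt)`` at the age midpoint of each
    bin.  With ``point_selection="auto"`` the regression uses the bins
    strictly after the pooled peak through the last bin holding at least
    ``min_count`` fish (small terminal counts give unstable logs); an
    integer index array selects points explicitly.  Bins at or beyond Linf
    are excluded with a warning.

    Raises
    ------
    ComputationError
        If fewer than three usable points remain.
    """
    pooled = lfq.pooled_counts().astype(float)
    lower = lfq.bin_lower_mm
    width = lfq.bin_width
    upper = lower + width
    inside = upper < growth.linf_mm
    if not inside.all():
        warnings.warn(
            f"{(~inside).sum()} bin(s) at or above Linf={growth.linf_mm:g} mm excluded",
            stacklevel=2,
        )
    idx_all = np.flatnonzero(inside)
    t_lo = inverse_vbgf_age(growth, lower[idx_all])
    t_hi = inverse_vbgf_age(growth, upper[idx_all])
    dt = t_hi - t_lo
    t_mid = 0.5 * (t_lo + t_hi)
    n = pooled[idx_all]
    with np.errstate(divide="ignore"):
        y = np.where(n > 0, np.log(np.maximum(n, 1e-300) / dt), -np.inf)
    if isinstance(point_selection, str):
        if point_selection != "auto":
            raise ValidationError(f"unknown point_selection {point_selection!r}")
        peak = int(np.argmax(n))
        usable = np.flatnonzero(n >= min_count)
        last = usable.max() if usable.size else -1
        sel = np.arange(peak + 1, last + 1)
        sel = sel[n[sel] >= min_count]
    else:
        sel = np.asarray(point_selection, dtype=int)
        peak = int(np.argmax(n))
        if np.any(n[sel] <= 0):
            raise ValidationError("selected points include zero counts")
    if sel.size < 3:
        raise ComputationError("fewer than 3 usable descending-limb points")
    res = stats.linregress(t_mid[sel], y[sel])
    used = np.zeros(n.size, dtype=bool)
    used[sel] = True
    return CatchCurveResult(
        z_per_yr=float(-res.slope),
        z_se=float(res.stderr),
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_mid=t_mid,
        dt=dt,
        log_n_dt=y,
        counts=n,
        used=used,
        peak_index=peak,
    )


def natural_mortality(
    growth: VBGFParams,
    method: str = "user",
    temp_c: float | None = None,
    m_user: float | None = None,
) -> float:
    """Natural mortality M (1/yr) from empirical estimators.

    ``pauly_T``:  log10 M = -0.0066 - 0.279 log10 Linf + 0.6543 log10 K
    + 0.4634 log10 T, with Linf in cm and T the mean water temperature (C).
    ``then_growth``:  M = 4.118 K^0.73 Linf^-0.33 (Linf in cm).
    ``user``: pass-through of ``m_user``.
    """
    linf_cm = growth.linf_mm / 10.0
    k = growth.k_per_yr
    if method == "user":
        if m_user is None or m_user < 0:
            raise ValidationError("user method requires a non-negative m_user")
        return float(m_user)
    if method == "pauly_T":
        if temp_c is None or temp_c <= 0:
            raise ValidationError("pauly_T requires a positive mean temperature")
        log10m = (
            -0.0066
            - 0.279 * np.log10(linf_cm)
            + 0.6543 * np.log10(k)
            + 0.4634 * np.log10(temp_c)
        )
        return float(10.0 ** log10m)
    if method == "then_growth":
        return float(4.118 * k**0.73 * linf_cm**-0.33)
    raise ValidationError(f"unknown natural-mortality method {method!r}")


def exploitation(
    z: float, m: float, z_se: float | None = None, m_method: str = "user"
) -> MortalityEstimates:
    """Fishing mortality and exploitation rate from Z and M.

    F = Z - M and E = F/Z, computed at full precision (round only when
    reporting).  M above Z flags an implausible estimate.
    """
    if z <= 0:
        raise ValidationError("Z must be positive")
    if m < 0 or m > z:
        raise ValidationError(f"implausible estimates: M={m} outside [0, Z={z}]")
    f = z - m
    return MortalityEstimates(
        z_per_yr=float(z), m_per_yr=float(m), f_per_yr=float(f),
        e_ratio=float(f / z), z_se=z_se, m_method=m_method,
    )


def fit_logistic_ogive(t, p) -> tuple[float, float]:
    """Least-squares fit of a logistic capture-probability curve.

    Parameterised directly by (t50, t95): P(t) = 1 / (1 + exp(-s (t - t50)))
    with s = ln(19) / (t95 - t50), so P(t50) = 0.5 and P(t95) = 0.95 by
    construction.  Returns (t50, t95).
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 3:
        raise ValidationError("need at least 3 points to fit the ogive")

    def logistic(tt, t50, t95):
        slope = np.log(19.0) / np.maximum(t95 - t50, 1e-9)
        return 1.0 / (1.0 + np.exp(-slope * (tt - t50)))

    i50 = int(np.argmin(np.abs(p - 0.5)))
    guess = (float(t[i50]), float(t[i50]) + 0.1)
    popt, _ = optimize.curve_fit(
        logistic, t, p, p0=guess, maxfev=20000,
        bounds=([-5.0, -5.0 + 1e-6], [t.max() + 5.0, t.max() + 10.0]),
    )
    t50, t95 = float(popt[0]), float(popt[1])
    if not t95 > t50:
        raise ComputationError("degenerate ogive fit: t95 <= t50")
    return t50, t95


def catch_probability_ogive(
    catch_curve: CatchCurveResult, growth: VBGFParams
) -> SelectivityOgive:
    """Fit the logistic capture-probability ogive from the ascending limb.

    Expected fully selected counts on the ascending limb (bins up to and
    including the pooled peak) are back-extrapolated from the catch-curve
    regression as ``exp(intercept + slope * t) * dt``; capture probability
    is observed/expected clipped to [0, 1].  A logistic in relative age is
    then least-squares fitted, giving t50 (P = 0.5) and t95 (P = 0.95), and
    the corresponding lengths via the growth curve.
    """
    first_used = int(np.flatnonzero(catch_curve.used).min())
    if first_used == 0:
        raise ComputationError("no ascending limb before the first regression point")
    last_used = int(np.flatnonzero(catch_curve.used).max())
    sel = np.arange(0, last_used + 1)
    t_all = catch_curve.t_mid[sel]
    expected = np.exp(catch_curve.intercept + catch_curve.slope * t_all) * catch_curve.dt[sel]
    p_all = np.clip(catch_curve.counts[sel] / expected, 0.0, 1.0)
    t50, t95 = fit_logistic_ogive(t_all, p_all)
    l50 = seasonal_vbgf_length(
        VBGFParams(growth.linf_mm, growth.k_per_yr, t0_yr=growth.t0_yr or 0.0), t50
    )
    l95 = seasonal_vbgf_length(
        VBGFParams(growth.linf_mm, growth.k_per_yr, t0_yr=growth.t0_yr or 0.0), t95
    )
    return SelectivityOgive(t50_yr=t50, t95_yr=t95, l50_mm=float(l50), l95_mm=float(l95))


def fit_length_weight(lengths_mm, weights_g) -> LengthWeightFit:
    """Fit w = a L^b by OLS on the log-log scale.

    Requires at least three positive (length, weight) pairs; returns a
    (g mm^-b), b, n and the log-scale r-squared.
    """
    L = np.asarray(lengths_mm, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if L.shape != w.shape or L.ndim != 1:
        raise ValidationError("lengths and weights must be 1-D arrays of equal size")
    if L.size < 3:
        raise ValidationError("need at least 3 length-weight pairs")
    if np.any(L <= 0) or np.any(w <= 0):
        raise ValidationError("lengths and weights must be positive")
    res = stats.linregress(np.log(L), np.log(w))
    return LengthWeightFit(
        a_coeff=float(np.exp(res.intercept)),
        b_exp=float(res.slope),
        n_fit=int(L.size),
        r2=float(res.rvalue**2),
    )
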