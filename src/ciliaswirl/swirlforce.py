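"""Annular swirl decomposition and the force-balance transport model.

Within a swirl, the propulsive force per unit area exerted by the cilia on
an annulus at radius r is proportional to ``nu_r * <sin alpha>_r`` — the
local active ciliated density times the mean tangential component of the
beat directions (alpha is the angle between a tuft's beat direction and
the outward radius through it).  This dimensionless product is the *force
proxy*.  Balancing it against the viscous friction of the sheared
periciliary layer yields an affine relation between force and surface-
fluid velocity:

    (phi n_c f_c / A_cc) nu_r <sin alpha>_r = eta_pc (V_SF + V_R) / e

so V_SF grows linearly with the proxy with slope
``(e / eta_pc) (phi n_c f_c / A_cc)`` — about 4e-5 m/s (40 um/s) for
typical parameter values — and a negative intercept set by the recovery-
stroke speed V_R.  This module computes annular profiles from tuft
tables, the model's stresses/velocities, and the affine and power-law
fits that summarise them.

Unit discipline: the model operations work in SI; tuft tables, profiles
and velocities at the interface are in micrometres and um/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelParams",
    "LinearFit",
    "PowerLawFit",
    "PowerLawResult",
    "annular_profile",
    "attach_velocity",
    "estimate_swirl_center",
    "force_proxy_fit",
    "propulsive_stress",
    "friction_stress",
    "model_slope",
    "steady_velocity",
    "fit_velocity_force",
    "fit_power_law",
]

#: SwirlProfile column layout (one row per populated annulus).
PROFILE_COLUMNS = ["r_mid_um", "nu_r", "sin_alpha_r", "n_tufts", "force_proxy"]


def annulus_edges(r_max: float, dr: float) -> np.ndarray:
    """Concentric annulus edges [0, dr, 2 dr, ..., r_max]; the outermost
    annulus is truncated at r_max so its area matches the sampled region."""
    edges = np.arange(0.0, r_max, dr)
    return np.append(edges, r_max)


@dataclass
class ModelParams:
    """Parameters of the force-balance model (SI units).

    ``V_R``, the recovery-stroke tip speed, has no canonical value and
    must be supplied explicitly (0 switches the friction offset off).
    The remaining defaults are typical literature estimates: a cilium
    exerts ~1 pN, a ciliated cell carries ~160 cilia over ~80 um^2, the
    power stroke occupies ~10% of the beat cycle, and the periciliary
    layer shears over ~1 um with viscosity ~5 mPa s.
    """

    V_R: float  # m/s, recovery-stroke tip speed (>= 0)
    phi: float = 0.1  # time fraction of the propulsive stroke
    n_c: float = 160.0  # cilia per ciliated cell
    f_c: float = 1e-12  # N, force per cilium on the mucus
    A_cc: float = 8e-11  # m^2, ciliated-cell area
    eta_pc: float = 5e-3  # Pa s, periciliary viscosity
    e: float = 1e-6  # m, sheared-layer thickness

    def __post_init__(self) -> None:
        if not 0 < self.phi < 1:
            raise ValueError("phi must lie in (0, 1)")
        for name in ("n_c", "f_c", "A_cc", "eta_pc", "e"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.V_R < 0:
            raise ValueError("V_R must be >= 0")


@dataclass
class LinearFit:
    """Ordinary-least-squares affine fit y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float
    stderr_intercept: float

    @classmethod
    def from_xy(cls, x: np.ndarray, y: np.ndarray) -> "LinearFit":
        res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
        return cls(
            float(res.slope),
            float(res.intercept),
            float(res.rvalue**2),
            float(res.stderr),
            float(res.intercept_stderr),
        )


def annular_profile(
    tufts: pd.DataFrame,
    center: tuple[float, float],
    dr: float = 20.0,
    r_max: float | None = None,
    min_tufts: int = 5,
) -> pd.DataFrame:
    """Decompose a tuft table into concentric annuli about ``center``.

    For the annulus [k dr, (k+1) dr): ``nu_r`` is the summed tuft area
    divided by the annulus area, and ``sin_alpha_r`` the mean over its
    tufts of sin(alpha), alpha being the angle between the beat direction
    (or bare axis — sin alpha is the same for both) and the outward
    radius.  Annuli holding fewer than ``min_tufts`` tufts are dropped
    (missing, not zero).  ``force_proxy = nu_r * sin_alpha_r`` exactly.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    if len(tufts) == 0:
        raise ValueError("tuft table is empty")
    x = tufts["x_um"].to_numpy() - center[0]
    y = tufts["y_um"].to_numpy() - center[1]
    r = np.hypot(x, y)
    if r_max is None:
        r_max = float(r.max())
    bx0, bx1 = tufts["x_um"].min(), tufts["x_um"].max()
    by0, by1 = tufts["y_um"].min(), tufts["y_um"].max()
    margin = max(bx0 - center[0], center[0] - bx1, by0 - center[1], center[1] - by1)
    if margin > r_max:
        warnings.warn("center lies far outside the tuft bounding box", stacklevel=2)

    radial_angle = np.arctan2(y, x)
    sin_alpha = np.abs(np.sin(tufts["beat_dir_rad"].to_numpy() - radial_angle))
    area = tufts["area_um2"].to_numpy()

    edges = annulus_edges(r_max, dr)
    idx = np.digitize(r, edges) - 1
    idx[r == edges[-1]] = len(edges) - 2  # the boundary itself belongs inside
    rows = []
    for k in range(len(edges) - 1):
        sel = idx == k
        n = int(sel.sum())
        if n < min_tufts:
            continue
        ann_area = np.pi * (edges[k + 1] ** 2 - edges[k] ** 2)
        nu_r = float(area[sel].sum() / ann_area)
        s = float(sin_alpha[sel].mean())
        rows.append(
            {
                "r_mid_um": (edges[k] + edges[k + 1]) / 2,
                "nu_r": nu_r,
                "sin_alpha_r": s,
                "n_tufts": n,
                "force_proxy": nu_r * s,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def attach_velocity(profile: pd.DataFrame, velocity: pd.DataFrame) -> pd.DataFrame:
    """Merge a velocity profile (r_mid_um, V_um_s) into a swirl profile on
    the annulus midpoint."""
    return profile.merge(velocity[["r_mid_um", "V_um_s"]], on="r_mid_um", how="inner")


def estimate_swirl_center(
    tufts: pd.DataFrame, x0: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Automated stand-in for a manually chosen swirl centre: the point
    maximising the mean tangential order <sin alpha> of the tuft table
    (area-weighted), found by Nelder-Mead from the tuft centroid."""
    xs = tufts["x_um"].to_numpy()
    ys = tufts["y_um"].to_numpy()
    beat = tufts["beat_dir_rad"].to_numpy()
    w = tufts["area_um2"].to_numpy() if "area_um2" in tufts else np.ones_like(xs)

    def neg_order(c):
        ang = np.arctan2(ys - c[1], xs - c[0])
        return -float(np.average(np.abs(np.sin(beat - ang)), weights=w))

    if x0 is None:
        x0 = (float(xs.mean()), float(ys.mean()))
    res = optimize.minimize(neg_order, x0, method="Nelder-Mead")
    return float(res.x[0]), float(res.x[1])


def force_proxy_fit(profile: pd.DataFrame) -> LinearFit:
    """Affine OLS fit of the force proxy nu_r * <sin alpha>_r against the
    annulus radius (the intercept is allowed to be nonzero: the force per
    unit area need not vanish at the centre)."""
    if len(profile) < 3:
        raise ValueError("need at least 3 populated annuli")
    return LinearFit.from_xy(profile["r_mid_um"], profile["force_proxy"])


def propulsive_stress(p: ModelParams, proxy: float | np.ndarray) -> float | np.ndarray:
    """Propulsive force per unit area (Pa): (phi n_c f_c / A_cc) * proxy."""
    proxy = np.asarray(proxy, dtype=float)
    if np.any(proxy < 0) or np.any(proxy > 1):
        raise ValueError("force proxy must lie in [0, 1]")
    out = (p.phi * p.n_c * p.f_c / p.A_cc) * proxy
    return out if out.ndim else float(out)


def friction_stress(
    p: ModelParams,
    V_SF: float | np.ndarray,
    nu_r: float | np.ndarray = 0.0,
    exact: bool = False,
) -> float | np.ndarray:
    """Resistive shear stress of the periciliary layer (Pa).

    Exact form: (1 - phi nu_r) eta_pc (V_SF + V_R) / e.  The default
    approximation drops the (1 - phi nu_r) factor, valid since
    phi nu_r << 1; the relative difference between the two is exactly
    phi nu_r.
    """
    V_SF = np.asarray(V_SF, dtype=float)
    if np.any(V_SF < 0):
        raise ValueError("V_SF must be >= 0")
    base = p.eta_pc * (V_SF + p.V_R) / p.e
    out = (1.0 - p.phi * np.asarray(nu_r, dtype=float)) * base if exact else base
    return out if np.ndim(out) else float(out)


def model_slope(p: ModelParams) -> float:
    """Predicted slope of V_SF versus the force proxy, in m/s:
    (e / eta_pc) * (phi n_c f_c / A_cc)."""
    return (p.e / p.eta_pc) * (p.phi * p.n_c * p.f_c / p.A_cc)


def steady_velocity(
    p: ModelParams, proxy: float | np.ndarray
) -> tuple[float | np.ndarray, bool | np.ndarray]:
    """Steady surface-fluid velocity (m/s) from the force balance.

    V_SF = model_slope * proxy - V_R, floored at 0.  The second return
    value flags proxies below the onset V_R / model_slope, where the
    propulsion cannot overcome the minimal friction and no flow results.
    """
    proxy = np.asarray(proxy, dtype=float)
    raw = model_slope(p) * proxy - p.V_R
    below = raw < 0
    v = np.where(below, 0.0, raw)
    if v.ndim:
        return v, below
    return float(v), bool(below)


def fit_velocity_force(profile: pd.DataFrame) -> tuple[LinearFit, float]:
    """OLS fit of the annular velocity V (um/s) against the force proxy.

    Returns the affine fit and ``V_R_inferred = -intercept`` (um/s), the
    recovery-stroke speed implied by the friction offset at zero force
    (meaningful when the intercept is negative; its standard error is
    ``fit.stderr_intercept``).
    """
    if "V_um_s" not in profile:
        raise ValueError("profile has no velocity column (attach_velocity first)")
    sub = profile.dropna(subset=["V_um_s", "force_proxy"])
    if len(sub) < 3:
        raise ValueError("need at least 3 annuli with both proxy and velocity")
    fit = LinearFit.from_xy(sub["force_proxy"], sub["V_um_s"])
    return fit, -fit.intercept


@dataclass
class PowerLawResult:
    exponent: float
    log10_prefactor: float
    r_squared: float
    stderr_exponent: float
    stderr_log10_prefactor: float


class PowerLawFit(BaseEstimator):
    """Power-law fit R = C * nu**m by OLS in log10-log10 space.

    Attributes: ``exponent_`` (the log-log slope m), ``log10_prefactor_``,
    ``r_squared_``, ``stderr_exponent_``, ``stderr_log10_prefactor_``.
    """

    def fit(self, nu: np.ndarray, R: np.ndarray) -> "PowerLawFit":
        nu = np.asarray(nu, dtype=float)
        R = np.asarray(R, dtype=float)
        if nu.size < 3:
            raise ValueError("need at least 3 (nu, R) pairs")
        if np.any(nu <= 0) or np.any(R <= 0):
            raise ValueError("nu and R must be strictly positive")
        lin = LinearFit.from_xy(np.log10(nu), np.log10(R))
        self.exponent_ = lin.slope
        self.log10_prefactor_ = lin.intercept
        self.r_squared_ = lin.r_squared
        self.stderr_exponent_ = lin.stderr_slope
        self.stderr_log10_prefactor_ = lin.stderr_intercept
        return self

    def predict(self, nu: np.ndarray) -> np.ndarray:
        return 10**self.log10_prefactor_ * np.asarray(nu, float) ** self.exponent_


def fit_power_law(data: pd.DataFrame) -> PowerLawResult:
    """Fit the swirl-size scaling law R ~ nu**m on a table with columns
    (nu, R_um).  If a ``chamber`` column is present, only the largest
    swirl of each chamber enters the fit (the quantity of interest is the
    maximal transport distance a given density sustains)."""
    if "chamber" in data:
        data = data.loc[data.groupby("chamber")["R_um"].idxmax()]
    est = PowerLawFit().fit(data["nu"].to_numpy(), data["R_um"].to_numpy())
    return PowerLawResult(
        est.exponent_,
        est.log10_prefactor_,
        est.r_squared_,
        est.stderr_exponent_,
        est.stderr_log10_prefactor_,
    )
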