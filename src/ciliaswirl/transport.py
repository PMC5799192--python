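"""Bead tracking, circular-motion fitting and transport statistics.

Mucus and surface-fluid velocities are measured by following tracer beads
(or mucus heterogeneities).  Trajectories are tables of (track_id, t_s,
x_um, y_um).  A swirl shows up as a family of concentric circular tracks;
fitting each track with a circle and an angular velocity, and comparing
the angular velocities across radii, tests whether the fluid rotates like
a rigid body (constant omega, curvilinear speed growing linearly with r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CircularFit",
    "CircleFit",
    "link_tracks",
    "fit_circle",
    "classify_trajectory",
    "rigid_body_test",
    "velocity_profile",
    "estimate_drift",
    "iter_tracks",
]

TRACK_COLUMNS = ["track_id", "t_s", "x_um", "y_um"]


def iter_tracks(trajs: pd.DataFrame):
    """Yield (track_id, sub-table sorted by time) pairs."""
    for tid, g in trajs.groupby("track_id", sort=True):
        yield tid, g.sort_values("t_s")


def link_tracks(detections: pd.DataFrame, max_disp: float) -> pd.DataFrame:
    """Greedy nearest-neighbour frame-to-frame linking.

    ``detections`` has columns (t, x, y) — or the canonical (t_s, x_um,
    y_um) — sorted by time.  Pairs between consecutive frames are linked
    in order of increasing distance, subject to the displacement gate
    ``max_disp``; unmatched detections start new tracks.  Intentionally
    minimal (no gap closing, no motion model): externally tracked CSV
    input is the first-class path for real data.
    """
    det = detections.rename(
        columns={"t": "t_s", "x": "x_um", "y": "y_um"}, errors="ignore"
    ).copy()
    times = det["t_s"].to_numpy()
    if np.any(np.diff(times) < 0):
        raise ValueError("detections must be sorted by time")
    det["track_id"] = -1
    next_id = 0
    frames = [g for _, g in det.groupby("t_s", sort=True)]
    prev_idx: list[int] = []
    for k, frame in enumerate(frames):
        idx = frame.index.to_numpy()
        if k == 0 or len(prev_idx) == 0:
            unmatched = list(idx)
        else:
            p = det.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            c = det.loc[idx, ["x_um", "y_um"]].to_numpy()
            d = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
            pairs = np.argwhere(d <= max_disp)
            order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
            used_p: set[int] = set()
            used_c: set[int] = set()
            for i, j in pairs[order]:
                if i in used_p or j in used_c:
                    continue
                det.loc[idx[j], "track_id"] = det.loc[prev_idx[i], "track_id"]
                used_p.add(i)
                used_c.add(j)
            unmatched = [idx[j] for j in range(len(idx)) if j not in used_c]
        for j in unmatched:
            det.loc[j, "track_id"] = next_id
            next_id += 1
        prev_idx = list(idx)
    return det[TRACK_COLUMNS]


@dataclass
class CircularFit:
    """Fitted circular motion of one track."""

    center: tuple[float, float]  # um
    radius: float  # um
    omega: float  # rad/s, signed (positive = angle increasing)
    rms_residual: float  # um, rms distance of samples to the circle
    sense: str  # "ccw" if omega > 0 (image coords, y down), else "cw"
    swept_angle: float  # rad, |total unwrapped angle|
    net_displacement: float  # um, first to last sample


class CircleFit(BaseEstimator):
    """Algebraic least-squares circle fit plus angular-velocity estimate.

    The centre and radius solve the Kasa linear system; the angular
    velocity is the OLS slope of the unwrapped polar angle about the
    fitted centre versus time — a direct test of "constant angular
    velocity", robust to sampling jitter.

    Attributes (after ``fit(t, xy)``)
    ---------------------------------
    center_, radius_, omega_, rms_residual_, sense_, swept_angle_.
    """

    def __init__(self) -> None:
        pass

    def fit(self, t: np.ndarray, xy: np.ndarray) -> "CircleFit":
        t = np.asarray(t, dtype=float)
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
            raise ValueError("need at least 3 (x, y) samples")
        x, y = xy[:, 0], xy[:, 1]
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        rhs = x**2 + y**2
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        cx, cy, c = sol
        r2 = c + cx**2 + cy**2
        if not np.isfinite(r2) or r2 <= 0 or np.linalg.matrix_rank(A) < 3:
            raise ValueError("degenerate geometry: points are collinear or coincident")
        radius = float(np.sqrt(r2))
        dist = np.hypot(x - cx, y - cy)
        angles = np.unwrap(np.arctan2(y - cy, x - cx))
        slope, intercept = np.polyfit(t, angles, 1) if len(t) > 1 else (0.0, angles[0])
        self.center_ = (float(cx), float(cy))
        self.radius_ = radius
        self.omega_ = float(slope)
        self.rms_residual_ = float(np.sqrt(np.mean((dist - radius) ** 2)))
        self.sense_ = "ccw" if slope >= 0 else "cw"
        self.swept_angle_ = float(abs(angles[-1] - angles[0]))
        self.net_displacement_ = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
        return self

    def result_(self) -> CircularFit:
        return CircularFit(
            self.center_,
            self.radius_,
            self.omega_,
            self.rms_residual_,
            self.sense_,
            self.swept_angle_,
            self.net_displacement_,
        )


def fit_circle(traj: pd.DataFrame) -> CircularFit:
    """Circle + angular-velocity fit of one trajectory table (t_s, x_um,
    y_um); see :class:`CircleFit`.  Collinear samples raise ValueError."""
    traj = traj.sort_values("t_s")
    t = traj["t_s"].to_numpy()
    xy = traj[["x_um", "y_um"]].to_numpy()
    # explicit collinearity check for a clear error message
    if xy.shape[0] >= 3:
        d = xy - xy.mean(axis=0)
        if np.linalg.matrix_rank(d, tol=1e-9 * max(1.0, np.abs(d).max())) < 2:
            raise ValueError("degenerate geometry: collinear points")
    return CircleFit().fit(t, xy).result_()


def classify_trajectory(
    traj: pd.DataFrame,
    fit: CircularFit | None = None,
    d_min: float = 2.0,
    rho_max: float = 0.15,
    theta_min: float = np.pi / 2,
) -> str:
    """Label a track ``immobile``, ``linear`` or ``circular``.

    Immobile: net displacement below ``d_min`` (um).  Circular: a circle
    fit exists with relative residual below ``rho_max`` and swept angle
    above ``theta_min``.  Everything else is linear (or pseudo-linear).
    """
    traj = traj.sort_values("t_s")
    xy = traj[["x_um", "y_um"]].to_numpy()
    net = float(np.hypot(*(xy[-1] - xy[0])))
    span = float(np.hypot(*(xy.max(axis=0) - xy.min(axis=0))))
    if max(net, span) < d_min:
        return "immobile"
    if fit is None:
        try:
            fit = fit_circle(traj)
        except ValueError:
            return "linear"
    if fit.rms_residual / fit.radius < rho_max and fit.swept_angle > theta_min:
        return "circular"
    return "linear"


def rigid_body_test(
    fits: list[CircularFit],
    center_tolerance: float = 50.0,
    cv_threshold: float = 0.1,
) -> tuple[float, float, bool]:
    """Do circular tracks at different radii share one angular velocity?

    Requires >= 3 fits whose centres agree within ``center_tolerance``
    (um); returns (mean omega, coefficient of variation of omega, pass).
    A rigidly rotating fluid gives CV ~ 0; differential rotation fails.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 circular fits")
    centers = np.array([f.center for f in fits])
    spread = np.linalg.norm(centers - centers.mean(axis=0), axis=1).max()
    if spread > center_tolerance:
        raise ValueError(
            f"fitted centres are dispersed by {spread:.1f} um "
            f"(tolerance {center_tolerance} um): not a single swirl"
        )
    omegas = np.array([f.omega for f in fits])
    mean = float(omegas.mean())
    if mean == 0:
        raise ValueError("mean angular velocity is zero")
    cv = float(omegas.std(ddof=0) / abs(mean))
    return mean, cv, cv < cv_threshold


def velocity_profile(
    trajs: pd.DataFrame,
    center: tuple[float, float],
    annulus_width: float = 20.0,
    r_max: float | None = None,
) -> pd.DataFrame:
    """Mean curvilinear speed per annulus about ``center``.

    Speeds are central-difference step speeds of each track; each speed
    sample is binned by the radial distance of its position.  Annuli with
    no samples are omitted (missing rows, not zeros).  Returns columns
    (r_mid_um, V_um_s, n_samples).
    """
    speeds: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    for _, g in iter_tracks(trajs):
        t = g["t_s"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        if len(t) < 2:
            continue
        v = np.gradient(xy, t, axis=0)
        speeds.append(np.linalg.norm(v, axis=1))
        radii.append(np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1]))
    if not speeds:
        return pd.DataFrame(columns=["r_mid_um", "V_um_s", "n_samples"])
    speed = np.concatenate(speeds)
    r = np.concatenate(radii)
    if r_max is None:
        r_max = float(r.max()) + 1e-9
    from .swirlforce import annulus_edges

    edges = annulus_edges(r_max, annulus_width)
    idx = np.digitize(r, edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        sel = idx == k
        if not sel.any():
            continue
        rows.append(
            {
                "r_mid_um": (edges[k] + edges[k + 1]) / 2,
                "V_um_s": float(speed[sel].mean()),
                "n_samples": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def estimate_drift(traj: pd.DataFrame) -> float:
    """Slow net drift speed of a track in um/h (net displacement over
    elapsed time)."""
    traj = traj.sort_values("t_s")
    if len(traj) < 2:
        raise ValueError("need at least 2 samples")
    dt = float(traj["t_s"].iloc[-1] - traj["t_s"].iloc[0])
    if dt <= 0:
        raise ValueError("elapsed time is zero")
    dx = float(traj["x_um"].iloc[-1] - traj["x_um"].iloc[0])
    dy = float(traj["y_um"].iloc[-1] - traj["y_um"].iloc[0])
    return float(np.hypot(dx, dy) / dt * 3600.0)
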