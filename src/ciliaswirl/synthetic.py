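"""Ground-truth-labelled synthetic data for the whole analysis chain.

The generators emulate the statistical structure of time-lapse recordings
of a beating bronchial epithelium and of the tracer-bead flows above it:

* :func:`generate_cilia_video` — textured tufts of cilia whose intensity
  oscillates at a per-tuft beat frequency, on a static noisy background;
* :func:`generate_swirl_tufts` — tuft positions and beat directions inside
  a circular domain ("swirl") where both the ciliated-area density and the
  tangential order of the beats increase with the distance to the centre;
* :func:`generate_bead_trajectories` — tracer beads advected by a rigid or
  differential rotation (or a uniform translation), with positional noise;
* :func:`generate_scaling_dataset` — (density, swirl radius) pairs that
  follow a power law with log-normal scatter over several decades.

They reproduce only the statistics the downstream analysis assumes; there
is no cilium mechanics or mucus rheology here.  Every generator is
deterministic under a fixed seed and returns its ground truth alongside
the data, so each downstream stage can be tested without any recording.

Angle conventions (fixed package-wide): radians, measured from the +x
axis, counterclockwise positive, in image coordinates (origin top-left,
y increasing downward).  A beat *direction* lives in [0, 2pi); a texture
*axis* (orientation) lives in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .video import VideoStack

__all__ = [
    "CiliaVideoSpec",
    "CiliaGroundTruth",
    "SwirlGroundTruth",
    "expected_sin_alpha",
    "generate_cilia_video",
    "generate_swirl_tufts",
    "generate_model_consistent_swirl",
    "generate_bead_trajectories",
    "generate_scaling_dataset",
]

#: Elongation (major/minor axis ratio) of rendered tufts along the beat axis.
TUFT_ELONGATION = 3.0


@dataclass
class CiliaVideoSpec:
    """Parameters of a synthetic ciliary-activity recording.

    Defaults mirror a typical high-speed acquisition: 250 fps for 3 s,
    beat frequencies between 10 and 30 Hz (well below the 125 Hz Nyquist
    limit).  ``tuft_coverage`` is the target areal fraction of the field
    occupied by oscillating tufts; ``amplitude / noise_sigma`` sets the
    signal-to-noise ratio of the oscillation.
    """

    height: int = 128
    width: int = 128
    fps: float = 250.0
    duration: float = 3.0
    pixel_size: float = 1.0  # um / pixel
    tuft_coverage: float = 0.2
    tuft_radius: float = 5.0  # um, radius of the equal-area circle
    freq_range: tuple[float, float] = (10.0, 30.0)
    freq_choices: tuple[float, ...] | None = None  # overrides freq_range if set
    orientation_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    amplitude: float = 1.0
    noise_sigma: float = 0.0
    background: float = 0.0
    texture_contrast: float = 0.15  # interior stripe contrast, keeps SNR near nominal
    stripe_period: float = 3.0  # px, stripes run parallel to the beat axis
    oscillation: str = "intensity"  # or "displacement"
    displacement_px: float = 1.0  # amplitude of the displacement mode
    avoid_overlap: bool = False  # reject placements overlapping earlier tufts
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.tuft_coverage <= 1.0:
            raise ValueError("tuft_coverage must lie in [0, 1]")
        lo, hi = self.freq_range
        if self.freq_choices is not None:
            lo, hi = min(self.freq_choices), max(self.freq_choices)
        if not 0.0 < lo <= hi:
            raise ValueError("freq_range must satisfy 0 < f_min <= f_max")
        if hi >= self.fps / 2.0:
            raise ValueError(
                f"beat frequency {hi} Hz is not below Nyquist {self.fps / 2} Hz"
            )
        if self.duration * self.fps < 2:
            raise ValueError("duration * fps must give at least 2 frames")
        if self.oscillation not in ("intensity", "displacement"):
            raise ValueError(f"unknown oscillation mode {self.oscillation!r}")


@dataclass
class CiliaGroundTruth:
    """Per-pixel ground truth accompanying a generated video."""

    tuft_mask: np.ndarray  # H x W bool
    freq_map: np.ndarray  # H x W float, NaN outside tufts
    orientation_map: np.ndarray  # H x W float in [0, pi), NaN outside tufts
    tufts: pd.DataFrame  # per-tuft x_um, y_um, beat_dir_rad, freq_hz, area_um2

    @property
    def coverage(self) -> float:
        return float(self.tuft_mask.mean())


def _tuft_membership(
    yy: np.ndarray, xx: np.ndarray, cx: float, cy: float, axis: float, radius_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean membership of an elongated elliptical tuft and the coordinate
    across its axis (used for the stripe texture)."""
    a = radius_px * np.sqrt(TUFT_ELONGATION)  # semi-major, along beat axis
    b = radius_px / np.sqrt(TUFT_ELONGATION)  # semi-minor
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(axis) + dy * np.sin(axis)
    v = -dx * np.sin(axis) + dy * np.cos(axis)
    member = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return member, v


def generate_cilia_video(spec: CiliaVideoSpec) -> tuple[VideoStack, CiliaGroundTruth]:
    """Render a synthetic video of locally oscillating ciliary tufts.

    Tufts are hard-edged ellipses (elongation 3 along the local beat axis)
    placed at random until the target areal coverage is reached.  Each
    tuft's intensity oscillates sinusoidally at a frequency drawn uniformly
    in ``freq_range``, with a low-contrast stripe texture perpendicular to
    the beat axis so the structure tensor has interior signal.  The rest of
    the field is static background plus i.i.d. Gaussian noise.

    Returns the stack together with the ground-truth tuft mask, frequency
    map and orientation map.  Fixed seed implies bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    n_frames = int(round(spec.duration * spec.fps))
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    amp_map = np.zeros((H, W))
    freq_map = np.full((H, W), np.nan)
    orient_map = np.full((H, W), np.nan)
    phase_map = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=bool)
    tuft_rows: list[dict] = []

    r_px = spec.tuft_radius / spec.pixel_size
    target_px = spec.tuft_coverage * H * W
    max_tufts = int(10 * target_px / max(np.pi * r_px**2, 1.0)) + 10

    # keep whole tufts inside the field so their shape (hence the ground-truth
    # orientation) is not truncated by the border
    margin = min(1.8 * r_px * np.sqrt(TUFT_ELONGATION), 0.4 * min(H, W))
    for _ in range(max_tufts):
        if mask.sum() >= target_px:
            break
        cx = rng.uniform(margin, W - margin)
        cy = rng.uniform(margin, H - margin)
        if spec.orientation_field is not None:
            direction = float(
                np.asarray(
                    spec.orientation_field(
                        np.array(cx * spec.pixel_size), np.array(cy * spec.pixel_size)
                    )
                )
            )
        else:
            direction = rng.uniform(0, 2 * np.pi)
        axis = direction % np.pi
        if spec.freq_choices is not None:
            freq = float(rng.choice(np.asarray(spec.freq_choices, dtype=float)))
        else:
            freq = rng.uniform(*spec.freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        member, v = _tuft_membership(yy, xx, cx, cy, axis, r_px)
        if not member.any():
            continue
        if spec.avoid_overlap:
            # test with an inflated footprint so neighbouring tufts keep a
            # clearance comparable to the orientation-analysis window
            inflated, _ = _tuft_membership(yy, xx, cx, cy, axis, 1.8 * r_px)
            if (inflated & mask).any():
                continue
        stripes = 1.0 + spec.texture_contrast * np.cos(2 * np.pi * v / spec.stripe_period)
        amp_map[member] = spec.amplitude * stripes[member]
        freq_map[member] = freq
        orient_map[member] = axis
        phase_map[member] = phase
        mask |= member
        tuft_rows.append(
            {
                "x_um": cx * spec.pixel_size,
                "y_um": cy * spec.pixel_size,
                "beat_dir_rad": direction % (2 * np.pi),
                "freq_hz": freq,
                "area_um2": float(member.sum()) * spec.pixel_size**2,
            }
        )

    t = np.arange(n_frames) / spec.fps
    frames = np.empty((n_frames, H, W), dtype=np.float32)
    if spec.oscillation == "intensity":
        # broadcast one frame at a time to keep the peak memory low
        f2pi = 2 * np.pi * np.nan_to_num(freq_map)
        for k in range(n_frames):
            frames[k] = spec.background + amp_map * np.sin(f2pi * t[k] + phase_map)
    else:
        # displacement mode: tuft support translates along the beat axis
        frames[:] = spec.background
        for k in range(n_frames):
            img = np.full((H, W), spec.background)
            for row in tuft_rows:
                d = row["beat_dir_rad"]
                s = spec.displacement_px * np.sin(2 * np.pi * row["freq_hz"] * t[k])
                member, v = _tuft_membership(
                    yy,
                    xx,
                    row["x_um"] / spec.pixel_size + s * np.cos(d),
                    row["y_um"] / spec.pixel_size + s * np.sin(d),
                    d % np.pi,
                    r_px,
                )
                stripes = 1.0 + spec.texture_contrast * np.cos(
                    2 * np.pi * v / spec.stripe_period
                )
                img[member] = spec.background + spec.amplitude * stripes[member]
            frames[k] = img
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape).astype(np.float32)

    columns = ["x_um", "y_um", "beat_dir_rad", "freq_hz", "area_um2"]
    tufts = pd.DataFrame(tuft_rows, columns=columns)
    truth = CiliaGroundTruth(mask, freq_map, orient_map, tufts)
    return VideoStack(frames, spec.fps, spec.pixel_size), truth


@dataclass
class SwirlGroundTruth:
    """Ground truth of a synthetic swirl.

    The areal density of ciliated tufts at radius r is ``a + b * r``
    (``density_intercept`` + ``density_slope`` * r), and beat directions
    scatter around the local tangential direction with a wrapped-normal
    dispersion of concentration ``tangential_concentration(r)`` (the
    wrapped-normal sigma is 1/sqrt(kappa); kappa = 0 means uniform).
    The sign of ``omega`` sets the sense of rotation.
    """

    center: tuple[float, float] = (0.0, 0.0)  # um
    radius: float = 300.0  # um
    density_intercept: float = 0.05
    density_slope: float = 1.5e-3  # fraction / um
    tangential_concentration: Callable[[np.ndarray], np.ndarray] = field(
        default=lambda r: 2.0 + 0.01 * np.asarray(r, dtype=float)
    )
    omega: float = 0.1  # rad/s, >0 counterclockwise in image coords

    def validate(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        r = np.linspace(0.0, self.radius, 256)
        cov = self.density_intercept + self.density_slope * r
        if cov.min() < 0 or cov.max() > 1:
            raise ValueError("density profile a + b*r must stay within [0, 1] on [0, R]")

    def coverage_at(self, r: np.ndarray | float) -> np.ndarray:
        return self.density_intercept + self.density_slope * np.asarray(r, dtype=float)


def expected_sin_alpha(kappa: np.ndarray | float) -> np.ndarray:
    """E[sin alpha] for beat directions scattered around the tangent with a
    wrapped-normal dispersion of concentration kappa.

    With alpha the angle to the outward radius, sin alpha = |cos eps| where
    eps ~ N(0, 1/kappa) wrapped; the expectation is evaluated numerically
    (kappa = 0 gives the uniform-angle value 2/pi).
    """
    from scipy.stats import norm

    kappa = np.asarray(kappa, dtype=float)
    flat = np.atleast_1d(kappa).astype(float)
    out = np.empty_like(flat)
    z = np.linspace(-8.0, 8.0, 8001)
    w = norm.pdf(z)
    for i, k in enumerate(flat):
        if k <= 0:
            out[i] = 2.0 / np.pi
        else:
            out[i] = np.trapezoid(np.abs(np.cos(z / np.sqrt(k))) * w, z)
    return out.reshape(kappa.shape) if kappa.ndim else float(out[0])


def generate_swirl_tufts(
    gt: SwirlGroundTruth, n_tufts: int, seed: int = 0
) -> pd.DataFrame:
    """Sample a tuft table (x_um, y_um, beat_dir_rad, area_um2) from a swirl.

    Radii are drawn from the density profile (pdf proportional to
    ``(a + b r) r``), angles uniformly; each tuft carries an equal area such
    that the expected areal coverage in an annulus at r equals ``a + b r``.
    Beat directions scatter around the local tangent (sense from the sign
    of omega) with wrapped-normal concentration ``kappa(r)``.
    """
    gt.validate()
    rng = np.random.default_rng(seed)
    a, b, R = gt.density_intercept, gt.density_slope, gt.radius

    r_grid = np.linspace(0.0, R, 4096)
    pdf = (a + b * r_grid) * r_grid
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(r_grid))])
    total_area = 2 * np.pi * cdf[-1]  # integral of (a+b r) 2 pi r dr
    cdf /= cdf[-1]
    r = np.interp(rng.uniform(size=n_tufts), cdf, r_grid)
    theta = rng.uniform(0, 2 * np.pi, size=n_tufts)

    tangent = theta + np.sign(gt.omega if gt.omega != 0 else 1.0) * np.pi / 2
    kappa = np.asarray(gt.tangential_concentration(r), dtype=float)
    if np.any(kappa < 0):
        raise ValueError("tangential_concentration must be >= 0")
    eps = np.where(
        kappa > 0,
        rng.standard_normal(n_tufts) / np.sqrt(np.maximum(kappa, 1e-300)),
        rng.uniform(-np.pi, np.pi, size=n_tufts),
    )
    beat = np.mod(tangent + eps, 2 * np.pi)

    area = total_area / n_tufts
    return pd.DataFrame(
        {
            "x_um": gt.center[0] + r * np.cos(theta),
            "y_um": gt.center[1] + r * np.sin(theta),
            "beat_dir_rad": beat,
            "area_um2": np.full(n_tufts, area),
        }
    )


def generate_model_consistent_swirl(
    gt: SwirlGroundTruth,
    slope_um_s: float,
    V_R_um_s: float,
    n_tufts: int = 100_000,
    n_beads: int = 300,
    dt: float = 0.5,
    T: float = 20.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Swirl tufts plus bead trajectories obeying the force balance.

    The beads are advected with the differential rotation whose curvilinear
    speed at radius r is ``slope_um_s * proxy(r) - V_R_um_s`` (floored at
    0), where ``proxy(r)`` is the *expected* force proxy of ``gt`` — the
    density profile times the expected tangential order.  Feeding the two
    tables through the annular-profile and velocity-profile analyses and
    regressing V on the proxy should recover ``slope_um_s`` and
    ``V_R_um_s``; choose ``gt`` so the proxy stays above the onset
    ``V_R / slope`` everywhere, otherwise inner annuli carry no flow.
    """
    gt.validate()

    def v_of_r(r: float) -> float:
        proxy = float(gt.coverage_at(r)) * float(
            expected_sin_alpha(float(np.asarray(gt.tangential_concentration(np.asarray(r, dtype=float)))))
        )
        return max(slope_um_s * proxy - V_R_um_s, 0.0)

    def omega_of_r(r: float) -> float:
        return np.sign(gt.omega) * v_of_r(r) / r if r > 0 else 0.0

    tufts = generate_swirl_tufts(gt, n_tufts, seed=seed)
    beads = generate_bead_trajectories(
        center=gt.center,
        omega=omega_of_r,
        n_beads=n_beads,
        dt=dt,
        T=T,
        noise_sigma=noise_sigma,
        seed=seed + 1,
        radii=(0.05 * gt.radius, gt.radius),
    )
    return tufts, beads


def generate_bead_trajectories(
    center: tuple[float, float] = (0.0, 0.0),
    omega: float | Callable[[np.ndarray], np.ndarray] = 0.1,
    n_beads: int = 50,
    dt: float = 0.1,
    T: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    radii: np.ndarray | tuple[float, float] | None = (10.0, 300.0),
    mode: str = "rotation",
    velocity: tuple[float, float] = (10.0, 0.0),
) -> pd.DataFrame:
    """Simulate tracer-bead trajectories (track_id, t_s, x_um, y_um).

    ``mode`` selects rigid/differential rotation about ``center`` (``omega``
    may be a constant in rad/s or a function of radius, enabling both
    rigid-body and sheared flows), a pure ``translation`` at ``velocity``
    (um/s), or ``immobile`` beads.  Isotropic Gaussian noise of scale
    ``noise_sigma`` (um) is added to every sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < 2 * dt:
        raise ValueError("T must cover at least two samples")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, T + dt / 2, dt)
    rows = []
    if radii is None:
        radii = (10.0, 300.0)
    if isinstance(radii, tuple) and len(radii) == 2:
        r0 = rng.uniform(radii[0], radii[1], size=n_beads)
    else:
        r0 = np.asarray(radii, dtype=float)
        n_beads = r0.size
    phi0 = rng.uniform(0, 2 * np.pi, size=n_beads)
    start = rng.uniform(-200, 200, size=(n_beads, 2))

    for i in range(n_beads):
        if mode == "rotation":
            w = float(omega(r0[i])) if callable(omega) else float(omega)
            phi = phi0[i] + w * t
            x = center[0] + r0[i] * np.cos(phi)
            y = center[1] + r0[i] * np.sin(phi)
        elif mode == "translation":
            x = start[i, 0] + velocity[0] * t
            y = start[i, 1] + velocity[1] * t
        elif mode == "immobile":
            x = np.full_like(t, start[i, 0])
            y = np.full_like(t, start[i, 1])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if noise_sigma > 0:
            x = x + rng.normal(0, noise_sigma, size=t.size)
            y = y + rng.normal(0, noise_sigma, size=t.size)
        rows.append(pd.DataFrame({"track_id": i, "t_s": t, "x_um": x, "y_um": y}))
    return pd.concat(rows, ignore_index=True)


def generate_scaling_dataset(
    prefactor: float = 3e4,
    exponent: float = 2.0,
    n: int = 30,
    log_noise_sigma: float = 0.15,
    nu_range: tuple[float, float] = (1e-3, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample (nu, R) pairs with R = prefactor * nu**exponent * 10**eps.

    nu is log-uniform over ``nu_range`` and eps ~ N(0, log_noise_sigma),
    emulating a power-law relation between active ciliated density and
    swirl radius holding over several decades.
    """
    lo, hi = nu_range
    if not 0 < lo <= hi <= 1:
        raise ValueError("nu_range must lie within (0, 1]")
    rng = np.random.default_rng(seed)
    nu = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    eps = rng.normal(0.0, log_noise_sigma, size=n) if log_noise_sigma > 0 else 0.0
    R = prefactor * nu**exponent * 10**eps
    return pd.DataFrame({"nu": nu, "R_um": R})
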