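"""Local beat-direction axes from the structure tensor.

In a standard-deviation projection of a high-speed recording, beating
ciliary tufts appear as elongated trails aligned with the beat axis.  The
structure tensor — the Gaussian-windowed outer product of the intensity
gradient — measures, at every pixel, the dominant local axis of intensity
variation and how anisotropic the neighbourhood is.  Because the trail
varies fastest *across* its length, the beat axis is the eigenvector of
the *smaller* eigenvalue; the coherency (l1-l2)/(l1+l2) in [0, 1] grades
how reliable the axis is (1: perfectly oriented texture, 0: isotropic).

An axis is defined modulo pi; turning it into a signed direction requires
observing the motion itself, which this module attempts by cross-
correlating frames along the axis and flags as ambiguous when the
displacement is below resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation
from sklearn.base import BaseEstimator

from .video import VideoStack
from .videoproc import std_projection, temporal_mean_subtract

__all__ = [
    "OrientationMap",
    "StructureTensorOrientation",
    "structure_tensor_orientation",
    "tuft_beat_directions",
    "circular_mean_axis",
]


@dataclass
class OrientationMap:
    """Per-pixel texture axis (radians in [0, pi)) and coherency in [0, 1]."""

    theta: np.ndarray
    coherency: np.ndarray


class StructureTensorOrientation(BaseEstimator):
    """Structure-tensor estimator of local orientation and coherency.

    Gradients are Gaussian derivatives at scale ``sigma_grad``; the tensor
    components <Ix^2>, <Ix Iy>, <Iy^2> are window-averaged with a Gaussian
    of scale ``sigma_window``.  Angles follow the package convention
    (radians from +x, counterclockwise positive, image coordinates with y
    down); ``theta_`` is the texture/trail axis in [0, pi).

    Attributes
    ----------
    theta_ : (H, W) float array — local axis, [0, pi).
    coherency_ : (H, W) float array — anisotropy in [0, 1], 0 where the
        tensor trace vanishes.
    """

    def __init__(self, sigma_grad: float = 1.0, sigma_window: float = 4.0) -> None:
        self.sigma_grad = sigma_grad
        self.sigma_window = sigma_window

    def fit(self, image: np.ndarray, y=None) -> "StructureTensorOrientation":
        image = np.asarray(image, dtype=float)
        if image.ndim != 2 or min(image.shape) < 3:
            raise ValueError("image must be 2D and at least 3x3")
        if not np.isfinite(image).all():
            raise ValueError("image contains non-finite pixels")
        if not (self.sigma_grad > 0 and self.sigma_window > 0):
            raise ValueError("sigmas must be positive")
        # axis 0 is y (rows), axis 1 is x (cols)
        Iy = gaussian_filter(image, self.sigma_grad, order=(1, 0), mode="nearest")
        Ix = gaussian_filter(image, self.sigma_grad, order=(0, 1), mode="nearest")
        w = dict(mode="nearest")
        Jxx = gaussian_filter(Ix * Ix, self.sigma_window, **w)
        Jxy = gaussian_filter(Ix * Iy, self.sigma_window, **w)
        Jyy = gaussian_filter(Iy * Iy, self.sigma_window, **w)
        # dominant gradient axis; the texture axis is its perpendicular
        theta_grad = 0.5 * np.arctan2(2 * Jxy, Jxx - Jyy)
        self.theta_ = np.mod(theta_grad + np.pi / 2, np.pi)
        trace = Jxx + Jyy
        split = np.sqrt((Jxx - Jyy) ** 2 + 4 * Jxy**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(trace > 0, split / trace, 0.0)
        self.coherency_ = np.clip(coh, 0.0, 1.0)
        return self

    def map_(self) -> OrientationMap:
        return OrientationMap(self.theta_, self.coherency_)


def structure_tensor_orientation(
    image: np.ndarray, sigma_grad: float = 1.0, sigma_window: float = 4.0
) -> OrientationMap:
    """Orientation/coherency map of an image (see
    :class:`StructureTensorOrientation`)."""
    est = StructureTensorOrientation(sigma_grad, sigma_window).fit(image)
    return est.map_()


def circular_mean_axis(theta: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of axial data (angles modulo pi).

    Computed on the doubled angle, hence independent of where individual
    angles were branch-cut.  Returns an angle in [0, pi).
    """
    theta = np.asarray(theta, dtype=float)
    if weights is None:
        weights = np.ones_like(theta)
    weights = np.asarray(weights, dtype=float)
    z = np.sum(weights * np.exp(2j * theta))
    if np.abs(z) <= 1e-12 * max(np.sum(np.abs(weights)), 1e-300):
        raise ValueError("axial data has no resultant (isotropic or empty)")
    return float(np.mod(np.angle(z) / 2.0, np.pi))


def _axis_displacement(video: VideoStack, bbox, axis: float) -> float:
    """Net image displacement (px) of a region along ``axis`` between the
    first and last frame, by phase correlation.  Positive along the axis
    direction; near zero for purely oscillatory motion."""
    y0, x0, y1, x1 = bbox
    a = np.asarray(video.frames[0, y0:y1, x0:x1], dtype=float)
    b = np.asarray(video.frames[-1, y0:y1, x0:x1], dtype=float)
    if min(a.shape) < 4 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    shift = phase_cross_correlation(a, b, upsample_factor=10)[0]
    dy, dx = -shift[0], -shift[1]  # displacement of content from frame 0 to -1
    return float(dx * np.cos(axis) + dy * np.sin(axis))


def tuft_beat_directions(
    video: VideoStack,
    tuft_mask: np.ndarray,
    omap: OrientationMap | None = None,
    coherency_floor: float = 0.2,
    min_displacement_px: float = 0.2,
    sigma_grad: float = 1.0,
    sigma_window: float = 4.0,
) -> pd.DataFrame:
    """Per-tuft beat axes from a mask of active regions.

    Each connected region of ``tuft_mask`` yields one record: centroid
    (um), area (um^2), and the coherency-weighted circular-mean axis of the
    orientation map (computed on the std-projection of ``video`` unless an
    ``omap`` is supplied).  Pixels below ``coherency_floor`` are excluded
    from the average.  The +-pi sign of the direction is resolved by
    frame correlation along the axis; records whose net displacement is
    below ``min_displacement_px`` are flagged ``ambiguous`` (their
    ``beat_dir_rad`` is the bare axis in [0, pi)) — they remain usable for
    any axis-based quantity such as sin(alpha).

    An empty mask returns an empty table.
    """
    tuft_mask = np.asarray(tuft_mask, dtype=bool)
    if omap is None:
        proj = std_projection(temporal_mean_subtract(video))
        omap = structure_tensor_orientation(proj, sigma_grad, sigma_window)
    ps = video.pixel_size
    rows = []
    for region in regionprops(label(tuft_mask)):
        yy, xx = region.coords[:, 0], region.coords[:, 1]
        theta = omap.theta[yy, xx]
        coh = omap.coherency[yy, xx]
        keep = coh >= coherency_floor
        if not keep.any():
            keep = slice(None)  # fall back to all pixels of the region
        try:
            axis = circular_mean_axis(theta[keep], coh[keep])
            # one trimming pass: drop the 20% of pixels deviating most from
            # the preliminary axis (robust to leakage from close neighbours)
            dev = np.abs(np.angle(np.exp(2j * (theta[keep] - axis)))) / 2
            good = dev <= np.percentile(dev, 80)
            axis = circular_mean_axis(theta[keep][good], coh[keep][good])
        except ValueError:
            continue
        disp = _axis_displacement(video, region.bbox, axis)
        ambiguous = abs(disp) < min_displacement_px
        direction = axis if ambiguous else (axis if disp > 0 else axis + np.pi)
        cy, cx = region.centroid
        rows.append(
            {
                "x_um": cx * ps,
                "y_um": cy * ps,
                "beat_dir_rad": float(np.mod(direction, 2 * np.pi)),
                "area_um2": region.area * ps**2,
                "coherency": float(np.mean(coh[keep])),
                "ambiguous": bool(ambiguous),
            }
        )
    columns = ["x_um", "y_um", "beat_dir_rad", "area_um2", "coherency", "ambiguous"]
    return pd.DataFrame(rows, columns=columns)
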