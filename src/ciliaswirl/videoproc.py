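"""Motion enhancement, projections, and the active ciliated density nu.

The active ciliated cell density nu is the fraction of the epithelial
surface covered by beating cilia.  It is measured on a high-speed
recording by (i) subtracting each pixel's temporal mean so only moving
structures remain, (ii) projecting the temporal standard deviation, and
(iii) thresholding the projection: pixels whose temporal activity clearly
exceeds the noise floor are counted as beating cilia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .video import VideoStack

__all__ = [
    "ActivityResult",
    "ActivityMasker",
    "temporal_mean_subtract",
    "std_projection",
    "activity_mask",
    "average_zones",
]


def temporal_mean_subtract(video: VideoStack) -> VideoStack:
    """Subtract each pixel's temporal mean from every frame.

    Enhances the visualisation of mobile cilia: static structures vanish,
    oscillating pixels keep their modulation.  The per-pixel temporal mean
    of the output is zero to floating tolerance.
    """
    v = video.astype_float()
    frames = v.frames - v.frames.mean(axis=0, keepdims=True)
    return VideoStack(frames, video.fps, video.pixel_size)


def std_projection(video: VideoStack) -> np.ndarray:
    """Temporal standard-deviation projection (population convention, ddof=0).

    Static pixels project to 0; oscillating or moving pixels project to the
    root-mean-square of their temporal fluctuation.
    """
    v = video.astype_float()
    return v.frames.std(axis=0, ddof=0)


@dataclass
class ActivityResult:
    """Binary activity mask plus the areal fraction nu it covers."""

    mask: np.ndarray
    nu: float
    threshold: float

    def __post_init__(self) -> None:
        expected = float(np.count_nonzero(self.mask)) / self.mask.size
        assert abs(self.nu - expected) < 1e-15


class ActivityMasker(BaseEstimator):
    """Estimator for the active-ciliated-area mask and density nu.

    Parameters
    ----------
    method : {"noise-referenced", "otsu"}
        "noise-referenced" (default) thresholds the std-projection at
        ``k`` times a robust per-pixel noise scale.  The noise scale is
        the median across pixels of the RMS spectral amplitude above
        ``noise_band_frac`` of the Nyquist frequency — a band where cilia
        do not beat, so it reflects sensor noise alone and stays valid at
        any active coverage (including a fully active field).
        "otsu" uses Otsu's threshold on the projection instead.
    k : float
        Multiplier on the noise scale (noise-referenced method only).
    noise_band_frac : float
        Lower edge of the noise-reference band, as a fraction of Nyquist.

    Attributes
    ----------
    mask_ : (H, W) bool array — pixels classified as beating cilia.
    nu_ : float — areal fraction of active pixels, in [0, 1].
    threshold_ : float — the threshold applied to the std-projection.
    """

    def __init__(
        self,
        method: str = "noise-referenced",
        k: float = 3.0,
        noise_band_frac: float = 0.7,
    ) -> None:
        self.method = method
        self.k = k
        self.noise_band_frac = noise_band_frac

    def fit(self, video: VideoStack, y=None) -> "ActivityMasker":
        proj = std_projection(video)
        if self.method == "noise-referenced":
            v = video.astype_float()
            x = v.frames - v.frames.mean(axis=0, keepdims=True)
            T = x.shape[0]
            power = np.abs(np.fft.rfft(x, axis=0)) ** 2 / T
            freqs = np.fft.rfftfreq(T, d=1.0 / video.fps)
            band = freqs >= self.noise_band_frac * (video.fps / 2.0)
            if not band.any():
                band = freqs == freqs.max()
            # white noise of variance s^2 has mean periodogram level s^2
            pixel_noise = np.sqrt(power[band].mean(axis=0))
            noise = float(np.median(pixel_noise))
            threshold = self.k * noise
        elif self.method == "otsu":
            if np.ptp(proj) == 0:
                threshold = float(proj.flat[0])
            else:
                threshold = float(threshold_otsu(proj))
        else:
            raise ValueError(f"unknown activity-mask method {self.method!r}")
        mask = proj > threshold
        self.projection_ = proj
        self.threshold_ = threshold
        self.mask_ = mask
        self.nu_ = float(np.count_nonzero(mask)) / mask.size
        return self

    def result_(self) -> ActivityResult:
        return ActivityResult(self.mask_, self.nu_, self.threshold_)


def activity_mask(video: VideoStack, method: str = "noise-referenced", **params) -> ActivityResult:
    """Threshold temporal activity and report the density nu (see
    :class:`ActivityMasker` for the method and parameters)."""
    return ActivityMasker(method=method, **params).fit(video).result_()


def average_zones(values) -> float:
    """Plain mean of per-zone measurements (e.g. nu over the three observed
    zones of each of three culture chambers)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no zone values to average")
    return float(values.mean())
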