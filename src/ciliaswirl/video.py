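"""Video-stack container and multi-page TIFF input/output.

A :class:`VideoStack` is the in-memory form of a time-lapse microscopy
acquisition: a ``T x H x W`` intensity array together with the frame rate
(Hz) and the pixel size (micrometres per pixel).  Every image operation in
this package consumes and produces this container.  On disk a stack is a
multi-page grayscale TIFF accompanied by a YAML sidecar carrying the
acquisition metadata, so that frame rate and calibration travel with the
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["VideoStack", "read_video", "write_video"]


@dataclass
class VideoStack:
    """A time-lapse intensity stack with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``.  Integer dtypes are accepted and
        promoted to float by the statistical operations.
    fps
        Frame rate in Hz, strictly positive.
    pixel_size
        Lateral calibration in micrometres per pixel, strictly positive.
    """

    frames: np.ndarray
    fps: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a video stack needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Record length in seconds (T / fps)."""
        return self.frames.shape[0] / self.fps

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.fps

    def astype_float(self) -> "VideoStack":
        """Return a float64 view/copy of the stack (metadata shared)."""
        if np.issubdtype(self.frames.dtype, np.floating):
            return self
        return VideoStack(self.frames.astype(np.float64), self.fps, self.pixel_size)


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".yaml")


def write_video(video: VideoStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar.

    Returns the sidecar path.  Float frames are written as 32-bit float
    TIFF; integer frames keep their dtype.
    """
    path = Path(path)
    frames = video.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = _sidecar_path(path)
    meta = {"fps": float(video.fps), "pixel_size_um": float(video.pixel_size)}
    sidecar.write_text(yaml.safe_dump(meta))
    return sidecar


def read_video(
    path: str | Path,
    fps: float | None = None,
    pixel_size: float | None = None,
) -> VideoStack:
    """Read a multi-page TIFF stack.

    ``fps`` and ``pixel_size`` default to the values in the YAML sidecar
    written by :func:`write_video`; explicit arguments override it.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if fps is None:
        fps = meta.get("fps")
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um", 1.0)
    if fps is None:
        raise ValueError(f"frame rate not given and no sidecar found for {path}")
    return VideoStack(frames, float(fps), float(pixel_size))
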