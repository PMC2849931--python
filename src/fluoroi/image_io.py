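"""Image stack I/O, registration, and reduction to 2D source images.

An :class:`ImageStack` holds a single-channel fluorescence time series as a
float array of shape ``(t, y, x)`` together with its physical pixel size and
frame interval.  All pixel coordinates elsewhere in the package follow the
``(x, y) = (column, row)`` convention with 0-based indices.

ROI detection operates on 2D "source images" derived from a stack: the
temporal mean (:func:`average_image`), the per-pixel temporal standard
deviation (:func:`sd_image`), or a stimulus-minus-rest difference
(:func:`response_image`).

Motion correction is rigid translation estimated by phase cross-correlation;
the estimator is pluggable so other engines can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "Image",
    "ImageStack",
    "load_stack",
    "save_stack",
    "save_image",
    "register_stack",
    "average_image",
    "sd_image",
    "response_image",
]


@dataclass
class ImageStack:
    """Single-channel fluorescence time series.

    Parameters
    ----------
    data
        Float array of shape ``(t, y, x)``; frames in acquisition order.
    pixel_size_xy
        Pixel edge length in µm (isotropic in x and y).
    frame_interval
        Time between consecutive frames in seconds.
    notes
        Free-text acquisition metadata (e.g. a TIFF header); stored
        verbatim and never parsed for scaling.
    """

    data: np.ndarray
    pixel_size_xy: float
    frame_interval: float
    notes: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack data must be 3D (t, y, x) with all dims >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.data.shape[1], self.data.shape[2]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


@dataclass
class Image:
    """A single 2D intensity image with physical pixel scaling."""

    data: np.ndarray
    pixel_size_xy: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("image data must be 2D (y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def load_stack(
    path: str | Path, pixel_size: float = 1.0, frame_interval: float = 1.0
) -> ImageStack:
    """Load a single- or multi-frame grayscale TIFF as an :class:`ImageStack`.

    Frames are returned in file order.  Any page-description header text is
    preserved verbatim in ``notes``.  Physical scaling always comes from the
    arguments, never from the header.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"frames of unequal size in {path}: {sorted(shapes)}")
        data = tif.asarray()
        descriptions = [p.description for p in pages if p.description]
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected single-channel 2D frames, got shape {data.shape}")
    notes = "\n".join(dict.fromkeys(descriptions))
    return ImageStack(
        data=data.astype(np.float64),
        pixel_size_xy=pixel_size,
        frame_interval=frame_interval,
        notes=notes,
    )


def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to a multi-frame 32-bit float TIFF."""
    tifffile.imwrite(Path(path), stack.data.astype(np.float32), photometric="minisblack")


def save_image(image: Image, path: str | Path) -> None:
    """Write a 2D image to a 32-bit float TIFF."""
    tifffile.imwrite(Path(path), image.data.astype(np.float32))


def _estimate_shift_phase(
    reference: np.ndarray, moving: np.ndarray, upsample_factor: int
) -> tuple[float, float]:
    """(dy, dx) shift that aligns ``moving`` to ``reference``."""
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    return float(shift[0]), float(shift[1])


def _translate(frame: np.ndarray, dy: float, dx: float, fill: float) -> np.ndarray:
    """Translate a frame by (dy, dx) pixels, filling exposed pixels."""
    if dy == int(dy) and dx == int(dx):
        iy, ix = int(dy), int(dx)
        out = np.full_like(frame, fill)
        h, w = frame.shape
        ys0, ys1 = max(0, iy), min(h, h + iy)
        xs0, xs1 = max(0, ix), min(w, w + ix)
        out[ys0:ys1, xs0:xs1] = frame[ys0 - iy : ys1 - iy, xs0 - ix : xs1 - ix]
        return out
    return ndi.shift(frame, (dy, dx), order=1, mode="constant", cval=fill)


def register_stack(
    stack: ImageStack,
    reference: int = 0,
    subpixel: bool = False,
    estimator: Callable[[np.ndarray, np.ndarray, int], tuple[float, float]] | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Rigidly register every frame to a reference frame.

    Each frame is translated to maximise similarity with the reference
    frame, estimated by phase cross-correlation (or a user-supplied
    ``estimator(reference, moving, upsample_factor) -> (dy, dx)``).
    Pixels shifted in from outside the frame are filled with the frame
    median, which is neutral for later averaging.

    Returns
    -------
    registered : ImageStack
        The translated stack.
    shifts : ndarray of shape (t, 2)
        Applied correction per frame as ``(dx, dy)`` in pixels.
    """
    if not 0 <= reference < stack.n_frames:
        raise ValueError(f"reference frame {reference} out of range")
    estimate = estimator or _estimate_shift_phase
    upsample = 10 if subpixel else 1
    ref = stack.data[reference]
    featureless_ref = float(np.std(ref)) == 0.0

    out = np.empty_like(stack.data)
    shifts = np.zeros((stack.n_frames, 2), dtype=float)
    for t in range(stack.n_frames):
        frame = stack.data[t]
        if featureless_ref or float(np.std(frame)) == 0.0:
            warnings.warn(
                f"frame {t}: no structure to register against; shift set to (0, 0)",
                stacklevel=2,
            )
            out[t] = frame
            continue
        dy, dx = estimate(ref, frame, upsample)
        shifts[t] = (dx, dy)
        out[t] = _translate(frame, dy, dx, fill=float(np.median(frame)))
    registered = replace(stack, data=out)
    return registered, shifts


def _as_frame_indices(frames, n_frames: int) -> np.ndarray:
    idx = np.arange(n_frames)[frames] if isinstance(frames, slice) else np.asarray(frames)
    idx = np.atleast_1d(idx)
    if idx.size == 0:
        raise ValueError("empty frame selection")
    if idx.min() < -n_frames or idx.max() >= n_frames:
        raise ValueError("frame selection out of bounds")
    return idx % n_frames


def average_image(stack: ImageStack, frames: slice | Sequence[int] | None = None) -> Image:
    """Pixel-wise mean over the selected frames (all frames by default)."""
    if frames is None:
        frames = slice(None)
    idx = _as_frame_indices(frames, stack.n_frames)
    return Image(stack.data[idx].mean(axis=0), stack.pixel_size_xy)


def sd_image(stack: ImageStack) -> Image:
    """Per-pixel standard deviation over time (population SD, ddof=0)."""
    if stack.n_frames < 2:
        raise ValueError("sd_image requires at least 2 frames")
    return Image(stack.data.std(axis=0), stack.pixel_size_xy)


def response_image(
    stack: ImageStack,
    rest_frames: slice | Sequence[int],
    stim_frames: slice | Sequence[int],
) -> Image:
    """Mean of stimulus frames minus mean of rest frames, pixel-wise.

    The result may be negative (units dimming during the stimulus).
    """
    rest = _as_frame_indices(rest_frames, stack.n_frames)
    stim = _as_frame_indices(stim_frames, stack.n_frames)
    if np.intersect1d(rest, stim).size:
        raise ValueError("rest and stimulus frame sets must be disjoint")
    return Image(
        stack.data[stim].mean(axis=0) - stack.data[rest].mean(axis=0),
        stack.pixel_size_xy,
    )
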