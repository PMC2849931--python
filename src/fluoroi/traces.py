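"""Per-ROI time-series extraction, background correction, and ΔF/F.

Background is a per-frame scalar: the mean over a user-specified region
devoid of reporter, subtracted from every pixel of that frame.  The ΔF/F
baseline F0 of a trace is the centre of the modal bin of a histogram of all
its values with ``ceil(1 + log2 N)`` bins — a mode estimate that is robust
to spontaneous transients as long as the unit spends most of the recording
at rest (it will overestimate F0 when the activity duty cycle exceeds 50%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fluoroi.image_io import ImageStack
from fluoroi.roi_detect import ROIMask

__all__ = [
    "TraceMatrix",
    "BaselineEstimate",
    "subtract_background",
    "extract_traces",
    "baseline_f0",
    "dff",
    "traces_to_csv",
    "traces_from_csv",
]

_STAGES = ("raw", "background_corrected", "dff")


@dataclass
class TraceMatrix:
    """Per-ROI mean-fluorescence time series, one row per ROI.

    ``stage`` records the processing state and may only advance
    raw → background_corrected → dff.
    """

    values: np.ndarray
    roi_ids: list[int]
    frame_interval: float
    stage: str = "raw"
    f0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape[0] != len(self.roi_ids):
            raise ValueError("row count must equal number of ROI ids")
        if self.stage != "dff" and not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class BaselineEstimate:
    """Histogram-mode baseline F0 for one trace."""

    f0: float
    n_bins: int
    bin_width: float

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.bin_width < 0:
            raise ValueError("invalid baseline estimate")


def _region_mask(bg_region, frame_shape: tuple[int, int]) -> np.ndarray:
    region = np.asarray(bg_region)
    if region.dtype == bool:
        if region.shape != frame_shape:
            raise ValueError("background mask shape must match the frames")
        mask = region
    else:
        # N×2 list of (x, y) pixel coordinates
        if region.ndim != 2 or region.shape[1] != 2:
            raise ValueError("background region must be a boolean mask or N×2 (x, y) list")
        xs, ys = region[:, 0].astype(int), region[:, 1].astype(int)
        h, w = frame_shape
        if xs.min() < 0 or ys.min() < 0 or xs.max() >= w or ys.max() >= h:
            raise ValueError("background pixels outside the frame")
        mask = np.zeros(frame_shape, dtype=bool)
        mask[ys, xs] = True
    if not mask.any():
        raise ValueError("background region is empty")
    return mask


def subtract_background(
    stack: ImageStack, bg_region: np.ndarray
) -> tuple[ImageStack, np.ndarray]:
    """Subtract the per-frame mean of a background region from every pixel.

    ``bg_region`` is either a boolean image of frame shape or an N×2 array
    of (x, y) pixel coordinates; it must be chosen by the user on an area
    devoid of reporter (never auto-detected).  Returns the corrected stack
    and the per-frame scalars for audit.
    """
    mask = _region_mask(bg_region, stack.frame_shape)
    offsets = stack.data[:, mask].mean(axis=1)
    from dataclasses import replace

    corrected = replace(stack, data=stack.data - offsets[:, None, None])
    return corrected, offsets


def extract_traces(stack: ImageStack, mask: ROIMask, stage: str = "raw") -> TraceMatrix:
    """Average intensity over each ROI at each time point.

    Row *n* of the result is the mean over pixels labelled −*n*, in ROI-id
    order.  A mask with zero ROIs yields an empty matrix.
    """
    if mask.labels.shape != stack.frame_shape:
        raise ValueError("mask shape does not match the stack frames")
    n = mask.n_rois
    values = np.empty((n, stack.n_frames))
    for i in range(n):
        values[i] = stack.data[:, mask.labels == -(i + 1)].mean(axis=1)
    return TraceMatrix(
        values=values.reshape(n, stack.n_frames),
        roi_ids=list(range(1, n + 1)),
        frame_interval=stack.frame_interval,
        stage=stage,
    )


def baseline_f0(trace: np.ndarray) -> BaselineEstimate:
    """Baseline as the bin centre of the modal histogram bin of a trace.

    The histogram spans [min, max] of the trace with ``ceil(1 + log2 N)``
    bins; modal ties break toward the lower-valued bin.  A constant trace
    yields F0 equal to that constant with a single degenerate bin.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    n = trace.size
    if n < 2:
        raise ValueError("trace must have at least 2 points")
    lo, hi = float(trace.min()), float(trace.max())
    if hi == lo:
        return BaselineEstimate(f0=lo, n_bins=1, bin_width=0.0)
    n_bins = math.ceil(1 + math.log2(n))
    counts, edges = np.histogram(trace, bins=n_bins, range=(lo, hi))
    mode = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    width = edges[1] - edges[0]
    return BaselineEstimate(f0=float(edges[mode] + width / 2), n_bins=n_bins, bin_width=float(width))


def dff(traces: TraceMatrix) -> TraceMatrix:
    """Normalise background-corrected traces to ΔF/F = (F − F0)/F0 per row.

    Rows whose F0 is zero cannot be normalised; they are set to NaN with a
    warning while the remaining rows proceed.
    """
    if traces.stage != "background_corrected":
        raise ValueError("dff requires background-corrected traces")
    f0 = np.array([baseline_f0(row).f0 for row in traces.values])
    out = np.empty_like(traces.values)
    for i, (row, b) in enumerate(zip(traces.values, f0)):
        if b == 0:
            warnings.warn(
                f"ROI {traces.roi_ids[i]}: baseline F0 = 0, ΔF/F undefined", stacklevel=2
            )
            out[i] = np.nan
        else:
            out[i] = (row - b) / b
    return TraceMatrix(
        values=out,
        roi_ids=list(traces.roi_ids),
        frame_interval=traces.frame_interval,
        stage="dff",
        f0=f0,
    )


def traces_to_csv(traces: TraceMatrix, path: str | Path) -> None:
    """Write traces as CSV with a time column and one column per ROI."""
    df = pd.DataFrame(
        traces.values.T, columns=[f"roi_{i}" for i in traces.roi_ids]
    )
    df.insert(0, "time_s", traces.times)
    df.to_csv(Path(path), index=False)


def traces_from_csv(path: str | Path, stage: str = "raw") -> TraceMatrix:
    df = pd.read_csv(Path(path))
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    times = df["time_s"].to_numpy()
    interval = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return TraceMatrix(
        values=df[roi_cols].to_numpy().T,
        roi_ids=[int(c.split("_")[1]) for c in roi_cols],
        frame_interval=interval,
        stage=stage,
    )
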