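"""Relative depth of ROIs within a layered structure, and polarity calls.

In laminated tissue such as the retinal inner plexiform layer (IPL), the
functional identity of a synaptic terminal correlates with its depth.  Two
user-drawn open contours bound the layer: C0 (0%, e.g. the ganglion-cell
side) and C100 (100%, the photoreceptor side).  After arc-length
resampling to a common dense point count (typically 8× the pixels per
line), LOWESS smoothing, and orientation matching, 99 intermediate
isocontours are interpolated point-wise,

    Ci[j] = (i·C100[j] + (100−i)·C0[j]) / 100,   i = 1…99,

plus two extrapolated contours at −1% and 101% (same formula) so that
terminals just outside the borders are binned into the respective group —
103 contours in all.  Each ROI's brightness-weighted centre of mass is
assigned the index of the nearest isocontour as its relative depth.

Response polarity (ON: calcium rises during a light stimulus; OFF: falls
during and/or rebounds immediately after it) is called from ΔF/F windows
with a z-score gate to make the sign decision deterministic on noisy
traces.  Depth histograms split by polarity give position–function maps.

Positions are meaningful only if the optical section cuts the layer
orthogonally; the tool computes them regardless and leaves that judgement
to the experimenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from fluoroi.image_io import Image
from fluoroi.roi_detect import ROIMask

__all__ = [
    "Contour",
    "IsocontourFamily",
    "CentreOfMass",
    "PolarityCall",
    "ISO_INDICES",
    "resample_contour",
    "smooth_contour",
    "orient_contours",
    "isocontour_family",
    "centre_of_mass",
    "assign_positions",
    "classify_polarity",
    "position_histogram",
    "contour_to_csv",
    "contour_from_csv",
]

#: ordered isocontour indices: −1, 0…100, 101 (103 contours)
ISO_INDICES = tuple(range(-1, 102))


@dataclass
class Contour:
    """Open polyline of (x, y) pixel coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] < 2:
            raise ValueError("contour needs an N×2 array with N >= 2")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("contour coordinates must be finite")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive contour points must be distinct")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def reversed(self) -> "Contour":
        return Contour(self.points[::-1].copy())


@dataclass
class IsocontourFamily:
    """103 polylines at indices −1…101, all sharing the same point count."""

    contours: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if sorted(self.contours) != list(ISO_INDICES):
            raise ValueError("family must hold exactly the indices -1…101")
        counts = {c.shape[0] for c in self.contours.values()}
        if len(counts) != 1:
            raise ValueError("all isocontours must share the same point count")

    @property
    def points_per_contour(self) -> int:
        return self.contours[0].shape[0]

    def contour(self, i: int) -> np.ndarray:
        return self.contours[i]


@dataclass
class CentreOfMass:
    """Brightness-weighted mean pixel position of one ROI."""

    roi_id: int
    position: tuple[float, float]  # (x, y)
    total_mass: float


@dataclass
class PolarityCall:
    roi_id: int
    polarity: str  # ON | OFF | NONRESPONSIVE
    stim_score: float
    post_score: float


def resample_contour(contour: Contour, m: int) -> Contour:
    """Resample to ``m`` points uniformly spaced by arc length.

    Endpoints are preserved.  The conventional density is 8× the number of
    pixels per image line, making vertex spacing ≪ 1 px.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    s = contour.arc_length()
    if s[-1] == 0:
        raise ValueError("degenerate zero-length contour")
    target = np.linspace(0.0, s[-1], m)
    pts = np.column_stack(
        [np.interp(target, s, contour.points[:, 0]), np.interp(target, s, contour.points[:, 1])]
    )
    return Contour(pts)


def smooth_contour(contour: Contour, span: float = 0.1) -> Contour:
    """Smooth a contour by locally weighted linear regression (LOWESS).

    Each coordinate is regressed against the arc-length parameter with a
    window covering ``span`` of the contour.  A span covering fewer than 3
    points returns the input unchanged with a warning.  Straight lines are
    invariant (local linear fits reproduce them).
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    n = contour.n_points
    if span * n < 3:
        warnings.warn("smoothing window covers < 3 points; contour returned unchanged",
                      stacklevel=2)
        return contour
    s = contour.arc_length()
    x = lowess(contour.points[:, 0], s, frac=span, it=0, return_sorted=False)
    y = lowess(contour.points[:, 1], s, frac=span, it=0, return_sorted=False)
    return Contour(np.column_stack([x, y]))


def orient_contours(c0: Contour, c100: Contour) -> tuple[Contour, Contour]:
    """Reverse ``c100`` if that pairs its endpoints with ``c0``'s.

    Point-wise interpolation presumes index-wise correspondence; if the
    second border was drawn in the opposite direction, index pairs would
    cross the layer diagonally.
    """
    if c0.n_points != c100.n_points:
        raise ValueError("contours must be resampled to the same point count first")
    d_same = np.linalg.norm(c0.points[0] - c100.points[0]) + np.linalg.norm(
        c0.points[-1] - c100.points[-1]
    )
    d_rev = np.linalg.norm(c0.points[0] - c100.points[-1]) + np.linalg.norm(
        c0.points[-1] - c100.points[0]
    )
    if d_rev < d_same:
        return c0, c100.reversed()
    return c0, c100


def isocontour_family(c0: Contour, c100: Contour) -> IsocontourFamily:
    """Interpolate 99 isocontours between two borders, plus −1% and 101%.

    Contours must already be resampled to a common point count, smoothed,
    and oriented.  Index 0 reproduces C0 exactly and index 100 C100.
    """
    if c0.n_points != c100.n_points:
        raise ValueError("borders must share the same number of points")
    a, b = c0.points, c100.points
    contours = {i: (i * b + (100 - i) * a) / 100.0 for i in ISO_INDICES}
    contours[0] = a.copy()  # keep the borders bit-exact
    contours[100] = b.copy()
    return IsocontourFamily(contours)


def centre_of_mass(mask: ROIMask, weights: Image | np.ndarray, roi_id: int) -> CentreOfMass:
    """Brightness-weighted centre of mass R = Σ(rᵢ·mᵢ)/Σmᵢ of one ROI.

    ``weights`` should be the same source image used for detection
    (average, SD, or response image).  Negative weights are clipped to
    zero with a warning; if the total mass is zero the unweighted centroid
    is returned instead.
    """
    w = weights.data if isinstance(weights, Image) else np.asarray(weights, dtype=float)
    if w.shape != mask.labels.shape:
        raise ValueError("weight image shape does not match the mask")
    inside = mask.pixels(roi_id)
    ys, xs = np.nonzero(inside)
    m = w[ys, xs]
    if np.any(m < 0):
        warnings.warn(f"ROI {roi_id}: negative weights clipped to zero", stacklevel=2)
        m = np.clip(m, 0, None)
    total = float(m.sum())
    if total <= 0:
        warnings.warn(f"ROI {roi_id}: zero total mass; using unweighted centroid",
                      stacklevel=2)
        return CentreOfMass(roi_id, (float(xs.mean()), float(ys.mean())), 0.0)
    return CentreOfMass(
        roi_id,
        (float((xs * m).sum() / total), float((ys * m).sum() / total)),
        total,
    )


def assign_positions(
    family: IsocontourFamily, centres: list[CentreOfMass]
) -> pd.DataFrame:
    """Relative depth of each centre of mass: index of the nearest isocontour.

    Distance is the minimum Euclidean distance to any contour vertex (the
    dense resampling makes vertex spacing ≪ 1 px, so segment projection is
    unnecessary).  Ties break toward the lower index.  Returns a table
    with columns roi_id, depth_percent, distance_px.
    """
    if not centres:
        raise ValueError("no centres of mass supplied")
    stackd = np.stack([family.contour(i) for i in ISO_INDICES])  # (103, M, 2)
    rows = []
    for c in centres:
        p = np.asarray(c.position)
        dmin = np.sqrt(((stackd - p) ** 2).sum(axis=2)).min(axis=1)  # per contour
        best = int(np.argmin(dmin))  # first minimum = lowest index
        rows.append(
            {
                "roi_id": c.roi_id,
                "depth_percent": ISO_INDICES[best],
                "distance_px": float(dmin[best]),
            }
        )
    return pd.DataFrame(rows, columns=["roi_id", "depth_percent", "distance_px"])


def _window_indices(window, n: int) -> np.ndarray:
    idx = np.arange(n)[window] if isinstance(window, slice) else np.asarray(window)
    idx = np.atleast_1d(idx)
    if idx.size == 0:
        raise ValueError("empty window")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("window out of trace bounds")
    return idx


def classify_polarity(
    dff_trace: np.ndarray,
    pre_window,
    stim_window,
    post_window,
    z_threshold: float = 3.0,
    roi_id: int = 0,
) -> PolarityCall:
    """Call ON / OFF / NONRESPONSIVE from ΔF/F stimulus windows.

    ``stim_score`` is the mean ΔF/F change during the stimulus relative to
    the pre-stimulus window, in units of the pre-stimulus SD; ``post_score``
    likewise for the post-stimulus window.  ON: stim_score ≥ z; OFF:
    stim_score ≤ −z, or a post-stimulus rebound (post_score ≥ z) without an
    ON response; otherwise NONRESPONSIVE.
    """
    trace = np.asarray(dff_trace, dtype=float).ravel()
    pre = _window_indices(pre_window, trace.size)
    stim = _window_indices(stim_window, trace.size)
    post = _window_indices(post_window, trace.size)
    if pre.size < 3:
        raise ValueError("pre-stimulus window must cover at least 3 frames")
    for a, b in ((pre, stim), (pre, post), (stim, post)):
        if np.intersect1d(a, b).size:
            raise ValueError("polarity windows must be disjoint")
    sd = float(trace[pre].std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        warnings.warn(f"ROI {roi_id}: pre-stimulus SD is 0; NONRESPONSIVE", stacklevel=2)
        return PolarityCall(roi_id, "NONRESPONSIVE", 0.0, 0.0)
    base = float(trace[pre].mean())
    stim_score = (float(trace[stim].mean()) - base) / sd
    post_score = (float(trace[post].mean()) - base) / sd
    if stim_score >= z_threshold:
        polarity = "ON"
    elif stim_score <= -z_threshold or post_score >= z_threshold:
        polarity = "OFF"
    else:
        polarity = "NONRESPONSIVE"
    return PolarityCall(roi_id, polarity, stim_score, post_score)


def position_histogram(
    table: pd.DataFrame,
    calls: list[PolarityCall] | None = None,
    polarity: str = "ALL",
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Histogram of depths, optionally restricted to one polarity class.

    Returns a table (bin_low, bin_high, count) whose counts sum to the
    number of ROIs of the requested class.
    """
    depths = table.set_index("roi_id")["depth_percent"]
    if polarity != "ALL":
        if calls is None:
            raise ValueError("polarity filtering requires polarity calls")
        keep = [c.roi_id for c in calls if c.polarity == polarity]
        depths = depths.loc[depths.index.intersection(keep)]
    edges = np.arange(-bin_width, 100 + 2 * bin_width, bin_width)
    counts, _ = np.histogram(depths.to_numpy(), bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def contour_to_csv(contour: Contour, path: str | Path) -> None:
    pd.DataFrame(contour.points, columns=["x", "y"]).to_csv(Path(path), index=False)


def contour_from_csv(path: str | Path) -> Contour:
    df = pd.read_csv(Path(path))
    return Contour(df[["x", "y"]].to_numpy())
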