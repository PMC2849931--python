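"""Group ROI traces with similar dynamics by single-linkage clustering.

Traces are compared pairwise under one of five metrics — Pearson
(1 − Pearson's r), Euclidean, normalised Euclidean, Manhattan, or
Chebychev — and clustered by cutting the single-linkage hierarchy at a
cutoff expressed as a percentage of the largest pairwise distance
(typically 25–30%).  Cutting single linkage at a height is equivalent to
taking connected components of the graph whose edges are pairs with
distance strictly below the cutoff, which is how it is computed here.
Singletons are reported as unclustered: a one-member cluster is not a
grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from fluoroi.traces import TraceMatrix

__all__ = [
    "METRICS",
    "UNCLUSTERED",
    "DistanceMatrix",
    "ClusterAssignment",
    "pairwise_distance",
    "cluster",
    "cluster_means",
]

METRICS = ("pearson", "euclidean", "normalized_euclidean", "manhattan", "chebychev")

#: cluster label given to traces that belong to no cluster of size >= 2
UNCLUSTERED = 0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise trace-distance matrix.

    Rows/columns follow trace order.  Entries involving traces for which
    the metric is undefined (constant traces under correlation-based
    metrics) are NaN and ``valid`` is False for those traces.
    """

    d: np.ndarray
    metric: str
    valid: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class ClusterAssignment:
    """Per-trace cluster labels: ids 1…n_clusters, or UNCLUSTERED (0)."""

    labels: np.ndarray
    cutoff_fraction: float
    cutoff_value: float
    n_clusters: int

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def _as_rows(traces: TraceMatrix | np.ndarray) -> np.ndarray:
    x = traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces, dtype=float)
    x = np.atleast_2d(x)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 traces")
    return x


def pairwise_distance(traces: TraceMatrix | np.ndarray, metric: str = "pearson") -> DistanceMatrix:
    """Pairwise distance matrix under the named metric.

    The Pearson distance is 1 − r, so 0 means perfect correlation and 2
    perfect anticorrelation.  "Normalised Euclidean" is Euclidean distance
    between traces individually standardised to zero mean and unit
    variance.  Constant traces are undefined under both (zero variance):
    their rows/columns are NaN, flagged invalid, and excluded from
    clustering.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = _as_rows(traces)
    n = x.shape[0]
    valid = np.ones(n, dtype=bool)

    if metric in ("pearson", "normalized_euclidean"):
        sd = x.std(axis=1)
        valid = sd > 0
        if not valid.all():
            warnings.warn(
                f"{np.count_nonzero(~valid)} constant trace(s): {metric} distance "
                "undefined; excluded from clustering",
                stacklevel=2,
            )
    if metric == "pearson":
        d = np.full((n, n), np.nan)
        if valid.any():
            r = np.corrcoef(x[valid])
            sub = np.clip(1.0 - np.atleast_2d(r), 0.0, 2.0)
            np.fill_diagonal(sub, 0.0)  # self-distance is identically 0
            d[np.ix_(valid, valid)] = sub
    elif metric == "normalized_euclidean":
        d = np.full((n, n), np.nan)
        if valid.any():
            z = (x[valid] - x[valid].mean(axis=1, keepdims=True)) / x[valid].std(
                axis=1, keepdims=True
            )
            d[np.ix_(valid, valid)] = squareform(pdist(z, metric="euclidean"))
    else:
        scipy_name = {"euclidean": "euclidean", "manhattan": "cityblock", "chebychev": "chebyshev"}
        d = squareform(pdist(x, metric=scipy_name[metric]))
    return DistanceMatrix(d=d, metric=metric, valid=valid)


def cluster(dist: DistanceMatrix, cutoff_fraction: float = 25.0) -> ClusterAssignment:
    """Flat single-linkage clustering at a cutoff.

    ``cutoff_value = (cutoff_fraction / 100) × max(d)``; two traces join a
    cluster if connected by a chain of pairs each strictly closer than the
    cutoff (connected components of the sub-cutoff graph).  Components of
    size 1 become UNCLUSTERED.  A degenerate all-zero matrix (all traces
    identical) yields one cluster containing every valid trace.
    """
    if not 0 < cutoff_fraction < 100:
        raise ValueError("cutoff_fraction must lie in (0, 100)")
    n = dist.n
    valid = np.flatnonzero(dist.valid)
    labels = np.full(n, UNCLUSTERED, dtype=int)
    if valid.size == 0:
        return ClusterAssignment(labels, cutoff_fraction, 0.0, 0)

    sub = dist.d[np.ix_(valid, valid)]
    off = ~np.eye(valid.size, dtype=bool)
    dmax = float(sub[off].max()) if valid.size > 1 else 0.0
    cutoff_value = (cutoff_fraction / 100.0) * dmax
    if dmax == 0.0:
        # all valid traces identical: a single cluster
        if valid.size >= 2:
            labels[valid] = 1
            return ClusterAssignment(labels, cutoff_fraction, 0.0, 1)
        return ClusterAssignment(labels, cutoff_fraction, 0.0, 0)

    adjacency = csr_matrix((sub < cutoff_value) & off)
    n_comp, comp = connected_components(adjacency, directed=False)
    next_id = 1
    for c in range(n_comp):
        members = valid[comp == c]
        if members.size >= 2:
            labels[members] = next_id
            next_id += 1
    # renumber in order of first member index for determinism
    order = sorted(range(1, next_id), key=lambda cid: int(np.flatnonzero(labels == cid)[0]))
    remap = {cid: i + 1 for i, cid in enumerate(order)}
    labels = np.array([remap.get(l, UNCLUSTERED) for l in labels])
    return ClusterAssignment(labels, cutoff_fraction, cutoff_value, len(order))


def cluster_means(
    traces: TraceMatrix | np.ndarray, assignment: ClusterAssignment
) -> dict[int, dict]:
    """Arithmetic mean trace and member list per cluster."""
    x = np.atleast_2d(traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces))
    if x.shape[0] != assignment.labels.size:
        raise ValueError("assignment does not match the trace matrix")
    out: dict[int, dict] = {}
    for cid in range(1, assignment.n_clusters + 1):
        members = assignment.members(cid)
        out[cid] = {"members": members.tolist(), "mean": x[members].mean(axis=0)}
    return out
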