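"""Flat-file results store and per-experiment synopsis reports.

Per-ROI results from many experiments accumulate in a single plain-text
CSV table (one header line, one row per terminal) keyed by
``(experiment_id, roi_id)``.  A plain tabular store keeps results easy to
exchange between laboratories and to screen with simple predicates, e.g.
"OFF terminals deeper than 50%" — the ectopic-terminal screen.

The synopsis is a directory of Markdown plus image files: imaging
parameters, the averaged field of view, the numbered ROI mask overlay, a
grey-scale raster of all traces, and one trace panel per ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from fluoroi.image_io import Image
from fluoroi.roi_detect import ROIMask
from fluoroi.traces import TraceMatrix

__all__ = [
    "STORE_COLUMNS",
    "QueryFilter",
    "ExperimentBundle",
    "records_from_results",
    "append_experiment",
    "query",
    "synopsis",
]

#: column dictionary of the store (see docs/methods.md)
STORE_COLUMNS = [
    "experiment_id",
    "roi_id",
    "com_x",
    "com_y",
    "depth_percent",
    "polarity",
    "cluster_id",
    "f0",
    "peak_dff",
    "area_px",
    "pixel_size_um",
    "frame_interval_s",
    "date",
]


@dataclass
class QueryFilter:
    """Conjunction of per-field predicates.

    Each predicate is keyed by a store column and is one of: a scalar
    (equality), a list/set/tuple-of-values (membership), or a 2-tuple
    ``(lo, hi)`` of numbers/None (inclusive range, open ends allowed).
    """

    predicates: dict[str, Any] = field(default_factory=dict)


def _apply_predicate(col: pd.Series, pred: Any) -> pd.Series:
    if isinstance(pred, tuple) and len(pred) == 2 and all(
        p is None or isinstance(p, (int, float)) for p in pred
    ):
        lo, hi = pred
        keep = pd.Series(True, index=col.index)
        if lo is not None:
            keep &= col >= lo
        if hi is not None:
            keep &= col <= hi
        return keep
    if isinstance(pred, (list, set, frozenset)):
        return col.isin(list(pred))
    return col == pred


def append_experiment(store: str | Path, records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Append per-terminal records to the store, enforcing unique keys.

    Duplicate ``(experiment_id, roi_id)`` pairs — within the new records or
    against the existing store — are rejected with a report of the
    offending ids.  Appending an empty record list leaves the store
    unchanged.  Returns the updated table.
    """
    store = Path(store)
    new = pd.DataFrame(records)
    existing = pd.read_csv(store) if store.exists() else pd.DataFrame(columns=STORE_COLUMNS)
    if new.empty:
        existing.to_csv(store, index=False)
        return existing
    missing = {"experiment_id", "roi_id"} - set(new.columns)
    if missing:
        raise ValueError(f"records lack key columns {sorted(missing)}")
    for col in STORE_COLUMNS:
        if col not in new.columns:
            new[col] = pd.NA
    new = new[STORE_COLUMNS]
    combined = (
        new.reset_index(drop=True)
        if existing.empty
        else pd.concat([existing, new], ignore_index=True)
    )
    dup = combined.duplicated(subset=["experiment_id", "roi_id"], keep=False)
    dup_new = dup.iloc[len(existing):]
    if dup_new.any():
        offending = combined.loc[dup_new.index[dup_new], ["experiment_id", "roi_id"]]
        raise ValueError(
            "duplicate (experiment_id, roi_id) keys: "
            + ", ".join(f"({r.experiment_id}, {r.roi_id})" for r in offending.itertuples())
        )
    combined.to_csv(store, index=False)
    return combined


def query(store: str | Path, filt: QueryFilter | None = None) -> pd.DataFrame:
    """All and only records satisfying every predicate, in insertion order."""
    table = pd.read_csv(Path(store))
    if filt is None or not filt.predicates:
        return table
    unknown = set(filt.predicates) - set(table.columns)
    if unknown:
        raise ValueError(f"unknown field(s) in filter: {sorted(unknown)}")
    keep = pd.Series(True, index=table.index)
    for name, pred in filt.predicates.items():
        keep &= _apply_predicate(table[name], pred)
    return table[keep].reset_index(drop=True)


@dataclass
class ExperimentBundle:
    """Everything the synopsis of one experiment can draw on.

    Stages that were skipped may be None; the corresponding report section
    is omitted with a note.
    """

    experiment_id: str
    parameters: dict[str, Any] = field(default_factory=dict)
    average: Image | None = None
    mask: ROIMask | None = None
    traces: TraceMatrix | None = None  # typically ΔF/F


def _save_gray(data: np.ndarray, path: Path) -> None:
    lo, hi = float(np.min(data)), float(np.max(data))
    scaled = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    plt.imsave(path, scaled, cmap="gray", vmin=0.0, vmax=1.0)


def records_from_results(
    experiment_id: str,
    mask: ROIMask,
    dff_traces: TraceMatrix | None = None,
    positions: pd.DataFrame | None = None,
    polarity: dict[int, str] | None = None,
    cluster_labels: dict[int, int] | None = None,
    centres: dict[int, tuple[float, float]] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    date: str | None = None,
) -> pd.DataFrame:
    """Assemble per-terminal store rows from pipeline outputs."""
    areas = mask.roi_areas
    pos = positions.set_index("roi_id") if positions is not None else None
    rows = []
    for n in range(1, mask.n_rois + 1):
        row: dict[str, Any] = {
            "experiment_id": experiment_id,
            "roi_id": n,
            "area_px": int(areas[n - 1]),
            "pixel_size_um": pixel_size_um,
            "frame_interval_s": frame_interval_s,
            "date": date,
        }
        if centres and n in centres:
            row["com_x"], row["com_y"] = centres[n]
        if pos is not None and n in pos.index:
            row["depth_percent"] = int(pos.loc[n, "depth_percent"])
        if polarity:
            row["polarity"] = polarity.get(n)
        if cluster_labels:
            row["cluster_id"] = cluster_labels.get(n)
        if dff_traces is not None:
            i = dff_traces.roi_ids.index(n)
            if dff_traces.f0 is not None:
                row["f0"] = float(dff_traces.f0[i])
            vals = dff_traces.values[i]
            row["peak_dff"] = float(np.nanmax(vals)) if np.isfinite(vals).any() else None
        rows.append(row)
    return pd.DataFrame(rows)


def synopsis(bundle: ExperimentBundle, out_dir: str | Path) -> Path:
    """Write the per-experiment synopsis report into ``out_dir``.

    Produces ``report.md`` plus PNG assets: averaged image, numbered mask
    overlay, grey-scale trace raster (one pixel row per ROI, one column
    per frame), and one numbered trace panel per ROI.  The output is
    deterministic for fixed inputs (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"# Experiment synopsis: {bundle.experiment_id}", ""]

    lines += ["## Imaging parameters", ""]
    if bundle.parameters:
        lines += ["| parameter | value |", "| --- | --- |"]
        lines += [f"| {k} | {v} |" for k, v in sorted(bundle.parameters.items())]
    else:
        lines.append("*(no parameters recorded)*")
    lines.append("")

    lines += ["## Averaged field of view", ""]
    if bundle.average is not None:
        _save_gray(bundle.average.data, out / "average_image.png")
        lines += ["![average](average_image.png)", ""]
    else:
        lines += ["*(stage skipped: no averaged image)*", ""]

    lines += ["## ROI mask", ""]
    if bundle.mask is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        base = bundle.average.data if bundle.average is not None else (bundle.mask.labels < 0)
        ax.imshow(base, cmap="gray", interpolation="nearest")
        for n in range(1, bundle.mask.n_rois + 1):
            ys, xs = np.nonzero(bundle.mask.labels == -n)
            ax.text(xs.mean(), ys.mean(), str(n), color="red", fontsize=7,
                    ha="center", va="center")
        ax.set_axis_off()
        fig.savefig(out / "mask_overlay.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
        lines += [f"{bundle.mask.n_rois} ROIs.", "", "![mask](mask_overlay.png)", ""]
    else:
        lines += ["*(stage skipped: no ROI mask)*", ""]

    n_panels = 0
    lines += ["## Signals", ""]
    if bundle.traces is not None and bundle.traces.n_rois > 0:
        tm = bundle.traces
        raster = np.nan_to_num(tm.values, nan=0.0)
        _save_gray(raster, out / "raster.png")
        lines += [
            f"Grey-scale raster of all {tm.n_rois} signals ({tm.n_rois}×{tm.n_frames} px):",
            "", "![raster](raster.png)", "", "### Per-ROI traces", "",
        ]
        gallery = out / "traces"
        gallery.mkdir(exist_ok=True)
        for i, roi in enumerate(tm.roi_ids):
            fig, ax = plt.subplots(figsize=(4, 1.6))
            ax.plot(tm.times, tm.values[i], lw=0.8, color="k")
            ax.set_title(f"ROI {roi}", fontsize=8)
            ax.set_xlabel("time (s)", fontsize=7)
            fig.savefig(gallery / f"roi_{roi:03d}.png", dpi=80, bbox_inches="tight")
            plt.close(fig)
            lines.append(f"![roi {roi}](traces/roi_{roi:03d}.png)")
            n_panels += 1
        lines.append("")
    else:
        lines += ["*(stage skipped: no traces)*", ""]

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
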