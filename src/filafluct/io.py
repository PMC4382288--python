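"""Readers and writers for the package's on-disk formats.

Cells travel as CSV with columns ``run_id,filament_id,cell_index,
fluorescence`` (``cell_index`` is 0-based along the filament); segmentation
adds ``area,centroid_y,centroid_x``.  Images and label maps are
single-channel 16-bit TIFF.  Curves are CSV, reports JSON.  All writers are
deterministic: fixed column order, fixed float formatting, sorted JSON keys
and no timestamps, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CorrelationCurve, FilamentSet
from .segmentation import CellRecord

__all__ = [
    "write_cells_csv",
    "read_cells_csv",
    "write_cell_records_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_json",
    "write_image_tiff",
    "read_image_tiff",
    "write_label_tiff",
]

_FLOAT_FMT = "%.10g"


def write_cells_csv(fset: FilamentSet, path) -> None:
    fset.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cells_csv(path, run_id: str | None = None) -> FilamentSet:
    df = pd.read_csv(path)
    return FilamentSet.from_dataframe(df, run_id=run_id)


def read_cells_csv_multi(path) -> dict[str, FilamentSet]:
    """Read a cells CSV that may hold several runs; one FilamentSet per run."""
    df = pd.read_csv(path)
    return {
        str(rid): FilamentSet.from_dataframe(grp)
        for rid, grp in df.groupby(df["run_id"].astype(str))
    }


def write_cell_records_csv(cells: list[CellRecord], path, run_id: str = "run0") -> None:
    rows = [
        (
            run_id,
            c.filament_id,
            c.position_in_filament,
            c.mean_fluorescence,
            c.area,
            c.centroid[0],
            c.centroid[1],
        )
        for c in sorted(cells, key=lambda c: (c.filament_id, c.position_in_filament))
    ]
    pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "filament_id",
            "cell_index",
            "fluorescence",
            "area",
            "centroid_y",
            "centroid_x",
        ],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_curve_csv(curve: CorrelationCurve, path) -> None:
    curve.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curve_csv(path) -> CorrelationCurve:
    df = pd.read_csv(path)
    return CorrelationCurve(
        df["n"].to_numpy(),
        df["g"].to_numpy(),
        df["se"].to_numpy(),
        corrected=bool(df["corrected"].iloc[0]),
        n_filaments_used=0,
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def write_image_tiff(image: np.ndarray, path) -> None:
    """Write a float image as 16-bit TIFF (clipped to the uint16 range)."""
    arr = np.clip(np.asarray(image), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, np.round(arr).astype(np.uint16))


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_label_tiff(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
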