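"""Per-object and per-field measurements.

For every whole-cell object: area (pixels², optionally µm²), centroid
position (x = column, y = row, 0-based, origin top-left), and a shape score.
Per field and per class: object count and total area covered, with
across-field sums matching the summed-field reporting used for multi-tile
chip acquisitions.

Shape is reported as the form factor 4πA/P² (1 for an ideal disc, smaller
for spread or irregular outlines), with eccentricity and solidity as
optional extras.  The perimeter P uses the Crofton approximation (4
directions), whose digital bias stays within ~20% for cell-sized objects.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from .linking import WholeCellSet

__all__ = ["OBJECT_COLUMNS", "measure_objects", "summarize", "perimeter_crofton"]

# fixed, versioned column order for the objects CSV
OBJECT_COLUMNS = [
    "field_id",
    "population",
    "object_id",
    "nucleus_id",
    "area",
    "centroid_x",
    "centroid_y",
    "form_factor",
    "eccentricity",
    "solidity",
]


def perimeter_crofton(mask: np.ndarray) -> float:
    return float(_skmeasure.perimeter_crofton(np.asarray(mask, dtype=bool), directions=4))


def measure_objects(
    cells: WholeCellSet,
    field_id: str = "field_0",
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """One row per whole-cell object; empty set → empty table with all columns."""
    labels = np.asarray(cells.labels)
    cols = list(OBJECT_COLUMNS) + (["area_um2"] if pixel_size else [])
    n = int(labels.max(initial=0))
    if n == 0:
        return pd.DataFrame(columns=cols)

    rows = []
    for prop in _skmeasure.regionprops(labels):
        area = int(prop.area)
        perim = perimeter_crofton(prop.image)
        ff = 4.0 * math.pi * area / (perim**2) if perim > 0 else float("nan")
        cy, cx = prop.centroid  # row, col → y, x
        row = {
            "field_id": field_id,
            "population": cells.population,
            "object_id": int(prop.label),
            "nucleus_id": cells.nucleus_of.get(int(prop.label), 0),
            "area": area,
            "centroid_x": float(cx),
            "centroid_y": float(cy),
            "form_factor": ff,
            "eccentricity": float(prop.eccentricity),
            "solidity": float(prop.solidity),
        }
        if pixel_size:
            row["area_um2"] = area * pixel_size**2
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-field per-class counts and areas, plus across-field sum rows.

    Mirrors the protocol's measures: ``count`` and ``area_covered`` for each
    field and population, and ``sum_count`` / ``sum_area_covered`` rows
    (``field_id == "ALL"``) accumulated over fields.
    """
    cols = ["field_id", "population", "count", "area_covered"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    per_field = (
        records.groupby(["field_id", "population"], sort=True)
        .agg(count=("object_id", "size"), area_covered=("area", "sum"))
        .reset_index()
    )
    totals = (
        per_field.groupby("population", sort=True)
        .agg(count=("count", "sum"), area_covered=("area_covered", "sum"))
        .reset_index()
    )
    totals.insert(0, "field_id", "ALL")
    out = pd.concat([per_field, totals], ignore_index=True)
    out["count"] = out["count"].astype(int)
    out["area_covered"] = out["area_covered"].astype(int)
    return out[cols]
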