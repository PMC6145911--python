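"""Field- and well-level quantification.

The screen's central statistic is per-cell ALP activity: for each field,
the summed background-corrected ELF 97 intensity within the detected spot
area divided by the field's nuclei count; per well, the unweighted mean of
this ratio over fields (fields without nuclei are excluded).  Cell number
per well is the plain sum of nuclei counts over fields.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    FieldImage,
    FieldMeasurement,
    PlateLayout,
    Role,
    WellMeasurement,
)
from .segment import DetectionParams, LabelMap, segment_field

__all__ = [
    "measure_field",
    "aggregate_well",
    "process_field",
    "process_screen",
    "timecourse_table",
]


def measure_field(
    nuclei: LabelMap,
    spots: LabelMap,
    elf_corrected: np.ndarray,
    ki67_positive_count: int | None = None,
    alp_stat: Literal["sum", "mean"] = "sum",
) -> FieldMeasurement:
    """Quantify one field from its label maps.

    ``alp_stat="sum"`` (canonical) sums the corrected ELF intensity over
    all spot pixels; ``"mean"`` instead uses the mean intensity within the
    spot area (the variant of the round-object acquisition path).
    """
    if spots.labels.shape != np.asarray(elf_corrected).shape:
        raise ValueError("spot label map and ELF raster shapes differ")
    in_spots = spots.labels > 0
    area = int(in_spots.sum())
    if area == 0:
        alp = 0.0
    elif alp_stat == "sum":
        alp = float(np.asarray(elf_corrected)[in_spots].sum())
    elif alp_stat == "mean":
        alp = float(np.asarray(elf_corrected)[in_spots].mean())
    else:
        raise ValueError(f"unknown alp_stat {alp_stat!r}")
    return FieldMeasurement(
        nuclei_count=nuclei.object_count,
        alp_intensity_in_spots=max(alp, 0.0),
        spot_area_px=area,
        ki67_positive_count=ki67_positive_count,
    )


def aggregate_well(
    fields: Sequence[FieldMeasurement],
    plate_id: str = "",
    well: str = "A1",
    gene_symbol: str = "",
    role: Role = Role.LIBRARY,
) -> WellMeasurement:
    """Aggregate field measurements into a well measurement.

    ``cell_number`` is the sum of nuclei over all fields.  ``alp_per_cell``
    is the mean over fields *with at least one nucleus* of
    ``alp_intensity_in_spots / nuclei_count``; it is ``None`` when no field
    has nuclei.  The Ki67 fraction is computed from pooled counts.
    """
    if not fields:
        raise ValueError("at least one field required")
    cell_number = int(sum(f.nuclei_count for f in fields))
    ratios = [
        f.alp_intensity_in_spots / f.nuclei_count for f in fields if f.nuclei_count > 0
    ]
    alp_per_cell = float(np.mean(ratios)) if ratios else None
    ki67_counts = [f.ki67_positive_count for f in fields if f.ki67_positive_count is not None]
    ki67_fraction = None
    if ki67_counts and cell_number > 0:
        ki67_fraction = float(sum(ki67_counts)) / cell_number
    return WellMeasurement(
        plate_id=plate_id,
        well=well,
        gene_symbol=gene_symbol,
        role=role,
        cell_number=cell_number,
        alp_per_cell=alp_per_cell,
        ki67_fraction=ki67_fraction,
        n_fields_used=len(fields),
    )


def process_field(
    field: FieldImage,
    params: DetectionParams,
    alp_stat: Literal["sum", "mean"] = "sum",
) -> FieldMeasurement:
    """Segment and quantify one field image."""
    nuclei, spots, elf_corrected, ki67_count = segment_field(field, params)
    return measure_field(nuclei, spots, elf_corrected, ki67_count, alp_stat=alp_stat)


def process_screen(
    images: Mapping[str, Iterable[FieldImage]],
    layout: PlateLayout,
    params: DetectionParams,
    alp_stat: Literal["sum", "mean"] = "sum",
) -> list[WellMeasurement]:
    """Segment and quantify every field of every plate, aggregated per well.

    ``images`` maps plate id to that plate's field images (as produced by
    :func:`osteoscreen.simulate.simulate_screen` or loaded from disk).
    """
    out: list[WellMeasurement] = []
    for plate_id, plate_images in images.items():
        per_well: dict[str, list[FieldMeasurement]] = defaultdict(list)
        for img in plate_images:
            per_well[img.well].append(process_field(img, params, alp_stat=alp_stat))
        for well in sorted(per_well, key=lambda w: (w[0], int(w[1:]))):
            ann = layout.wells.get(well)
            out.append(
                aggregate_well(
                    per_well[well],
                    plate_id=plate_id,
                    well=well,
                    gene_symbol=ann.gene_symbol if ann else "",
                    role=ann.role if ann else Role.UNTREATED,
                )
            )
    return out


def timecourse_table(
    wells: pd.DataFrame,
    value_columns: Sequence[str] = ("cell_number", "alp_per_cell", "ki67_fraction"),
) -> pd.DataFrame:
    """Per-condition time-course summary with fold changes vs the untreated arm.

    ``wells`` needs columns ``condition`` (``"+OI"`` / ``"-OI"``), ``day``
    and the value columns; replicate wells are rows.  Returns mean, SEM
    (``sd/sqrt(n)``; absent for n = 1) and, for each ``+OI`` group, the
    fold change relative to the ``-OI`` mean at the same day.
    """
    required = {"condition", "day"} | set(value_columns)
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (cond, day), grp in wells.groupby(["condition", "day"], sort=True):
        row: dict = {"condition": cond, "day": day, "n": len(grp)}
        for col in value_columns:
            vals = grp[col].dropna().astype(float)
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) >= 2 else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    # fold change of +OI vs -OI at the same day
    for col in value_columns:
        table[f"{col}_fold_vs_minus_oi"] = np.nan
        for day in table["day"].unique():
            base = table.loc[
                (table["day"] == day) & (table["condition"] == "-OI"), f"{col}_mean"
            ]
            if len(base) == 1 and base.iloc[0] and not np.isnan(base.iloc[0]):
                sel = table["day"] == day
                table.loc[sel, f"{col}_fold_vs_minus_oi"] = (
                    table.loc[sel, f"{col}_mean"] / base.iloc[0]
                )
    return table
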