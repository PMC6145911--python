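"""Image I/O: one single-channel 16-bit TIFF per channel per field.

File naming: ``{plate}_{well}_f{field}_{channel}.tif``.  Intensities are
stored as unsigned 16-bit; values are clipped to [0, 65535] on write.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

from .model import FieldImage

__all__ = ["write_field_images", "read_field_images", "write_label_map"]

_NAME_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{1,2})_f(?P<field>\d+)_(?P<channel>nuclear|elf|ki67)\.tif$")


def write_field_images(
    images: Mapping[str, Iterable[FieldImage]], out_dir
) -> list[Path]:
    """Write every channel of every field as 16-bit TIFF; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for plate_id, fields in images.items():
        for fi in fields:
            for channel, raster in fi.channels.items():
                path = out_dir / f"{plate_id}_{fi.well}_f{fi.field_index}_{channel}.tif"
                data = np.clip(np.asarray(raster), 0, 65535).astype(np.uint16)
                tifffile.imwrite(path, data)
                paths.append(path)
    return sorted(paths)


def read_field_images(in_dir, pixel_size_um: float) -> dict[str, list[FieldImage]]:
    """Read a directory of per-channel TIFFs back into field images per plate."""
    in_dir = Path(in_dir)
    grouped: dict[tuple[str, str, int], dict[str, np.ndarray]] = defaultdict(dict)
    for path in sorted(in_dir.glob("*.tif")):
        m = _NAME_RE.match(path.name)
        if not m:
            continue
        key = (m["plate"], m["well"], int(m["field"]))
        grouped[key][m["channel"]] = tifffile.imread(path).astype(float)
    plates: dict[str, list[FieldImage]] = defaultdict(list)
    for (plate, well, field), channels in sorted(grouped.items()):
        plates[plate].append(
            FieldImage(
                well=well,
                field_index=field,
                channels=channels,
                pixel_size_um=pixel_size_um,
            )
        )
    return dict(plates)


def write_label_map(labels: np.ndarray, path) -> None:
    """Export a label map as 16-bit TIFF for visual inspection."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))
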