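"""Core data model for 384-well screening plates.

A screen is organized as plates of 16 rows (A-P) x 24 columns, each well
annotated with a treatment role (library siRNA, Non-Targeting control,
positive control, Kif11 transfection control, mock, untreated).  Each well
is imaged as several fields; segmentation and quantification operate on
:class:`FieldImage` objects and produce :class:`FieldMeasurement` /
:class:`WellMeasurement` records.

Well addresses use the unpadded convention ``"A1"`` ... ``"P24"``; the
parser also accepts zero-padded forms (``"A01"``), the writer always emits
unpadded addresses.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLS = 24

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")


class Role(str, Enum):
    """Treatment role of a well."""

    LIBRARY = "library"
    NON_TARGETING = "non_targeting"
    POSITIVE_CONTROL = "positive_control"
    KIF11_CONTROL = "kif11_control"
    MOCK = "mock"
    UNTREATED = "untreated"


#: Roles whose annotation must carry a gene symbol.
GENE_ROLES = frozenset({Role.LIBRARY, Role.POSITIVE_CONTROL, Role.KIF11_CONTROL})

#: Default positive-control genes (known positive regulators of osteoblast
#: differentiation used on the screening plate).
POSITIVE_CONTROL_GENES = ("Alpl", "Il11", "Sp7", "Runx2")


class PlateLayoutError(ValueError):
    """Raised for invalid plate maps (bad addresses, duplicate wells, bad roles)."""


def parse_well(address: str) -> tuple[str, int]:
    """Parse a well address into ``(row_letter, column)``.

    Accepts both ``"A1"`` and ``"A01"``; rejects addresses outside the
    384-well grid.
    """
    m = _WELL_RE.match(str(address).strip())
    if not m:
        raise PlateLayoutError(f"invalid well address: {address!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > N_COLS:
        raise PlateLayoutError(
            f"well address {address!r} outside the 384-well grid (column > {N_COLS})"
        )
    return row, col


def format_well(row: str, col: int) -> str:
    """Format ``(row_letter, column)`` as an unpadded address like ``"A1"``."""
    if row not in ROW_LETTERS or not 1 <= col <= N_COLS:
        raise PlateLayoutError(f"({row!r}, {col}) outside the 384-well grid")
    return f"{row}{col}"


def normalize_well(address: str) -> str:
    """Canonical (unpadded, upper-case) form of a well address."""
    return format_well(*parse_well(address))


def well_sort_key(address: str) -> tuple[int, int]:
    row, col = parse_well(address)
    return ROW_LETTERS.index(row), col


def all_wells() -> list[str]:
    """All 384 well addresses in row-major order (A1 ... P24)."""
    return [f"{r}{c}" for r in ROW_LETTERS for c in range(1, N_COLS + 1)]


@dataclass
class WellAnnotation:
    """Treatment assigned to one well."""

    role: Role
    gene_symbol: str = ""
    n_fields_expected: int = 15

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.gene_symbol = (self.gene_symbol or "").strip()
        if self.role in GENE_ROLES and not self.gene_symbol:
            raise PlateLayoutError(
                f"role {self.role.value!r} requires a gene_symbol"
            )
        if self.role not in GENE_ROLES and self.gene_symbol:
            raise PlateLayoutError(
                f"role {self.role.value!r} must not carry a gene_symbol "
                f"(got {self.gene_symbol!r})"
            )
        if self.n_fields_expected < 1:
            raise PlateLayoutError("n_fields_expected must be >= 1")


@dataclass
class PlateLayout:
    """Maps wells of one 384-well plate to their treatment annotations."""

    plate_id: str
    wells: dict[str, WellAnnotation]
    replicate_group: str = ""

    def __post_init__(self) -> None:
        normalized: dict[str, WellAnnotation] = {}
        for addr, ann in self.wells.items():
            canon = normalize_well(addr)
            if canon in normalized:
                raise PlateLayoutError(f"duplicate well address {canon!r}")
            normalized[canon] = ann
        self.wells = normalized
        if not self.wells_with_role(Role.NON_TARGETING):
            warnings.warn(
                f"plate {self.plate_id!r} has no non_targeting wells; "
                "normalization will not be possible",
                stacklevel=2,
            )

    def wells_with_role(self, role: Role) -> list[str]:
        return sorted(
            (w for w, a in self.wells.items() if a.role == role), key=well_sort_key
        )

    def sorted_wells(self) -> list[str]:
        return sorted(self.wells, key=well_sort_key)

    def gene_of(self, well: str) -> str:
        return self.wells[normalize_well(well)].gene_symbol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateLayout):
            return NotImplemented
        return (
            self.plate_id == other.plate_id
            and self.replicate_group == other.replicate_group
            and self.wells == other.wells
        )


@dataclass
class FieldImage:
    """One field's per-channel intensity rasters.

    Channels are named ``nuclear`` (DNA stain, e.g. DRAQ5), ``elf``
    (ELF 97 alkaline-phosphatase stain) and optionally ``ki67``.
    """

    well: str
    field_index: int
    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        if self.field_index < 0:
            raise ValueError("field_index must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2-D raster")
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValueError(f"channel {name!r} has non-finite or negative values")


@dataclass
class FieldMeasurement:
    """Per-field readouts: nuclei count and ALP signal within the spot area."""

    nuclei_count: int
    alp_intensity_in_spots: float
    spot_area_px: int
    ki67_positive_count: int | None = None

    def __post_init__(self) -> None:
        if self.nuclei_count < 0 or self.spot_area_px < 0:
            raise ValueError("counts must be >= 0")
        if self.alp_intensity_in_spots < 0:
            raise ValueError("alp_intensity_in_spots must be >= 0")
        if (
            self.ki67_positive_count is not None
            and not 0 <= self.ki67_positive_count <= self.nuclei_count
        ):
            raise ValueError("ki67_positive_count must be in [0, nuclei_count]")


@dataclass
class WellMeasurement:
    """Per-well aggregate of a set of field measurements.

    ``alp_per_cell`` is the screen's central statistic: per field, the summed
    background-corrected ELF intensity within the detected spot area divided
    by that field's nuclei count, averaged over the well's fields.  It is
    ``None`` when no field had any nuclei.
    """

    plate_id: str
    well: str
    gene_symbol: str
    role: Role
    cell_number: int
    alp_per_cell: float | None
    ki67_fraction: float | None
    n_fields_used: int

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        self.role = Role(self.role)
        if self.cell_number < 0:
            raise ValueError("cell_number must be >= 0")
        if self.alp_per_cell is not None and self.alp_per_cell < 0:
            raise ValueError("alp_per_cell must be >= 0")
        if self.ki67_fraction is not None and not 0 <= self.ki67_fraction <= 1:
            raise ValueError("ki67_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# plate-map I/O

_PLATE_MAP_COLUMNS = ("well", "role", "gene_symbol")


def read_plate_map(
    path, plate_id: str | None = None, replicate_group: str = ""
) -> PlateLayout:
    """Read a plate map from a comma-separated file.

    Required columns: ``well``, ``role``, ``gene_symbol``; optional
    ``n_fields_expected`` and ``plate_id``.  Unknown roles and duplicate
    well addresses raise :class:`PlateLayoutError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateLayoutError(f"plate map {path} missing columns: {missing}")
    if plate_id is None:
        if "plate_id" in df.columns and df["plate_id"].nunique() == 1:
            plate_id = df["plate_id"].iloc[0]
        else:
            plate_id = "plate1"
    wells: dict[str, WellAnnotation] = {}
    for i, row in df.iterrows():
        try:
            addr = normalize_well(row["well"])
            role = Role(row["role"].strip())
        except (PlateLayoutError, ValueError) as exc:
            raise PlateLayoutError(f"plate map row {i + 1}: {exc}") from exc
        if addr in wells:
            raise PlateLayoutError(f"plate map row {i + 1}: duplicate well {addr!r}")
        nfe = row.get("n_fields_expected", "")
        wells[addr] = WellAnnotation(
            role=role,
            gene_symbol=row["gene_symbol"],
            n_fields_expected=int(nfe) if str(nfe).strip() else 15,
        )
    return PlateLayout(plate_id=plate_id, wells=wells, replicate_group=replicate_group)


def write_plate_map(layout: PlateLayout, path) -> None:
    """Write a plate map readable by :func:`read_plate_map` (lossless)."""
    rows = [
        {
            "plate_id": layout.plate_id,
            "well": w,
            "role": layout.wells[w].role.value,
            "gene_symbol": layout.wells[w].gene_symbol,
            "n_fields_expected": layout.wells[w].n_fields_expected,
        }
        for w in layout.sorted_wells()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# measurement-table I/O

#: Fixed column order of the well-measurement table.
MEASUREMENT_COLUMNS = (
    "plate_id",
    "well",
    "gene_symbol",
    "role",
    "cell_number",
    "alp_per_cell",
    "ki67_fraction",
    "n_fields_used",
)


def write_measurements(rows: Iterable[WellMeasurement], path) -> None:
    """Write well measurements as CSV; missing values become empty cells."""
    records = []
    for m in rows:
        records.append(
            {
                "plate_id": m.plate_id,
                "well": m.well,
                "gene_symbol": m.gene_symbol,
                "role": m.role.value,
                "cell_number": m.cell_number,
                "alp_per_cell": "" if m.alp_per_cell is None else repr(m.alp_per_cell),
                "ki67_fraction": ""
                if m.ki67_fraction is None
                else repr(m.ki67_fraction),
                "n_fields_used": m.n_fields_used,
            }
        )
    df = pd.DataFrame(records, columns=list(MEASUREMENT_COLUMNS))
    df.to_csv(path, index=False)


def read_measurements(path) -> list[WellMeasurement]:
    """Read a well-measurement table written by :func:`write_measurements`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            WellMeasurement(
                plate_id=row["plate_id"],
                well=row["well"],
                gene_symbol=row["gene_symbol"],
                role=Role(row["role"]),
                cell_number=int(row["cell_number"]),
                alp_per_cell=float(row["alp_per_cell"])
                if row["alp_per_cell"].strip()
                else None,
                ki67_fraction=float(row["ki67_fraction"])
                if row["ki67_fraction"].strip()
                else None,
                n_fields_used=int(row["n_fields_used"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# default screen layout

def default_screen_layout(
    plate_id: str = "plate1",
    replicate_group: str = "rep1",
    library_genes: Iterable[str] | None = None,
    n_fields_expected: int = 15,
) -> PlateLayout:
    """The default 384-well screening layout: 320 library genes + controls.

    Columns 3-22 hold the 320 library genes (row-major).  Control columns:

    * column 1 — Non-Targeting (16 wells),
    * column 2 — positive controls Alpl/Il11/Sp7/Runx2 (4 wells each),
    * column 23 — Kif11 transfection control (rows A-H), mock (rows I-P),
    * column 24 — untreated (rows A-H), Non-Targeting (rows I-P).

    The grid position of controls is a configurable convention, not a fixed
    fact of the assay.
    """
    if library_genes is None:
        library_genes = [f"Gene{i:03d}" for i in range(1, 321)]
    genes = list(library_genes)
    if len(genes) != 320:
        raise PlateLayoutError(f"expected 320 library genes, got {len(genes)}")

    def ann(role: Role, gene: str = "") -> WellAnnotation:
        return WellAnnotation(role=role, gene_symbol=gene, n_fields_expected=n_fields_expected)

    wells: dict[str, WellAnnotation] = {}
    gene_iter = iter(genes)
    for ri, r in enumerate(ROW_LETTERS):
        wells[f"{r}1"] = ann(Role.NON_TARGETING)
        wells[f"{r}2"] = ann(Role.POSITIVE_CONTROL, POSITIVE_CONTROL_GENES[ri // 4])
        for c in range(3, 23):
            wells[f"{r}{c}"] = ann(Role.LIBRARY, next(gene_iter))
        wells[f"{r}23"] = ann(Role.KIF11_CONTROL, "Kif11") if ri < 8 else ann(Role.MOCK)
        wells[f"{r}24"] = ann(Role.UNTREATED) if ri < 8 else ann(Role.NON_TARGETING)
    return PlateLayout(plate_id=plate_id, wells=wells, replicate_group=replicate_group)
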