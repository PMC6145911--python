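"""Synthetic screen generator.

Simulates the experiment the analysis pipeline was built for: 384-well
plates of primary osteoblast monolayers, reverse-transfected with siRNA,
imaged after differentiation in a nuclear channel (DRAQ5-like), an ELF 97
alkaline-phosphatase channel and optionally a Ki67 channel.  Each gene
carries a planted effect on viability (expected cell number) and on
per-cell ALP activity, so every downstream stage — segmentation,
quantification, normalization, hit calling — can be tested against a known
ground truth.

Statistical model
-----------------
* Expected cell count per well = ``baseline_cells_per_well`` x the gene's
  ``viability_fraction``.  For Kif11 transfection-control wells the
  knockdown kills only transfected, dividing cells, so viability acts on
  the transfected fraction: surviving fraction
  ``(1 - transfection_efficiency) + transfection_efficiency * viability``.
* Realized per-field counts are Poisson around the expected value after a
  well-level multiplicative lognormal factor with coefficient of variation
  ``noise_cv`` (triplicate-scale variability).  ``noise_cv = 0`` switches
  the simulation to fully deterministic expectations.
* ALP activity appears as punctate spots: per field, spot count is Poisson
  with rate ``spots_per_cell_mean`` per nucleus; each spot's peak amplitude
  is lognormal around ``spot_intensity_mean x alp_fold`` (x the well noise
  factor).
* Rendering: nuclei and spots are drawn as disks with a raised-cosine edge
  of 1 px; images get a constant background plus additive Gaussian read
  noise, clipped at zero.

Nuclei are placed without overlap by rejection sampling (monolayer
culture); overlapping-culture geometries are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    FieldImage,
    PlateLayout,
    Role,
    WellMeasurement,
    parse_well,
)

__all__ = [
    "GeneEffect",
    "SimulationConfig",
    "FieldTruth",
    "WellTruth",
    "GroundTruth",
    "simulate_screen",
    "simulate_well",
    "simulate_measurements",
    "render_field",
]


@dataclass(frozen=True)
class GeneEffect:
    """Planted per-gene effect: multiplicative on cell number and on per-cell ALP."""

    gene_symbol: str
    viability_fraction: float = 1.0
    alp_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.viability_fraction < 0 or self.alp_fold < 0:
            raise ValueError("effects must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults describe the assay conditions: 1800 cells seeded per well
    growing to ~4000 by the imaging endpoint, 15 fields per well in
    triplicate, nuclei diameters well inside the 4-21.22 µm detection
    window, ALP spots inside 1.3-8 µm, pixel size 1.29 µm at 2x binning.
    The noise parameters (well-level CV, read noise) are stated model
    assumptions, not measured facts.
    """

    baseline_cells_per_well: float = 4000.0
    nuclei_diameter_um: tuple[float, float] = (7.0, 14.0)
    spot_diameter_um: tuple[float, float] = (2.6, 6.0)
    spots_per_cell_mean: float = 1.5
    spot_intensity_mean: float = 3000.0
    spot_intensity_cv: float = 0.25
    nuclear_intensity_au: float = 3000.0
    background_level: float = 100.0
    read_noise_sd: float = 5.0
    noise_cv: float = 0.10
    transfection_efficiency: float = 0.75
    n_replicates: int = 3
    n_fields: int = 15
    pixel_size_um: float = 1.29
    field_shape: tuple[int, int] = (520, 696)
    placement_margin_um: float = 4.0
    ki67_positive_fraction: float | None = None
    ki67_positive_mean_au: float = 700.0
    ki67_negative_mean_au: float = 120.0
    ki67_sd_au: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.nuclei_diameter_um
        if not 4.0 <= lo < hi <= 21.22:
            raise ValueError("nuclei_diameter_um must be an increasing range within [4, 21.22]")
        lo, hi = self.spot_diameter_um
        if not 1.3 <= lo < hi <= 8.0:
            raise ValueError("spot_diameter_um must be an increasing range within [1.3, 8]")
        if not 0.0 <= self.transfection_efficiency <= 1.0:
            raise ValueError("transfection_efficiency must be in [0, 1]")
        if self.ki67_positive_fraction is not None and not 0.0 <= self.ki67_positive_fraction <= 1.0:
            raise ValueError("ki67_positive_fraction must be in [0, 1]")
        for name in (
            "baseline_cells_per_well",
            "spots_per_cell_mean",
            "spot_intensity_mean",
            "spot_intensity_cv",
            "background_level",
            "read_noise_sd",
            "noise_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class FieldTruth:
    """Planted objects of one field (pixel coordinates, row/col)."""

    nuclei_centers: np.ndarray  # (n, 2)
    nuclei_radii_px: np.ndarray  # (n,)
    spot_centers: np.ndarray  # (m, 2)
    spot_radii_px: np.ndarray  # (m,)
    spot_amplitudes: np.ndarray  # (m,) planted peak amplitudes
    spot_sums: np.ndarray | None = None  # (m,) rendered pixel sums (set by render)
    ki67_positive: np.ndarray | None = None  # (n,) bool

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei_radii_px)

    @property
    def n_spots(self) -> int:
        return len(self.spot_radii_px)


@dataclass
class WellTruth:
    """Ground truth for one well: planted fields plus summary counts."""

    plate_id: str
    well: str
    gene_symbol: str
    role: Role
    alp_fold: float
    expected_cells: float
    fields: list[FieldTruth] = field(default_factory=list)

    @property
    def true_cell_count(self) -> int:
        return int(sum(f.n_nuclei for f in self.fields))

    @property
    def true_spot_intensity(self) -> float:
        total = 0.0
        for f in self.fields:
            if f.spot_sums is None:
                raise ValueError("fields not rendered yet; spot sums unknown")
            total += float(f.spot_sums.sum())
        return total


class GroundTruth(dict):
    """Mapping ``(plate_id, well) -> WellTruth``."""

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "plate_id": t.plate_id,
                "well": t.well,
                "gene_symbol": t.gene_symbol,
                "role": t.role.value,
                "alp_fold": t.alp_fold,
                "expected_cells": t.expected_cells,
                "true_cell_count": t.true_cell_count,
            }
            for t in self.values()
        ]
        return pd.DataFrame(rows)


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# geometry helpers

def _place_disks(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    margin_px: float,
    max_tries_per_disk: int = 200,
) -> np.ndarray:
    """Place ``n`` disks without overlap by rejection sampling.

    Returns an (n, 2) array of centers.  Raises :class:`PlacementError` when
    a disk cannot be placed within the retry budget (density too high).
    """
    centers = np.empty((n, 2))
    for i in range(n):
        r = radii[i]
        lo = r + 1.0
        hi_r, hi_c = shape[0] - r - 1.0, shape[1] - r - 1.0
        if hi_r <= lo or hi_c <= lo:
            raise PlacementError("object larger than field; enlarge field_shape")
        for _ in range(max_tries_per_disk):
            c = np.array([rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)])
            if i == 0:
                centers[0] = c
                break
            d = np.hypot(*(centers[:i] - c).T)
            if np.all(d > radii[:i] + r + margin_px):
                centers[i] = c
                break
        else:
            raise PlacementError(
                f"could not place disk {i + 1}/{n} without overlap after "
                f"{max_tries_per_disk} tries; lower the cell density or "
                "enlarge the field"
            )
    return centers


def _disk_profile(shape, center, radius, amplitude):
    """Render one disk with a raised-cosine edge of 1 px into a local window.

    Returns ``(rows, cols, values)`` slices for in-place accumulation.
    """
    r0 = max(int(np.floor(center[0] - radius - 1)), 0)
    r1 = min(int(np.ceil(center[0] + radius + 2)), shape[0])
    c0 = max(int(np.floor(center[1] - radius - 1)), 0)
    c1 = min(int(np.ceil(center[1] + radius + 2)), shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dist = np.hypot(rr - center[0], cc - center[1])
    prof = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    # raised-cosine taper across the 1-px boundary band
    band = prof * (1 - prof) > 0
    prof[band] = 0.5 * (1.0 - np.cos(np.pi * prof[band]))
    return slice(r0, r1), slice(c0, c1), amplitude * prof


# ---------------------------------------------------------------------------
# per-well simulation

def _surviving_fraction(role: Role, effect: GeneEffect | None, config: SimulationConfig) -> float:
    if role == Role.KIF11_CONTROL:
        v = effect.viability_fraction if effect is not None else 0.0
        return (1.0 - config.transfection_efficiency) + config.transfection_efficiency * v
    if role in (Role.LIBRARY, Role.POSITIVE_CONTROL) and effect is not None:
        return effect.viability_fraction
    return 1.0


def _well_rng(config: SimulationConfig, plate_index: int, well: str) -> np.random.Generator:
    row, col = parse_well(well)
    return np.random.default_rng(
        [config.seed, plate_index, "ABCDEFGHIJKLMNOP".index(row) * 24 + col]
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def simulate_well(
    plate_id: str,
    well: str,
    role: Role,
    gene_symbol: str,
    effect: GeneEffect | None,
    config: SimulationConfig,
    plate_index: int = 0,
) -> tuple[list[FieldImage], WellTruth]:
    """Simulate and render all fields of one well."""
    rng = _well_rng(config, plate_index, well)
    deterministic = config.noise_cv == 0

    surv = _surviving_fraction(role, effect, config)
    alp_fold = effect.alp_fold if (effect is not None and role in (Role.LIBRARY, Role.POSITIVE_CONTROL)) else 1.0
    expected = config.baseline_cells_per_well * surv
    cell_factor = _lognormal_factor(rng, config.noise_cv)
    alp_factor = _lognormal_factor(rng, config.noise_cv)

    truth = WellTruth(
        plate_id=plate_id,
        well=well,
        gene_symbol=gene_symbol,
        role=role,
        alp_fold=alp_fold,
        expected_cells=expected,
    )
    images: list[FieldImage] = []
    per_field = expected * cell_factor / config.n_fields
    rad_lo, rad_hi = (d / 2.0 / config.pixel_size_um for d in config.nuclei_diameter_um)
    srad_lo, srad_hi = (d / 2.0 / config.pixel_size_um for d in config.spot_diameter_um)
    margin_px = config.placement_margin_um / config.pixel_size_um
    lognorm_sigma = np.sqrt(np.log(1.0 + config.spot_intensity_cv**2))

    for f_idx in range(config.n_fields):
        n_nuc = int(round(per_field)) if deterministic else int(rng.poisson(per_field))
        nuc_radii = rng.uniform(rad_lo, rad_hi, size=n_nuc)
        nuc_centers = _place_disks(rng, n_nuc, nuc_radii, config.field_shape, margin_px)

        spot_rate = n_nuc * config.spots_per_cell_mean
        n_spots = int(round(spot_rate)) if deterministic else int(rng.poisson(spot_rate))
        spot_radii = rng.uniform(srad_lo, srad_hi, size=n_spots)
        spot_centers = _place_disks(rng, n_spots, spot_radii, config.field_shape, margin_px)
        base_amp = rng.lognormal(-0.5 * lognorm_sigma**2, lognorm_sigma, size=n_spots)
        if deterministic:
            base_amp = np.ones(n_spots)
        spot_amp = config.spot_intensity_mean * alp_fold * alp_factor * base_amp

        ki67_pos = None
        if config.ki67_positive_fraction is not None:
            ki67_pos = rng.random(n_nuc) < config.ki67_positive_fraction

        ft = FieldTruth(
            nuclei_centers=nuc_centers,
            nuclei_radii_px=nuc_radii,
            spot_centers=spot_centers,
            spot_radii_px=spot_radii,
            spot_amplitudes=spot_amp,
            ki67_positive=ki67_pos,
        )
        images.append(render_field(ft, config, well=well, field_index=f_idx, rng=rng))
        truth.fields.append(ft)
    return images, truth


def render_field(
    truth: FieldTruth,
    config: SimulationConfig,
    well: str = "A1",
    field_index: int = 0,
    rng: np.random.Generator | None = None,
) -> FieldImage:
    """Render one field's channels from its planted objects.

    Fills ``truth.spot_sums`` with the rendered (noise-free) pixel sum of
    each spot, the quantity the per-cell ALP statistic measures.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = config.field_shape

    nuclear = np.full(shape, config.background_level, dtype=float)
    for center, radius in zip(truth.nuclei_centers, truth.nuclei_radii_px):
        rs, cs, prof = _disk_profile(shape, center, radius, config.nuclear_intensity_au)
        nuclear[rs, cs] += prof

    elf = np.full(shape, config.background_level, dtype=float)
    sums = np.zeros(truth.n_spots)
    for i, (center, radius, amp) in enumerate(
        zip(truth.spot_centers, truth.spot_radii_px, truth.spot_amplitudes)
    ):
        rs, cs, prof = _disk_profile(shape, center, radius, amp)
        elf[rs, cs] += prof
        sums[i] = prof.sum()
    truth.spot_sums = sums

    channels = {"nuclear": nuclear, "elf": elf}
    if truth.ki67_positive is not None:
        ki67 = np.full(shape, config.background_level, dtype=float)
        amps = np.where(
            truth.ki67_positive, config.ki67_positive_mean_au, config.ki67_negative_mean_au
        ) + (0.0 if config.noise_cv == 0 else rng.normal(0.0, config.ki67_sd_au, truth.n_nuclei))
        amps = np.clip(amps, 0.0, None)
        for center, radius, amp in zip(truth.nuclei_centers, truth.nuclei_radii_px, amps):
            rs, cs, prof = _disk_profile(shape, center, radius, amp)
            ki67[rs, cs] += prof
        channels["ki67"] = ki67

    if config.read_noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, config.read_noise_sd, shape), 0.0, None
            )
    return FieldImage(
        well=well,
        field_index=field_index,
        channels=channels,
        pixel_size_um=config.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# whole-screen simulation

def _effect_map(effects: Iterable[GeneEffect]) -> dict[str, GeneEffect]:
    return {e.gene_symbol: e for e in effects}


def _check_effects(layout: PlateLayout, emap: Mapping[str, GeneEffect]) -> None:
    missing = sorted(
        {
            a.gene_symbol
            for a in layout.wells.values()
            if a.role in (Role.LIBRARY, Role.POSITIVE_CONTROL)
            and a.gene_symbol not in emap
        }
    )
    if missing:
        raise ValueError(f"no GeneEffect entry for genes: {missing[:5]}{'...' if len(missing) > 5 else ''}")


def simulate_screen(
    layout: PlateLayout,
    effects: Iterable[GeneEffect],
    config: SimulationConfig,
) -> tuple[dict[str, list[FieldImage]], GroundTruth]:
    """Simulate ``config.n_replicates`` rendered replicate plates.

    Returns a mapping ``plate_id -> list of FieldImage`` (plate ids are
    ``{layout.plate_id}-r1`` ...) and the :class:`GroundTruth`.  Output is
    deterministic given (layout, effects, config): every well derives its
    random stream from ``(config.seed, replicate, well)``.
    """
    emap = _effect_map(effects)
    _check_effects(layout, emap)
    images: dict[str, list[FieldImage]] = {}
    truth = GroundTruth()
    for rep in range(config.n_replicates):
        plate_id = f"{layout.plate_id}-r{rep + 1}"
        plate_images: list[FieldImage] = []
        for well in layout.sorted_wells():
            ann = layout.wells[well]
            imgs, wt = simulate_well(
                plate_id,
                well,
                ann.role,
                ann.gene_symbol,
                emap.get(ann.gene_symbol),
                config,
                plate_index=rep,
            )
            plate_images.extend(imgs)
            truth[(plate_id, well)] = wt
        images[plate_id] = plate_images
    return images, truth


def simulate_measurements(
    layout: PlateLayout,
    effects: Iterable[GeneEffect],
    config: SimulationConfig,
) -> list[WellMeasurement]:
    """Simulate well measurements directly, without rendering images.

    Draws per-field nuclei counts, spot counts and spot amplitudes from the
    same statistical model as :func:`simulate_screen` and aggregates them
    with the canonical per-cell ALP formula.  The ALP scale differs from
    the image path by the mean spot area (amplitudes vs rendered pixel
    sums); all screen statistics are percent-of-control normalized, so this
    has no effect downstream.  Intended for screen-scale statistical
    studies where rendering every field would be wasteful.
    """
    emap = _effect_map(effects)
    _check_effects(layout, emap)
    deterministic = config.noise_cv == 0
    lognorm_sigma = np.sqrt(np.log(1.0 + config.spot_intensity_cv**2))
    out: list[WellMeasurement] = []
    for rep in range(config.n_replicates):
        plate_id = f"{layout.plate_id}-r{rep + 1}"
        for well in layout.sorted_wells():
            ann = layout.wells[well]
            effect = emap.get(ann.gene_symbol)
            rng = _well_rng(config, rep, well)
            surv = _surviving_fraction(ann.role, effect, config)
            alp_fold = (
                effect.alp_fold
                if (effect is not None and ann.role in (Role.LIBRARY, Role.POSITIVE_CONTROL))
                else 1.0
            )
            expected = config.baseline_cells_per_well * surv
            cell_factor = _lognormal_factor(rng, config.noise_cv)
            alp_factor = _lognormal_factor(rng, config.noise_cv)
            per_field = expected * cell_factor / config.n_fields

            ratios = []
            total_cells = 0
            ki67_pos = 0
            for _ in range(config.n_fields):
                n_nuc = int(round(per_field)) if deterministic else int(rng.poisson(per_field))
                total_cells += n_nuc
                if n_nuc == 0:
                    continue
                rate = n_nuc * config.spots_per_cell_mean
                n_spots = int(round(rate)) if deterministic else int(rng.poisson(rate))
                if deterministic:
                    amps = np.ones(n_spots)
                else:
                    amps = rng.lognormal(-0.5 * lognorm_sigma**2, lognorm_sigma, n_spots)
                field_sum = config.spot_intensity_mean * alp_fold * alp_factor * float(amps.sum())
                ratios.append(field_sum / n_nuc)
                if config.ki67_positive_fraction is not None:
                    ki67_pos += int(rng.binomial(n_nuc, config.ki67_positive_fraction))
            out.append(
                WellMeasurement(
                    plate_id=plate_id,
                    well=well,
                    gene_symbol=ann.gene_symbol,
                    role=ann.role,
                    cell_number=total_cells,
                    alp_per_cell=float(np.mean(ratios)) if ratios else None,
                    ki67_fraction=(ki67_pos / total_cells)
                    if (config.ki67_positive_fraction is not None and total_cells > 0)
                    else None,
                    n_fields_used=config.n_fields,
                )
            )
    return out
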