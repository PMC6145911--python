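"""Segmentation and detection operators for nuclei, ALP spots and Ki67.

Two operator sets are provided, mirroring the two acquisition/analysis
paths of the assay:

``threshold_pipeline``
    Nuclei by adaptive (windowed) Otsu thresholding with optional
    distance-transform watershed splitting of touching nuclei and a size
    gate in µm; ALP spots by median-filter background correction followed
    by a "background" global threshold (a multiple of the histogram mode).

``round_object_pipeline``
    White top-hat background correction per channel (feature size 50 for
    the nuclear stain, 100 for ELF 97 / Ki67), then round-object detection:
    connected components above an intensity threshold, gated on equivalent
    diameter (4-21.22 µm nuclei, 1.3-8 µm spots) and circularity.

All sizes cross the µm/px boundary via ``pixel_size_um``; the equivalent
diameter of an object is the diameter of the circle of equal area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .model import FieldImage, FieldMeasurement

__all__ = [
    "LabelMap",
    "DetectionMode",
    "DetectionParams",
    "segment_nuclei_otsu",
    "correct_background_median",
    "detect_spots_background_global",
    "tophat_correct",
    "detect_round_objects",
    "classify_ki67",
    "segment_field",
]


class DetectionMode(str, Enum):
    THRESHOLD = "threshold_pipeline"
    ROUND_OBJECT = "round_object_pipeline"


@dataclass
class LabelMap:
    """Labelled objects: 0 = background, 1..object_count = objects."""

    labels: np.ndarray
    object_count: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "LabelMap":
        lab, n = sk_label(mask, return_num=True)
        return cls(labels=lab.astype(np.int32), object_count=int(n))

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMap":
        """Relabel to consecutive 1..n."""
        lab, _, _ = _relabel_consecutive(labels)
        return cls(labels=lab, object_count=int(lab.max()))

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        if self.object_count != len(present) or (
            len(present) and present[-1] != self.object_count
        ):
            raise ValueError("labels must be consecutive 1..object_count")


def _relabel_consecutive(labels: np.ndarray):
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels], vals, lut


@dataclass
class DetectionParams:
    """Tunable parameters of both detection pipelines (sizes in µm, a.u. thresholds)."""

    mode: DetectionMode = DetectionMode.THRESHOLD
    nuclei_size_um: tuple[float, float] = (4.0, 21.22)
    nuclei_intensity_threshold_au: float = 200.0
    spot_size_um: tuple[float, float] = (1.3, 8.0)
    spot_intensity_threshold_au: float = 1000.0
    median_object_size: int = 10
    median_smoothing_size: int = 20
    tophat_feature_size_nuclear: int = 50
    tophat_feature_size_elf: int = 100
    tophat_feature_size_ki67: int = 100
    tophat_feature_size_spot: int = 10
    ki67_positive_threshold_au: float = 300.0
    otsu_window_px: int = 50
    background_mode_multiplier: float = 2.0
    circularity_min: float = 0.6
    split_touching: bool = True

    def __post_init__(self) -> None:
        self.mode = DetectionMode(self.mode)
        for rng in (self.nuclei_size_um, self.spot_size_um):
            if not rng[0] < rng[1]:
                raise ValueError("size ranges must satisfy min < max")
        for name in (
            "nuclei_intensity_threshold_au",
            "spot_intensity_threshold_au",
            "ki67_positive_threshold_au",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# threshold pipeline

def _adaptive_otsu_threshold(image: np.ndarray, window: int) -> np.ndarray:
    """Per-tile Otsu threshold map with a global fallback for flat tiles.

    The image is tiled into ``window``-sized blocks; tiles whose dynamic
    range is below 25% of the global range carry too little foreground for
    a stable Otsu split and fall back to the global Otsu threshold.
    """
    img = np.asarray(image, dtype=float)
    global_range = img.max() - img.min()
    if global_range == 0:
        # constant image: no threshold separates anything; return +inf map
        return np.full(img.shape, np.inf)
    global_thr = threshold_otsu(img)
    thr = np.empty(img.shape)
    for r0 in range(0, img.shape[0], window):
        for c0 in range(0, img.shape[1], window):
            tile = img[r0 : r0 + window, c0 : c0 + window]
            if tile.max() - tile.min() < 0.25 * global_range:
                t = global_thr
            else:
                t = threshold_otsu(tile)
            thr[r0 : r0 + window, c0 : c0 + window] = t
    return thr


def _split_touching(mask: np.ndarray, min_diameter_px: float) -> np.ndarray:
    """Split touching objects by distance-transform watershed."""
    dist = ndi.distance_transform_edt(mask)
    dist_s = gaussian(dist, sigma=1.0, preserve_range=True)
    min_distance = max(3, int(round(0.7 * min_diameter_px)))
    coords = peak_local_max(
        dist_s, min_distance=min_distance, labels=sk_label(mask), exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return sk_label(mask)
    return watershed(-dist_s, markers, mask=mask)


def segment_nuclei_otsu(
    nuclear: np.ndarray, params: DetectionParams, pixel_size_um: float
) -> LabelMap:
    """Segment nuclei by adaptive Otsu thresholding.

    Connected components of the thresholded foreground are optionally split
    by watershed, then gated on equivalent diameter within
    ``params.nuclei_size_um``.  A constant image yields zero objects.
    """
    img = np.asarray(nuclear, dtype=float)
    thr = _adaptive_otsu_threshold(img, params.otsu_window_px)
    mask = img > thr
    if not mask.any():
        return LabelMap(np.zeros(img.shape, dtype=np.int32), 0)
    mask = ndi.binary_fill_holes(mask)
    lo_px = params.nuclei_size_um[0] / pixel_size_um
    if params.split_touching:
        lab = _split_touching(mask, lo_px)
    else:
        lab = sk_label(mask)
    lab = _filter_by_diameter(lab, params.nuclei_size_um, pixel_size_um)
    return LabelMap.from_labels(lab)


def _filter_by_diameter(labels: np.ndarray, size_um, pixel_size_um: float) -> np.ndarray:
    lo, hi = size_um
    out = labels.copy()
    for p in regionprops(labels):
        d_um = p.equivalent_diameter_area * pixel_size_um
        if not lo <= d_um <= hi:
            out[labels == p.label] = 0
    return out


def correct_background_median(
    elf: np.ndarray, object_size: int = 10, smoothing_size: int = 20
) -> np.ndarray:
    """Median-filter background correction of the ELF channel.

    The background is estimated as a median filter of window
    ``object_size`` (objects up to roughly that size vanish from the
    estimate), smoothed with a Gaussian scaled from ``smoothing_size``; the
    corrected image is the input minus this estimate, clipped at zero.
    """
    if object_size < 1 or smoothing_size < 1:
        raise ValueError("filter sizes must be >= 1")
    img = np.asarray(elf, dtype=float)
    background = ndi.median_filter(img, size=object_size * 2 + 1)
    background = gaussian(background, sigma=smoothing_size / 4.0, preserve_range=True)
    return np.clip(img - background, 0.0, None)


def detect_spots_background_global(
    elf_corrected: np.ndarray, params: DetectionParams
) -> LabelMap:
    """Detect ALP spots with a single "background" global threshold.

    The threshold is ``background_mode_multiplier`` x the mode of the
    lightly smoothed intensity histogram — the convention of background
    global thresholding, which assumes most pixels are background.  No size
    gate is applied in this mode.  An all-background image yields zero
    objects.
    """
    img = np.asarray(elf_corrected, dtype=float)
    if img.max() <= 0:
        return LabelMap(np.zeros(img.shape, dtype=np.int32), 0)
    smoothed = gaussian(img, sigma=params.median_smoothing_size / 20.0, preserve_range=True)
    hist, edges = np.histogram(smoothed, bins=256, range=(0.0, float(smoothed.max())))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    thr = params.background_mode_multiplier * mode
    # threshold estimated on the smoothed histogram, applied to the
    # unsmoothed image: smoothing tails would otherwise bridge close spots
    mask = img > thr
    return LabelMap.from_mask(mask)


# ---------------------------------------------------------------------------
# round-object pipeline

def tophat_correct(raster: np.ndarray, feature_size: int) -> np.ndarray:
    """White top-hat background correction with a disk of the given feature size (px)."""
    if feature_size < 1:
        raise ValueError("feature_size must be >= 1")
    img = np.asarray(raster, dtype=float)
    footprint = morphology.disk(
        max(1, int(round(feature_size / 2))), decomposition="sequence"
    )
    return morphology.white_tophat(img, footprint=footprint)


def _circularity(prop) -> float:
    perim = prop.perimeter
    if perim == 0:
        return 1.0  # single pixel / degenerate: treat as round
    return float(4.0 * np.pi * prop.area / perim**2)


def detect_round_objects(
    raster: np.ndarray,
    size_um_range: tuple[float, float],
    intensity_threshold_au: float,
    pixel_size_um: float,
    circularity_min: float = 0.6,
) -> LabelMap:
    """Round-object detection: threshold, then size and roundness gates.

    Objects are connected components of pixels above the intensity
    threshold whose equivalent diameter lies within ``size_um_range`` and
    whose circularity (4*pi*area/perimeter^2) is at least
    ``circularity_min``.
    """
    img = np.asarray(raster, dtype=float)
    mask = img > intensity_threshold_au
    lab = sk_label(mask)
    lo, hi = size_um_range
    out = lab.copy()
    for p in regionprops(lab):
        d_um = p.equivalent_diameter_area * pixel_size_um
        if not lo <= d_um <= hi or _circularity(p) < circularity_min:
            out[lab == p.label] = 0
    return LabelMap.from_labels(out)


# ---------------------------------------------------------------------------
# Ki67

def classify_ki67(
    nuclei: LabelMap, ki67: np.ndarray, threshold_au: float = 300.0
) -> tuple[np.ndarray, int]:
    """Per-nucleus Ki67 positivity: mean intensity strictly above threshold.

    Returns a boolean array indexed by label-1 and the positive count.
    """
    img = np.asarray(ki67, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise ValueError("ki67 raster shape does not match label map")
    if nuclei.object_count == 0:
        return np.zeros(0, dtype=bool), 0
    means = ndi.mean(img, labels=nuclei.labels, index=np.arange(1, nuclei.object_count + 1))
    positive = np.asarray(means) > threshold_au
    return positive, int(positive.sum())


# ---------------------------------------------------------------------------
# per-field pipeline dispatch

def segment_field(
    field: FieldImage, params: DetectionParams
) -> tuple[LabelMap, LabelMap, np.ndarray, int | None]:
    """Run the configured pipeline on one field.

    Returns ``(nuclei, spots, elf_corrected, ki67_positive_count)`` where
    ``elf_corrected`` is the background-corrected ELF raster the ALP
    statistic sums over, and the Ki67 count is ``None`` when the channel is
    absent.
    """
    px = field.pixel_size_um
    nuclear = np.asarray(field.channels["nuclear"], dtype=float)
    elf = np.asarray(field.channels["elf"], dtype=float)
    ki67 = field.channels.get("ki67")

    if params.mode == DetectionMode.THRESHOLD:
        nuclei = segment_nuclei_otsu(nuclear, params, px)
        elf_corrected = correct_background_median(
            elf, params.median_object_size, params.median_smoothing_size
        )
        spots = detect_spots_background_global(elf_corrected, params)
        ki67_img = (
            correct_background_median(
                np.asarray(ki67, dtype=float),
                params.median_object_size,
                params.median_smoothing_size,
            )
            if ki67 is not None
            else None
        )
    else:
        nuc_corrected = tophat_correct(nuclear, params.tophat_feature_size_nuclear)
        nuclei_lab = detect_round_objects(
            nuc_corrected,
            params.nuclei_size_um,
            params.nuclei_intensity_threshold_au,
            px,
            params.circularity_min,
        )
        nuclei = nuclei_lab
        elf_corrected = tophat_correct(elf, params.tophat_feature_size_elf)
        spot_stage = tophat_correct(elf_corrected, params.tophat_feature_size_spot)
        spots = detect_round_objects(
            spot_stage,
            params.spot_size_um,
            params.spot_intensity_threshold_au,
            px,
            params.circularity_min,
        )
        ki67_img = (
            tophat_correct(np.asarray(ki67, dtype=float), params.tophat_feature_size_ki67)
            if ki67 is not None
            else None
        )

    ki67_count: int | None = None
    if ki67_img is not None:
        _, ki67_count = classify_ki67(nuclei, ki67_img, params.ki67_positive_threshold_au)
    return nuclei, spots, elf_corrected, ki67_count
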