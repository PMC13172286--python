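"""Fixed-geometry ROI construction and SNR / uniformity metrics.

ROIs are physical circles: an area-defined ROI of A mm² has radius
r = sqrt(A/pi) mm, converted per image axis to pixels through the DICOM
pixel spacing, so anisotropic spacing yields an ellipse in index space
that preserves the physical circle.  The standard large ROI is 340 cm²
(34 000 mm²); element-level peak ROIs have a fixed 3 mm radius centered
on the brightest in-phantom pixel.

Metric conventions
------------------
* Single-image SNR = ROI mean / ROI standard deviation (population, n
  divisor), the reconstruction of the weekly-QA report row.
* Two-image SNR = correction x signal-ROI mean / noise-ROI SD, with the
  correction factor defaulting to 1.0 (set e.g. 0.66 for a Rayleigh
  background).
* PIU = 100 x (1 - (Smax - Smin)/(Smax + Smin)), the NEMA
  percent-integral-uniformity form; 100 is perfectly uniform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from mrcoilqa.dicom_io import SliceMeta
from mrcoilqa.errors import DegenerateInputError, GeometryError
from mrcoilqa.phantom_detect import PhantomMask

logger = logging.getLogger(__name__)

STANDARD_ROI_AREA_MM2 = 34_000.0  # 340 cm^2
ELEMENT_ROI_RADIUS_MM = 3.0

RoiKind = Literal["noise_image_center", "signal_in_phantom", "element_peak"]


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI in physical units anchored at a pixel location."""

    kind: RoiKind
    center_rc: tuple[float, float]
    radius_mm: float
    area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.area_mm2 is not None:
            expected = math.sqrt(self.area_mm2 / math.pi)
            if not math.isclose(self.radius_mm, expected, rel_tol=1e-9):
                raise GeometryError(
                    f"radius {self.radius_mm} mm inconsistent with area "
                    f"{self.area_mm2} mm² (expected {expected:.6f} mm)"
                )


@dataclass(frozen=True)
class RoiStats:
    """Pixel statistics over an ROI (SD is population, divisor n)."""

    mean: float
    min: float
    max: float
    sum: float
    sd: float
    n_px: int


@dataclass(frozen=True)
class QaMetrics:
    """Derived image-quality metrics for one acquisition."""

    snr: float
    piu: float | None = None


def radius_px(area_mm2: float, meta: SliceMeta) -> tuple[float, float]:
    """Per-axis pixel radii of a physical circle of the given area.

    radius_mm = sqrt(area/pi); the row/column radii divide by the spacing
    on that axis, so the physical circle is preserved even when pixel
    spacing is anisotropic.
    """
    if area_mm2 <= 0:
        raise ValueError(f"ROI area must be positive, got {area_mm2}")
    r_mm = math.sqrt(area_mm2 / math.pi)
    return r_mm / meta.pixel_spacing_row, r_mm / meta.pixel_spacing_col


def make_roi_mask(
    spec: RoiSpec, meta: SliceMeta, image_shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize an ROI: pixel centers within radius_mm of the center.

    A pixel (i, j) is included iff
    ``((i-ci)*sr)^2 + ((j-cj)*sc)^2 <= radius_mm^2``
    with sr/sc the row/column pixel spacing.

    Raises
    ------
    GeometryError
        If the ROI extends beyond the image bounds.
    """
    rows, cols = image_shape
    ci, cj = spec.center_rc
    rr_px = spec.radius_mm / meta.pixel_spacing_row
    rc_px = spec.radius_mm / meta.pixel_spacing_col

    lo_r, hi_r = ci - rr_px, ci + rr_px
    lo_c, hi_c = cj - rc_px, cj + rc_px
    if lo_r < -0.5 or hi_r > rows - 0.5 or lo_c < -0.5 or hi_c > cols - 0.5:
        raise GeometryError(
            f"{spec.kind} ROI (center ({ci:.1f}, {cj:.1f}), radius "
            f"{spec.radius_mm:.2f} mm) extends beyond the {rows}x{cols} image: "
            f"rows [{lo_r:.1f}, {hi_r:.1f}], cols [{lo_c:.1f}, {hi_c:.1f}]"
        )

    i = np.arange(rows, dtype=np.float64)[:, None]
    j = np.arange(cols, dtype=np.float64)[None, :]
    d2 = ((i - ci) * meta.pixel_spacing_row) ** 2 + ((j - cj) * meta.pixel_spacing_col) ** 2
    return d2 <= spec.radius_mm**2


def noise_roi_spec(meta: SliceMeta, area_mm2: float = STANDARD_ROI_AREA_MM2) -> RoiSpec:
    """Standard noise ROI: fixed-area circle at the geometric image center."""
    center = ((meta.rows - 1) / 2.0, (meta.cols - 1) / 2.0)
    return RoiSpec(
        kind="noise_image_center",
        center_rc=center,
        radius_mm=math.sqrt(area_mm2 / math.pi),
        area_mm2=area_mm2,
    )


def place_signal_roi(
    mask: PhantomMask,
    area_mm2: float = STANDARD_ROI_AREA_MM2,
    meta: SliceMeta | None = None,
    *,
    strict_containment: bool = False,
) -> RoiSpec:
    """Fixed-area signal ROI centered at the phantom centroid.

    When part of the ROI falls outside the phantom mask a containment
    warning is logged; with ``strict_containment=True`` this becomes a
    GeometryError instead.
    """
    if meta is None:
        raise ValueError("meta is required to check ROI containment")
    spec = RoiSpec(
        kind="signal_in_phantom",
        center_rc=mask.centroid_rc,
        radius_mm=math.sqrt(area_mm2 / math.pi),
        area_mm2=area_mm2,
    )
    roi = make_roi_mask(spec, meta, mask.mask.shape)
    outside = int(np.count_nonzero(roi & ~mask.mask))
    if outside:
        msg = (
            f"signal ROI not contained in phantom: {outside} of "
            f"{int(roi.sum())} ROI pixels fall outside the mask"
        )
        if strict_containment:
            raise GeometryError(msg)
        logger.warning(msg)
    return spec


def place_element_roi(
    image: np.ndarray, mask: PhantomMask, meta: SliceMeta
) -> RoiSpec:
    """3 mm-radius ROI at the brightest pixel inside the phantom.

    The maximum is taken over the phantom mask only; ties go to the
    smallest (row, col) in lexicographic order.
    """
    if not mask.mask.any():
        raise GeometryError("cannot place element ROI: empty phantom mask")
    masked = np.where(mask.mask, np.asarray(image, dtype=np.float64), -np.inf)
    # argmax of the flattened array is already the lexicographic tie-break
    flat_idx = int(np.argmax(masked))
    center = np.unravel_index(flat_idx, masked.shape)
    return RoiSpec(
        kind="element_peak",
        center_rc=(float(center[0]), float(center[1])),
        radius_mm=ELEMENT_ROI_RADIUS_MM,
    )


def roi_stats(image: np.ndarray, roi_mask: np.ndarray) -> RoiStats:
    """Mean / min / max / sum / population SD over the ROI pixels."""
    values = np.asarray(image, dtype=np.float64)[np.asarray(roi_mask, dtype=bool)]
    if values.size == 0:
        raise ValueError("ROI mask selects no pixels")
    return RoiStats(
        mean=float(values.mean()),
        min=float(values.min()),
        max=float(values.max()),
        sum=float(values.sum()),
        sd=float(values.std(ddof=0)),
        n_px=int(values.size),
    )


def snr_single_image(stats: RoiStats) -> float:
    """Single-acquisition SNR: ROI mean over ROI (population) SD."""
    if stats.sd <= 0:
        raise DegenerateInputError(
            "ROI standard deviation is zero; image looks constant/synthetic"
        )
    return stats.mean / stats.sd


def snr_two_image(
    signal_stats: RoiStats, noise_stats: RoiStats, correction: float = 1.0
) -> float:
    """Two-acquisition SNR: correction x signal mean / noise SD.

    The default correction is 1.0; pass e.g. 0.66 to apply a
    Rayleigh-background factor for magnitude-image noise.
    """
    if noise_stats.sd <= 0:
        raise DegenerateInputError("noise ROI standard deviation is zero")
    return correction * signal_stats.mean / noise_stats.sd


def piu(stats: RoiStats) -> float:
    """Percent image uniformity: 100 x (1 - (Smax-Smin)/(Smax+Smin)).

    For a NEMA-style low-pass before the min/max, compute ``stats`` with
    :func:`smoothed_roi_stats` (off by default in all workflows).
    """
    if stats.max + stats.min <= 0:
        raise ValueError(
            f"PIU undefined for Smax + Smin = {stats.max + stats.min} (<= 0)"
        )
    return 100.0 * (1.0 - (stats.max - stats.min) / (stats.max + stats.min))


def smoothed_roi_stats(image: np.ndarray, roi_mask: np.ndarray) -> RoiStats:
    """ROI statistics after a 3x3 mean filter (optional NEMA-style low-pass).

    Off by default in all workflows; provided because uniformity methods
    commonly low-pass before taking min/max.
    """
    filtered = ndimage.uniform_filter(np.asarray(image, dtype=np.float64), size=3)
    return roi_stats(filtered, roi_mask)
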