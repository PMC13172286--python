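"""Phantom localization: Otsu thresholding, morphological refinement, and
representative-slice selection.

The phantom is assumed to be a single bright connected object on a dark
background.  Segmentation binarizes at the Otsu threshold (256-bin
histogram over the intensity range), fills holes, applies a morphological
opening with a disk of radius 2 px, and keeps the largest 8-connected
component.  The representative slice of a multi-slice series is the one
with the highest mean intensity inside its own phantom mask; near-ties are
broken by proximity to the isocenter (slice location 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from mrcoilqa.dicom_io import ImageSeries, SliceMeta
from mrcoilqa.errors import DegenerateInputError, SegmentationError

logger = logging.getLogger(__name__)

OTSU_BINS = 256
OPENING_RADIUS_PX = 2
MIN_AREA_FRACTION = 0.01
TIE_RTOL = 1e-3  # relative tolerance treating two slice means as tied


@dataclass(frozen=True)
class PhantomMask:
    """Binary phantom segmentation with summary geometry.

    ``boundary_ok`` is False when the detected component touches the image
    border or covers less than 1% of the image — both signs that the
    segmentation cannot be trusted for ROI placement.
    """

    mask: np.ndarray
    centroid_rc: tuple[float, float]
    area_px: int
    area_mm2: float
    boundary_ok: bool


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the value range.

    Returns the bin edge maximizing the between-class variance of the
    two-class split.  Deterministic for a given input.

    Raises
    ------
    DegenerateInputError
        If all values are identical (no two classes to separate).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2 or np.min(values) == np.max(values):
        raise DegenerateInputError("cannot threshold a constant image")
    return float(threshold_otsu(values, nbins=OTSU_BINS))


def segment_phantom(image: np.ndarray, meta: SliceMeta) -> PhantomMask:
    """Segment the phantom in one slice.

    Binarize at the Otsu threshold, fill interior holes, open with a
    radius-2 disk, and keep the largest 8-connected component.

    Raises
    ------
    DegenerateInputError
        Constant image.
    SegmentationError
        Nothing remains after morphological refinement.
    """
    image = np.asarray(image, dtype=np.float64)
    thr = otsu_threshold(image)
    binary = image > thr

    filled = ndimage.binary_fill_holes(binary)
    opened = morphology.opening(filled, morphology.disk(OPENING_RADIUS_PX))

    labels, n = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise SegmentationError("no phantom component survived morphological refinement")
    counts = np.bincount(labels.ravel())[1:]
    mask = labels == (int(np.argmax(counts)) + 1)

    area_px = int(mask.sum())
    centroid = ndimage.center_of_mass(mask)
    touches_border = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    boundary_ok = (not touches_border) and (area_px >= MIN_AREA_FRACTION * mask.size)

    return PhantomMask(
        mask=mask,
        centroid_rc=(float(centroid[0]), float(centroid[1])),
        area_px=area_px,
        area_mm2=area_px * meta.pixel_spacing_row * meta.pixel_spacing_col,
        boundary_ok=boundary_ok,
    )


def select_slice(series: ImageSeries) -> int:
    """Index of the representative slice of a series.

    For each slice the mean intensity inside its phantom mask is computed;
    the slice with the highest mean wins.  Means within 0.1% (relative) of
    the best are treated as tied and the tie goes to the slice closest to
    the isocenter (smallest |slice location|).  A single-slice series
    returns 0 without segmenting.

    Raises
    ------
    SegmentationError
        If every slice fails segmentation.
    """
    if len(series) == 1:
        return 0

    means: list[tuple[int, float, float]] = []  # (index, mean, |location|)
    for i, (img, meta) in enumerate(zip(series.slices, series.meta)):
        try:
            pm = segment_phantom(img, meta)
        except (DegenerateInputError, SegmentationError) as exc:
            logger.warning("slice %d: segmentation failed (%s)", i, exc)
            continue
        means.append((i, float(img[pm.mask].mean()), abs(meta.slice_location)))

    if not means:
        raise SegmentationError("phantom segmentation failed on every slice")

    best_mean = max(m for _, m, _ in means)
    candidates = [t for t in means if t[1] >= best_mean * (1.0 - TIE_RTOL)]
    candidates.sort(key=lambda t: (t[2], t[0]))
    return candidates[0][0]
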