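"""DICOM ingestion: read, validate, and rescale phantom image series.

Stored pixel values are converted to double-precision floats as
``stored * RescaleSlope + RescaleIntercept`` and slices are ordered by
SliceLocation (ascending, ties broken by InstanceNumber) so that repeated
reads of the same files yield identical arrays in identical order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from mrcoilqa.coils import COIL_ELEMENTS, extract_element_label
from mrcoilqa.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

# ViewRay/Siemens private tag carrying the receive-element name.
COIL_PRIVATE_TAG = (0x0051, 0x100F)

_ORIENTATION_WORDS = {
    "transverse": "transverse",
    "tra": "transverse",
    "axial": "transverse",
    "ax": "transverse",
    "sagittal": "sagittal",
    "sag": "sagittal",
    "coronal": "coronal",
    "cor": "coronal",
}


def _orientation_from_iop(iop: list[float]) -> str | None:
    """Classify slice orientation from ImageOrientationPatient cosines.

    The slice normal (row x col direction) is compared to the patient
    axes: dominant z -> transverse, x -> sagittal, y -> coronal.
    """
    row = np.asarray(iop[:3], dtype=float)
    col = np.asarray(iop[3:], dtype=float)
    normal = np.abs(np.cross(row, col))
    axis = int(np.argmax(normal))
    if normal[axis] < 0.8:  # oblique: do not guess
        return None
    return ("sagittal", "coronal", "transverse")[axis]


def _orientation_from_text(text: str) -> str | None:
    for token in re.split(r"[^a-z]+", (text or "").lower()):
        if token in _ORIENTATION_WORDS:
            return _ORIENTATION_WORDS[token]
    return None


@dataclass(frozen=True)
class SliceMeta:
    """Per-slice geometry and identification metadata.

    Attributes
    ----------
    pixel_spacing_row, pixel_spacing_col : float
        Physical size of a pixel along image rows / columns, mm.
    slice_location : float
        Signed position along the slice axis, mm; 0 is taken as isocenter.
    rescale_slope, rescale_intercept : float
        Linear map from stored values to output units (defaults 1.0 / 0.0).
    rows, cols : int
        Image matrix size.
    series_label : str
        SeriesDescription, or the filename stem when absent.
    coil_id : str or None
        Receive coil/element identifier, from the private tag (0051,100F)
        when present, else parsed from the series description.
    instance_number : int
        DICOM InstanceNumber, used only as a deterministic sort tie-break.
    """

    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_location: float
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    rows: int = 0
    cols: int = 0
    series_label: str = ""
    coil_id: str | None = None
    instance_number: int = 0
    orientation: str | None = None  # transverse | sagittal | coronal
    source_file: str = ""  # basename of the file the slice came from

    def __post_init__(self) -> None:
        if self.pixel_spacing_row <= 0 or self.pixel_spacing_col <= 0:
            raise ValidationError(
                f"PixelSpacing must be positive, got "
                f"({self.pixel_spacing_row}, {self.pixel_spacing_col})"
            )


@dataclass
class ImageSeries:
    """An ordered stack of rescaled floating-point slices with metadata."""

    slices: list[np.ndarray] = field(default_factory=list)
    meta: list[SliceMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slices) != len(self.meta):
            raise ValidationError(
                f"{len(self.slices)} slices but {len(self.meta)} metadata records"
            )
        if len(self.slices) < 1:
            raise ValidationError("a series must contain at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValidationError(f"inconsistent slice shapes: {sorted(shapes)}")
        spacings = {(m.pixel_spacing_row, m.pixel_spacing_col) for m in self.meta}
        if len(spacings) > 1:
            raise ValidationError(f"inconsistent PixelSpacing: {sorted(spacings)}")

    def __len__(self) -> int:
        return len(self.slices)


def _collect_dicom_paths(path: Path) -> list[Path]:
    if path.is_file():
        return [path]
    if path.is_dir():
        skip = {".json", ".csv", ".png", ".txt"}  # manifests / report sidecars
        found = sorted(
            p for p in path.iterdir()
            if p.is_file() and p.suffix.lower() not in skip
        )
        if not found:
            raise FormatError(f"no DICOM files found in {path}")
        return found
    raise FormatError(f"no such file or directory: {path}")


def _read_one(fp: Path) -> tuple[np.ndarray, SliceMeta, bool]:
    """Read one file; returns (pixels, meta, had_slice_location)."""
    try:
        ds = pydicom.dcmread(fp)
    except InvalidDicomError as exc:
        raise FormatError(f"{fp}: not a DICOM file ({exc})") from exc

    if "PixelData" not in ds:
        raise FormatError(f"{fp}: missing pixel data")
    try:
        stored = ds.pixel_array
    except Exception as exc:  # unsupported transfer syntax etc.
        raise FormatError(f"{fp}: cannot decode pixel data ({exc})") from exc
    if stored.ndim != 2:
        raise FormatError(f"{fp}: expected a single-frame 2-D image, got shape {stored.shape}")

    if "PixelSpacing" not in ds:
        raise ValidationError(f"{fp}: missing required attribute PixelSpacing")
    spacing = [float(v) for v in ds.PixelSpacing]

    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    pixels = stored.astype(np.float64) * slope + intercept

    has_loc = "SliceLocation" in ds
    loc = float(ds.SliceLocation) if has_loc else 0.0

    label = str(getattr(ds, "SeriesDescription", "") or fp.stem)
    coil_id: str | None = None
    if COIL_PRIVATE_TAG in ds:
        raw = ds[COIL_PRIVATE_TAG].value
        coil_id = raw.decode() if isinstance(raw, bytes) else str(raw)
        coil_id = coil_id.strip() or None
    if coil_id is None:
        coil_id = extract_element_label(label)

    orientation: str | None = None
    if "ImageOrientationPatient" in ds:
        orientation = _orientation_from_iop([float(v) for v in ds.ImageOrientationPatient])
    if orientation is None:
        orientation = _orientation_from_text(label) or _orientation_from_text(fp.stem)

    meta = SliceMeta(
        pixel_spacing_row=spacing[0],
        pixel_spacing_col=spacing[1],
        slice_location=loc,
        rescale_slope=slope,
        rescale_intercept=intercept,
        rows=int(ds.Rows),
        cols=int(ds.Columns),
        series_label=label,
        coil_id=coil_id,
        instance_number=int(getattr(ds, "InstanceNumber", 0) or 0),
        orientation=orientation,
        source_file=fp.name,
    )
    return pixels, meta, has_loc


def read_series(path: str | Path) -> ImageSeries:
    """Read a DICOM file or a directory of DICOM files into an ImageSeries.

    Pixel values are rescaled to floats, slices are sorted by slice
    location ascending (ties by instance number), and the coil element
    identifier is populated from the private tag (0051,100F) when present,
    falling back to the series description.

    Raises
    ------
    FormatError
        For unreadable files, missing pixel data, or unsupported encodings.
    ValidationError
        For missing PixelSpacing or inconsistent geometry across slices.
    """
    paths = _collect_dicom_paths(Path(path))
    records = [_read_one(p) for p in paths]

    missing_loc = [i for i, (_, _, has) in enumerate(records) if not has]
    if missing_loc:
        if len(records) > 1:
            raise ValidationError(
                f"multi-slice series with {len(missing_loc)} slice(s) missing "
                "SliceLocation; slice selection requires it"
            )
        logger.warning("single-slice series missing SliceLocation; assuming 0.0")

    records.sort(key=lambda r: (r[1].slice_location, r[1].instance_number))
    return ImageSeries(
        slices=[r[0] for r in records],
        meta=[r[1] for r in records],
    )


def validate_series(series: ImageSeries, workflow: str) -> list[str]:
    """Soft-check a series against a workflow's structural expectations.

    Returns a list of human-readable messages, empty when the series
    matches what the workflow expects.  Never raises for soft violations.

    Workflows: ``weekly`` and ``body`` expect at least one slice; ``torso``
    and ``head_neck`` per-element runs expect one labeled acquisition per
    coil element (12 and 10 respectively).
    """
    messages: list[str] = []
    if workflow in ("weekly", "body"):
        return messages

    if workflow in COIL_ELEMENTS:
        expected = COIL_ELEMENTS[workflow]
        # paired noise-only acquisitions carry the same element label;
        # only signal acquisitions count toward the expected set
        present = [
            m.coil_id
            for m in series.meta
            if m.coil_id and "noise" not in f"{m.series_label} {m.source_file}".lower()
        ]
        present_set = set(present)
        for label in expected:
            if label not in present_set:
                messages.append(f"{workflow}: missing element acquisition {label}")
        for label in sorted(present_set - set(expected)):
            messages.append(f"{workflow}: unexpected element label {label}")
        if len(present) != len(present_set):
            messages.append(f"{workflow}: duplicate element labels present")
        return messages

    messages.append(f"unknown workflow id: {workflow}")
    return messages
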