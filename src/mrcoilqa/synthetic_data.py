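"""Synthetic phantom images and FID signals with known ground truth.

The generators emulate the acquisitions the QA workflows consume:

* a bright uniform disk (the fluid phantom) on a dark background, with an
  optional radial parabolic bias field, Gaussian or Rician noise, written
  as DICOM Part-10 files;
* per-element acquisitions with a localized sensitivity hot spot and a
  paired noise-only image per element;
* mono-exponentially decaying complex sinusoid FIDs whose spectrum is a
  Lorentzian of known center (the frequency offset) and known linewidth
  FWHM = 1/(pi*T2*), written in the open FID container.

Every generator is a pure function of its spec: a fixed seed yields
byte-identical output files, and each writer returns a JSON-serializable
manifest of the ground truth (true SNR, disk area and centroid, analytic
linewidths) for parameter-recovery tests.

Pixel quantization: DICOM stores integers, so each float image is mapped
to uint16 through a per-file RescaleSlope/Intercept chosen to span the
image range; the manifest's ground truth refers to the underlying
continuous model, while round-trip tests compare against the quantized
values the writer itself reports (exact by construction).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from mrcoilqa.coils import COIL_ELEMENTS
from mrcoilqa.dicom_io import COIL_PRIVATE_TAG
from mrcoilqa.fid_homogeneity import FidRecord, write_fid

# Rayleigh-background SD factor: sqrt(2 - pi/2), the SD of the magnitude
# of a complex Gaussian with per-channel sigma 1.
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)

_IOP = {
    "transverse": [1, 0, 0, 0, 1, 0],
    "sagittal": [0, 1, 0, 0, 0, -1],
    "coronal": [1, 0, 0, 0, 0, -1],
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic uniform-disk phantom acquisition.

    Defaults mirror a weekly body-phantom SSFP slice on a 0.35 T system:
    256x256 matrix at 1.5 mm spacing, a 120 mm-radius disk of signal 400
    on a background of 5, Gaussian noise sigma 18.5.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_spacing: float = 1.5  # mm, isotropic
    disk_center_rc: tuple[float, float] | None = None  # None -> image center
    disk_radius_mm: float = 120.0
    signal_level: float = 400.0
    background_level: float = 5.0
    noise_sigma: float = 18.5
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    bias_field_amplitude: float = 0.0  # center-to-edge fractional falloff
    n_slices: int = 1
    slice_spacing: float = 5.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.signal_level > self.background_level >= 0:
            raise ValueError(
                "require signal_level > background_level >= 0, got "
                f"{self.signal_level} / {self.background_level}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0 <= self.bias_field_amplitude < 1:
            raise ValueError("bias_field_amplitude must be in [0, 1)")

    @property
    def center_rc(self) -> tuple[float, float]:
        if self.disk_center_rc is not None:
            return self.disk_center_rc
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)


@dataclass(frozen=True)
class FidSpec:
    """Parameters of a synthetic FID: exp(-t/T2*) * exp(2i*pi*df*t) + noise.

    Defaults describe a well-shimmed 0.35 T magnet: T2* = 25 ms gives a
    Lorentzian linewidth of 1/(pi*T2*) ~ 12.7 Hz ~ 0.85 ppm at 14.9 MHz.
    """

    n_samples: int = 4096
    dwell_time_s: float = 1e-4
    t2_star_s: float = 0.025
    freq_offset_hz: float = 30.0
    reference_frequency_hz: float = 14.9e6
    gantry_angle_deg: float = 0.0
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t2_star_s <= 0:
            raise ValueError(f"t2_star_s must be positive, got {self.t2_star_s}")
        if self.n_samples < 64:
            raise ValueError(f"n_samples must be >= 64, got {self.n_samples}")

    @property
    def analytic_fwhm_hz(self) -> float:
        return 1.0 / (math.pi * self.t2_star_s)


def disk_mask(spec: PhantomSpec) -> np.ndarray:
    """True where pixel centers lie inside the disk (same rasterization
    rule the ROI code uses)."""
    rows, cols = spec.image_shape
    ci, cj = spec.center_rc
    i = np.arange(rows, dtype=np.float64)[:, None]
    j = np.arange(cols, dtype=np.float64)[None, :]
    d2 = ((i - ci) * spec.pixel_spacing) ** 2 + ((j - cj) * spec.pixel_spacing) ** 2
    return d2 <= spec.disk_radius_mm**2


def make_phantom_image(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One noisy phantom slice as a float array (no DICOM quantization).

    The bias field multiplies the in-disk signal by
    ``1 - a * (d / disk_radius)**2`` with d the distance to the disk
    center, so the modulation runs from 1 at the center to ``1 - a`` at
    the disk edge.  Rician noise is the magnitude of the image plus a
    complex Gaussian of per-channel sigma ``noise_sigma``.
    """
    rows, cols = spec.image_shape
    ci, cj = spec.center_rc
    i = np.arange(rows, dtype=np.float64)[:, None]
    j = np.arange(cols, dtype=np.float64)[None, :]
    d2_mm2 = ((i - ci) * spec.pixel_spacing) ** 2 + ((j - cj) * spec.pixel_spacing) ** 2
    inside = d2_mm2 <= spec.disk_radius_mm**2

    signal = spec.signal_level * (
        1.0 - spec.bias_field_amplitude * d2_mm2 / spec.disk_radius_mm**2
    )
    image = np.where(inside, signal, spec.background_level)

    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
        elif spec.noise_model == "rician":
            re = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
            im = rng.normal(0.0, spec.noise_sigma, size=image.shape)
            image = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise model: {spec.noise_model}")
    return image


def _quantize(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map a float image to uint16 stored values + rescale slope/intercept."""
    vmin = float(image.min())
    vmax = float(image.max())
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    stored = np.rint((image - vmin) / slope).astype(np.uint16)
    return stored, slope, vmin


def _write_dicom(
    path: Path,
    image: np.ndarray,
    *,
    pixel_spacing: float,
    slice_location: float,
    series_label: str,
    instance_number: int,
    uid_tag: str,
    coil_id: str | None = None,
    orientation: str | None = None,
) -> np.ndarray:
    """Write one quantized slice as DICOM; returns the values a reader
    recovers after rescale (stored * slope + intercept)."""
    stored, slope, intercept = _quantize(image)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[uid_tag, "sop"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), Dataset(), file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[uid_tag, "series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[uid_tag, "study"])
    ds.Modality = "MR"
    ds.SeriesDescription = series_label
    ds.InstanceNumber = instance_number
    ds.ContentDate = "20000101"
    ds.ContentTime = "000000"

    ds.Rows, ds.Columns = image.shape
    ds.PixelSpacing = [pixel_spacing, pixel_spacing]
    ds.SliceLocation = slice_location
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = stored.tobytes()
    if orientation is not None:
        ds.ImageOrientationPatient = _IOP[orientation]
    if coil_id is not None:
        ds.add_new(COIL_PRIVATE_TAG, "LO", coil_id)

    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return stored.astype(np.float64) * slope + intercept


def make_phantom_series(
    spec: PhantomSpec,
    out_dir: str | Path,
    *,
    series_label: str = "weekly phantom",
    orientation: str | None = "transverse",
) -> dict:
    """Write a phantom series as DICOM files plus a ground-truth manifest.

    Slice locations are centered on the isocenter (location 0).  The
    manifest records the generator parameters and the analytic truth:
    disk centroid and area, in-disk mean, the model SNR
    (signal / noise SD, with the Rayleigh SD for Rician noise), and the
    analytic uniformity of the bias field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n = spec.n_slices
    locations = [(k - (n - 1) / 2.0) * spec.slice_spacing for k in range(n)]
    files = []
    for k, loc in enumerate(locations):
        image = make_phantom_image(spec, rng)
        fp = out_dir / f"slice_{k:03d}.dcm"
        _write_dicom(
            fp,
            image,
            pixel_spacing=spec.pixel_spacing,
            slice_location=loc,
            series_label=series_label,
            instance_number=k + 1,
            uid_tag=f"mrcoilqa-{spec.seed}-{series_label}-{k}",
            orientation=orientation,
        )
        files.append(fp.name)

    if spec.noise_model == "rician":
        noise_sd = RAYLEIGH_SD_FACTOR * spec.noise_sigma
    else:
        noise_sd = spec.noise_sigma
    a = spec.bias_field_amplitude
    manifest = {
        "spec": _spec_dict(spec),
        "files": files,
        "slice_locations": locations,
        "true_centroid_rc": list(spec.center_rc),
        "true_area_mm2": math.pi * spec.disk_radius_mm**2,
        "true_snr": (spec.signal_level / noise_sd) if noise_sd > 0 else None,
        "analytic_piu": 100.0 * (1.0 - a / (2.0 - a)),
        "analytic_fwhm_hz": None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_noise_series(
    spec: PhantomSpec,
    out_dir: str | Path,
    *,
    series_label: str = "noise",
    orientation: str | None = "transverse",
) -> dict:
    """Write a noise-only acquisition (no phantom signal) matching ``spec``'s
    geometry and noise model; returns its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape

    if spec.noise_model == "rician":
        re = rng.normal(0.0, spec.noise_sigma, size=(rows, cols))
        im = rng.normal(0.0, spec.noise_sigma, size=(rows, cols))
        image = np.hypot(re, im)
        noise_sd = RAYLEIGH_SD_FACTOR * spec.noise_sigma
    else:
        image = rng.normal(0.0, spec.noise_sigma, size=(rows, cols))
        noise_sd = spec.noise_sigma

    fp = out_dir / "noise_000.dcm"
    _write_dicom(
        fp,
        image,
        pixel_spacing=spec.pixel_spacing,
        slice_location=0.0,
        series_label=series_label,
        instance_number=1,
        uid_tag=f"mrcoilqa-{spec.seed}-{series_label}-noise",
        orientation=orientation,
    )
    manifest = {
        "spec": _spec_dict(spec),
        "files": [fp.name],
        "true_noise_sd": noise_sd,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_element_set(
    coil: str,
    base_spec: PhantomSpec,
    out_dir: str | Path,
    *,
    target_snr: float | dict[str, float] = 60.0,
) -> dict:
    """Write one labeled acquisition per coil element plus paired noise images.

    Each element image is the base phantom with a broad quadratic
    sensitivity hot spot at a distinct location inside the phantom:
    ``value(d) = peak * (1 - (d/w)**2)`` with w = 30 mm, taken where it
    exceeds the base disk signal.  The apex ``peak = target_snr x noise
    SD``, so the element's two-image SNR (3 mm peak-ROI mean over noise
    SD) has a known truth; the gentle curvature keeps the detected peak
    near the apex and the ROI droop below ~3%.  A noise-only image is
    written alongside each element (``<label>_noise``), emulating the
    paired noise acquisition element SNR is measured against.  The
    manifest records per-element hot-spot positions and target SNRs.

    The apex must dominate the disk (peak >= 1.15 x signal_level) or the
    brightest pixel would be a noise excursion elsewhere in the phantom;
    a ValueError states the minimum feasible target SNR.
    """
    if coil not in COIL_ELEMENTS:
        raise ValueError(f"unknown coil id: {coil!r} (expected torso or head_neck)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = COIL_ELEMENTS[coil]
    rows, cols = base_spec.image_shape
    ci, cj = base_spec.center_rc

    hot_spot_width_mm = 30.0

    elements: dict[str, dict] = {}
    for idx, label in enumerate(labels):
        snr_target = target_snr[label] if isinstance(target_snr, dict) else target_snr
        if base_spec.noise_model == "rician":
            noise_sd = RAYLEIGH_SD_FACTOR * base_spec.noise_sigma
        else:
            noise_sd = base_spec.noise_sigma
        # noiseless sets (closed-form/geometry tests) have no SNR notion;
        # the apex is pinned at twice the disk signal instead
        peak_level = (
            snr_target * noise_sd if noise_sd > 0 else 2.0 * base_spec.signal_level
        )
        if noise_sd > 0 and peak_level < 1.15 * base_spec.signal_level:
            raise ValueError(
                f"element {label}: target SNR {snr_target} puts the hot-spot "
                f"apex ({peak_level:.0f}) too close to the disk signal "
                f"({base_spec.signal_level:.0f}); need target >= "
                f"{1.15 * base_spec.signal_level / noise_sd:.1f} at this noise "
                "level (or lower signal_level / noise_sigma in base_spec)"
            )

        # distinct hot-spot position per element, on a ring at 60% radius
        angle = 2.0 * math.pi * idx / len(labels)
        r_px = 0.6 * base_spec.disk_radius_mm / base_spec.pixel_spacing
        hot_rc = (ci + r_px * math.sin(angle), cj + r_px * math.cos(angle))

        rng = np.random.default_rng(base_spec.seed + idx + 1)
        image = make_phantom_image(replace(base_spec, noise_sigma=0.0), rng)
        i = np.arange(rows, dtype=np.float64)[:, None]
        j = np.arange(cols, dtype=np.float64)[None, :]
        d2 = ((i - hot_rc[0]) * base_spec.pixel_spacing) ** 2 + (
            (j - hot_rc[1]) * base_spec.pixel_spacing
        ) ** 2
        hot = peak_level * (1.0 - d2 / hot_spot_width_mm**2)
        image = np.maximum(image, np.where(disk_mask(base_spec), hot, image))
        if base_spec.noise_sigma > 0:
            if base_spec.noise_model == "rician":
                re = image + rng.normal(0.0, base_spec.noise_sigma, size=image.shape)
                im = rng.normal(0.0, base_spec.noise_sigma, size=image.shape)
                image = np.hypot(re, im)
            else:
                image = image + rng.normal(0.0, base_spec.noise_sigma, size=image.shape)

        fp = out_dir / f"{label}.dcm"
        _write_dicom(
            fp,
            image,
            pixel_spacing=base_spec.pixel_spacing,
            slice_location=0.0,
            series_label=f"{coil} element {label}",
            instance_number=1,
            uid_tag=f"mrcoilqa-{base_spec.seed}-{coil}-{label}",
            coil_id=label,
        )

        noise_image = rng.normal(0.0, base_spec.noise_sigma, size=(rows, cols))
        if base_spec.noise_model == "rician":
            noise_image = np.hypot(
                noise_image, rng.normal(0.0, base_spec.noise_sigma, size=(rows, cols))
            )
        nfp = out_dir / f"{label}_noise.dcm"
        _write_dicom(
            nfp,
            noise_image,
            pixel_spacing=base_spec.pixel_spacing,
            slice_location=0.0,
            series_label=f"{coil} element {label} noise",
            instance_number=1,
            uid_tag=f"mrcoilqa-{base_spec.seed}-{coil}-{label}-noise",
            coil_id=label,
        )

        elements[label] = {
            "file": fp.name,
            "noise_file": nfp.name,
            "hot_spot_rc": [hot_rc[0], hot_rc[1]],
            "peak_level": peak_level,
            "target_snr": snr_target if noise_sd > 0 else None,
        }

    manifest = {
        "coil": coil,
        "spec": _spec_dict(base_spec),
        "elements": elements,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_fid(spec: FidSpec, out_path: str | Path) -> dict:
    """Write one synthetic FID in the open container; returns its manifest.

    The signal is ``exp(-t/T2*) * exp(2i*pi*df*t)`` plus complex Gaussian
    noise of per-channel sigma ``noise_sigma``; the manifest records the
    analytic Lorentzian FWHM ``1/(pi*T2*)`` and the frequency offset.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    t = np.arange(spec.n_samples, dtype=np.float64) * spec.dwell_time_s
    samples = np.exp(-t / spec.t2_star_s) * np.exp(2j * math.pi * spec.freq_offset_hz * t)
    if spec.noise_sigma > 0:
        samples = samples + spec.noise_sigma * (
            rng.normal(size=spec.n_samples) + 1j * rng.normal(size=spec.n_samples)
        )

    record = FidRecord(
        samples=samples,
        dwell_time=spec.dwell_time_s,
        reference_frequency=spec.reference_frequency_hz,
        gantry_angle=spec.gantry_angle_deg,
    )
    write_fid(record, out_path)

    f0 = spec.reference_frequency_hz
    manifest = {
        "spec": asdict(spec),
        "file": out_path.name,
        "analytic_fwhm_hz": spec.analytic_fwhm_hz,
        "analytic_fwhm_ppm": spec.analytic_fwhm_hz / f0 * 1e6,
        "freq_offset_hz": spec.freq_offset_hz,
        "freq_offset_ppm": spec.freq_offset_hz / f0 * 1e6,
    }
    out_path.with_name(out_path.stem + "_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


def make_gantry_sweep(
    base_spec: FidSpec,
    out_dir: str | Path,
    *,
    angles: tuple[float, ...] = tuple(range(0, 360, 30)),
    t2_star_by_angle: dict[float, float] | None = None,
) -> dict:
    """Write one FID per gantry angle (default 0..330 in 30-degree steps).

    ``t2_star_by_angle`` overrides the decay constant at selected angles to
    emulate angle-dependent field inhomogeneity.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = {}
    for k, angle in enumerate(angles):
        t2 = (t2_star_by_angle or {}).get(angle, base_spec.t2_star_s)
        spec = replace(
            base_spec,
            gantry_angle_deg=angle,
            t2_star_s=t2,
            seed=base_spec.seed + k + 1,
        )
        manifest = make_fid(spec, out_dir / f"fid_ga{int(round(angle)):03d}.fid")
        records[str(float(angle))] = manifest
    sweep = {"angles": list(angles), "records": records}
    (out_dir / "sweep_manifest.json").write_text(json.dumps(sweep, indent=1, sort_keys=True))
    return sweep


def _spec_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["image_shape"] = list(spec.image_shape)
    d["disk_center_rc"] = list(spec.center_rc)
    return d
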