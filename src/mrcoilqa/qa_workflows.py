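"""QA workflow orchestration: run the five protocols and apply thresholds.

Workflows
---------
weekly
    One single-slice body-phantom acquisition; signal ROI statistics,
    single-image SNR (> 11) and PIU (> 60).
body
    Three signal/noise acquisition pairs (transverse, sagittal, coronal);
    two-image SNR per orientation (> 30 transverse/sagittal, >= 25
    coronal) plus PIU of the signal ROI.
torso / head_neck (element coils)
    Combined views (Prescan Normalize ON for uniformity, OFF for SNR)
    plus one acquisition per coil element; each element gets a 3 mm peak
    ROI whose SNR is judged by element class: VAS2/VPS2 > 55, posterior
    head elements VAP1/VAP2/VPP1/VPP2 > 25, all other elements > 35.
homogeneity
    Per-gantry-angle FID linewidth in ppm against a 5 ppm limit
    (inclusive).

Every verdict is carried as a :class:`QaResult` holding the metric value,
the threshold, and the comparator, so PASS/FAIL is always recomputable
from the stored numbers alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

from mrcoilqa import roi_metrics
from mrcoilqa.coils import COIL_ELEMENTS, ELEMENT_PATTERN
from mrcoilqa.dicom_io import ImageSeries, read_series
from mrcoilqa.errors import ClassificationError, QaError, ValidationError
from mrcoilqa.fid_homogeneity import analyze_gantry_set, load_fid
from mrcoilqa.phantom_detect import segment_phantom, select_slice
from mrcoilqa.roi_metrics import (
    RoiStats,
    make_roi_mask,
    noise_roi_spec,
    piu,
    place_element_roi,
    place_signal_roi,
    roi_stats,
    snr_single_image,
    snr_two_image,
)

logger = logging.getLogger(__name__)

ORIENTATIONS = ("transverse", "sagittal", "coronal")

HIGH_SNR_ELEMENTS = frozenset({"VAS2", "VPS2"})
POSTERIOR_HEAD_ELEMENTS = frozenset({"VAP1", "VAP2", "VPP1", "VPP2"})


@dataclass(frozen=True)
class ThresholdSet:
    """Acceptance limits, defaulting to the vendor SAT-04 levels.

    Comparators are fixed per limit: strict ``>`` everywhere except the
    coronal combined-view SNR (``>=`` 25, "at least") and the homogeneity
    linewidth (``<=`` 5 ppm, inclusive).
    """

    weekly_snr_min: float = 11.0
    weekly_piu_min: float = 60.0
    combined_snr_min_sagittal: float = 30.0
    combined_snr_min_transverse: float = 30.0
    combined_snr_min_coronal: float = 25.0
    element_snr_min_high: float = 55.0
    element_snr_min_standard: float = 35.0
    element_snr_min_posterior_head: float = 25.0
    homogeneity_ppm_max: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")

    def with_overrides(self, overrides: Mapping[str, float]) -> "ThresholdSet":
        """New ThresholdSet with selected limits replaced; unknown keys
        are rejected."""
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return replace(self, **{k: float(v) for k, v in overrides.items()})


@dataclass(frozen=True)
class QaResult:
    """One metric judged against one threshold.

    ``status`` is PASS iff ``value <comparator> threshold`` holds; the
    three fields are stored so the verdict can always be re-derived.
    """

    workflow: str
    item_label: str
    metric_name: str  # snr | piu | fwhm_ppm
    value: float
    threshold: float
    comparator: str  # > | >= | <=
    status: str  # PASS | FAIL
    stats: RoiStats | None = None
    extra: dict[str, Any] = field(default_factory=dict)


def _passes(value: float, comparator: str, threshold: float) -> bool:
    if comparator == ">":
        return value > threshold
    if comparator == ">=":
        return value >= threshold
    if comparator == "<=":
        return value <= threshold
    if comparator == "<":
        return value < threshold
    raise ValueError(f"unknown comparator: {comparator!r}")


def _result(
    workflow: str,
    item_label: str,
    metric_name: str,
    value: float,
    threshold: float,
    comparator: str,
    stats: RoiStats | None = None,
    extra: dict[str, Any] | None = None,
) -> QaResult:
    return QaResult(
        workflow=workflow,
        item_label=item_label,
        metric_name=metric_name,
        value=value,
        threshold=threshold,
        comparator=comparator,
        status="PASS" if _passes(value, comparator, threshold) else "FAIL",
        stats=stats,
        extra=extra or {},
    )


def classify_element(label: str, coil: str = "torso") -> tuple[str, str]:
    """Map an element label to its threshold class.

    Returns ``(class_name, threshold_field)`` where class_name is one of
    ``high`` (VAS2, VPS2), ``posterior_head`` (VAP1, VAP2, VPP1, VPP2) or
    ``standard`` (any other valid element).

    Raises
    ------
    ClassificationError
        If the label does not match the element grammar V(A|P)(S|P)<digit>.
    """
    norm = (label or "").strip().upper()
    if not ELEMENT_PATTERN.fullmatch(norm):
        raise ClassificationError(
            f"unrecognized element label {label!r}; expected V(A|P)(S|P)<digit>"
        )
    if norm in HIGH_SNR_ELEMENTS:
        return "high", "element_snr_min_high"
    if norm in POSTERIOR_HEAD_ELEMENTS:
        return "posterior_head", "element_snr_min_posterior_head"
    return "standard", "element_snr_min_standard"


def _as_series(source: str | Path | ImageSeries) -> ImageSeries:
    if isinstance(source, ImageSeries):
        return source
    return read_series(source)


def _stage(name: str):
    """Context manager annotating propagated errors with the stage name."""

    class _Stage:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, QaError):
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Stage()


def _analyze_single_image(
    series: ImageSeries, *, strict_containment: bool = False
) -> tuple[RoiStats, str]:
    """Select slice -> segment -> 340 cm² signal ROI -> statistics.

    Returns the ROI statistics and the source filename of the slice used.
    """
    with _stage("slice selection"):
        idx = select_slice(series)
    image, meta = series.slices[idx], series.meta[idx]
    with _stage("segmentation"):
        mask = segment_phantom(image, meta)
    with _stage("ROI placement"):
        spec = place_signal_roi(
            mask, roi_metrics.STANDARD_ROI_AREA_MM2, meta,
            strict_containment=strict_containment,
        )
        roi = make_roi_mask(spec, meta, image.shape)
    return roi_stats(image, roi), meta.source_file or meta.series_label


def run_weekly(
    series_path: str | Path | ImageSeries,
    thresholds: ThresholdSet | None = None,
) -> list[QaResult]:
    """Weekly QA: single-image SNR and PIU of one body-phantom acquisition.

    Returns two results (snr vs > weekly_snr_min, piu vs > weekly_piu_min)
    sharing the same ROI statistics, labeled with the source filename.
    """
    thr = thresholds or ThresholdSet()
    series = _as_series(series_path)
    stats, label = _analyze_single_image(series)
    with _stage("metrics"):
        snr = snr_single_image(stats)
        uniformity = piu(stats)
    return [
        _result("weekly", label, "snr", snr, thr.weekly_snr_min, ">", stats),
        _result("weekly", label, "piu", uniformity, thr.weekly_piu_min, ">", stats),
    ]


def _read_by_orientation(
    sources: Sequence[str | Path | ImageSeries] | str | Path,
    what: str,
) -> dict[str, ImageSeries]:
    """Read acquisitions and key them by detected orientation."""
    if isinstance(sources, (str, Path)):
        p = Path(sources)
        if p.is_dir():
            # one acquisition per file, or per subdirectory (one series each)
            items: list[str | Path | ImageSeries] = sorted(
                q for q in p.iterdir()
                if (q.is_file() and q.suffix != ".json") or q.is_dir()
            )
        else:
            items = [p]
    else:
        items = list(sources)

    by_orient: dict[str, ImageSeries] = {}
    for item in items:
        series = _as_series(item)
        orient = series.meta[0].orientation
        if orient is None:
            raise ValidationError(
                f"{what}: cannot determine orientation of "
                f"{series.meta[0].source_file or series.meta[0].series_label!r}"
            )
        if orient in by_orient:
            raise ValidationError(f"{what}: duplicate {orient} acquisition")
        by_orient[orient] = series
    return by_orient


def run_body(
    signal_series: Sequence[str | Path | ImageSeries] | str | Path,
    noise_series: Sequence[str | Path | ImageSeries] | str | Path,
    thresholds: ThresholdSet | None = None,
    *,
    correction: float = 1.0,
) -> list[QaResult]:
    """NEMA body-coil QA: two-image SNR and PIU per orientation.

    ``signal_series`` and ``noise_series`` each hold one acquisition per
    orientation (transverse, sagittal, coronal), given as directories,
    file paths, or ImageSeries.  Per orientation the SNR is
    ``correction x signal-ROI mean / noise-ROI SD`` with the 340 cm²
    noise ROI at the image center of the noise acquisition.
    """
    thr = thresholds or ThresholdSet()
    signals = _read_by_orientation(signal_series, "signal")
    noises = _read_by_orientation(noise_series, "noise")

    missing = [o for o in ORIENTATIONS if o not in signals or o not in noises]
    if missing:
        raise ValidationError(f"missing orientation acquisition(s): {missing}")

    snr_limits = {
        "transverse": (thr.combined_snr_min_transverse, ">"),
        "sagittal": (thr.combined_snr_min_sagittal, ">"),
        "coronal": (thr.combined_snr_min_coronal, ">="),
    }

    results: list[QaResult] = []
    for orient in ORIENTATIONS:
        sig, noi = signals[orient], noises[orient]
        smeta, nmeta = sig.meta[0], noi.meta[0]
        if (smeta.pixel_spacing_row, smeta.pixel_spacing_col) != (
            nmeta.pixel_spacing_row, nmeta.pixel_spacing_col,
        ):
            raise ValidationError(
                f"{orient}: pixel spacing differs between signal and noise images"
            )
        sig_stats, label = _analyze_single_image(sig)
        with _stage("noise ROI"):
            nspec = noise_roi_spec(nmeta)
            nroi = make_roi_mask(nspec, nmeta, noi.slices[0].shape)
            noi_stats = roi_stats(noi.slices[0], nroi)
        with _stage("metrics"):
            snr = snr_two_image(sig_stats, noi_stats, correction)
            uniformity = piu(sig_stats)
        limit, cmp_ = snr_limits[orient]
        extra = {"orientation": orient, "noise_sd": noi_stats.sd}
        results.append(
            _result("body", label, "snr", snr, limit, cmp_, sig_stats, extra)
        )
        results.append(
            _result("body", label, "piu", uniformity, thr.weekly_piu_min, ">",
                    sig_stats, extra)
        )
    return results


def _split_element_files(
    element_series: Sequence[str | Path | ImageSeries] | str | Path,
) -> tuple[dict[str, ImageSeries], dict[str, ImageSeries]]:
    """Group element acquisitions by coil label, separating paired
    noise-only images (identified by a 'noise' token in the series label
    or filename)."""
    if isinstance(element_series, (str, Path)):
        p = Path(element_series)
        items: list[str | Path | ImageSeries] = (
            sorted(q for q in p.iterdir() if q.is_file() and q.suffix != ".json")
            if p.is_dir()
            else [p]
        )
    else:
        items = list(element_series)

    signal_by_label: dict[str, ImageSeries] = {}
    noise_by_label: dict[str, ImageSeries] = {}
    for item in items:
        series = _as_series(item)
        meta = series.meta[0]
        label = meta.coil_id
        if label is None:
            raise ValidationError(
                f"element acquisition {meta.source_file or meta.series_label!r} "
                "has no coil element label"
            )
        text = f"{meta.series_label} {meta.source_file}".lower()
        target = noise_by_label if "noise" in text else signal_by_label
        if label in target:
            raise ValidationError(f"duplicate acquisition for element {label}")
        target[label] = series
    return signal_by_label, noise_by_label


def run_element_coil(
    combined_uniformity_series: str | Path | ImageSeries | None,
    combined_snr_series: str | Path | ImageSeries | None,
    element_series: Sequence[str | Path | ImageSeries] | str | Path,
    coil: str,
    thresholds: ThresholdSet | None = None,
) -> list[QaResult]:
    """Torso / head-and-neck coil QA: combined views plus per-element SNR.

    The combined Normalize-ON series contributes PIU and the Normalize-OFF
    series single-image SNR, judged with the orientation limits.  Each
    element acquisition gets a 3 mm ROI at its in-phantom intensity peak;
    element SNR is peak-ROI mean over the center-noise-ROI SD of the
    paired noise image when one is present, else the peak ROI's own
    mean/SD with a logged note.  The element set must be complete
    (12 torso / 10 head_neck) or a ValidationError lists the discrepancy.
    """
    thr = thresholds or ThresholdSet()
    if coil not in COIL_ELEMENTS:
        raise ValidationError(f"unknown coil id {coil!r}; expected torso or head_neck")
    expected = COIL_ELEMENTS[coil]

    results: list[QaResult] = []

    snr_limits = {
        "transverse": (thr.combined_snr_min_transverse, ">"),
        "sagittal": (thr.combined_snr_min_sagittal, ">"),
        "coronal": (thr.combined_snr_min_coronal, ">="),
    }

    # the two combined views are distinct acquisitions (Prescan Normalize
    # OFF for SNR, ON for uniformity): label rows by series description so
    # they never collapse into one report row
    if combined_snr_series is not None:
        series = _as_series(combined_snr_series)
        stats, label = _analyze_single_image(series)
        label = series.meta[0].series_label or label
        orient = series.meta[0].orientation or "transverse"
        limit, cmp_ = snr_limits[orient]
        with _stage("metrics"):
            snr = snr_single_image(stats)
        results.append(
            _result(coil, label, "snr", snr, limit, cmp_, stats,
                    {"orientation": orient, "view": "combined"})
        )
    if combined_uniformity_series is not None:
        series = _as_series(combined_uniformity_series)
        stats, label = _analyze_single_image(series)
        label = series.meta[0].series_label or label
        with _stage("metrics"):
            uniformity = piu(stats)
        results.append(
            _result(coil, label, "piu", uniformity, thr.weekly_piu_min, ">", stats,
                    {"orientation": series.meta[0].orientation, "view": "combined"})
        )

    signal_by_label, noise_by_label = _split_element_files(element_series)
    missing = [e for e in expected if e not in signal_by_label]
    extra_labels = sorted(set(signal_by_label) - set(expected))
    if missing or extra_labels:
        parts = []
        if missing:
            parts.append(f"missing elements: {missing}")
        if extra_labels:
            parts.append(f"unexpected elements: {extra_labels}")
        raise ValidationError(f"{coil} element set incomplete; " + "; ".join(parts))

    for label in expected:
        series = signal_by_label[label]
        image, meta = series.slices[0], series.meta[0]
        with _stage(f"element {label} segmentation"):
            mask = segment_phantom(image, meta)
        with _stage(f"element {label} ROI"):
            spec = place_element_roi(image, mask, meta)
            roi = make_roi_mask(spec, meta, image.shape)
            stats = roi_stats(image, roi)
        with _stage(f"element {label} metrics"):
            if label in noise_by_label:
                noi = noise_by_label[label]
                nspec = noise_roi_spec(noi.meta[0])
                nroi = make_roi_mask(nspec, noi.meta[0], noi.slices[0].shape)
                noi_stats = roi_stats(noi.slices[0], nroi)
                snr = snr_two_image(stats, noi_stats)
                noise_source = "paired noise image"
            else:
                logger.info(
                    "element %s: no paired noise image; using single-image "
                    "mean/SD fallback", label,
                )
                snr = snr_single_image(stats)
                noise_source = "single-image fallback"
        cls, thr_field = classify_element(label, coil)
        results.append(
            _result(
                coil, label, "snr", snr, getattr(thr, thr_field), ">", stats,
                {"element": label, "element_class": cls,
                 "noise_source": noise_source,
                 "peak_rc": spec.center_rc},
            )
        )
    return results


def run_homogeneity(
    fid_paths: Sequence[str | Path] | str | Path,
    thresholds: ThresholdSet | None = None,
    *,
    zero_pad_factor: int = 4,
) -> list[QaResult]:
    """B0 homogeneity QA: per-gantry-angle FID linewidth vs the ppm limit.

    Accepts a directory of ``.fid`` containers or an explicit list of
    paths; returns one result per angle, sorted by angle, judging
    ``fwhm_ppm <= homogeneity_ppm_max`` (inclusive).
    """
    thr = thresholds or ThresholdSet()
    if isinstance(fid_paths, (str, Path)):
        p = Path(fid_paths)
        paths = sorted(p.glob("*.fid")) if p.is_dir() else [p]
    else:
        paths = [Path(q) for q in fid_paths]
    if not paths:
        raise ValidationError("no FID files found")

    with _stage("FID loading"):
        records = [load_fid(q) for q in paths]
    with _stage("spectral analysis"):
        homog = analyze_gantry_set(
            records, limit_ppm=thr.homogeneity_ppm_max, zero_pad_factor=zero_pad_factor
        )

    f0_by_angle = {r.gantry_angle: r.reference_frequency for r in records}
    return [
        _result(
            "homogeneity",
            f"GA {rec.gantry_angle:g}",
            "fwhm_ppm",
            rec.fwhm_ppm,
            thr.homogeneity_ppm_max,
            "<=",
            None,
            {
                "gantry_angle": rec.gantry_angle,
                "cf_ppm": rec.cf_ppm,
                "fwhm_hz": rec.fwhm_ppm * 1e-6 * f0_by_angle[rec.gantry_angle],
            },
        )
        for rec in homog
    ]
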