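"""Structured report writing and QA plots.

CSV is the canonical report format (RFC-4180 style, UTF-8, "." decimal);
xlsx is available through the same call.  Reports contain no timestamps
or hostnames, so identical results produce byte-identical files and
longitudinal tracking reduces to appending rows.  Plots (PNG) are
backend-dependent and therefore excluded from byte-identity; each plot
gets a data-twin CSV carrying exactly the numbers drawn.

Numeric formatting follows the tabular QA convention: ROI mean and SD to
two decimals, SNR and PIU to one decimal, thresholds rendered with their
comparator (e.g. ``>11``), spectral quantities to two (Hz) or three (ppm)
decimals.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from mrcoilqa.fid_homogeneity import HomogeneityRecord, Spectrum
from mrcoilqa.qa_workflows import QaResult

REPORT_COLUMNS = [
    "filename",
    "element",
    "orientation",
    "gantry_angle",
    "mean",
    "min",
    "max",
    "sum",
    "sd",
    "snr",
    "snr_threshold",
    "snr_status",
    "piu",
    "piu_threshold",
    "piu_status",
    "cf_ppm",
    "fwhm_hz",
    "fwhm_ppm",
    "fwhm_threshold",
    "fwhm_status",
]


def _fmt_trim(value: float) -> str:
    """Float to string with up to 2 decimals, trailing zeros trimmed."""
    out = f"{value:.2f}".rstrip("0").rstrip(".")
    return out if out not in ("", "-") else "0"


def _fmt_threshold(comparator: str, value: float) -> str:
    return f"{comparator}{_fmt_trim(value)}"


def results_to_rows(results: Sequence[QaResult]) -> list[dict[str, str]]:
    """Merge QaResults into one report row per (workflow, item).

    A weekly result pair (snr + piu) for the same file collapses into a
    single row with both verdicts, matching the tabular layout of the
    weekly report; homogeneity results fill the spectral columns instead.
    """
    order: list[tuple[str, str]] = []
    grouped: dict[tuple[str, str], list[QaResult]] = {}
    for res in results:
        key = (res.workflow, res.item_label)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(res)

    rows = []
    for key in order:
        group = grouped[key]
        row = dict.fromkeys(REPORT_COLUMNS, "")
        row["filename"] = key[1]
        first = group[0]
        row["element"] = str(first.extra.get("element", ""))
        row["orientation"] = str(first.extra.get("orientation") or "")
        if "gantry_angle" in first.extra:
            row["gantry_angle"] = _fmt_trim(first.extra["gantry_angle"])
        if first.stats is not None:
            st = first.stats
            row["mean"] = f"{st.mean:.2f}"
            row["min"] = _fmt_trim(st.min)
            row["max"] = _fmt_trim(st.max)
            row["sum"] = _fmt_trim(st.sum)
            row["sd"] = f"{st.sd:.2f}"
        for res in group:
            if res.metric_name == "snr":
                row["snr"] = f"{res.value:.1f}"
                row["snr_threshold"] = _fmt_threshold(res.comparator, res.threshold)
                row["snr_status"] = res.status
            elif res.metric_name == "piu":
                row["piu"] = f"{res.value:.1f}"
                row["piu_threshold"] = _fmt_threshold(res.comparator, res.threshold)
                row["piu_status"] = res.status
            elif res.metric_name == "fwhm_ppm":
                row["fwhm_ppm"] = f"{res.value:.3f}"
                row["fwhm_threshold"] = _fmt_threshold(res.comparator, res.threshold)
                row["fwhm_status"] = res.status
                if "cf_ppm" in res.extra:
                    row["cf_ppm"] = f"{res.extra['cf_ppm']:.3f}"
                if "fwhm_hz" in res.extra:
                    row["fwhm_hz"] = f"{res.extra['fwhm_hz']:.2f}"
        rows.append(row)
    return rows


def write_report(
    rows: Sequence[dict[str, str]],
    out_path: str | Path,
    format: str = "csv",
    *,
    append: bool = False,
) -> Path:
    """Write report rows with the fixed column header.

    ``append=True`` adds rows to an existing CSV (header written once),
    enabling longitudinal accumulation across QA sessions.
    """
    if not rows:
        raise ValueError("no report rows to write")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    if format == "csv":
        exists = append and out_path.exists() and out_path.stat().st_size > 0
        mode = "a" if exists else "w"
        with open(out_path, mode, newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
            if not exists:
                writer.writeheader()
            for row in rows:
                writer.writerow({k: row.get(k, "") for k in REPORT_COLUMNS})
    elif format == "xlsx":
        import pandas as pd

        frame = pd.DataFrame(list(rows), columns=REPORT_COLUMNS)
        if append and out_path.exists():
            old = pd.read_excel(out_path, dtype=str).fillna("")
            frame = pd.concat([old, frame.astype(str)], ignore_index=True)
        frame.to_excel(out_path, index=False)
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return out_path


def write_results(
    results: Sequence[QaResult],
    out_path: str | Path,
    format: str = "csv",
    *,
    append: bool = False,
) -> Path:
    """Convenience wrapper: QaResults -> merged rows -> written report."""
    return write_report(results_to_rows(results), out_path, format, append=append)


def write_spectrum_csv(spec: Spectrum, out_path: str | Path) -> Path:
    """Export a spectrum as (frequency_hz, magnitude) CSV."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency_hz", "magnitude"])
        for f, m in zip(spec.frequencies, spec.magnitudes):
            writer.writerow([f"{f:.6g}", f"{m:.8g}"])
    return out_path


def plot_spectrum(spec: Spectrum, out_path: str | Path, *, title: str = "") -> Path:
    """Plot a normalized spectrum with its CF and FWHM annotated (PNG),
    plus a data-twin CSV."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(spec.frequencies, spec.magnitudes, lw=0.8)
    if spec.cf_hz is not None:
        ax.axvline(spec.cf_hz, color="tab:red", ls="--", lw=0.8)
        label = f"CF {spec.cf_hz:.1f} Hz ({spec.cf_ppm:.3f} ppm)"
        if spec.fwhm_hz is not None:
            label += f"\nFWHM {spec.fwhm_hz:.1f} Hz ({spec.fwhm_ppm:.3f} ppm)"
        ax.annotate(label, xy=(0.02, 0.95), xycoords="axes fraction", va="top")
    ax.set_xlabel("frequency offset (Hz)")
    ax.set_ylabel("normalized magnitude")
    if title:
        ax.set_title(title)
    if spec.fwhm_hz is not None and spec.cf_hz is not None:
        span = max(20 * spec.fwhm_hz, 10 * abs(spec.cf_hz), 100.0)
        ax.set_xlim(spec.cf_hz - span, spec.cf_hz + span)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    write_spectrum_csv(spec, out_path.with_suffix(".csv"))
    return out_path


def plot_element_bars(results: Sequence[QaResult], out_path: str | Path) -> Path:
    """Bar chart of per-element SNR with class threshold lines (PNG + CSV twin).

    FAIL elements are drawn in a distinct color, derived from each
    result's stored status.
    """
    element_results = [r for r in results if r.extra.get("element")]
    if not element_results:
        raise ValueError("no element-level results to plot")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    labels = [r.extra["element"] for r in element_results]
    values = [r.value for r in element_results]
    colors = ["tab:blue" if r.status == "PASS" else "tab:red" for r in element_results]
    thresholds = sorted({(r.threshold, r.comparator) for r in element_results})

    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(labels)), 4))
    ax.bar(labels, values, color=colors)
    for thr_value, cmp_ in thresholds:
        ax.axhline(thr_value, ls="--", lw=0.8, color="gray")
        ax.annotate(
            f"{cmp_}{thr_value:g}",
            xy=(1.0, thr_value),
            xycoords=("axes fraction", "data"),
            ha="right", va="bottom", fontsize=8, color="gray",
        )
    ax.set_ylabel("SNR")
    ax.set_xlabel("coil element")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    with open(out_path.with_suffix(".csv"), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["element", "snr", "threshold", "status"])
        for r in element_results:
            writer.writerow(
                [r.extra["element"], f"{r.value:.1f}",
                 _fmt_threshold(r.comparator, r.threshold), r.status]
            )
    return out_path


def plot_polar_homogeneity(
    records: Iterable[HomogeneityRecord],
    limit_ppm: float,
    out_path: str | Path,
) -> Path:
    """Polar plot of linewidth (ppm) vs gantry angle with the acceptance
    contour (PNG + CSV twin); records are plotted in ascending angle order.
    """
    recs = sorted(records, key=lambda r: r.gantry_angle)
    if not recs:
        raise ValueError("no homogeneity records to plot")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    theta = np.deg2rad([r.gantry_angle for r in recs])
    rho = np.array([r.fwhm_ppm for r in recs])

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    if len(recs) > 1:
        ax.plot(
            np.append(theta, theta[0]), np.append(rho, rho[0]),
            "o-", color="tab:blue", lw=1.0,
        )
    else:
        ax.plot(theta, rho, "o", color="tab:blue")
    contour = np.linspace(0, 2 * np.pi, 361)
    ax.plot(contour, np.full_like(contour, limit_ppm), color="red", lw=1.2)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_rmax(max(limit_ppm * 1.3, float(rho.max()) * 1.15))
    ax.set_title(f"B0 homogeneity (FWHM, ppm) vs gantry angle — limit {limit_ppm:g} ppm")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    with open(out_path.with_suffix(".csv"), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg", "cf_ppm", "fwhm_ppm", "status"])
        for r in recs:
            writer.writerow(
                [f"{r.gantry_angle:g}", f"{r.cf_ppm:.3f}", f"{r.fwhm_ppm:.3f}",
                 "PASS" if r.pass_5ppm else "FAIL"]
            )
    return out_path
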