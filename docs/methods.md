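# Methods

This note documents the models, algorithmic choices, and known limits of
the `mrcoilqa` pipeline. Everything stated here is exercised by the test
suite or `scripts/acceptance.py`; no empirical claim is made beyond what
those compute.

## DICOM ingestion

Stored pixel values are mapped to double precision as
`stored × RescaleSlope + RescaleIntercept` (slope/intercept default to
1.0/0.0 when absent). Slices are ordered by SliceLocation ascending with
InstanceNumber as tie-break — no ordering is mandated by the file set
itself, and a fixed rule is required for reproducibility. A single-slice
series missing SliceLocation is placed at 0.0 with a warning; a
multi-slice series missing it is rejected, because representative-slice
selection depends on location. The receive-element identifier is taken
from the private tag (0051,100F) when present; otherwise a
case-insensitive match of `V(A|P)(S|P)<digit>` against the series
description is used, since the private tag is platform-specific.
Orientation is classified from the ImageOrientationPatient slice normal
(dominant axis, rejected below cosine 0.8 as oblique) with a
token-based fallback on the series description and filename.

## Phantom segmentation

Otsu's threshold is computed on a 256-bin histogram over the intensity
range (delegated to scikit-image). Refinement is fixed at: binary fill
holes → morphological opening with a radius-2 disk → keep the largest
8-connected component. 8-connectivity avoids splitting a disk boundary at
diagonal steps. The mask is flagged untrustworthy (`boundary_ok=False`)
when the component touches the image border or covers < 1% of the image.
On noiseless rasterized disks this recipe returns the true pixel set
exactly, and it is idempotent (opening is mathematically idempotent).

Otsu's objective can tie: when the histogram has an empty gap between the
classes the between-class variance is constant across the gap, and on
near-ties different float summation orders pick different maximizers.
Equivalence with the exhaustive-search oracle is therefore asserted on the
attained objective value (relative 1e-9), not on the raw threshold.

Representative-slice selection uses mean in-phantom intensity as the
primary key and distance to the isocenter (slice location 0) only to
break ties within 0.1% relative — a pure proximity rule would make the
signal criterion vacuous. Otsu is applied per slice, not on the volume
histogram.

## ROI geometry and statistics

Area-defined ROIs use r = √(A/π) in millimeters; rasterization includes a
pixel iff its center lies within r of the ROI center in physical
coordinates, so anisotropic spacing yields an index-space ellipse that
preserves the physical circle. At 1.5 mm spacing the 340 cm² ROI area is
accurate to ~0.02%, and |area error| decreases with spacing (verified at
2.0 → 1.0 → 0.5 mm with the center on a pixel; a half-integer-centered
ROI on an even grid cancels the error exactly at 2.0 mm by symmetry,
which would make the convergence check degenerate).

ROI standard deviation uses the population divisor n; at the pixel counts
involved (10⁴ pixels in a 340 cm² ROI at 1.5 mm) the distinction from
n−1 is far below reporting precision. Report formatting is fixed: mean
and SD to two decimals, SNR and PIU to one, thresholds rendered with
their comparator (e.g. `>11`).

The weekly (single-image) SNR is the signal-ROI mean over its own SD —
this reconstructs the published weekly example row exactly
(392.91/18.52 → 21.2). The two-image SNR divides the signal-ROI mean by
the noise-ROI SD of a separate noise-only acquisition with a configurable
correction factor (default 1.0; 0.66 approximates a Rayleigh-background
magnitude correction). PIU is the percent-integral-uniformity form
100·(1 − (Smax−Smin)/(Smax+Smin)) with no pre-filtering by default; a
3×3 mean filter variant (`smoothed_roi_stats`) is available because
uniformity protocols commonly low-pass before taking min/max. Note the
published example's min/max (323, 452) give PIU 83.355, which rounds to
83.4 where the original table prints 83.3; the implemented formula is
kept and the discrepancy documented rather than matched.

Element-level SNR uses the 3 mm peak ROI mean divided by the center-ROI
SD of a paired noise-only image when one accompanies the element
acquisition; without one it falls back to the peak ROI's own mean/SD with
a logged note. The fallback is markedly noisier (the 3 mm ROI holds only
~12 pixels at 1.5 mm), so paired noise images are the recommended and
default synthetic protocol.

## FID spectral analysis

Records are exchanged in an open container (interleaved little-endian
float32 real/imag pairs plus a JSON sidecar with dwell time, reference
frequency, gantry angle, and sample count) because vendor raw formats are
proprietary. A missing reference frequency defaults to 14.9 MHz
(0.35 T × 42.577 MHz/T) with a warning.

Processing: a constant (ADC/DC) offset is estimated as the mean of the
last quarter of the record — where the signal has decayed — and
subtracted. Estimating the offset from the full record would subtract
part of any resonance near zero frequency; for a 5 ms T2* line offset
30 Hz from center that distortion narrows the measured width by ~8%.
The signal is zero-padded to 4× the next power of two (configurable),
Fourier transformed with a centered frequency axis, and the magnitude
normalized to unit peak. No apodization is applied.

CF is the global magnitude maximum refined by three-point parabolic
interpolation (recovery error is well under one pre-padding resolution
bin). FWHM is measured at half maximum of the spectral **power**, i.e.
where the magnitude crosses 1/√2, with linear interpolation between
samples. For a Lorentzian line this equals the absorption-mode linewidth
1/(π·T2*), the quantity conventionally quoted as spectral FWHM; half
maximum of the magnitude profile would overstate the width by √3. On
noiseless synthetic decays the measured width matches 1/(π·T2*) to
~0.5% at pad 4, and the error decreases monotonically with padding.

ppm conversions are exact ratios of the Hz value to the reference
frequency. Per-angle verdicts compare FWHM in ppm against the acceptance
level (default 5 ppm) inclusively; the homogeneity quantity plotted and
judged is the linewidth, with CF reported alongside.

Known limitation: spectral noise inflates the observed peak maximum
(the normalization denominator), biasing measured widths of wide,
low-amplitude lines downward — at time-domain noise σ = 0.01 of the
initial amplitude, a T2* = 3 ms line (106 Hz) reads ~5–10% narrow. Lines
near the acceptance limit should come from averaged (low-noise) FIDs;
the synthetic gantry-sweep fixtures place failing angles at ~7 ppm so
verdicts are robust to this bias.

## Synthetic data

The generators emulate the study conditions end to end and are pure
functions of their spec (fixed seed ⇒ byte-identical files, including
DICOM UIDs, which are derived deterministically from the seed).

- **Weekly phantom** (defaults): 256×256 matrix, 1.5 mm pixels, disk
  radius 120 mm, signal 400 on background 5, Gaussian σ = 18.5 — i.e. a
  true single-image SNR of 21.6, matching the scale of the published
  weekly example. Rician noise (magnitude of complex Gaussian) is
  available as the physically faithful option for magnitude images;
  Gaussian is the default because it keeps closed-form checks exact.
- **Bias field**: multiplicative radial parabola 1 − a·(d/R)², running
  from 1 at the disk center to 1−a at the edge, chosen because it drives
  PIU to the closed form 100·(1 − a/(2−a)) over the disk.
- **Body protocol**: three signal/noise orientation pairs at σ = 10
  (true two-image SNR 40), representing a healthy coil against the
  30/30/25 limits.
- **Element sets**: one acquisition per element (12 torso, 10
  head-and-neck) plus a paired noise-only image each. The sensitivity
  hot spot is a broad quadratic bump, value peak·(1 − (d/30 mm)²),
  placed on a ring at 60% of the disk radius; the apex equals
  target SNR × noise SD (default target 60, comfortably above all three
  class limits). The gentle curvature keeps the detected peak within a
  few millimeters of the apex and the 3 mm-ROI mean within ~3% of the
  apex value. Targets whose apex would not dominate the disk signal by
  at least 15% are rejected rather than silently producing a fixture
  whose brightest pixel is a noise excursion.
- **FIDs**: exp(−t/T2*)·exp(2πi·Δf·t) plus complex Gaussian noise;
  defaults 4096 samples at 0.1 ms dwell, T2* = 25 ms (12.7 Hz ≈ 0.85 ppm
  at 14.9 MHz — a well-shimmed magnet), offset 30 Hz, noise σ = 0.01.
  Gantry sweeps write one record per angle, 0°–330° in 30° steps.

DICOM quantization: stored values are uint16 with per-file
slope/intercept spanning the image range, so quantization error is
≤ (max−min)/2¹⁶ — negligible against any noise level used — and the
reader recovers the writer's quantized values exactly.

What the generators do **not** model: coil-sensitivity physics
(Biot–Savart), k-space acquisition and reconstruction artifacts,
ghosting, geometric distortion, B0 maps beyond a single linewidth, or
correlated multi-channel noise. Passing tests therefore demonstrate
correctness of the measurement pipeline on images with known truth, not
performance claims about any particular scanner.

## Workflows, thresholds, reports

Every verdict is stored as (value, comparator, threshold, status), so
PASS/FAIL is always re-derivable from the report alone; the CLI exit code
(0 pass / 1 fail / 2 error) encodes the same information for scheduled
runs. Comparators follow the acceptance wording: strict `>` for weekly
SNR 11, PIU 60, element 55/35/25, and sagittal/transverse 30; `>=` for
the coronal 25 ("at least"); `<=` for the 5 ppm linewidth. Element
classification is label-based (VAS2/VPS2 high; VAP1/VAP2/VPP1/VPP2
posterior-head; other valid elements standard) for both coils.

Combined-view uniformity is computed on the Prescan-Normalize-ON series
and combined-view SNR on the OFF series; the designation is taken from
the protocol/config on trust since it is not verifiable from pixels.
Combined-view PIU is judged against the same > 60 limit as weekly PIU
(no separate combined uniformity level is specified by the vendor
levels encoded here).

CSV is the canonical report format; deterministic mode (always on) omits
timestamps and hostnames so repeated runs are byte-identical. Plot PNGs
are backend-dependent and excluded from byte-identity; each plot writes a
data-twin CSV carrying exactly the plotted numbers. Longitudinal tracking
is plain CSV appending with a single header.

## Problem sizes

Tests and the acceptance script run on 256×256 images (up to 901×901 for
the rasterization-convergence check), 20-seed recovery ensembles, 50-image
Otsu comparisons, and 4096-sample FIDs padded to 16384 — sizes chosen so
each stage's estimator noise is well below the tolerances being asserted.
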