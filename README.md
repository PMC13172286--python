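# mrcoilqa

Automated quality assurance for MRI receive coils on a 0.35 T MR-linac:
from uniform-phantom DICOM series and raw free-induction-decay (FID)
records to signal-to-noise ratio (SNR), percent image uniformity (PIU),
and B0 field-homogeneity metrics, with pass/fail verdicts against
vendor acceptance levels and structured CSV/xlsx reports.

It is written for medical physicists who run weekly and NEMA-style coil
QA and want the slice selection, phantom detection, and region-of-interest
(ROI) placement to be fully automatic and reproducible — identical inputs
always produce byte-identical reports, so longitudinal drift is never an
artifact of the analysis.

## What it computes

**Phantom detection.** Each slice is segmented by Otsu thresholding
(256-bin histogram) followed by hole filling, a radius-2 morphological
opening, and largest-component selection. In a multi-slice series the
representative slice is the one with the highest mean in-phantom signal,
ties going to the slice nearest the isocenter.

**ROIs.** Circles of fixed physical area A are placed with radius
r = √(A/π), converted per axis to pixels through the DICOM PixelSpacing
(an anisotropic grid gives an ellipse in index space, preserving the
physical circle). The standard large ROI is 340 cm²; element-level
analysis uses a 3 mm-radius ROI at the brightest in-phantom pixel.

**Metrics.** With S the ROI pixel values,

- single-image SNR = mean(S) / sd(S)   (population SD),
- two-image SNR = c · mean(S_signal) / sd(S_noise), noise taken in a
  340 cm² ROI at the image center of a noise-only acquisition
  (correction factor c defaults to 1.0),
- PIU = 100 · (1 − (S_max − S_min)/(S_max + S_min)).

**B0 homogeneity.** Each FID (complex, exponentially decaying) is
DC-corrected, zero-padded, and Fourier transformed; the center frequency
(CF) is the parabolic-refined spectral peak and the linewidth is the full
width at half maximum (FWHM) of the spectral power — for a Lorentzian
line this equals 1/(π·T2*). Both are reported in Hz and in ppm of the
operating frequency (14.9 MHz at 0.35 T) per gantry angle, judged against
a 5 ppm acceptance level.

**Thresholds** default to the vendor system-acceptance levels: weekly
SNR > 11 and PIU > 60; combined-view SNR > 30 (sagittal, transverse) and
≥ 25 (coronal); element SNR > 55 for VAS2/VPS2, > 25 for the posterior
head elements VAP1/VAP2/VPP1/VPP2, > 35 otherwise; FWHM ≤ 5 ppm. All are
overridable from a config file.

A synthetic-data module generates DICOM phantom fixtures (uniform disk,
optional radial bias field, Gaussian/Rician noise, per-element hot spots)
and FID records with known ground truth, so the whole pipeline is testable
without scanner data.

## Worked example

Generate a weekly-QA fixture (256×256, 1.5 mm pixels, disk signal 400,
Gaussian noise σ = 18.5) and analyze it:

```
$ mrcoilqa simulate weekly --out sim --seed 7
$ mrcoilqa weekly sim/weekly --out qa
INFO mrcoilqa: weekly slice_000.dcm: snr=21.812 (>11) PASS
INFO mrcoilqa: weekly slice_000.dcm: piu=80.911 (>60) PASS
INFO mrcoilqa: report written to qa/report.csv (2 checks, 0 failed)
```

The measured SNR 21.8 estimates the generator truth 400/18.5 = 21.6; PIU
80.9 reflects the noise-driven min/max spread inside the 340 cm² ROI of
an otherwise uniform disk. `qa/report.csv` begins

```
filename,element,orientation,gantry_angle,mean,min,max,sum,sd,snr,...
slice_000.dcm,,,,399.69,316.71,466.15,6038474.81,18.32,21.8,>11,PASS,80.9,>60,PASS,...
```

and the exit code is 0 (all checks passed), 1 on any FAIL, 2 on error —
suitable for scheduled runs. The other subcommands are `body` (three
signal/noise orientation pairs), `torso` and `hnc` (combined views plus
12/10 element acquisitions), `homogeneity` (a directory of `.fid`
records, one per gantry angle, producing a polar linewidth plot), and
`simulate` for fixtures.

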