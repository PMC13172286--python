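"""ROI geometry and SNR/PIU metrics: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcoilqa.errors import DegenerateInputError, GeometryError
from mrcoilqa.phantom_detect import segment_phantom
from mrcoilqa.roi_metrics import (
    RoiSpec,
    RoiStats,
    make_roi_mask,
    noise_roi_spec,
    piu,
    place_element_roi,
    place_signal_roi,
    radius_px,
    roi_stats,
    snr_single_image,
    snr_two_image,
)
from mrcoilqa.synthetic_data import PhantomSpec, make_phantom_image

from conftest import meta_factory


class TestRadiusPx:
    def test_standard_area_isotropic(self, meta15):
        rr, rc = radius_px(34_000.0, meta15)
        # r = sqrt(A/pi) for the standard 340 cm^2 ROI
        assert math.sqrt(34_000.0 / math.pi) == pytest.approx(104.031, abs=1e-3)
        assert rr == pytest.approx(104.031 / 1.5, abs=0.01)
        assert rc == pytest.approx(104.031 / 1.5, abs=0.01)

    def test_unit_area(self):
        meta = meta_factory(spacing=1.0)
        rr, rc = radius_px(math.pi, meta)
        assert rr == pytest.approx(1.0) and rc == pytest.approx(1.0)

    def test_anisotropic_spacing_per_axis(self):
        meta = meta_factory(pixel_spacing_row=1.0, pixel_spacing_col=2.0)
        rr, rc = radius_px(34_000.0, meta)
        assert rr == pytest.approx(104.04, abs=0.01)
        assert rc == pytest.approx(52.02, abs=0.01)

    def test_nonpositive_area_rejected(self, meta15):
        with pytest.raises(ValueError):
            radius_px(0.0, meta15)


class TestMakeRoiMask:
    def test_rasterized_area_within_2pct(self, meta15):
        spec = noise_roi_spec(meta15)
        mask = make_roi_mask(spec, meta15, (256, 256))
        area = mask.sum() * 1.5 * 1.5
        assert area == pytest.approx(34_000.0, rel=0.02)

    def test_area_error_decreases_with_spacing(self):
        # odd matrices put the ROI center on a pixel, the generic alignment
        # (half-integer centers cancel the error by symmetry at 2 mm)
        errors = []
        for spacing, shape in [(2.0, (257, 257)), (1.0, (513, 513)), (0.5, (901, 901))]:
            meta = meta_factory(spacing=spacing, rows=shape[0], cols=shape[1])
            mask = make_roi_mask(noise_roi_spec(meta), meta, shape)
            errors.append(abs(mask.sum() * spacing**2 - 34_000.0))
        assert errors[0] > errors[1] > errors[2]

    def test_subpixel_radius_selects_single_pixel(self):
        meta = meta_factory(spacing=1.0, rows=9, cols=9)
        spec = RoiSpec(kind="element_peak", center_rc=(4.0, 4.0), radius_mm=0.4)
        mask = make_roi_mask(spec, meta, (9, 9))
        assert mask.sum() == 1 and mask[4, 4]

    def test_roi_exceeding_bounds_is_geometry_error(self):
        meta = meta_factory(spacing=1.5, rows=128, cols=128)
        with pytest.raises(GeometryError, match="beyond"):
            make_roi_mask(noise_roi_spec(meta), meta, (128, 128))

    def test_anisotropic_mask_is_physical_circle(self):
        meta = meta_factory(pixel_spacing_row=1.0, pixel_spacing_col=2.0,
                            rows=256, cols=256)
        spec = RoiSpec(kind="noise_image_center", center_rc=(127.5, 127.5),
                       radius_mm=math.sqrt(5000.0 / math.pi),
                       area_mm2=5000.0)
        mask = make_roi_mask(spec, meta, (256, 256))
        assert mask.sum() * 1.0 * 2.0 == pytest.approx(5000.0, rel=0.02)
        # index-space ellipse: twice as many rows spanned as columns
        rows_span = np.ptp(np.nonzero(mask)[0])
        cols_span = np.ptp(np.nonzero(mask)[1])
        assert rows_span == pytest.approx(2 * cols_span, abs=2)


class TestRoiPlacement:
    def _mask(self, radius_mm, meta, center=None):
        spec = PhantomSpec(disk_radius_mm=radius_mm, noise_sigma=0.0,
                           disk_center_rc=center)
        return segment_phantom(make_phantom_image(spec), meta)

    def test_contained_roi_no_warning(self, meta15, caplog):
        pm = self._mask(120.0, meta15)
        with caplog.at_level("WARNING"):
            spec = place_signal_roi(pm, 34_000.0, meta15)
        assert spec.center_rc == pm.centroid_rc
        assert not caplog.records

    def test_too_small_phantom_warns_on_containment(self, meta15, caplog):
        pm = self._mask(100.0, meta15)  # 104.04 mm ROI > 100 mm phantom
        with caplog.at_level("WARNING"):
            place_signal_roi(pm, 34_000.0, meta15)
        assert any("contain" in r.message for r in caplog.records)

    def test_strict_containment_raises(self, meta15):
        pm = self._mask(100.0, meta15)
        with pytest.raises(GeometryError, match="contain"):
            place_signal_roi(pm, 34_000.0, meta15, strict_containment=True)

    def test_off_center_phantom_roi_follows_centroid(self, meta15):
        pm = self._mask(100.0, meta15, center=(110.0, 140.0))
        spec = place_signal_roi(pm, 20_000.0, meta15)
        assert spec.center_rc == pytest.approx((110.0, 140.0), abs=0.5)

    def test_element_roi_at_hot_spot(self, meta15):
        spec = PhantomSpec(disk_radius_mm=120.0, noise_sigma=0.0)
        img = make_phantom_image(spec)
        img[100, 90] = 900.0  # hot pixel inside the phantom
        pm = segment_phantom(img, meta15)
        roi = place_element_roi(img, pm, meta15)
        assert roi.center_rc == (100.0, 90.0)
        assert roi.radius_mm == 3.0

    def test_element_roi_ignores_out_of_mask_maximum(self, meta15):
        spec = PhantomSpec(disk_radius_mm=75.0, noise_sigma=0.0)
        img = make_phantom_image(spec)
        img[2, 2] = 5000.0  # global max on the background
        img[130, 130] = 900.0
        pm = segment_phantom(img, meta15)
        roi = place_element_roi(img, pm, meta15)
        assert roi.center_rc == (130.0, 130.0)

    def test_element_roi_tie_breaks_lexicographically(self, meta15):
        spec = PhantomSpec(disk_radius_mm=120.0, noise_sigma=0.0)
        img = make_phantom_image(spec)
        img[110, 110] = 900.0
        img[120, 120] = 900.0
        pm = segment_phantom(img, meta15)
        assert place_element_roi(img, pm, meta15).center_rc == (110.0, 110.0)


class TestRoiStats:
    def test_constant_roi(self):
        img = np.full((8, 8), 7.0)
        st_ = roi_stats(img, np.ones((8, 8), dtype=bool))
        assert (st_.mean, st_.min, st_.max, st_.sd) == (7.0, 7.0, 7.0, 0.0)

    def test_two_pixel_population_sd(self):
        img = np.array([[1.0, 3.0]])
        st_ = roi_stats(img, np.ones((1, 2), dtype=bool))
        assert st_.mean == 2.0 and st_.sd == 1.0  # population divisor n

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(50, 10, size=(32, 32))
        mask = rng.random((32, 32)) < 0.3
        if not mask.any():
            mask[0, 0] = True
        st_ = roi_stats(img, mask)
        vals = [img[i, j] for i in range(32) for j in range(32) if mask[i, j]]
        assert st_.n_px == len(vals)
        assert st_.mean == pytest.approx(np.mean(vals))
        assert st_.min == min(vals) and st_.max == max(vals)
        assert st_.sum == pytest.approx(sum(vals))
        assert st_.sd == pytest.approx(
            math.sqrt(sum((v - np.mean(vals)) ** 2 for v in vals) / len(vals))
        )
        assert st_.sum == pytest.approx(st_.mean * st_.n_px)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_stats(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestSnr:
    def test_weekly_report_reconstruction(self):
        st_ = RoiStats(mean=392.91, min=323, max=452, sum=5872434, sd=18.52, n_px=14945)
        assert f"{snr_single_image(st_):.1f}" == "21.2"

    def test_unit_ratio(self):
        st_ = RoiStats(mean=100, min=0, max=200, sum=1000, sd=100, n_px=10)
        assert snr_single_image(st_) == 1.0

    def test_scale_invariance(self, rng):
        img = rng.normal(400, 20, size=(64, 64))
        mask = np.ones((64, 64), dtype=bool)
        base = snr_single_image(roi_stats(img, mask))
        for c in (0.25, 3.0, 1000.0):
            scaled = snr_single_image(roi_stats(c * img, mask))
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_sd_degenerate(self):
        st_ = RoiStats(mean=7, min=7, max=7, sum=70, sd=0.0, n_px=10)
        with pytest.raises(DegenerateInputError):
            snr_single_image(st_)

    def test_two_image_ratio_and_correction(self):
        sig = RoiStats(mean=400, min=0, max=500, sum=0, sd=30, n_px=100)
        noi = RoiStats(mean=0, min=-30, max=30, sum=0, sd=10, n_px=100)
        assert snr_two_image(sig, noi) == 40.0
        assert snr_two_image(sig, noi, correction=0.66) == pytest.approx(26.4)

    def test_two_image_recovers_known_noise(self, rng):
        """Rayleigh-background pair: recovered SNR within 5% of truth at
        >= 10^4 noise pixels."""
        sigma, signal = 12.0, 400.0
        noise_img = np.hypot(rng.normal(0, sigma, (128, 128)),
                             rng.normal(0, sigma, (128, 128)))
        sig = RoiStats(mean=signal, min=0, max=0, sum=0, sd=1, n_px=1)
        noi = roi_stats(noise_img, np.ones_like(noise_img, dtype=bool))
        truth = signal / (sigma * math.sqrt(2 - math.pi / 2))
        assert snr_two_image(sig, noi) == pytest.approx(truth, rel=0.05)

    def test_single_image_parameter_recovery(self):
        """S=400, Gaussian sigma=20: mean estimated SNR within 5% of 20
        across 20 seeds, full segmentation + ROI pipeline."""
        meta = meta_factory()
        estimates = []
        for seed in range(20):
            spec = PhantomSpec(signal_level=400.0, noise_sigma=20.0, seed=seed)
            img = make_phantom_image(spec)
            pm = segment_phantom(img, meta)
            roi = make_roi_mask(place_signal_roi(pm, 34_000.0, meta), meta, img.shape)
            estimates.append(snr_single_image(roi_stats(img, roi)))
        assert np.mean(estimates) == pytest.approx(20.0, rel=0.05)


class TestPiu:
    def test_weekly_report_reconstruction(self):
        st_ = RoiStats(mean=392.91, min=323, max=452, sum=5872434, sd=18.52, n_px=14945)
        assert piu(st_) == pytest.approx(83.36, abs=0.01)

    def test_uniform_limit(self):
        st_ = RoiStats(mean=5, min=5, max=5, sum=50, sd=0, n_px=10)
        assert piu(st_) == 100.0

    def test_zero_minimum(self):
        st_ = RoiStats(mean=5, min=0, max=10, sum=50, sd=5, n_px=10)
        assert piu(st_) == 0.0

    def test_nonpositive_sum_rejected(self):
        st_ = RoiStats(mean=0, min=-5, max=5, sum=0, sd=5, n_px=10)
        with pytest.raises(ValueError):
            piu(st_)

    def test_noiseless_disk_is_exactly_100(self, meta15):
        spec = PhantomSpec(noise_sigma=0.0)
        img = make_phantom_image(spec)
        pm = segment_phantom(img, meta15)
        roi = make_roi_mask(place_signal_roi(pm, 34_000.0, meta15), meta15, img.shape)
        assert piu(roi_stats(img, roi)) == 100.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.01, 2.0), st.floats(1e-3, 1e6))
    def test_scale_invariance(self, lo_frac, c):
        img = np.linspace(lo_frac * 100, 100, 64).reshape(8, 8)
        mask = np.ones((8, 8), dtype=bool)
        base = piu(roi_stats(img, mask))
        assert piu(roi_stats(c * img, mask)) == pytest.approx(base, rel=1e-9)

    def test_radial_bias_field_closed_form(self, meta15):
        """PIU over the full disk under a parabolic bias of amplitude a
        equals 100*(1 - a/(2-a))."""
        from mrcoilqa.synthetic_data import disk_mask

        for a in (0.1, 0.2, 0.4):
            spec = PhantomSpec(noise_sigma=0.0, bias_field_amplitude=a)
            img = make_phantom_image(spec)
            measured = piu(roi_stats(img, disk_mask(spec)))
            assert measured == pytest.approx(100.0 * (1 - a / (2 - a)), abs=0.5)
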