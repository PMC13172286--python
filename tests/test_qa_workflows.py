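"""Workflow orchestration: thresholds, element classification, end-to-end runs."""

import numpy as np
import pytest

from mrcoilqa.errors import ClassificationError, ValidationError
from mrcoilqa.qa_workflows import (
    QaResult,
    ThresholdSet,
    classify_element,
    run_body,
    run_element_coil,
    run_homogeneity,
    run_weekly,
)
from mrcoilqa.reporting import write_results
from mrcoilqa.synthetic_data import (
    FidSpec,
    PhantomSpec,
    make_element_set,
    make_gantry_sweep,
    make_noise_series,
    make_phantom_series,
)


class TestThresholdSet:
    def test_defaults_are_sat04_levels(self):
        thr = ThresholdSet()
        assert thr.weekly_snr_min == 11 and thr.weekly_piu_min == 60
        assert thr.combined_snr_min_sagittal == 30
        assert thr.combined_snr_min_transverse == 30
        assert thr.combined_snr_min_coronal == 25
        assert (thr.element_snr_min_high, thr.element_snr_min_standard,
                thr.element_snr_min_posterior_head) == (55, 35, 25)
        assert thr.homogeneity_ppm_max == 5

    def test_overrides_and_unknown_keys(self):
        thr = ThresholdSet().with_overrides({"weekly_snr_min": 15})
        assert thr.weekly_snr_min == 15
        with pytest.raises(ValueError, match="unknown"):
            ThresholdSet().with_overrides({"snr": 10})


class TestClassifyElement:
    @pytest.mark.parametrize("label,cls,limit", [
        ("VAS2", "high", 55), ("VPS2", "high", 55),
        ("VPP1", "posterior_head", 25), ("VAP2", "posterior_head", 25),
        ("VAS1", "standard", 35), ("VPS3", "standard", 35),
        ("VAP3", "standard", 35),
    ])
    def test_classes(self, label, cls, limit):
        name, field = classify_element(label)
        assert name == cls
        assert getattr(ThresholdSet(), field) == limit

    def test_case_insensitive(self):
        assert classify_element("vas2")[0] == "high"

    def test_bad_label_rejected(self):
        with pytest.raises(ClassificationError):
            classify_element("XYZ1")


class TestStatusRecomputable:
    def test_status_matches_comparator(self):
        r = QaResult("weekly", "x", "snr", 12.0, 11.0, ">", "PASS")
        assert (r.value > r.threshold) == (r.status == "PASS")


class TestWeekly:
    def test_pass_fixture(self, weekly_dir):
        out, manifest = weekly_dir
        results = run_weekly(out)
        by_metric = {r.metric_name: r for r in results}
        # true SNR 400/18.5 = 21.6; estimate within a few percent
        assert by_metric["snr"].value == pytest.approx(manifest["true_snr"], rel=0.05)
        assert by_metric["snr"].status == "PASS"
        assert by_metric["piu"].status == "PASS"
        assert by_metric["snr"].comparator == ">"

    def test_low_snr_fails(self, tmp_path):
        make_phantom_series(PhantomSpec(noise_sigma=50.0, seed=2), tmp_path)
        results = run_weekly(tmp_path)
        snr = next(r for r in results if r.metric_name == "snr")
        assert snr.value < 11 and snr.status == "FAIL"

    def test_reruns_byte_identical(self, weekly_dir, tmp_path):
        out, _ = weekly_dir
        p1, p2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        write_results(run_weekly(out), p1)
        write_results(run_weekly(out), p2)
        assert p1.read_bytes() == p2.read_bytes()


def _body_dirs(tmp_path, sigma=10.0):
    for k, orient in enumerate(("transverse", "sagittal", "coronal")):
        make_phantom_series(
            PhantomSpec(seed=10 + k, noise_sigma=sigma),
            tmp_path / "signal" / orient,
            series_label=f"body {orient} signal", orientation=orient,
        )
        make_noise_series(
            PhantomSpec(seed=20 + k, noise_sigma=sigma),
            tmp_path / "noise" / orient,
            series_label=f"body {orient} noise", orientation=orient,
        )
    return tmp_path / "signal", tmp_path / "noise"


class TestBody:
    def test_snr40_all_pass(self, tmp_path):
        sig, noi = _body_dirs(tmp_path, sigma=10.0)  # truth 400/10 = 40
        results = run_body(sig, noi)
        assert len(results) == 6
        snrs = [r for r in results if r.metric_name == "snr"]
        assert {r.extra["orientation"] for r in snrs} == \
            {"transverse", "sagittal", "coronal"}
        for r in snrs:
            assert r.value == pytest.approx(40.0, rel=0.07)
            assert r.status == "PASS"

    def test_orientation_specific_thresholds(self, tmp_path):
        """SNR ~26 passes the coronal 'at least 25' but fails the strict
        >30 sagittal/transverse limits."""
        sig, noi = _body_dirs(tmp_path, sigma=400.0 / 26.0)
        results = run_body(sig, noi)
        status = {r.extra["orientation"]: r.status
                  for r in results if r.metric_name == "snr"}
        assert status["coronal"] == "PASS"
        assert status["sagittal"] == "FAIL"
        assert status["transverse"] == "FAIL"

    def test_missing_orientation_rejected(self, tmp_path):
        sig, noi = _body_dirs(tmp_path)
        import shutil

        shutil.rmtree(noi / "coronal")
        with pytest.raises(ValidationError, match="coronal"):
            run_body(sig, noi)

    def test_mismatched_spacing_rejected(self, tmp_path):
        sig, noi = _body_dirs(tmp_path)
        import shutil

        shutil.rmtree(noi / "coronal")
        make_noise_series(
            PhantomSpec(seed=22, noise_sigma=10.0, pixel_spacing=2.0,
                        image_shape=(192, 192), disk_radius_mm=120.0),
            noi / "coronal", series_label="body coronal noise",
            orientation="coronal",
        )
        with pytest.raises(ValidationError, match="spacing"):
            run_body(sig, noi)


class TestElementCoil:
    def test_torso_all_pass_at_target_60(self, tmp_path):
        make_element_set("torso", PhantomSpec(seed=5), tmp_path / "el")
        results = run_element_coil(None, None, tmp_path / "el", "torso")
        element_rows = [r for r in results if r.extra.get("element")]
        assert len(element_rows) == 12
        assert all(r.status == "PASS" for r in element_rows)
        for r in element_rows:
            assert r.value == pytest.approx(60.0, rel=0.08)
            assert r.extra["noise_source"] == "paired noise image"

    def test_missing_element_named(self, tmp_path):
        make_element_set("head_neck", PhantomSpec(seed=5), tmp_path / "el")
        (tmp_path / "el" / "VPP2.dcm").unlink()
        (tmp_path / "el" / "VPP2_noise.dcm").unlink()
        with pytest.raises(ValidationError, match="VPP2"):
            run_element_coil(None, None, tmp_path / "el", "head_neck")

    def test_posterior_head_threshold_is_25(self, tmp_path):
        make_element_set(
            "head_neck", PhantomSpec(seed=5, noise_sigma=14.0), tmp_path / "el",
            target_snr={lbl: 60.0 for lbl in
                        ("VAS1", "VAS2", "VAS3", "VPS1", "VPS2", "VPS3")} |
                       {lbl: 33.0 for lbl in ("VAP1", "VAP2", "VPP1", "VPP2")},
        )
        results = run_element_coil(None, None, tmp_path / "el", "head_neck")
        for r in results:
            label = r.extra["element"]
            if label in ("VAP1", "VAP2", "VPP1", "VPP2"):
                assert r.threshold == 25.0 and r.status == "PASS"
            elif label in ("VAS2", "VPS2"):
                assert r.threshold == 55.0
            else:
                assert r.threshold == 35.0

    def test_combined_views_contribute_snr_and_piu(self, tmp_path):
        make_element_set("torso", PhantomSpec(seed=5), tmp_path / "el")
        make_phantom_series(PhantomSpec(seed=6), tmp_path / "uni",
                            series_label="torso combined uniformity")
        make_phantom_series(PhantomSpec(seed=7), tmp_path / "snr",
                            series_label="torso combined snr")
        results = run_element_coil(tmp_path / "uni", tmp_path / "snr",
                                   tmp_path / "el", "torso")
        views = [r for r in results if r.extra.get("view") == "combined"]
        assert {r.metric_name for r in views} == {"snr", "piu"}
        assert len(results) == 14

    def test_fallback_without_noise_images(self, tmp_path):
        make_element_set("torso", PhantomSpec(seed=5), tmp_path / "el")
        for p in (tmp_path / "el").glob("*_noise.dcm"):
            p.unlink()
        results = run_element_coil(None, None, tmp_path / "el", "torso")
        assert all(r.extra["noise_source"] == "single-image fallback"
                   for r in results)


class TestHomogeneity:
    def test_sweep_pass_fail_split(self, tmp_path):
        make_gantry_sweep(
            FidSpec(seed=2), tmp_path,
            t2_star_by_angle={90.0: 0.003, 270.0: 0.003},  # 7.1 ppm, fail
        )
        results = run_homogeneity(tmp_path)
        assert len(results) == 12
        assert [r.extra["gantry_angle"] for r in results] == \
            [float(a) for a in range(0, 360, 30)]
        failed = {r.extra["gantry_angle"] for r in results if r.status == "FAIL"}
        assert failed == {90.0, 270.0}
        passed = next(r for r in results if r.extra["gantry_angle"] == 0.0)
        assert passed.value == pytest.approx(12.732 / 14.9, rel=0.02)  # ppm

    def test_single_fid(self, tmp_path):
        from mrcoilqa.synthetic_data import make_fid

        make_fid(FidSpec(seed=1, gantry_angle_deg=30.0), tmp_path / "one.fid")
        results = run_homogeneity(tmp_path / "one.fid")
        assert len(results) == 1
        assert results[0].comparator == "<="
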