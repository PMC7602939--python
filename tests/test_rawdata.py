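import math

import numpy as np
import pytest

from mscurate import (
    Chromatogram,
    GaussianFeature,
    MSSpectrum,
    RawRunSpec,
    accumulate_spectra,
    detect_features,
    detect_peaks_cwt,
    generate_raw_run,
    make_chromatogram,
    make_rois,
    read_mzml,
    targeted_feature_detection,
    write_mzml,
)


def _spectrum(points, time=0.0, **kw):
    mz, inten = zip(*points)
    return MSSpectrum(np.array(mz), np.array(inten), time=time, **kw)


class TestReadMzml:
    def test_small_run_preserves_scan_order_and_content(self, tmp_path):
        spectra = [
            _spectrum([(100.0, 10.0), (200.0, 20.0)], time=1.0),
            _spectrum([(150.0, 5.0)], time=2.0),
            _spectrum([(100.0, 7.0)], time=3.0),
        ]
        path = tmp_path / "tiny.mzML"
        write_mzml(spectra, path)
        back = read_mzml(path)
        assert len(back) == 3
        assert [s.time for s in back] == [1.0, 2.0, 3.0]
        assert all(s.is_centroid and s.ms_level == 1 for s in back)
        np.testing.assert_allclose(back[0].mz, [100.0, 200.0])
        np.testing.assert_allclose(back[0].intensity, [10.0, 20.0])

    def test_generated_run_round_trips_exactly(self, tmp_path):
        spec = RawRunSpec(
            n_scans=100,
            features=(GaussianFeature(300.1, 20.0, 2.0, 5e4, mz_jitter=1e-3),),
            noise_points=3,
            noise_level=40.0,
            seed=11,
        )
        spectra, _ = generate_raw_run(spec)
        path = tmp_path / "run.mzML"
        write_mzml(spectra, path)
        back = read_mzml(path)
        assert len(back) == 100
        for orig, rt in zip(spectra, back):
            np.testing.assert_allclose(rt.mz, orig.mz)
            np.testing.assert_allclose(rt.intensity, orig.intensity)
            assert np.all(np.diff(rt.mz) > 0) or rt.mz.size < 2

    def test_non_mzml_file_raises_io_error(self, tmp_path):
        bad = tmp_path / "not_mzml.txt"
        bad.write_text("this is not xml at all {")
        with pytest.raises(IOError):
            read_mzml(bad)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError, match="absent.mzML"):
            read_mzml(tmp_path / "absent.mzML")


class TestMakeChromatogram:
    def test_sum_aggregation_over_closed_window(self):
        s = _spectrum([(100.00, 50.0), (100.004, 30.0), (101.0, 99.0)])
        eic = make_chromatogram([s], 100.0, 0.005, "sum")
        assert eic.intensity[0] == 80.0

    def test_max_aggregation(self):
        s = _spectrum([(100.00, 50.0), (100.004, 30.0)])
        eic = make_chromatogram([s], 100.0, 0.005, "max")
        assert eic.intensity[0] == 50.0

    def test_target_far_from_all_points_gives_zero_trace(self):
        spectra = [_spectrum([(100.0, 5.0)], time=float(t)) for t in range(4)]
        eic = make_chromatogram(spectra, 700.0, 0.01)
        assert eic.intensity.shape == (4,)
        assert np.all(eic.intensity == 0)

    def test_planted_elution_profile_peaks_at_apex_scan(self):
        spec = RawRunSpec(
            n_scans=80, features=(GaussianFeature(300.1, 20.0, 2.0, 1e4),), seed=0
        )
        spectra, _ = generate_raw_run(spec)
        eic = make_chromatogram(spectra, 300.1, 0.01)
        assert eic.time[np.argmax(eic.intensity)] == pytest.approx(20.0, abs=0.5)

    def test_linearity_in_the_spectra(self):
        # EIC(sum of two runs) == EIC(run A) + EIC(run B) for sum aggregation
        rng = np.random.default_rng(5)
        times = np.arange(10.0)
        runs = []
        for _ in range(2):
            run = []
            for t in times:
                mz = np.sort(rng.uniform(100, 110, 6))
                mz += np.arange(6) * 1e-9  # enforce strict ordering
                run.append(MSSpectrum(mz, rng.uniform(0, 100, 6), time=t))
            runs.append(run)
        merged = []
        for a, b in zip(*runs):
            mz = np.concatenate([a.mz, b.mz])
            inten = np.concatenate([a.intensity, b.intensity])
            order = np.argsort(mz)
            merged.append(MSSpectrum(mz[order], inten[order], time=a.time))
        eic_sum = make_chromatogram(merged, 105.0, 2.0, "sum")
        eic_a = make_chromatogram(runs[0], 105.0, 2.0, "sum")
        eic_b = make_chromatogram(runs[1], 105.0, 2.0, "sum")
        np.testing.assert_allclose(eic_sum.intensity, eic_a.intensity + eic_b.intensity)

    def test_no_ms1_spectra_is_an_error(self):
        s = _spectrum([(100.0, 1.0)], ms_level=2)
        with pytest.raises(ValueError, match="MS1"):
            make_chromatogram([s], 100.0, 0.01)

    def test_ppm_window_equals_equivalent_absolute_window(self):
        s = _spectrum([(499.9999, 10.0), (500.003, 30.0), (500.2, 99.0)])
        # 10 ppm at m/z 500 is 0.005 Th
        by_ppm = make_chromatogram([s], 500.0, tolerance_ppm=10.0)
        by_abs = make_chromatogram([s], 500.0, tolerance=0.005)
        np.testing.assert_array_equal(by_ppm.intensity, by_abs.intensity)


class TestAccumulateSpectra:
    def test_identical_points_double(self):
        a = _spectrum([(100.0, 10.0)], time=0.0)
        b = _spectrum([(100.0, 10.0)], time=1.0)
        acc = accumulate_spectra([a, b], (0.0, 1.0), 0.005)
        assert acc.mz.tolist() == [100.0]
        assert acc.intensity.tolist() == [20.0]

    def test_intensity_weighted_merge(self):
        a = _spectrum([(100.000, 10.0), (100.003, 30.0)], time=0.0)
        acc = accumulate_spectra([a], (0.0, 1.0), 0.005)
        assert acc.mz[0] == pytest.approx(100.00225, abs=1e-9)
        assert acc.intensity[0] == 40.0

    def test_zero_tolerance_takes_the_union(self):
        a = _spectrum([(100.000, 10.0)], time=0.0)
        b = _spectrum([(100.003, 30.0)], time=0.5)
        acc = accumulate_spectra([a, b], (0.0, 1.0), 0.0)
        assert acc.mz.size == 2

    def test_empty_window_is_an_error(self):
        a = _spectrum([(100.0, 1.0)], time=5.0)
        with pytest.raises(ValueError, match="window"):
            accumulate_spectra([a], (0.0, 1.0))


class TestDetectPeaksCWT:
    def test_single_gaussian_apex_and_analytic_area(self):
        t = np.arange(200) * 0.25
        sd, amp = 2.0, 1e4
        y = amp * np.exp(-((t - 25.0) ** 2) / (2 * sd**2))
        peaks = detect_peaks_cwt(Chromatogram(t, y), widths=np.geomspace(1, 20, 9))
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 25.0) <= 0.25
        assert peaks[0].area == pytest.approx(amp * sd * math.sqrt(2 * math.pi), rel=0.02)

    def test_flat_signal_yields_no_peaks(self):
        y = np.full(100, 7.0)
        assert detect_peaks_cwt(Chromatogram(np.arange(100.0), y), widths=[1, 2, 4]) == []

    def test_two_gaussians_six_sigma_apart_both_found(self):
        t = np.arange(300) * 0.5
        y = 1e4 * np.exp(-((t - 50.0) ** 2) / (2 * 4.0**2))
        y = y + 8e3 * np.exp(-((t - 74.0) ** 2) / (2 * 4.0**2))
        peaks = detect_peaks_cwt(Chromatogram(t, y), widths=np.geomspace(1, 20, 10))
        assert len(peaks) == 2
        assert peaks[0].apex_time == pytest.approx(50.0, abs=0.5)
        assert peaks[1].apex_time == pytest.approx(74.0, abs=0.5)

    def test_pure_noise_rarely_passes_high_snr(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.abs(rng.normal(0, 50, 200))
            peaks = detect_peaks_cwt(
                Chromatogram(np.arange(200) * 0.5, y),
                widths=np.geomspace(1, 15, 8),
                min_snr=10,
            )
            hits += bool(peaks)
        assert hits <= 1

    def test_agrees_with_scipy_ridge_picker_on_clean_signal(self):
        from scipy.signal import find_peaks_cwt

        t = np.arange(250, dtype=float)
        y = np.zeros(250)
        for center, sd, amp in [(60, 5.0, 100.0), (150, 8.0, 60.0)]:
            y += amp * np.exp(-((t - center) ** 2) / (2 * sd**2))
        ours = detect_peaks_cwt(Chromatogram(t, y), widths=np.geomspace(1, 20, 10))
        scipy_idx = find_peaks_cwt(y, np.arange(1, 20))
        our_apexes = sorted(p.apex_time for p in ours)
        assert len(our_apexes) == 2
        for apex in our_apexes:
            assert min(abs(apex - i) for i in scipy_idx) <= 2

    def test_signal_shorter_than_largest_width_is_an_error(self):
        with pytest.raises(ValueError, match="width"):
            detect_peaks_cwt(np.ones(10), widths=[1, 50])


class TestMakeRois:
    def test_single_stable_trace_gives_one_roi(self):
        spec = RawRunSpec(
            n_scans=60, features=(GaussianFeature(300.1, 15.0, 2.0, 1e4),), seed=0
        )
        spectra, _ = generate_raw_run(spec)
        rois = make_rois(spectra, mz_tolerance=0.01, min_length=5, min_intensity=500)
        assert len(rois) == 1
        assert rois[0].mean_mz == pytest.approx(300.1, abs=1e-6)
        assert rois[0].n_points >= 20

    def test_min_length_beyond_run_length_gives_nothing(self):
        spec = RawRunSpec(n_scans=10, features=(GaussianFeature(300.1, 2.5, 1.0, 1e4),), seed=0)
        spectra, _ = generate_raw_run(spec)
        assert make_rois(spectra, min_length=50) == []

    def test_close_features_stay_disjoint(self):
        spec = RawRunSpec(
            n_scans=60,
            features=(
                GaussianFeature(300.0, 15.0, 2.0, 1e4),
                GaussianFeature(300.5, 15.0, 2.0, 1e4),
            ),
            seed=0,
        )
        spectra, _ = generate_raw_run(spec)
        rois = make_rois(spectra, mz_tolerance=0.01)
        assert len(rois) == 2
        assert {round(r.mean_mz, 1) for r in rois} == {300.0, 300.5}

    def test_point_order_within_scan_does_not_matter(self):
        spec = RawRunSpec(
            n_scans=50,
            features=(
                GaussianFeature(300.0, 12.0, 2.0, 1e4, mz_jitter=2e-3),
                GaussianFeature(400.0, 18.0, 2.0, 8e3, mz_jitter=2e-3),
            ),
            noise_points=4,
            noise_level=100.0,
            seed=9,
        )
        spectra, _ = generate_raw_run(spec)
        rng = np.random.default_rng(1)
        shuffled = []
        for s in spectra:
            perm = rng.permutation(s.mz.size)
            mz, inten = s.mz[perm], s.intensity[perm]
            order = np.argsort(mz)
            shuffled.append(MSSpectrum(mz[order], inten[order], time=s.time))
        a = make_rois(spectra, mz_tolerance=0.01)
        b = make_rois(shuffled, mz_tolerance=0.01)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            np.testing.assert_allclose(ra.intensity_trace, rb.intensity_trace)
            assert ra.mean_mz == pytest.approx(rb.mean_mz, abs=1e-9)

    def test_profile_spectra_are_rejected(self):
        s = _spectrum([(100.0, 1.0), (100.01, 2.0)], is_centroid=False)
        with pytest.raises(ValueError, match="centroid"):
            make_rois([s])

    def test_ppm_tolerance_tracks_the_running_mean(self):
        spec = RawRunSpec(
            n_scans=60, features=(GaussianFeature(500.0, 15.0, 2.0, 1e4),), seed=0
        )
        spectra, _ = generate_raw_run(spec)
        rois = make_rois(spectra, mz_tolerance_ppm=10.0)
        assert len(rois) == 1
        assert rois[0].mean_mz == pytest.approx(500.0, abs=1e-6)


class TestDetectFeatures:
    FEATURES = (
        GaussianFeature(210.08, 12.0, 1.5, 4e4),
        GaussianFeature(301.14, 18.0, 2.0, 9e4),
        GaussianFeature(415.21, 24.0, 2.0, 2e4),
        GaussianFeature(522.35, 30.0, 2.5, 6e4),
        GaussianFeature(688.44, 36.0, 2.0, 3e4),
    )

    def _run(self, seed=0, **kw):
        spec = RawRunSpec(n_scans=120, scan_interval=0.5, features=self.FEATURES, seed=seed, **kw)
        return generate_raw_run(spec)

    def test_recovers_all_planted_features(self):
        spectra, truth = self._run()
        table = detect_features(
            spectra, roi_params={"mz_tolerance": 0.01}, cwt_params={"min_snr": 5}
        )
        assert len(table) == 5
        for _, row in truth.iterrows():
            match = table[(table["mz"] - row["mz"]).abs() < 0.01]
            assert len(match) == 1
            assert abs(match["rt"].iloc[0] - row["rt"]) <= 0.5

    def test_blank_noise_only_run_yields_nothing(self):
        found = 0
        for seed in range(5):
            spec = RawRunSpec(n_scans=100, noise_points=10, noise_level=100.0, seed=seed)
            spectra, _ = generate_raw_run(spec)
            table = detect_features(
                spectra,
                roi_params={"mz_tolerance": 0.01, "min_intensity": 500},
                cwt_params={"min_snr": 10},
            )
            found += len(table)
        assert found == 0

    def test_feature_below_min_intensity_excluded(self):
        spec = RawRunSpec(
            n_scans=100, features=(GaussianFeature(300.1, 25.0, 2.0, 100.0),), seed=0
        )
        spectra, _ = generate_raw_run(spec)
        table = detect_features(spectra, roi_params={"min_intensity": 500})
        assert len(table) == 0

    def test_untargeted_matches_targeted_on_same_run(self):
        spectra, truth = self._run()
        untargeted = detect_features(
            spectra, roi_params={"mz_tolerance": 0.01}, cwt_params={"min_snr": 5}
        )
        targets = [{"name": f"T{i}", "mz": row["mz"]} for i, row in truth.iterrows()]
        targeted = targeted_feature_detection(
            spectra, targets, mz_tolerance=0.01, cwt_params={"min_snr": 5}
        )
        for (_, u), (_, t) in zip(
            untargeted.sort_values("mz").iterrows(), targeted.sort_values("mz").iterrows()
        ):
            assert u["area"] == pytest.approx(t["area"], rel=0.01)


class TestTargetedDetection:
    def test_five_standards_recovered_within_two_percent(self):
        spec = RawRunSpec(
            n_scans=120, scan_interval=0.5, features=TestDetectFeatures.FEATURES, seed=0
        )
        spectra, truth = generate_raw_run(spec)
        targets = [{"name": f"std{i}", "mz": r["mz"]} for i, r in truth.iterrows()]
        table = targeted_feature_detection(spectra, targets, mz_tolerance=0.01)
        assert bool(table["detected"].all())
        for (i, r), (_, got) in zip(truth.iterrows(), table.iterrows()):
            assert got["area"] == pytest.approx(r["area"], rel=0.02)
            assert got["mz"] == pytest.approx(r["mz"], abs=0.005)

    def test_absent_target_yields_explicit_not_detected_row(self):
        spec = RawRunSpec(n_scans=100, features=(GaussianFeature(300.1, 25.0, 2.0, 1e4),), seed=0)
        spectra, _ = generate_raw_run(spec)
        table = targeted_feature_detection(
            spectra, [{"name": "ghost", "mz": 888.8}], mz_tolerance=0.01
        )
        assert not table.at["ghost", "detected"]
        assert math.isnan(table.at["ghost", "area"])

    def test_rt_window_selects_the_smaller_peak(self):
        spec = RawRunSpec(
            n_scans=240,
            scan_interval=0.5,
            features=(
                GaussianFeature(300.1, 30.0, 2.0, 1e5),
                GaussianFeature(300.1, 90.0, 2.0, 2e4),
            ),
            seed=0,
        )
        spectra, _ = generate_raw_run(spec)
        table = targeted_feature_detection(
            spectra,
            [{"name": "late", "mz": 300.1, "rt_min": 70.0, "rt_max": 110.0}],
            mz_tolerance=0.01,
        )
        assert table.at["late", "rt"] == pytest.approx(90.0, abs=1.0)
        assert table.at["late", "height"] == pytest.approx(2e4, rel=0.05)
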