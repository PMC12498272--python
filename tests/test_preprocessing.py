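"""Acquisition processing: binning, segmentation, background handling."""

import dataclasses
import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from asapml import io
from asapml.preprocessing import (
    PreprocessingError,
    RawAcquisition,
    Scan,
    average_replicates,
    bin_to_unit_mass,
    normalize_unit_area,
    process_acquisition,
    segment_acquisition,
    subtract_background,
    summarize_window,
)
from asapml.synthetic import simulate_raw_acquisition


def _flat_scan(time, tic, n_peaks=10):
    mz = np.linspace(50, 50 + n_peaks - 1, n_peaks)
    return Scan(time=time, mz=mz, intensity=np.full(n_peaks, tic / n_peaks))


def _acq(tics, scan_period=0.9):
    return RawAcquisition(
        scans=[_flat_scan(i * scan_period, t) for i, t in enumerate(tics)]
    )


class TestBinning:
    @pytest.mark.parametrize(
        "mz, intensity, bin_label, expected",
        [
            ([100.2, 100.4], [3.0, 4.0], 100, 7.0),  # both round to 100
            ([100.5], [2.0], 101, 2.0),  # half-open convention rounds up
            ([99.5], [1.0], 100, 1.0),
        ],
    )
    def test_round_half_up_convention(self, mz, intensity, bin_label, expected):
        binned, dropped = bin_to_unit_mass(mz, intensity, (11, 1000))
        assert binned[bin_label - 11] == pytest.approx(expected)
        assert dropped == 0.0

    def test_out_of_range_peaks_counted_as_dropped(self):
        binned, dropped = bin_to_unit_mass(
            [5.0, 100.0, 2000.0], [1.0, 2.0, 3.0], (11, 1000)
        )
        assert dropped == pytest.approx(4.0)
        assert binned.sum() == pytest.approx(2.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bin_to_unit_mass([100.0], [-1.0], (11, 1000))

    @given(
        mz=hnp.arrays(float, 200, elements=st.floats(1.0, 1200.0)),
        intensity=hnp.arrays(float, 200, elements=st.floats(0.0, 1e4)),
    )
    def test_intensity_conservation(self, mz, intensity):
        binned, dropped = bin_to_unit_mass(mz, intensity, (11, 1000))
        assert binned.sum() + dropped == pytest.approx(
            intensity.sum(), abs=1e-9 * max(1.0, intensity.sum())
        )

    def test_peak_order_invariance(self):
        rng = np.random.default_rng(0)
        mz = rng.uniform(11, 1000, 500)
        intensity = rng.uniform(0, 10, 500)
        a, _ = bin_to_unit_mass(mz, intensity)
        perm = rng.permutation(500)
        b, _ = bin_to_unit_mass(mz[perm], intensity[perm])
        np.testing.assert_allclose(a, b)


class TestBackgroundAndNormalisation:
    def test_subtract_equal_vectors_gives_zero(self):
        corrected, clip = subtract_background([1.0, 2.0], [1.0, 2.0])
        np.testing.assert_array_equal(corrected, [0.0, 0.0])
        assert clip == 0.0

    def test_subtract_clips_negatives_and_reports_mass(self):
        corrected, clip = subtract_background([5.0, 3.0], [1.0, 4.0])
        np.testing.assert_array_equal(corrected, [4.0, 0.0])
        assert clip == pytest.approx(1.0)

    def test_subtract_zero_background_is_identity(self):
        signal = np.array([3.0, 0.0, 7.0])
        corrected, clip = subtract_background(signal, np.zeros(3))
        np.testing.assert_array_equal(corrected, signal)
        assert clip == 0.0

    def test_subtract_length_mismatch(self):
        with pytest.raises(PreprocessingError):
            subtract_background([1.0], [1.0, 2.0])

    def test_normalize_simple(self):
        np.testing.assert_allclose(normalize_unit_area([2.0, 2.0]), [0.5, 0.5])

    def test_normalize_idempotent(self):
        rng = np.random.default_rng(1)
        v = normalize_unit_area(rng.uniform(0.1, 5, 100))
        np.testing.assert_allclose(normalize_unit_area(v), v, atol=1e-12)

    def test_normalize_random_sums_to_one(self):
        rng = np.random.default_rng(2)
        assert normalize_unit_area(rng.uniform(0, 10, 990)).sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_normalize_all_zero_is_error(self):
        with pytest.raises(PreprocessingError, match="empty measurement"):
            normalize_unit_area(np.zeros(10))


class TestWindowSummaries:
    def test_identical_scans_have_zero_sd(self):
        acq = _acq([100.0] * 4)
        mean, sd = summarize_window(acq, (0, 4))
        assert np.all(sd == 0.0)
        assert mean.sum() == pytest.approx(100.0)

    def test_two_point_population_sd(self):
        scans = [
            Scan(0.0, [100.0], [4.0]),
            Scan(0.9, [100.0], [6.0]),
        ]
        mean, sd = summarize_window(RawAcquisition(scans=scans), (0, 2))
        assert mean[100 - 11] == pytest.approx(5.0)
        assert sd[100 - 11] == pytest.approx(1.0)  # N divisor

    def test_mean_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        scans = [
            Scan(0.9 * i, rng.uniform(11, 1000, 50), rng.uniform(0, 5, 50))
            for i in range(33)
        ]
        acq = RawAcquisition(scans=scans)
        mean, _ = summarize_window(acq, (0, 33))
        brute = np.mean(
            [bin_to_unit_mass(s.mz, s.intensity).intensities for s in scans],
            axis=0,
        )
        np.testing.assert_allclose(mean, brute, atol=1e-12)

    def test_empty_window_is_error(self):
        with pytest.raises(PreprocessingError):
            summarize_window(_acq([1.0, 1.0]), (1, 1))


class TestAverageReplicates:
    def test_identical_replicates(self):
        v = normalize_unit_area(np.arange(1.0, 991.0))
        out = average_replicates([v] * 5)
        np.testing.assert_allclose(out.intensities, v)
        np.testing.assert_allclose(out.per_bin_sd, 0.0, atol=1e-15)
        assert out.n_replicates == 5

    def test_two_complementary_replicates(self):
        out = average_replicates(
            [np.array([1.0, 0.0]), np.array([0.0, 1.0])], bin_range=(11, 12)
        )
        np.testing.assert_allclose(out.intensities, [0.5, 0.5])

    def test_mean_of_unit_area_replicates_has_unit_area(self):
        rng = np.random.default_rng(4)
        reps = [normalize_unit_area(rng.uniform(0, 1, 990)) for _ in range(5)]
        out = average_replicates(reps)
        assert out.intensities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_list_is_error(self):
        with pytest.raises(PreprocessingError):
            average_replicates([])


class TestSegmentation:
    def test_constant_tic_stream_is_all_background(self):
        seg = segment_acquisition(_acq([100.0] * 40))
        assert seg.sample_windows == []
        assert seg.background_window == (0, 40)

    def test_short_spike_rejected_as_transient(self):
        tics = [100.0] * 10 + [1000.0] * 2 + [100.0] * 10
        seg = segment_acquisition(_acq(tics), min_window_scans=5)
        assert seg.sample_windows == []

    def test_planted_plateaus_recovered_exactly(self, short_acq_config,
                                                unit_baseline):
        cfg = dataclasses.replace(short_acq_config, scan_noise_cv=0.0)
        sim = simulate_raw_acquisition(unit_baseline, cfg, seed=7)
        seg = segment_acquisition(sim.raw)
        assert seg.sample_windows == sim.truth.sample_windows
        assert seg.background_window == sim.truth.background_window

    def test_zero_scans_is_error(self):
        with pytest.raises(PreprocessingError):
            segment_acquisition(RawAcquisition(scans=[]))

    def test_stream_with_leading_spike_is_error(self):
        # first scan already above the rise threshold: no clean leading
        # background region exists
        tics = [1e6] + [1.0] * 20 + [1000.0] * 10
        with pytest.raises(PreprocessingError, match="background"):
            segment_acquisition(_acq(tics))


class TestProcessAcquisition:
    def test_round_trip_recovers_spectrum_at_zero_noise(
        self, short_acq_config, unit_baseline
    ):
        cfg = dataclasses.replace(short_acq_config, scan_noise_cv=0.0)
        sim = simulate_raw_acquisition(unit_baseline, cfg, seed=8)
        spectrum = process_acquisition(sim.raw)
        assert spectrum.n_replicates == 5
        assert np.abs(spectrum.intensities - unit_baseline).max() <= 1e-6
        assert spectrum.intensities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_background_only_acquisition_is_error(self):
        with pytest.raises(PreprocessingError, match="no sample windows"):
            process_acquisition(_acq([100.0] * 40))

    def test_three_window_acquisition_warns(
        self, short_acq_config, unit_baseline, caplog
    ):
        cfg = dataclasses.replace(short_acq_config, scan_noise_cv=0.0)
        sim = simulate_raw_acquisition(
            unit_baseline, cfg, seed=9, n_sample_windows=3
        )
        with caplog.at_level(logging.WARNING):
            spectrum = process_acquisition(sim.raw)
        assert spectrum.n_replicates == 3
        assert any("expected 5" in m for m in caplog.messages)


class TestAcquisitionIO:
    def test_scan_csv_round_trip_is_exact(self, short_acq_config, unit_baseline,
                                           tmp_path):
        sim = simulate_raw_acquisition(unit_baseline, short_acq_config, seed=10,
                                       n_sample_windows=2)
        path = tmp_path / "scans.csv"
        io.write_scan_csv(sim.raw, path)
        back = io.read_scan_csv(path)
        assert len(back) == len(sim.raw)
        for a, b in zip(sim.raw.scans, back.scans):
            assert a.time == b.time
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_mzml_round_trip_is_exact(self, short_acq_config, unit_baseline,
                                      tmp_path):
        sim = simulate_raw_acquisition(unit_baseline, short_acq_config, seed=11,
                                       n_sample_windows=2)
        path = tmp_path / "acq.mzML"
        io.write_mzml(sim.raw, path)
        back = io.read_mzml(path)
        assert len(back) == len(sim.raw)
        for a, b in zip(sim.raw.scans, back.scans):
            assert a.time == b.time
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_mzml_minute_units_converted(self, tmp_path):
        acq = RawAcquisition(scans=[_flat_scan(30.0, 10.0)])
        path = tmp_path / "acq.mzML"
        io.write_mzml(acq, path)
        text = path.read_text().replace(
            'value="30.0" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
            'value="0.5" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"',
        )
        path.write_text(text)
        back = io.read_mzml(path)
        assert back.scans[0].time == pytest.approx(30.0)

    def test_processed_spectrum_round_trips_through_matrix_csv(
        self, short_acq_config, unit_baseline, tmp_path
    ):
        import pandas as pd

        cfg = dataclasses.replace(short_acq_config, scan_noise_cv=0.0)
        sim = simulate_raw_acquisition(unit_baseline, cfg, seed=12)
        sim.raw.metadata["sample_id"] = "S1"
        spectrum = process_acquisition(sim.raw)
        row = pd.DataFrame(
            [spectrum.intensities], index=["S1"], columns=spectrum.bin_labels
        )
        path = tmp_path / "matrix.csv"
        io.write_spectrum_matrix(row, path)
        back = io.read_spectrum_matrix(path)
        np.testing.assert_array_equal(back.to_numpy(), row.to_numpy())
        assert list(back.columns) == list(spectrum.bin_labels)
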