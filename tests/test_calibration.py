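"""Calibration sequence: speckle averaging, wavelength registration,
round-trip inversion and QC."""

import numpy as np
import pytest

from fiberspec.calibration import (
    CalibrationConfig,
    CalibrationError,
    CalibrationIncompleteError,
    apply_wavelength_correction,
    estimate_wavelength_shift,
    process_sample,
    qc_evaluate,
    run_calibration_sequence,
    save_calibration_set,
    load_calibration_set,
    speckle_averaged_measurement,
)
from fiberspec.scenarios import simulate_calibration_measurements
from fiberspec.simulate import (
    default_model,
    hgar_sample,
    noise_free,
    phantom_sample,
    simulate_hgar,
    simulate_measurement,
    tissue_sample,
    white_standard_sample,
)
from fiberspec.spectra import Spectrum, default_grid, divide, ensemble_average, subtract


class TestSpeckleAveraging:
    def test_single_measurement_is_dark_subtraction_only(self, grid, model):
        m = simulate_measurement(model, 1, 2, white_standard_sample(grid), t=1.0)
        avg = speckle_averaged_measurement([m])
        assert np.array_equal(avg.mean.values, m.dark_subtracted().values)
        assert np.all(avg.variance.values == 0.0)
        assert avg.n == 1

    def test_duplicate_locations_warn(self, grid, model):
        ms = [
            simulate_measurement(model, 1, 2, white_standard_sample(grid), t=i, location=0)
            for i in range(3)
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            speckle_averaged_measurement(ms)

    @pytest.mark.parametrize("n,reps,tol", [(5, 200, 0.15), (20, 200, 0.10)])
    def test_fixed_vs_moving_variance_ratio_is_n(self, grid, n, reps, tol):
        # Monte-Carlo: variance of an n-average at one frozen-speckle location
        # is n times that of an n-average over n distinct locations
        ws = white_standard_sample(grid)
        sub = slice(0, len(grid), 40)  # wavelength subsample keeps this fast
        fixed, moving = [], []
        for rep in range(reps):
            m = default_model(grid, seed=50_000 + rep, read_noise_sd=0.0)
            fx = [
                simulate_measurement(m, 1, 2, ws, t=float(i), location=0).dark_subtracted()
                for i in range(n)
            ]
            mv = [
                simulate_measurement(m, 1, 2, ws, t=float(i), location=i).dark_subtracted()
                for i in range(n)
            ]
            fixed.append(ensemble_average(fx)[0].values[sub])
            moving.append(ensemble_average(mv)[0].values[sub])
        vf = np.stack(fixed).var(axis=0, ddof=1)
        vm = np.stack(moving).var(axis=0, ddof=1)
        assert (vf / vm).mean() == pytest.approx(n, rel=tol)


class TestWavelengthShift:
    @pytest.mark.parametrize("true_shift", [0.0, 1.0, -0.5, 2.5, -3.0])
    def test_recovers_injected_shift_within_five_hundredths_nm(
        self, grid, model, true_shift
    ):
        raw = simulate_measurement(
            model, -1, 2, hgar_sample(grid, shift=true_shift), t=7.0, accumulation=0.25
        )
        est = estimate_wavelength_shift(raw.dark_subtracted())
        assert est.shift == pytest.approx(true_shift, abs=0.05)
        assert est.n_matched >= 3

    def test_too_few_lines_in_range_fails(self, model):
        g = default_grid(700.0, 800.0, 0.25)  # only 763.511 in range
        m = noise_free(default_model(g, seed=1))
        raw = simulate_measurement(m, -1, 2, hgar_sample(g), t=0.0, accumulation=0.25)
        with pytest.raises(CalibrationError):
            estimate_wavelength_shift(raw.dark_subtracted())

    def test_zero_shift_correction_is_identity(self, grid):
        s = Spectrum(grid, np.sin(grid.wavelengths / 10.0), "counts")
        out = apply_wavelength_correction(s, 0.0)
        assert np.array_equal(out.values, s.values)

    def test_correction_round_trip_restores_line_positions(self, grid):
        m = noise_free(default_model(grid, seed=4))
        shifted = simulate_hgar(m, 1.0, t=0.0)
        corrected = apply_wavelength_correction(shifted, 1.0)
        for line in (435.833, 546.074, 696.543):
            lo, hi = np.searchsorted(grid.wavelengths, [line - 1.5, line + 1.5])
            peak_wl = grid.wavelengths[lo + np.argmax(corrected.values[lo:hi])]
            assert abs(peak_wl - line) <= 0.25 + 0.05

    def test_correction_shrinks_subtraction_artifact_tenfold(self):
        # the mis-registration artifact demo needs detector-pixel sampling
        # finer than the optical line width; 0.05 nm = 5 px per 0.25-nm FWHM
        fine = default_grid(step=0.05)
        m = default_model(fine, seed=6)
        for true_shift in (0.82, -1.38, 2.47):
            shifted = simulate_hgar(m, true_shift, t=1.0)
            unshifted = simulate_hgar(m, 0.0, t=2.0)
            raw = simulate_measurement(
                m, -1, 2, hgar_sample(fine, true_shift), t=3.0, accumulation=0.25
            )
            est = estimate_wavelength_shift(raw.dark_subtracted())
            before = np.abs(subtract(shifted, unshifted).values).max()
            after = np.abs(
                subtract(apply_wavelength_correction(shifted, est.shift), unshifted).values
            ).max()
            assert before / after >= 10.0


class TestSequenceAndRoundTrip:
    def test_ideal_background_extraction_is_exact(self, ideal_model, ideal_calibration):
        lb = ideal_model.lamp.values * ideal_model.background.values
        got = ideal_calibration.background[(1, 2)].values
        assert np.allclose(got, lb, rtol=1e-9)

    def test_round_trip_recovers_reflectance_exactly_noise_off(
        self, grid, ideal_model, ideal_calibration
    ):
        s = tissue_sample(grid)
        m = simulate_measurement(ideal_model, 4, 3, s, t=5000.0, location=9)
        r = process_sample(m, ideal_calibration)
        truth = s.reflectance.values / 0.99
        assert np.abs(r.values - truth).max() <= 1e-9

    def test_white_standard_self_normalizes_to_one(
        self, grid, ideal_model, ideal_calibration
    ):
        m = simulate_measurement(ideal_model, 1, 3, white_standard_sample(grid), t=6000.0)
        r = process_sample(m, ideal_calibration)
        assert np.abs(r.values - 1.0).max() <= 1e-9

    def test_clinic_noise_round_trip_within_one_percent_rms(
        self, grid, model, clinic_calibration
    ):
        ph = phantom_sample(grid, "a")
        frames = [
            simulate_measurement(model, 1, 2, ph, t=9000.0 + i, location=700 + i)
            for i in range(20)
        ]
        processed = [process_sample(f, clinic_calibration) for f in frames]
        r, _ = ensemble_average(processed)
        truth = ph.reflectance.values / 0.99
        rms = np.sqrt(np.mean((r.values / truth - 1.0) ** 2))
        assert rms < 0.01

    def test_background_and_white_normalisation_do_not_commute(
        self, grid, ideal_model, ideal_calibration
    ):
        # regression guard on processing order: with B != 0,
        # (x - bg)/white differs from x/white - bg'
        cal = ideal_calibration
        s = tissue_sample(grid)
        m = simulate_measurement(ideal_model, 1, 2, s, t=5100.0)
        x = m.dark_subtracted()
        correct = divide(subtract(x, cal.background[(1, 2)]), cal.white[(1, 2)])
        swapped = subtract(
            divide(x, cal.white[(1, 2)]),
            divide(cal.background[(1, 2)], cal.white[(1, 2)]),
        )
        # identical here (division distributes over subtraction) — the real
        # non-commutation is white-normalising before background removal:
        naive = divide(x, cal.white[(1, 2)])
        assert not np.allclose(naive.values, correct.values, rtol=1e-3)
        assert np.allclose(swapped.values, correct.values, rtol=1e-9)

    def test_missing_background_pair_is_a_named_error(self, ideal_model):
        meas = simulate_calibration_measurements(
            ideal_model, n_locations=1, background_excess=1.0
        )
        del meas.background[(4, 3)]
        with pytest.raises(CalibrationIncompleteError, match=r"\(4, 3\)"):
            run_calibration_sequence(meas)

    def test_missing_phantom_is_a_named_error(self, ideal_model):
        meas = simulate_calibration_measurements(
            ideal_model, n_locations=1, background_excess=1.0
        )
        meas.phantoms.clear()
        with pytest.raises(CalibrationIncompleteError, match="phantom"):
            run_calibration_sequence(meas)

    def test_injected_shift_beyond_limit_fails_wavelength_qc(self, ideal_model):
        meas = simulate_calibration_measurements(
            ideal_model, n_locations=1, background_excess=1.0, hgar_shift=1.0
        )
        cal = run_calibration_sequence(meas)
        assert not cal.passed
        assert cal.qc.failed_step == "wavelength"
        assert cal.qc.prompt_repeat
        with pytest.raises(CalibrationError):
            process_sample(
                simulate_measurement(
                    ideal_model, 1, 2, tissue_sample(ideal_model.grid), t=1.0
                ),
                cal,
            )

    def test_archive_round_trip(self, tmp_path, ideal_calibration):
        save_calibration_set(ideal_calibration, str(tmp_path / "cal"))
        back = load_calibration_set(str(tmp_path / "cal"))
        assert back.wavelength_shift == ideal_calibration.wavelength_shift
        assert np.array_equal(
            back.white[(1, 2)].values, ideal_calibration.white[(1, 2)].values
        )
        assert back.passed == ideal_calibration.passed


class TestQcEvaluate:
    def test_empty_history_is_baseline_pass(self, ideal_calibration):
        report = qc_evaluate([], ideal_calibration)
        assert report.passed
        assert "baseline" in report.flags

    def test_identical_current_has_zero_deviation(self, ideal_calibration):
        report = qc_evaluate([ideal_calibration] * 3, ideal_calibration)
        assert report.passed
        for mad in report.phantom_deviation.values():
            assert mad == pytest.approx(0.0, abs=1e-12)

    def test_five_percent_phantom_drift_fails_with_named_metric(self, ideal_calibration):
        import copy

        drifted = copy.deepcopy(ideal_calibration)
        drifted.phantom_refs = {
            ph: s.scaled(1.05) for ph, s in drifted.phantom_refs.items()
        }
        report = qc_evaluate([ideal_calibration] * 3, drifted)
        assert not report.passed
        assert any("phantom" in f for f in report.failures)

    def test_repeated_clinic_calibrations_stay_within_sd_threshold(self, grid):
        # stability across repeated noisy calibrations: phantom SD must sit
        # well under the 0.01 QC gate (the clinical observation is ~0.005)
        cfg = CalibrationConfig(n_locations=8)
        sets = []
        for k in range(6):
            m = default_model(grid, seed=900 + k)
            meas = simulate_calibration_measurements(
                m, n_locations=8, start_time=3600.0 * k
            )
            sets.append(run_calibration_sequence(meas, cfg))
        report = qc_evaluate(sets[:-1], sets[-1], cfg)
        assert report.passed, report.failures
        for sd in report.phantom_sd.values():
            assert 0.0 < sd <= 0.01
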