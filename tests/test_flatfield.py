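"""Real-time flat-field correction: exact throughput cancellation for
symmetric probes, stream flagging under bending."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberspec.flatfield import (
    ProbeGeometry,
    SymmetricPairSet,
    correct_ratio,
    default_geometry,
    naive_ratio,
    stream_correct,
    validate_symmetry,
)
from fiberspec.measurement import RawMeasurement
from fiberspec.scenarios import (
    ground_truth_region_ratio,
    simulate_calibration_measurements,
    simulate_pair_stream,
)
from fiberspec.calibration import run_calibration_sequence
from fiberspec.simulate import (
    BendingEvent,
    BendingSchedule,
    Sample,
    default_model,
    noise_free,
    white_standard_sample,
)
from fiberspec.spectra import Spectrum, WavelengthGrid, divide

GRID9 = WavelengthGrid(np.linspace(500.0, 600.0, 9))
PAIRS = ((1, 2), (1, 3), (4, 2), (4, 3))


def _const(v, units="counts"):
    return Spectrum(GRID9, np.full(9, float(v)), units)


def _raw(value, illum, collect):
    return RawMeasurement(
        signal=_const(value),
        dark=_const(0.0),
        illum_fiber=illum,
        collect_fiber=collect,
        accumulation=1.0,
    )


def _pair_set(L, t1i, t4i, t2c, t3c, s_alpha, s_beta):
    """Build the four measurements directly from the signal equations."""
    return SymmetricPairSet(
        s21=_raw(L * t1i * t2c * s_alpha, 1, 2),
        s31=_raw(L * t1i * t3c * s_beta, 1, 3),
        s24=_raw(L * t4i * t2c * s_beta, 4, 2),
        s34=_raw(L * t4i * t3c * s_alpha, 4, 3),
    )


ZERO_BG = {p: _const(0.0, "counts_per_s") for p in PAIRS}


class TestCorrectRatio:
    def test_hand_worked_example(self):
        # L=1, T1i=0.9, T4i=1.1, T2c=0.8, T3c=1.2, S_alpha=2, S_beta=0.5:
        # S21=1.44, S34=2.64, S24=0.44, S31=0.54 -> product ratio 16, sqrt 4
        p = _pair_set(1.0, 0.9, 1.1, 0.8, 1.2, 2.0, 0.5)
        assert p.s21.signal.values[0] == pytest.approx(1.44)
        assert p.s34.signal.values[0] == pytest.approx(2.64)
        assert p.s24.signal.values[0] == pytest.approx(0.44)
        assert p.s31.signal.values[0] == pytest.approx(0.54)
        lit = correct_ratio(p, ZERO_BG, mode="literal")
        sq = correct_ratio(p, ZERO_BG, mode="sqrt")
        assert np.allclose(lit.values, 16.0)
        assert np.allclose(sq.values, 4.0)

    def test_equal_regions_give_unity_for_any_throughputs(self):
        p = _pair_set(7.3, 0.31, 1.7, 0.52, 0.09, 1.3, 1.3)
        for mode in ("sqrt", "literal"):
            out = correct_ratio(p, ZERO_BG, mode=mode)
            assert np.allclose(out.values, 1.0, atol=1e-12)

    @given(
        L=st.floats(0.1, 1e4),
        t1i=st.floats(0.05, 1.0),
        t4i=st.floats(0.05, 1.0),
        t2c=st.floats(0.05, 1.0),
        t3c=st.floats(0.05, 1.0),
        sa=st.floats(0.01, 10.0),
        sb=st.floats(0.01, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_sqrt_mode_is_exact_and_literal_is_its_square(
        self, L, t1i, t4i, t2c, t3c, sa, sb
    ):
        p = _pair_set(L, t1i, t4i, t2c, t3c, sa, sb)
        sq = correct_ratio(p, ZERO_BG, mode="sqrt")
        lit = correct_ratio(p, ZERO_BG, mode="literal")
        assert np.allclose(sq.values, sa / sb, rtol=1e-12)
        assert np.allclose(lit.values, sq.values**2, rtol=1e-12)

    def test_output_invariant_under_collection_otf_perturbation(self):
        base = _pair_set(1.0, 0.9, 1.1, 0.8, 1.2, 2.0, 0.5)
        bent = _pair_set(1.0, 0.9, 1.1, 0.8 * 1.015, 1.2, 2.0, 0.5)
        out0 = correct_ratio(base, ZERO_BG)
        out1 = correct_ratio(bent, ZERO_BG)
        assert np.allclose(out0.values, out1.values, rtol=1e-12)
        # while the naive short/long division moves by exactly the 1.5 %
        n0 = naive_ratio(base, ZERO_BG)
        n1 = naive_ratio(bent, ZERO_BG)
        assert np.allclose(n1.values / n0.values, 1.015, rtol=1e-12)

    def test_outer_fiber_relabelling_invariance(self):
        # swapping which outer fiber is called 1 vs 4 (with the measurements
        # relabelled accordingly) must not change the output
        p = _pair_set(2.0, 0.9, 1.1, 0.8, 1.2, 3.0, 0.75)
        swapped = SymmetricPairSet(
            s21=_raw(2.0 * 1.1 * 0.8 * 3.0, 4, 2),
            s31=_raw(2.0 * 1.1 * 1.2 * 0.75, 4, 3),
            s24=_raw(2.0 * 0.9 * 0.8 * 0.75, 1, 2),
            s34=_raw(2.0 * 0.9 * 1.2 * 3.0, 1, 3),
        )
        a = correct_ratio(p, ZERO_BG)
        b = correct_ratio(swapped, ZERO_BG)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_missing_background_is_an_error(self):
        p = _pair_set(1.0, 0.9, 1.1, 0.8, 1.2, 2.0, 0.5)
        bgs = {k: v for k, v in ZERO_BG.items() if k != (4, 3)}
        with pytest.raises(KeyError, match=r"\(4, 3\)"):
            correct_ratio(p, bgs)

    def test_non_positive_inputs_are_masked_not_infinite(self):
        p = _pair_set(1.0, 0.9, 1.1, 0.8, 1.2, 2.0, 0.5)
        p.s31.signal.values[4] = 0.0
        out = correct_ratio(p, ZERO_BG)
        assert out.mask[4]
        assert np.all(np.isfinite(out.values))


class TestSymmetryValidation:
    def test_linear_array_60um_pitch_is_valid(self):
        diag = validate_symmetry(default_geometry(0.060))
        assert diag.valid

    def test_five_micron_displacement_is_named_in_diagnostic(self):
        pos = {i: ((i - 1) * 0.060, 0.0) for i in (1, 2, 3, 4)}
        pos[3] = (pos[3][0] + 0.005, 0.0)
        diag = validate_symmetry(ProbeGeometry(positions=pos))
        assert not diag.valid
        assert "3" in diag.message

    @pytest.mark.parametrize("half_sep", [0.03, 0.1, 0.25])
    def test_any_mirror_symmetric_layout_is_valid(self, half_sep):
        # collectors mirrored about the array centre between two illuminators
        pos = {
            1: (-0.2, 0.0),
            4: (0.2, 0.0),
            2: (-half_sep, 0.0),
            3: (half_sep, 0.0),
        }
        diag = validate_symmetry(ProbeGeometry(positions=pos))
        # brute-force the distance equalities
        d = lambda a, b: abs(pos[a][0] - pos[b][0])
        assert diag.valid == (
            abs(d(1, 2) - d(4, 3)) < 1e-3 and abs(d(1, 3) - d(4, 2)) < 1e-3
        )
        assert diag.valid


@pytest.fixture(scope="module")
def ideal(grid):
    model = noise_free(default_model(grid, seed=21))
    meas = simulate_calibration_measurements(
        model, n_locations=1, background_excess=1.0
    )
    cal = run_calibration_sequence(meas)
    return model, cal


class TestStreamCorrect:
    def test_static_stream_is_constant_and_unflagged(self, grid, ideal):
        model, cal = ideal
        stream = simulate_pair_stream(
            model, white_standard_sample(grid), n_sets=6, start_time=100.0
        )
        res = stream_correct(stream, cal.background)
        assert not any(res.flagged)
        for out in res.outputs:
            assert np.abs(out.values - 1.0).max() <= 1e-9

    def test_mid_set_bend_flags_that_set_only(self, grid, ideal):
        model, cal = ideal
        # event lands between the two frames of set 5
        sched = BendingSchedule([BendingEvent(100.0 + 5 * 0.6 + 0.15, 2, 1.03)])
        stream = simulate_pair_stream(
            model,
            white_standard_sample(grid),
            schedule=sched,
            n_sets=12,
            start_time=100.0,
        )
        res = stream_correct(stream, cal.background)
        assert res.flagged == [False] * 5 + [True] + [False] * 6
        for i, out in enumerate(res.outputs):
            if i != 5:
                assert np.abs(out.values - 1.0).max() <= 1e-9

    def test_bend_and_release_to_new_state_keeps_corrected_output_exact(
        self, grid, ideal
    ):
        # bend, then release to a different state than the original: the
        # corrected ratio recovers, the naive division keeps a persistent error
        model, cal = ideal
        sched = BendingSchedule(
            [
                BendingEvent(100.0 + 3 * 0.6 + 0.15, 2, 1.04),
                BendingEvent(100.0 + 7 * 0.6 + 0.15, 2, 1 / 1.04 * 1.02),
            ]
        )
        stream = simulate_pair_stream(
            model,
            white_standard_sample(grid),
            schedule=sched,
            n_sets=12,
            start_time=100.0,
        )
        res = stream_correct(stream, cal.background)
        assert res.flagged[3] and res.flagged[7]
        for i, out in enumerate(res.outputs):
            if not res.flagged[i]:
                assert np.abs(out.values - 1.0).max() <= 1e-9
        # naive ratio after release differs from before by the residual 2 %
        base = divide(cal.white[(1, 2)], cal.white[(1, 3)])
        n_first = divide(naive_ratio(stream[0], cal.background), base)
        n_last = divide(naive_ratio(stream[-1], cal.background), base)
        assert np.allclose(n_first.values, 1.0, atol=1e-9)
        assert np.allclose(n_last.values / n_first.values, 1.02, rtol=1e-6)

    def test_corrected_beats_naive_tenfold_on_noisy_bending_protocol(
        self, grid, model, clinic_calibration
    ):
        cal = clinic_calibration
        ev = [
            BendingEvent(500 + 2.05, 2, 1.05),
            BendingEvent(500 + 4.85, 3, 0.96),
            BendingEvent(500 + 7.30, 2, 0.97),
            BendingEvent(500 + 9.65, 3, 1.04),
        ]
        stream = simulate_pair_stream(
            model,
            white_standard_sample(grid),
            schedule=BendingSchedule(ev),
            n_sets=25,
            start_time=500.0,
        )
        res = stream_correct(stream, cal.background)
        truth = 1.0
        corr = [
            np.sqrt(np.mean((o.values - truth) ** 2))
            for o, f in zip(res.outputs, res.flagged)
            if not f
        ]
        base = divide(cal.white[(1, 2)], cal.white[(1, 3)])
        naive = [
            np.sqrt(np.mean((divide(naive_ratio(p, cal.background), base).values - truth) ** 2))
            for p in stream
        ]
        rms_corr = np.sqrt(np.mean(np.square(corr)))
        rms_naive = np.sqrt(np.mean(np.square(naive)))
        assert rms_naive / rms_corr >= 10.0
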