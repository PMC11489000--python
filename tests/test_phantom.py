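"""Phantom construction, the breath protocol, and the forward models."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lungmap as lm
from lungmap.phantom import simulate_acquisitions


class TestBreathSchedule:
    def test_default_protocol_structure(self):
        sch = lm.default_schedule(breath_rate=12)
        assert len(sch) == 140
        assert np.all(sch.fio2[:20] == 0.21)          # air baseline first
        assert np.all(sch.fio2[20:60] == 1.0)         # extended first O2 cycle
        assert np.count_nonzero(sch.fio2 == 1.0) == 80  # 40 + 20 + 20
        assert set(np.unique(sch.fio2)) == {0.21, 1.0}

    @pytest.mark.parametrize("rate", [5.0, 25.0])
    def test_breath_rate_bounds(self, rate):
        with pytest.raises(ValueError):
            lm.default_schedule(breath_rate=rate)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            lm.BreathSchedule(fio2=np.array([]))


class TestGasStep:
    @pytest.mark.parametrize(
        "f_prev, f_insp, sv, expected",
        [
            (0.21, 1.0, 0.0, 0.21),          # zero ventilation changes nothing
            (0.21, 0.21, 0.5, 0.21),         # fixed point at equal fractions
            (0.21, 1.0, 0.2, 0.41 / 1.2),    # one dilution step by hand
        ],
    )
    def test_known_steps(self, f_prev, f_insp, sv, expected):
        assert lm.gas_step(f_prev, f_insp, sv) == pytest.approx(expected, abs=1e-12)

    def test_negative_sv_rejected(self):
        with pytest.raises(ValueError):
            lm.gas_step(0.21, 1.0, -0.1)

    @given(
        f_prev=st.floats(0, 1),
        f_insp=st.floats(0, 1),
        sv=st.floats(0, 100, allow_nan=False),
    )
    def test_result_bounded_between_inputs(self, f_prev, f_insp, sv):
        out = lm.gas_step(f_prev, f_insp, sv)
        assert min(f_prev, f_insp) - 1e-12 <= out <= max(f_prev, f_insp) + 1e-12


class TestMakePhantom:
    def test_requested_sv_mean_hit(self):
        ph = lm.make_phantom(shape=(64, 64), sv_mean=0.20, seed=7)
        assert 0.18 <= ph.sv_true[ph.lung_mask].mean() <= 0.22

    def test_same_seed_bit_identical(self):
        a = lm.make_phantom(seed=7)
        b = lm.make_phantom(seed=7)
        for f in ("sv_true", "q_true", "density_true", "coil_field"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            lm.make_phantom(sv_mean=-0.1)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            lm.make_phantom(shape=(16, 16))

    def test_geometry_invariants(self, phantom):
        assert np.all(phantom.sv_true[~phantom.lung_mask] == 0)
        assert np.all(phantom.sv_true >= 0)
        assert not np.any(phantom.vessel_mask & ~phantom.lung_mask)
        assert not np.any(phantom.phantom_roi & phantom.lung_mask)
        assert np.all(phantom.coil_field > 0)
        support = phantom.lung_mask | phantom.phantom_roi
        d = phantom.density_true[support]
        assert np.all((d > 0) & (d <= 1.1))

    def test_vessels_exceed_three_times_parenchymal_median(self, phantom):
        parench = phantom.lung_mask & ~phantom.vessel_mask
        assert phantom.q_true[phantom.vessel_mask].min() > 3 * np.median(
            phantom.q_true[parench]
        )

    def test_degenerate_sv_outside_mask_rejected(self, phantom):
        bad_sv = phantom.sv_true.copy()
        bad_sv[0, 0] = 0.5  # outside the lung
        with pytest.raises(ValueError):
            dataclasses.replace(phantom, sv_true=bad_sv)


class TestSvSeriesForwardModel:
    def test_zero_sv_voxel_is_flat(self, phantom, schedule):
        sv = np.zeros(phantom.shape)
        ph = dataclasses.replace(phantom, sv_true=sv)
        series = lm.simulate_sv_series(ph, schedule, snr=np.inf)
        lung_courses = series[:, ph.lung_mask]
        assert np.allclose(lung_courses, lung_courses[0], atol=1e-12)

    def test_infinite_sv_limit_tracks_inspired_gas(self, phantom, schedule):
        sv = np.where(phantom.lung_mask, 1e3, 0.0)
        ph = dataclasses.replace(phantom, sv_true=sv)
        series = lm.simulate_sv_series(ph, schedule, enhancement=0.12, snr=np.inf)
        r, c = np.argwhere(ph.lung_mask)[0]
        course = series[:, r, c]
        # normalise to [0, 1] washin fraction
        frac = (course - course.min()) / (course.max() - course.min())
        target = (schedule.fio2 - 0.21) / 0.79
        assert np.abs(frac - target).max() < 2e-3  # <= 1-breath lag

    def test_plateau_fraction_closed_form(self, uniform_sv_phantom, schedule):
        """After 40 O2 breaths a unit with SV=0.2 reaches 1-(1/1.2)^40 of
        its plateau (geometric washin)."""
        series = lm.simulate_sv_series(uniform_sv_phantom, schedule, snr=np.inf)
        ph = uniform_sv_phantom
        r, c = np.argwhere(ph.lung_mask)[0]
        course = series[:, r, c]
        s_air = course[19]
        plateau = course[19] + (course[59] - course[19]) / (1 - (1 / 1.2) ** 40)
        frac = (course[59] - s_air) / (plateau - s_air)
        assert frac == pytest.approx(1 - (1 / 1.2) ** 40, rel=1e-9)

    def test_equilibration_monotone_in_sv(self, phantom, schedule):
        """Time to reach 63% of plateau during the first O2 cycle strictly
        decreases as SV increases (noiseless)."""
        times = []
        for sv_val in (0.05, 0.1, 0.2, 0.4, 0.8):
            ph = dataclasses.replace(
                phantom, sv_true=np.where(phantom.lung_mask, sv_val, 0.0)
            )
            series = lm.simulate_sv_series(ph, schedule, snr=np.inf)
            r, c = np.argwhere(ph.lung_mask)[0]
            course = series[:, r, c]
            washin = course[20:60] - course[19]
            frac = washin / washin.max() if washin.max() > 0 else washin
            times.append(np.argmax(frac >= 1 - 1 / np.e))
        assert all(a > b for a, b in zip(times, times[1:]))

    def test_background_carries_no_washin_signal(self, phantom, schedule):
        series = lm.simulate_sv_series(phantom, schedule, snr=np.inf)
        outside = ~(phantom.lung_mask | phantom.phantom_roi)
        assert np.all(series[:, outside] == 0)

    def test_noise_seed_determinism(self, phantom, schedule):
        a = lm.simulate_sv_series(phantom, schedule, snr=20, seed=3)
        b = lm.simulate_sv_series(phantom, schedule, snr=20, seed=3)
        assert np.array_equal(a, b)


class TestAslForwardModel:
    def test_zero_perfusion_zero_subtraction(self, phantom):
        ph = dataclasses.replace(phantom, q_true=np.zeros(phantom.shape),
                                 vessel_mask=np.zeros(phantom.shape, bool))
        sel, nonsel, _ = lm.simulate_asl_pair(ph, snr=np.inf)
        assert np.allclose(sel - nonsel, 0, atol=1e-12)

    def test_doubling_heart_rate_halves_delivery_signal(self, phantom):
        slow = dataclasses.replace(phantom, heart_rate=60.0)
        fast = dataclasses.replace(phantom, heart_rate=120.0)
        sub_slow = np.subtract(*lm.simulate_asl_pair(slow, snr=np.inf)[:2])
        sub_fast = np.subtract(*lm.simulate_asl_pair(fast, snr=np.inf)[:2])
        m = phantom.lung_mask
        assert np.allclose(sub_fast[m], 0.5 * sub_slow[m], rtol=1e-12)

    def test_inversion_delay_is_80pct_rr(self, phantom):
        _, _, ti = lm.simulate_asl_pair(phantom, snr=np.inf)
        assert abs(ti - 0.8 * 60000.0 / phantom.heart_rate) < 1.0  # ms


class TestDualEchoForwardModel:
    def test_echo_ratio_encodes_t2star(self, phantom):
        t2 = np.full(phantom.shape, 2.5)
        e1, e2 = lm.simulate_dual_echo(phantom, te1=0.82, te2=1.8,
                                       t2star_map=t2, snr=np.inf, coil="body")
        m = phantom.lung_mask
        assert np.allclose(e1[m] / e2[m], np.exp((1.8 - 0.82) / 2.5), rtol=1e-12)

    def test_infinite_t2star_limit(self, phantom):
        t2 = np.full(phantom.shape, 1e6)
        e1, e2 = lm.simulate_dual_echo(phantom, t2star_map=t2, snr=np.inf, coil="body")
        m = phantom.lung_mask
        assert np.allclose(e1[m], e2[m], rtol=1e-5)

    def test_zero_density_zero_signal(self, phantom):
        ph = dataclasses.replace(phantom)
        e1, e2 = lm.simulate_dual_echo(ph, snr=np.inf, coil="body")
        outside = ~(phantom.lung_mask | phantom.phantom_roi)
        assert np.all(e1[outside] == 0) and np.all(e2[outside] == 0)

    def test_bad_echo_times_rejected(self, phantom):
        with pytest.raises(ValueError):
            lm.simulate_dual_echo(phantom, te1=2.0, te2=1.0)


def test_full_bundle_is_deterministic(phantom, schedule):
    a = simulate_acquisitions(phantom, schedule, snr=30, seed=11)
    b = simulate_acquisitions(phantom, schedule, snr=30, seed=11)
    assert np.array_equal(a.sv_series, b.sv_series)
    assert np.array_equal(a.asl_selective, b.asl_selective)
    assert np.array_equal(a.echo1_torso, b.echo1_torso)
    assert a.ti == b.ti
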