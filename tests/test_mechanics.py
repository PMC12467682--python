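"""Dual-chamber mechanics: transfer function, muscle drive, active simulation."""

import warnings

import numpy as np
import pytest
from scipy.signal import lsim

from lungsim.mechanics import (
    CYLINDER_CALIBRATION,
    MuscleProfile,
    RespiratoryMechanics,
    actuation_plan,
    build_transfer_function,
    calibration_slope,
    cylinder_position,
    intrapulmonary_pressure,
    muscle_profile,
    position_volume_ratio,
    simulate_active,
    tf_coefficients,
)
from lungsim.presets import get_preset
from lungsim.series import WAVEFORM_CSV_COLUMNS, WaveformSeries

from _oracles import circuit_admittance, single_compartment_admittance


def _mech(**kw):
    base = dict(Rt=4, Rl=1, Rr=1, Cll=35, Clr=35, Ccw=200, r=2.84, RR=16)
    base.update(kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return RespiratoryMechanics(**base)


class TestCoefficients:
    def test_normal_values(self):
        """Hand-checked products for the normal parameter set."""
        c = tf_coefficients(_mech())
        assert c.f1 == pytest.approx(0.001225, rel=1e-12)
        assert c.f4 == pytest.approx(0.07, rel=1e-12)
        assert c.g3 == pytest.approx(0.27, rel=1e-12)
        # the rest, from the same printed definitions evaluated by hand
        assert c.f2 == pytest.approx(0.07, rel=1e-12)
        assert c.f3 == pytest.approx(0.00245, rel=1e-12)
        assert c.g1 == pytest.approx(0.002205, rel=1e-12)
        assert c.g2 == pytest.approx(0.07245, rel=1e-12)
        assert c.g4 == pytest.approx(0.00049, rel=1e-12)
        assert c.g5 == pytest.approx(0.014, rel=1e-12)

    def test_symmetric_lungs(self):
        R, C = 2.0, 50.0
        c = tf_coefficients(_mech(Rl=R, Rr=R, Cll=C, Clr=C))
        assert c.f2 == pytest.approx(2 * R * C / 1000)
        assert c.f3 == pytest.approx(2 * R * (C / 1000) ** 2)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="Cll"):
            _mech(Cll=0.0)
        with pytest.raises(ValueError, match="Rt"):
            _mech(Rt=-1.0)


class TestTransferFunction:
    def test_zero_dc_gain(self):
        tf = build_transfer_function(_mech())
        assert tf(0.0) == 0.0

    def test_stable_for_positive_parameters(self):
        tf = build_transfer_function(_mech())
        assert tf.is_stable()

    def test_numerator_constant_term_zero(self):
        tf = build_transfer_function(_mech())
        assert tf.num[-1] == 0.0

    def test_matches_circuit_oracle_normal(self):
        """Frequency response equals the phasor circuit oracle at 0.25 Hz."""
        mech = _mech()
        tf = build_transfer_function(mech)
        s = 1j * 2 * np.pi * 0.25
        ours = tf(s)
        oracle = -60.0 * circuit_admittance(mech, s)
        assert abs(ours - oracle) / abs(oracle) < 1e-6

    def test_matches_circuit_oracle_random_parameters(self):
        """20 random positive parameter sets, 10 log-spaced frequencies."""
        rng = np.random.default_rng(42)
        omega = 2 * np.pi * np.logspace(-2, 1, 10)
        for _ in range(20):
            mech = _mech(
                Rt=rng.uniform(0.5, 20),
                Rl=rng.uniform(0.5, 50),
                Rr=rng.uniform(0.5, 50),
                Cll=rng.uniform(5, 100),
                Clr=rng.uniform(5, 100),
                Ccw=rng.uniform(50, 250),
            )
            tf = build_transfer_function(mech)
            ours = tf.freqresp(omega)
            oracle = -60.0 * circuit_admittance(mech, 1j * omega)
            np.testing.assert_allclose(ours, oracle, rtol=1e-6)

    def test_symmetric_reduction(self):
        """Symmetric lungs collapse to the single-compartment circuit."""
        mech = _mech(Rl=2, Rr=2, Cll=40, Clr=40)
        tf = build_transfer_function(mech)
        omega = 2 * np.pi * np.logspace(-2, 1, 15)
        reduced = -60.0 * single_compartment_admittance(
            mech.Rt, 2.0, 40.0, mech.Ccw, 1j * omega
        )
        np.testing.assert_allclose(tf.freqresp(omega), reduced, rtol=1e-9)


class TestMuscleProfile:
    def test_peak_equals_pmus_max(self):
        prof = MuscleProfile(Pmus_max=10, RR=16)
        t_peak = prof.rise_fraction * prof.period
        assert muscle_profile(prof, t_peak) == pytest.approx(10.0)

    def test_periodic(self):
        prof = MuscleProfile(Pmus_max=10, RR=16)
        t = np.linspace(0, prof.period, 200)
        np.testing.assert_allclose(
            muscle_profile(prof, t), muscle_profile(prof, t + prof.period),
            atol=1e-12,
        )

    def test_continuous(self):
        prof = MuscleProfile(Pmus_max=10, RR=16)
        t = np.arange(0, 2 * prof.period, 1e-4)
        p = muscle_profile(prof, t)
        assert np.max(np.abs(np.diff(p))) < 0.02  # no jumps at 0.1 ms

    def test_returns_to_zero_in_rest_phase(self):
        prof = MuscleProfile(Pmus_max=10, RR=16)
        t_rest = (prof.rise_fraction + prof.decay_fraction) * prof.period + 0.1
        assert muscle_profile(prof, t_rest) == 0.0

    def test_drive_grid_ordered_at_peak(self):
        """Higher peak drives dominate pointwise at the profile peak."""
        t_peak = 0.35 * (60 / 15)
        vals = [
            muscle_profile(MuscleProfile(Pmus_max=p, RR=15), t_peak)
            for p in (8, 10, 12)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_rise_must_exceed_decay(self):
        with pytest.raises(ValueError):
            MuscleProfile(Pmus_max=10, RR=16, rise_fraction=0.1, decay_fraction=0.2)


class TestSimulateActive:
    def test_zero_drive_zero_response(self):
        mech = _mech()
        s = simulate_active(mech, MuscleProfile(Pmus_max=0.0, RR=16), duration=5.0)
        assert np.all(s.Q == 0) and np.all(s.Vt == 0) and np.all(s.Pl == 0)

    def test_rk4_matches_scipy_lsim(self, normal_preset, normal_active_series):
        """Fixed-step integration agrees with an independent LTI solver."""
        mech, prof = normal_preset.mechanics, normal_preset.profile
        tf = build_transfer_function(mech)
        A, B, C, D = tf.to_statespace()
        s = normal_active_series
        u = -muscle_profile(prof, s.t)
        _, y, _ = lsim((A, B, C, D), u, s.t)
        # lsim holds the input piecewise-linear; RK4 samples it exactly at
        # the midpoints — agreement to ~1e-5 relative at the 1 ms step
        assert np.max(np.abs(s.Q - y)) < 1e-4 * np.max(np.abs(s.Q))

    def test_volume_is_integral_of_flow(self, normal_active_series):
        s = normal_active_series
        vt = np.concatenate(
            [[0.0], np.cumsum((s.Q[1:] + s.Q[:-1]) / 2) / 60.0 * s.dt * 1e3]
        )
        assert np.max(np.abs(s.Vt - vt)) < 0.1  # mL

    def test_expiratory_peak_exceeds_inspiratory(self, normal_active_series):
        s = normal_active_series
        m = s.t >= 2 * (60 / 16)
        assert -s.Q[m].min() > s.Q[m].max()

    def test_severe_ards_smaller_tidal_volume_than_mild(self):
        vts = {}
        for sev in ("mild", "severe"):
            p = get_preset(f"ards:{sev}")
            s = simulate_active(p.mechanics, p.profile, duration=4 * p.profile.period)
            m = s.t >= 2 * p.profile.period
            vts[sev] = s.Vt[m].max()
        assert vts["severe"] < vts["mild"]

    def test_drive_monotonicity(self):
        """Peak |Q|, peak |Pl| and max Vt all increase strictly with drive."""
        rows = []
        for key in ("pmus1", "pmus2", "pmus3"):
            p = get_preset(key)
            s = simulate_active(p.mechanics, p.profile, duration=4 * p.profile.period)
            m = s.t >= 2 * p.profile.period
            rows.append((np.abs(s.Q[m]).max(), np.abs(s.Pl[m]).max(), s.Vt[m].max()))
        for a, b in zip(rows, rows[1:]):
            assert all(x < y for x, y in zip(a, b))

    def test_severity_ordering_both_families(self):
        """Tidal volume is non-increasing with severity at fixed drive."""
        for family in ("ards", "copd"):
            vts = []
            for sev in ("mild", "moderate", "severe"):
                p = get_preset(f"{family}:{sev}")
                s = simulate_active(p.mechanics, p.profile,
                                    duration=4 * p.profile.period)
                m = s.t >= 2 * p.profile.period
                vts.append(s.Vt[m].max())
            assert vts[0] >= vts[1] >= vts[2]

    def test_dt_above_control_cycle_refused(self):
        with pytest.raises(ValueError, match="dt"):
            simulate_active(_mech(), MuscleProfile(Pmus_max=10, RR=16),
                            duration=5.0, dt=5e-3)

    def test_duration_must_cover_one_breath(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_active(_mech(), MuscleProfile(Pmus_max=10, RR=16), duration=1.0)


class TestIntrapulmonaryPressure:
    def test_zero_flow(self):
        assert intrapulmonary_pressure(0.0, 2.84) == 0.0

    def test_magnitude_and_sign(self):
        # (2.84 * 0.5)^2, suction during inspiration
        assert intrapulmonary_pressure(0.5, 2.84) == pytest.approx(-2.0164)
        assert intrapulmonary_pressure(-0.5, 2.84) == pytest.approx(2.0164)

    def test_even_magnitude(self):
        Q = np.linspace(-2, 2, 41)
        pl = intrapulmonary_pressure(Q, 3.0)
        np.testing.assert_allclose(np.abs(pl), np.abs(pl[::-1]), atol=1e-12)


class TestActuationPlan:
    def _series(self, vt_mL, q_lmin):
        n = len(vt_mL)
        return WaveformSeries(
            t=np.arange(n) * 1e-3, Q=np.asarray(q_lmin, float),
            Pl=np.zeros(n), Vt=np.asarray(vt_mL, float), Pmus=np.zeros(n),
        )

    def test_home_position_at_zero_volume(self):
        x, v = actuation_plan(self._series([0.0, 0.0], [0.0, 0.0]))
        assert x[0] == pytest.approx(0.423)
        assert v[0] == 0.0

    def test_position_at_one_litre(self):
        # sum of the calibration coefficients
        x, _ = actuation_plan(self._series([0.0, 1000.0], [0.0, 10.0]))
        assert x[1] == pytest.approx(7.8208)

    def test_zero_flow_zero_speed(self):
        _, v = actuation_plan(self._series([0.0, 500.0], [0.0, 0.0]))
        assert np.all(v == 0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="calibration range"):
            actuation_plan(self._series([0.0, 1500.0], [0.0, 10.0]))

    def test_secant_guard_and_slope(self):
        assert position_volume_ratio(0.0) == pytest.approx(CYLINDER_CALIBRATION[2])
        assert calibration_slope(0.0) == pytest.approx(5.6886)
        # slope bounded over the fitted range
        vt = np.linspace(0, 1, 101)
        sl = calibration_slope(vt)
        assert sl.min() > 5.5 and sl.max() < 8.2


class TestWaveformSeries:
    def test_csv_round_trip(self, tmp_path, normal_active_series):
        path = tmp_path / "wave.csv"
        normal_active_series.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == ",".join(WAVEFORM_CSV_COLUMNS)
        back = WaveformSeries.from_csv(path)
        np.testing.assert_allclose(back.Q, normal_active_series.Q, rtol=1e-9)
        np.testing.assert_allclose(back.Vt, normal_active_series.Vt, atol=1e-6)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            WaveformSeries(t=[0, 1, 3], Q=[0, 0, 0], Pl=[0, 0, 0],
                           Vt=[0, 0, 0], Pmus=[0, 0, 0])
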