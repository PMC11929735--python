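import numpy as np
import pytest

import neurorun as nr
from neurorun.analysis import (MetabolicParams, WorkLedger, accumulate_work,
                               basal_cot, basal_energy, cost_of_transport,
                               detect_gait_events, muscle_energy,
                               normalize_stance, pontzer_cot, rms_difference,
                               stance_intervals, torso_longitudinal_rotation)


class TestWorkAccumulation:
    def test_constant_positive_power(self):
        led = WorkLedger.empty(["m"], ["lower_limb"])
        for _ in range(2000):
            led = accumulate_work(led, np.array([10.0]), 1e-3)
        assert led.w_pos[0] == pytest.approx(20.0)
        assert led.w_neg[0] == 0.0

    def test_constant_negative_power(self):
        led = WorkLedger.empty(["m"], ["torso"])
        for _ in range(2000):
            led = accumulate_work(led, np.array([-5.0]), 1e-3)
        assert led.w_neg[0] == pytest.approx(-10.0)

    def test_sinusoidal_power_splits_symmetrically(self):
        led = WorkLedger.empty(["m"], ["lower_limb"])
        dt = 1e-4
        t = np.arange(0, 1.0, dt)
        for p in 7.0 * np.sin(2 * np.pi * t):
            led = accumulate_work(led, np.array([p]), dt)
        assert led.w_pos[0] == pytest.approx(-led.w_neg[0], rel=1e-3)

    def test_dt_validation(self):
        led = WorkLedger.empty(["m"], ["torso"])
        with pytest.raises(ValueError):
            accumulate_work(led, np.array([1.0]), 0.0)


class TestMetabolicEnergy:
    def test_positive_work_efficiency(self):
        assert muscle_energy(1.0, 0.0) == pytest.approx(4.0)

    def test_negative_work_efficiency(self):
        assert muscle_energy(0.0, -1.2) == pytest.approx(1.0)

    def test_zero_work_zero_energy(self):
        assert muscle_energy(0.0, 0.0) == 0.0

    def test_sign_violations_rejected(self):
        with pytest.raises(ValueError):
            muscle_energy(-1.0, 0.0)
        with pytest.raises(ValueError):
            muscle_energy(0.0, 0.5)

    def test_energy_nonnegative_for_admissible_ledgers(self, rng):
        wp = rng.uniform(0, 50, 100)
        wn = -rng.uniform(0, 50, 100)
        assert np.all(muscle_energy(wp, wn) >= 0.0)

    def test_basal_energy_for_the_model_subject(self):
        assert basal_energy(65.4, 1.0) == pytest.approx(78.48)

    @pytest.mark.parametrize("speed,rounded", [(3.24, 0.37), (3.11, 0.39),
                                               (3.20, 0.37)])
    def test_basal_cot_at_reported_speeds(self, speed, rounded):
        assert round(basal_cot(speed), 2) == rounded

    def test_zero_speed_undefined(self):
        with pytest.raises(ValueError):
            basal_cot(0.0)


def _ledger_for_cots(cots, mass, distance):
    """Ledger whose positive work yields exactly the requested per-group CoT."""
    names, groups, wpos = [], [], []
    for g, cot in cots.items():
        names.append(g)
        groups.append(g)
        wpos.append(cot * mass * distance * MetabolicParams().eff_pos)
    return WorkLedger(names, groups, np.array(wpos), np.zeros(len(wpos)))


class TestCostOfTransport:
    def test_gross_is_component_sum(self):
        mass, speed, duration = 65.4, 3.24, 20.0
        distance = speed * duration
        led = _ledger_for_cots({"upper_limb": 0.71, "torso": 0.55,
                                "lower_limb": 3.89}, mass, distance)
        rep = cost_of_transport(led, mass, distance, duration)
        assert rep.gross_cot == pytest.approx(
            rep.group_cot["upper_limb"] + rep.group_cot["torso"]
            + rep.group_cot["lower_limb"] + rep.basal_cot, abs=1e-12)
        assert round(rep.gross_cot, 2) == 5.52

    def test_empty_ledger_reports_basal_only(self):
        led = WorkLedger.empty([], [])
        rep = cost_of_transport(led, 70.0, 60.0, 20.0)
        assert rep.gross_cot == pytest.approx(rep.basal_cot)

    def test_doubling_distance_halves_every_entry(self):
        led = _ledger_for_cots({"lower_limb": 2.0}, 60.0, 50.0)
        r1 = cost_of_transport(led, 60.0, 50.0, 20.0)
        r2 = cost_of_transport(led, 60.0, 100.0, 40.0)
        assert r2.group_cot["lower_limb"] == pytest.approx(
            r1.group_cot["lower_limb"] / 2)
        assert r2.basal_cot == pytest.approx(r1.basal_cot)  # same speed

    def test_mean_speed_is_distance_over_duration(self):
        led = WorkLedger.empty([], [])
        rep = cost_of_transport(led, 70.0, 64.8, 20.0)
        assert rep.mean_speed == pytest.approx(64.8 / 20.0)


def test_pontzer_formula_at_reported_speed():
    assert round(pontzer_cot(3.24), 2) == 3.70


class TestGaitEvents:
    def test_square_wave_edges(self):
        dt = 0.01
        z = np.zeros(300)
        z[100:200] = 800.0
        hs, to = detect_gait_events(z, dt, threshold=20.0)
        assert hs == pytest.approx([1.0])
        assert to == pytest.approx([2.0])

    def test_flight_only_trace_has_no_events(self):
        hs, to = detect_gait_events(np.zeros(500), 0.01)
        assert len(hs) == 0 and len(to) == 0

    def test_noisy_square_wave_with_debounce(self, rng):
        dt = 1 / 600
        period = 0.7
        t = np.arange(0, 3.5, dt)
        phase = t % period
        z = np.where((phase >= 0.3) & (phase < 0.55), 800.0, 0.0)
        z += rng.normal(0, 10.0, len(t))
        hs, to = detect_gait_events(z, dt, threshold=20.0, debounce=0.05)
        assert len(hs) == 5
        assert len(to) == 5
        # a noise spike just before a true edge can latch an event up to one
        # debounce window early; accuracy is bounded by that window
        assert np.abs(hs - (0.3 + np.arange(5) * period)).max() <= 0.05 + 1e-9
        assert np.abs(to - (0.55 + np.arange(5) * period)).max() <= 0.05 + 1e-9

    def test_events_stable_under_2x_resampling(self, rng):
        dt = 0.01
        t = np.arange(0, 3.0, dt)
        z = 800 * np.clip(np.sin(2 * np.pi * t / 0.75), 0, None)
        hs1, _ = detect_gait_events(z, dt)
        t2 = np.arange(0, 3.0, dt / 2)
        z2 = np.interp(t2, t, z)
        hs2, _ = detect_gait_events(z2, dt / 2)
        assert len(hs1) == len(hs2)
        assert np.abs(np.array(hs1) - np.array(hs2)).max() <= dt


class TestStanceNormalization:
    def test_constant_trace(self):
        out = normalize_stance(np.full(100, 3.3), 0.01, (0.2, 0.6))
        assert np.allclose(out, 3.3)
        assert len(out) == 101

    def test_linear_ramp_preserves_endpoints(self):
        trace = np.arange(100) * 2.0
        out = normalize_stance(trace, 0.01, (0.1, 0.5))
        assert out[0] == pytest.approx(trace[10])
        assert out[-1] == pytest.approx(trace[50])
        assert np.allclose(np.diff(out), np.diff(out)[0])

    def test_half_sine_round_trip_error_below_1pct(self):
        dt = 1 / 60
        dur = 0.3
        t = np.arange(0, 0.5, dt)
        z = 800 * np.sin(np.pi * np.clip(t, 0, dur) / dur) * (t <= dur)
        curve = normalize_stance(z, dt, (0.0, dur))
        ts = np.linspace(0, dur, 101)
        back = np.interp(t[t <= dur], ts, curve)
        assert np.abs(back - z[t <= dur]).max() < 0.01 * 800

    def test_too_short_interval(self):
        with pytest.raises(ValueError):
            normalize_stance(np.zeros(100), 0.01, (0.5, 0.505))


def _yaw_rig():
    return nr.build_model({
        "bodies": [
            {"name": "pelvis", "mass": 10, "inertia": [0.1, 0.1, 0.1]},
            {"name": "torso", "mass": 20, "inertia": [0.3, 0.3, 0.2],
             "com": [0, 0, 0.2]},
        ],
        "joints": [
            {"name": "root", "type": "free6", "child": "pelvis"},
            {"name": "thoraco", "type": "spherical3", "parent": "pelvis",
             "child": "torso", "translation": [0, 0, 0.1]},
        ],
    })


class TestTorsoRotation:
    def test_rigid_torso_zero_range(self):
        m = _yaw_rig()
        q, _ = m.default_state_arrays()
        trace, rng_ = torso_longitudinal_rotation(m, np.tile(q, (50, 1)))
        assert rng_ == pytest.approx(0.0, abs=1e-12)

    def test_sinusoidal_yaw_range_is_twice_amplitude(self):
        m = _yaw_rig()
        A = np.deg2rad(15.0)
        qs = []
        for t in np.linspace(0, 1, 200, endpoint=False):
            q, _ = m.default_state_arrays()
            q[m.q_coord_index("thoraco_z")] = A * np.sin(2 * np.pi * t)
            qs.append(q)
        _, rng_ = torso_longitudinal_rotation(m, np.array(qs))
        assert rng_ == pytest.approx(30.0, rel=1e-3)

    def test_robust_to_constant_pelvis_roll(self):
        from neurorun._math import mat_to_quat, rot_x
        m = _yaw_rig()
        A = np.deg2rad(15.0)
        qroll = mat_to_quat(rot_x(np.deg2rad(10.0)))
        qs = []
        for t in np.linspace(0, 1, 200, endpoint=False):
            q, _ = m.default_state_arrays()
            q[0:4] = qroll
            q[m.q_coord_index("thoraco_z")] = A * np.sin(2 * np.pi * t)
            qs.append(q)
        _, rng_ = torso_longitudinal_rotation(m, np.array(qs))
        assert abs(rng_ - 30.0) < 0.5

    def test_missing_torso_body(self):
        m = nr.build_model({
            "bodies": [{"name": "pelvis", "mass": 1, "inertia": [1, 1, 1]}],
            "joints": [{"name": "root", "type": "free6", "child": "pelvis"}],
        })
        with pytest.raises(ValueError):
            torso_longitudinal_rotation(m, np.zeros((1, 7)))


class TestRMSDifference:
    def test_identical_curves(self):
        x = np.linspace(0, 1, 101)
        assert rms_difference(x, x) == 0.0

    def test_constant_offset(self):
        x = np.linspace(0, 1, 101)
        assert rms_difference(x, x + 2.5) == pytest.approx(2.5)

    def test_sine_vs_zero_is_amplitude_over_sqrt2(self):
        t = np.linspace(0, 4, 4000, endpoint=False)
        s = 3.0 * np.sin(2 * np.pi * t)
        assert rms_difference(s, np.zeros_like(s)) == pytest.approx(
            3.0 / np.sqrt(2), rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rms_difference(np.zeros(5), np.zeros(6))


def test_stance_intervals_pairing():
    hs = np.array([0.1, 0.8, 1.5])
    to = np.array([0.4, 1.1])
    ivs = stance_intervals(hs, to)
    assert ivs == [(0.1, 0.4), (0.8, 1.1)]
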