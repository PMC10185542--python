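import math

import numpy as np
import pytest

from aortasim import (
    ChamberPressures,
    analytic_wave_speed,
    default_wall_material,
    extract_features,
    measure_ptt,
    simulate_config,
)
from aortasim.experiments import generate_fixture
from aortasim.units import PA_PER_MMHG
from aortasim.wave_engine import (
    PressureWaveform,
    PTTError,
    SimulationError,
    SimulationSettings,
    characteristic_impedance,
    reflection_coefficient,
    terminal_resistance,
    waveforms_to_frame,
)


class TestCharacteristicImpedance:
    def test_hand_evaluation_with_unit_conversion(self):
        area = math.pi * 0.014**2
        oracle = 1000.0 * 6.54 / area / PA_PER_MMHG / 1e6
        assert characteristic_impedance(0.028, 6.54, 1000.0) == pytest.approx(oracle, rel=1e-12)

    def test_doubling_area_halves_impedance(self):
        z1 = characteristic_impedance(0.02, 6.0, 1000.0)
        z2 = characteristic_impedance(0.02 * math.sqrt(2), 6.0, 1000.0)
        assert z2 == pytest.approx(z1 / 2, rel=1e-12)

    def test_linear_in_wave_speed(self):
        z1 = characteristic_impedance(0.02, 5.0, 1000.0)
        z2 = characteristic_impedance(0.02, 10.0, 1000.0)
        assert z2 == pytest.approx(2 * z1, rel=1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            characteristic_impedance(0.0, 6.0, 1000.0)


class TestTerminalResistance:
    def test_calibration_anchor(self):
        assert terminal_resistance(0.15, 1.7) == pytest.approx(1.7, rel=1e-14)

    def test_monotone_in_occlusion(self):
        values = [terminal_resistance(o, 1.0) for o in (0.05, 0.15, 0.25)]
        assert values[0] < values[1] < values[2]

    def test_fully_open_limit(self):
        assert terminal_resistance(0.0, 2.0) == pytest.approx(2.0 * 0.85**2, rel=1e-14)

    def test_complete_closure_rejected(self):
        with pytest.raises(ValueError):
            terminal_resistance(1.0, 1.0)


class TestReflectionCoefficient:
    def test_matched_load(self):
        assert reflection_coefficient(1.3, 1.3) == 0.0

    def test_closed_end(self):
        assert reflection_coefficient(1.3, math.inf) == 1.0

    def test_hand_value(self):
        assert reflection_coefficient(1.0, 3.0) == pytest.approx(0.5)

    def test_bounded(self):
        for r in (0.0, 0.1, 1.0, 50.0):
            assert -1.0 <= reflection_coefficient(0.8, r) <= 1.0


class TestSimulateStandard:
    def test_reproduces_human_standard_pressures(self, standard_features):
        assert standard_features.sbp == pytest.approx(120.0, abs=1.0)
        assert standard_features.dbp == pytest.approx(80.0, abs=1.0)

    def test_pulse_pressure_increases_toward_bifurcation(self, standard):
        g = standard.geometry
        sensors = [s for s in g.sensor_positions if s <= g.reflection_position]
        sensors.append(g.ab_position)
        sensors.sort()
        waveforms = simulate_config(standard, sensor_positions=sensors)
        pps = [extract_features(w).pp for w in waveforms]
        assert all(b > a for a, b in zip(pps, pps[1:]))

    def test_periodic_steady_state(self, standard_waveforms, standard):
        n = int(round(standard.settings.sample_rate * standard.cardiac.period))
        for w in standard_waveforms.values():
            assert np.max(np.abs(w.samples[:n] - w.samples[n : 2 * n])) < 0.1

    def test_all_samples_finite(self, standard_waveforms):
        for w in standard_waveforms.values():
            assert np.all(np.isfinite(w.samples))


class TestMatchedLoad:
    def test_no_reflection_means_pure_delay_and_no_augmentation(self, standard):
        mat = default_wall_material()
        c = analytic_wave_speed(mat, standard.pressures, standard.geometry, standard.settings)
        from aortasim.wave_engine import characteristic_impedance as zc
        from aortasim.vessel_geometry import diameter_at

        z_ab = zc(diameter_at(standard.geometry, standard.geometry.reflection_position), c,
                  standard.settings.fluid_density)
        cfg = standard.with_overrides(load__reflection_resistance_ref=z_ab)
        g = cfg.geometry
        aa, ab = simulate_config(cfg, sensor_positions=[g.aa_position, g.ab_position])
        # identical shape up to the propagation delay
        delay = g.sensor_distance_aa_ab / c
        shift = int(round(delay * aa.sample_rate))
        a_sig = aa.samples[: len(aa.samples) - shift]
        b_sig = ab.samples[shift:]
        assert np.max(np.abs(a_sig - b_sig)) < 0.15  # sub-sample interpolation residue
        f = extract_features(aa)
        assert f.ap is None or f.ap < 0.5

    def test_ptt_still_measurable(self, standard):
        cfg = standard.with_overrides(load__reflection_resistance_ref=0.2452)
        g = cfg.geometry
        aa, ab = simulate_config(cfg, sensor_positions=[g.aa_position, g.ab_position])
        ptt = measure_ptt(aa, ab, g.sensor_distance_aa_ab)
        assert ptt.dt > 0


class TestDelayLineEquivalence:
    def test_measured_ptt_matches_analytic_speed_within_one_sample(self, standard):
        g = standard.geometry
        c = analytic_wave_speed(
            default_wall_material(), standard.pressures, g, standard.settings
        )
        for fs in (1000.0, 4000.0):
            cfg = standard.with_overrides(settings__sample_rate=fs)
            aa, ab = simulate_config(cfg, sensor_positions=[g.aa_position, g.ab_position])
            ptt = measure_ptt(aa, ab, g.sensor_distance_aa_ab)
            assert abs(ptt.dt - g.sensor_distance_aa_ab / c) <= 1.0 / fs


class TestLevelShiftInvariance:
    def test_tp_zero_levels_shift_without_shape_change(self, standard):
        g = standard.geometry
        reference = None
        ptts = []
        for level in (40.0, 60.0, 80.0, 100.0, 120.0):
            cfg = standard.with_overrides(
                pressures__ivp_offset=level, pressures__evp=level
            )
            aa, ab = simulate_config(cfg, sensor_positions=[g.aa_position, g.ab_position])
            centred = aa.samples - np.mean(aa.samples)
            if reference is None:
                reference = centred
            assert np.max(np.abs(centred - reference)) < 0.1
            ptts.append(measure_ptt(aa, ab, g.sensor_distance_aa_ab).dt)
        assert np.ptp(ptts) <= 1.0 / standard.settings.sample_rate


class TestTransmuralPressureEffects:
    def test_raising_tp_slows_the_waves(self, standard):
        speeds = [
            analytic_wave_speed(default_wall_material(), ChamberPressures(86.0 + tp, 86.0))
            for tp in (0.0, 10.0, 20.0)
        ]
        assert speeds[0] > speeds[1] > speeds[2]
        assert speeds[0] == pytest.approx(6.51, abs=0.01)
        assert speeds[2] == pytest.approx(3.13, abs=0.01)


class TestMeasurePtt:
    def test_constructed_shift_recovered(self):
        prox, dist, delay = generate_fixture("shifted_pair")
        ptt = measure_ptt(prox, dist, 0.5)
        assert abs(ptt.dt - delay) <= 1.0 / prox.sample_rate
        assert ptt.pwv == pytest.approx(0.5 / delay, rel=0.03)

    def test_identical_waveforms_rejected(self):
        w = generate_fixture("gaussian_pulse_train")
        with pytest.raises(PTTError):
            measure_ptt(w, w, 0.5)

    def test_flat_signal_rejected(self):
        w = PressureWaveform(np.full(2000, 90.0), 1000.0, 0.0)
        with pytest.raises(PTTError):
            measure_ptt(w, w, 0.5)


class TestValidation:
    def test_non_finite_samples_rejected(self):
        bad = np.full(100, 80.0)
        bad[3] = np.nan
        with pytest.raises(SimulationError):
            PressureWaveform(bad, 1000.0, 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sample_rate=100.0),
            dict(n_beats=2),
            dict(root_reflection_coefficient=1.0),
            dict(n_reflections=0),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSettings(**kwargs)


class TestNoiseInjection:
    def test_seeded_noise_is_reproducible(self, standard):
        w1 = simulate_config(standard, sensor_positions=[0.0], noise_mmhg=0.5, seed=7)[0]
        w2 = simulate_config(standard, sensor_positions=[0.0], noise_mmhg=0.5, seed=7)[0]
        w3 = simulate_config(standard, sensor_positions=[0.0], noise_mmhg=0.5, seed=8)[0]
        assert np.array_equal(w1.samples, w2.samples)
        assert not np.array_equal(w1.samples, w3.samples)


def test_tidy_frame_export(standard_waveforms):
    df = waveforms_to_frame(list(standard_waveforms.values()))
    assert list(df.columns) == ["time_s", "sensor_position_m", "pressure_mmHg"]
    assert df.sensor_position_m.nunique() == 3
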