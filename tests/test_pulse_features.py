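import numpy as np
import pytest

from aortasim import extract_features, simulate_config
from aortasim.experiments import generate_fixture
from aortasim.pulse_features import (
    FeatureError,
    aix,
    cfpwv_to_apwv,
    lowpass_filter,
    map_formula,
    read_waveform_csv,
    write_waveform_csv,
)
from aortasim.wave_engine import PressureWaveform


class TestMapFormula:
    @pytest.mark.parametrize(
        "sbp, dbp, expected", [(120.0, 80.0, 93.3), (100.0, 70.0, 80.0), (95.0, 95.0, 95.0)]
    )
    def test_values(self, sbp, dbp, expected):
        assert round(map_formula(sbp, dbp), 1) == expected

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError):
            map_formula(70.0, 100.0)


class TestAix:
    @pytest.mark.parametrize("ap, pp, expected", [(5.3, 40.0, 13.3), (0.0, 40.0, 0.0), (10.0, 40.0, 25.0)])
    def test_values(self, ap, pp, expected):
        assert aix(ap, pp) == pytest.approx(expected, abs=0.06)  # printed precision

    def test_zero_pulse_pressure_rejected(self):
        with pytest.raises(ValueError):
            aix(1.0, 0.0)


class TestCfpwvConversion:
    def test_target_aortic_speed(self):
        assert round(cfpwv_to_apwv(7.52), 2) == 6.54

    def test_definition(self):
        assert cfpwv_to_apwv(10.0) == pytest.approx(8.7)

    def test_contraction(self):
        for v in (1.0, 6.0, 12.0):
            assert cfpwv_to_apwv(v) < v


class TestLowpassFilter:
    def test_constant_unchanged(self):
        w = PressureWaveform(np.full(4000, 93.3), 1000.0, 0.0)
        out = lowpass_filter(w)
        assert np.allclose(out.samples, 93.3, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        t = np.arange(8000) / 1000.0
        w = PressureWaveform(100 + 10 * np.sin(2 * np.pi * 5 * t), 1000.0, 0.0)
        out = lowpass_filter(w, 30.0)
        mid = out.samples[2000:-2000]
        assert np.ptp(mid) == pytest.approx(20.0, rel=0.01)

    def test_stopband_attenuated(self):
        t = np.arange(8000) / 1000.0
        w = PressureWaveform(100 + 10 * np.sin(2 * np.pi * 100 * t), 1000.0, 0.0)
        out = lowpass_filter(w, 30.0)
        mid = out.samples[2000:-2000] - 100.0
        assert np.max(np.abs(mid)) < 10.0 * 10 ** (-20 / 20)  # > 20 dB down

    def test_cutoff_above_nyquist_rejected(self):
        w = PressureWaveform(np.zeros(100) + 1.0, 200.0, 0.0)
        with pytest.raises(ValueError):
            lowpass_filter(w, 150.0)


class TestExtractFeatures:
    def test_sinusoid_closed_form(self):
        w = generate_fixture("sinusoid")
        f = extract_features(w)
        assert f.sbp == pytest.approx(120.0, abs=0.05)
        assert f.dbp == pytest.approx(80.0, abs=0.05)
        assert f.pp == pytest.approx(40.0, abs=0.1)
        assert f.map_integral == pytest.approx(100.0, abs=0.1)
        assert f.map_formula == pytest.approx(93.3, abs=0.1)

    def test_invariants_on_fixtures(self):
        for kind in ("sinusoid", "gaussian_pulse_train", "standard_like"):
            f = extract_features(generate_fixture(kind))
            assert f.dbp <= f.map_integral <= f.sbp
            assert f.pp == pytest.approx(f.sbp - f.dbp, abs=1e-9)

    def test_offset_invariance(self):
        w = generate_fixture("standard_like")
        f0 = extract_features(w)
        w2 = PressureWaveform(w.samples + 17.0, w.sample_rate, w.sensor_position, w.t0)
        f1 = extract_features(w2)
        assert f1.sbp == pytest.approx(f0.sbp + 17.0, abs=1e-6)
        assert f1.pp == pytest.approx(f0.pp, abs=1e-9)
        if f0.ap is not None:
            assert f1.ap == pytest.approx(f0.ap, abs=1e-9)
            assert f1.aix == pytest.approx(f0.aix, abs=1e-9)

    def test_standard_simulation_augmentation(self, standard_features):
        # mid-range human augmentation reproduced by the calibrated defaults
        assert standard_features.ap == pytest.approx(5.3, abs=1.5)
        assert standard_features.aix == pytest.approx(13.3, abs=3.0)

    def test_map_formula_underestimates_integral_mean(self, standard_features):
        assert standard_features.map_formula < standard_features.map_integral

    def test_flat_signal_raises(self):
        w = PressureWaveform(np.full(3000, 85.0), 1000.0, 0.0)
        with pytest.raises(FeatureError):
            extract_features(w)

    def test_reflected_free_waveform_has_no_augmentation(self, standard):
        from aortasim.wave_engine import characteristic_impedance
        from aortasim.vessel_geometry import diameter_at
        from aortasim import analytic_wave_speed, default_wall_material

        c = analytic_wave_speed(default_wall_material(), standard.pressures,
                                standard.geometry, standard.settings)
        z_ab = characteristic_impedance(
            diameter_at(standard.geometry, standard.geometry.reflection_position),
            c, standard.settings.fluid_density)
        cfg = standard.with_overrides(load__reflection_resistance_ref=z_ab)
        f = extract_features(simulate_config(cfg, sensor_positions=[0.0])[0])
        assert f.ap is None or f.ap < 0.5


class TestCsvIo:
    def test_round_trip(self, tmp_path):
        w = generate_fixture("standard_like")
        path = tmp_path / "wave.csv"
        write_waveform_csv(w, path)
        again = read_waveform_csv(path)
        assert again.sample_rate == pytest.approx(w.sample_rate, rel=1e-9)
        assert np.allclose(again.samples, w.samples)
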