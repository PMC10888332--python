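import math

import numpy as np
import pytest
from scipy.signal import hilbert

from pwqus.acoustic import (
    PlaneWaveRF,
    ProbeConfig,
    ScattererField,
    beamform_das,
    generate_scatterers,
    load_rf,
    save_rf,
    simulate_rf,
    transmit_delays,
)
from pwqus.phantom import LesionClass, TissuePhantom, uniform_phantom


class TestTransmitDelays:
    def test_broadside_is_all_zero(self, probe):
        np.testing.assert_array_equal(transmit_delays(probe, 0.0), 0.0)

    def test_printed_formula_case(self):
        # element 64, 0.3 mm pitch, 10 degrees, 1540 m/s -> 2.165 us
        probe = ProbeConfig(pitch_mm=0.3, c_ref=1540.0)
        d = transmit_delays(probe, 10.0)
        assert d[64] == pytest.approx(2.165e-6, rel=1e-3)

    @pytest.mark.parametrize("angle", [3.0, 10.0, 45.0])
    def test_odd_symmetry_in_angle(self, probe, angle):
        np.testing.assert_allclose(
            transmit_delays(probe, -angle), -transmit_delays(probe, angle), atol=1e-18
        )

    def test_steep_angle_rejected(self, probe):
        with pytest.raises(ValueError):
            transmit_delays(probe, 90.0)


class TestGenerateScatterers:
    def test_zero_concentration_gives_empty_field(self):
        base = uniform_phantom(grid_shape=(64, 64))
        ph = TissuePhantom(
            ac_map=base.ac_map,
            sos_map=base.sos_map,
            density_map=base.density_map,
            esd_map=base.esd_map,
            esc_map=np.zeros_like(base.esc_map),
            pixel_pitch_mm=base.pixel_pitch_mm,
            lesion_mask=base.lesion_mask,
            lesion_class=LesionClass.none,
        )
        assert len(generate_scatterers(ph, 0)) == 0

    def test_count_matches_poisson_expectation(self):
        esc = 2.0
        ph = uniform_phantom(esc=esc, grid_shape=(256, 256))  # 51.2 mm square
        field = generate_scatterers(ph, 123)
        lam = 1540.0 / 5e6 * 1e3
        expected = esc * (51.2 * 51.2) / lam**2
        assert abs(len(field) - expected) < 3 * math.sqrt(expected)

    def test_deterministic_under_seed(self):
        ph = uniform_phantom(grid_shape=(64, 64))
        a = generate_scatterers(ph, 9)
        b = generate_scatterers(ph, 9)
        np.testing.assert_array_equal(a.positions_mm, b.positions_mm)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_positions_inside_roi(self):
        ph = uniform_phantom(grid_shape=(64, 64))
        field = generate_scatterers(ph, 5)
        assert (field.positions_mm >= 0).all()
        assert (field.positions_mm <= 12.8).all()


class TestSimulateRF:
    def test_single_scatterer_two_way_time_of_flight(self, single_scatterer_rf):
        rf = single_scatterer_rf
        el = rf.probe.element_positions_mm(rf.roi_mm[0])
        e = int(np.argmin(np.abs(el - 12.8)))
        env = np.abs(hilbert(rf.data[0, e]))
        t_peak = np.argmax(env) / rf.probe.sampling_rate_hz
        assert t_peak == pytest.approx(2 * 0.020 / 1540.0, abs=2 / rf.probe.sampling_rate_hz)

    def test_arrival_shift_matches_sound_speed_ratio(self, single_angle_probe):
        sc = ScattererField(
            positions_mm=np.array([[12.8, 20.0]]),
            amplitudes=np.array([1.0]),
            esd_um=np.array([85.0]),
        )
        peaks = {}
        for sos in (1540.0, 1560.0):
            ph = uniform_phantom(ac=0.0, sos=sos, grid_shape=(128, 128))
            rf = simulate_rf(ph, single_angle_probe, rng_seed=1, scatterers=sc)
            el = rf.probe.element_positions_mm(rf.roi_mm[0])
            e = int(np.argmin(np.abs(el - 12.8)))
            env = np.abs(hilbert(rf.data[0, e]))
            peaks[sos] = np.argmax(env) / rf.probe.sampling_rate_hz
        expected = peaks[1540.0] * 1540.0 / 1560.0
        assert abs(peaks[1560.0] - expected) <= 1.0 / single_angle_probe.sampling_rate_hz

    def test_empty_field_is_pure_noise(self, single_angle_probe):
        base = uniform_phantom(grid_shape=(64, 64))
        ph = TissuePhantom(
            ac_map=base.ac_map,
            sos_map=base.sos_map,
            density_map=base.density_map,
            esd_map=base.esd_map,
            esc_map=np.zeros_like(base.esc_map),
            pixel_pitch_mm=0.2,
            lesion_mask=base.lesion_mask,
            lesion_class=LesionClass.none,
        )
        rf = simulate_rf(ph, single_angle_probe, rng_seed=4)
        assert rf.data.std() > 0  # noise present
        # Gaussianity: no sample should be an extreme outlier of the noise
        assert np.abs(rf.data).max() < 8 * rf.data.std()

    def test_pure_function_of_seed(self, single_angle_probe):
        ph = uniform_phantom(grid_shape=(64, 64))
        a = simulate_rf(ph, single_angle_probe, rng_seed=3)
        b = simulate_rf(ph, single_angle_probe, rng_seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_attenuation_monotonically_dims_deep_echoes(self, single_angle_probe):
        # doubling the attenuation strictly decreases deep-window amplitude
        sc_field = None
        amps = {}
        for ac in (0.4, 0.8):
            ph = uniform_phantom(ac=ac, grid_shape=(128, 128))
            if sc_field is None:
                sc_field = generate_scatterers(ph, 77)
            rf = simulate_rf(ph, single_angle_probe, rng_seed=1, scatterers=sc_field)
            fs = rf.probe.sampling_rate_hz
            for depth_mm, key in ((10.0, "shallow"), (22.0, "deep")):
                s0 = int(2 * depth_mm * 1e-3 / 1540.0 * fs)
                window = rf.data[0, :, s0 : s0 + 300]
                amps.setdefault(key, {})[ac] = np.sqrt((window**2).mean())
        assert amps["deep"][0.8] < amps["deep"][0.4]
        # and the deep windows lose more than the shallow ones
        assert (amps["deep"][0.8] / amps["deep"][0.4]) < (
            amps["shallow"][0.8] / amps["shallow"][0.4]
        )

    def test_shape_and_provenance(self, speckle_rf):
        _, rf = speckle_rf
        assert rf.data.shape == (5, 128, 3018)
        assert rf.provenance["n_scatterers"] > 0


class TestBeamformDAS:
    def test_single_scatterer_focuses_at_true_position(self, single_scatterer_rf):
        env = beamform_das(single_scatterer_rf, assumed_c=1540.0, grid_shape=(128, 128))
        iz, ix = np.unravel_index(np.argmax(env), env.shape)
        pitch = 25.6 / 128
        assert abs((iz + 0.5) * pitch - 20.0) <= 1.5 * pitch
        assert abs((ix + 0.5) * pitch - 12.8) <= 1.5 * pitch

    def test_zero_input_gives_zero_image(self, single_angle_probe):
        rf = PlaneWaveRF(
            data=np.zeros((1, 128, 3018)),
            probe=single_angle_probe,
            roi_mm=(25.6, 25.6),
        )
        assert beamform_das(rf, 1540.0).max() == 0.0

    def test_compounding_improves_peak_to_sidelobe(self):
        probe3 = ProbeConfig(steering_angles_deg=(-10.0, 0.0, 10.0))
        probe1 = ProbeConfig(steering_angles_deg=(0.0,))
        sc = ScattererField(
            positions_mm=np.array([[12.8, 15.0]]),
            amplitudes=np.array([1.0]),
            esd_um=np.array([85.0]),
        )
        ph = uniform_phantom(ac=0.0, grid_shape=(128, 128))

        def psr(probe):
            rf = simulate_rf(ph, probe, rng_seed=1, scatterers=sc)
            env = beamform_das(rf, 1540.0, grid_shape=(128, 128))
            peak = env.max()
            iz, ix = np.unravel_index(np.argmax(env), env.shape)
            masked = env.copy()
            masked[max(0, iz - 6) : iz + 7, max(0, ix - 6) : ix + 7] = 0
            return peak / masked.max()

        assert psr(probe3) >= psr(probe1)


def test_rf_hdf5_roundtrip(tmp_path, single_scatterer_rf):
    path = tmp_path / "rf.h5"
    save_rf(single_scatterer_rf, path)
    back = load_rf(path)
    np.testing.assert_array_equal(back.data, single_scatterer_rf.data)
    assert back.probe.steering_angles_deg == single_scatterer_rf.probe.steering_angles_deg


def test_probe_validation():
    with pytest.raises(ValueError):
        ProbeConfig(n_elements=1)
    with pytest.raises(ValueError):
        ProbeConfig(sampling_rate_hz=9e6)
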