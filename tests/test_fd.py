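"""Frequency-domain forward model, calibration and lifetime estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from flimpair.fd import (
    FDMeasurement,
    FDSettings,
    calibrate_reference,
    fd_response,
    lifetime_from_modulation,
    lifetime_from_phase,
    phasor_coordinates,
    simulate_fd_measurement,
)

OMEGA_40MHZ = 2 * math.pi * 4.0e7


class TestFDResponse:
    def test_instantaneous_emitter(self):
        m = fd_response([(1.0, 0.0)], OMEGA_40MHZ)
        assert m.phase_phi == pytest.approx(0.0)
        assert m.modulation_m == pytest.approx(1.0)

    def test_fluorescein_at_40mhz(self):
        m = fd_response([(1.0, 4.000)], OMEGA_40MHZ)
        assert m.phase_phi == pytest.approx(0.78805, abs=1e-5)
        assert m.modulation_m == pytest.approx(0.70523, abs=1e-5)

    def test_erythrosin_at_40mhz(self):
        m = fd_response([(1.0, 0.086)], OMEGA_40MHZ)
        assert m.phase_phi == pytest.approx(0.021611, abs=1e-6)
        assert m.modulation_m == pytest.approx(0.99977, abs=1e-5)

    def test_mixture_matches_fourier_oracle(self):
        # phase/modulation are the argument/magnitude of the normalised
        # Fourier transform of the decay at omega
        comps = [(0.35, 1.2), (0.65, 3.7)]

        def decay(t_ns):
            return sum(a / tau * math.exp(-t_ns / tau) for a, tau in comps)

        w_per_ns = OMEGA_40MHZ * 1e-9
        re, _ = quad(lambda t: decay(t) * math.cos(w_per_ns * t), 0, 400, limit=400)
        im, _ = quad(lambda t: decay(t) * math.sin(w_per_ns * t), 0, 400, limit=400)
        norm, _ = quad(decay, 0, 400, limit=400)
        m = fd_response(comps, OMEGA_40MHZ)
        assert m.phase_phi == pytest.approx(math.atan2(im, re), abs=1e-9)
        assert m.modulation_m == pytest.approx(math.hypot(re, im) / norm, abs=1e-9)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fd_response([(0.6, 1.0), (0.6, 2.0)], OMEGA_40MHZ)

    def test_low_frequency_limit(self):
        m = fd_response([(0.5, 1.0), (0.5, 9.0)], 1.0)  # omega -> 0
        assert m.phase_phi == pytest.approx(0.0, abs=1e-6)
        assert m.modulation_m == pytest.approx(1.0, abs=1e-12)


class TestLifetimeInversion:
    def test_zero_phase(self):
        assert lifetime_from_phase(0.0, OMEGA_40MHZ) == 0.0

    def test_phase_round_trip(self):
        assert lifetime_from_phase(0.78805, OMEGA_40MHZ) == pytest.approx(4.000, abs=1e-3)

    def test_tan_unity_gives_inverse_omega(self):
        assert lifetime_from_phase(math.pi / 4, OMEGA_40MHZ) == pytest.approx(
            1e9 / OMEGA_40MHZ, rel=1e-12
        )

    def test_full_modulation(self):
        assert lifetime_from_modulation(1.0, OMEGA_40MHZ) == 0.0

    def test_modulation_round_trip(self):
        assert lifetime_from_modulation(0.70523, OMEGA_40MHZ) == pytest.approx(
            4.000, abs=1e-3
        )

    def test_slightly_super_unity_modulation_clamps(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert lifetime_from_modulation(1.0 + 5e-7, OMEGA_40MHZ) == 0.0
        with pytest.raises(ValueError):
            lifetime_from_modulation(1.01, OMEGA_40MHZ)

    @given(tau=st.floats(0.01, 20.0))
    @settings(derandomize=True, max_examples=60)
    def test_mono_exponential_phase_equals_modulation(self, tau):
        m = fd_response([(1.0, tau)], OMEGA_40MHZ)
        tau_phi = lifetime_from_phase(m.phase_phi, OMEGA_40MHZ)
        tau_m = lifetime_from_modulation(m.modulation_m, OMEGA_40MHZ)
        assert tau_phi == pytest.approx(tau, rel=1e-9)
        assert tau_m == pytest.approx(tau_phi, rel=1e-9)

    @given(
        tau1=st.floats(0.1, 3.0),
        dtau=st.floats(0.5, 10.0),
        frac=st.floats(0.05, 0.95),
    )
    @settings(derandomize=True, max_examples=60)
    def test_mixtures_split_phase_below_modulation(self, tau1, dtau, frac):
        m = fd_response([(frac, tau1), (1 - frac, tau1 + dtau)], OMEGA_40MHZ)
        tau_phi = lifetime_from_phase(m.phase_phi, OMEGA_40MHZ)
        tau_m = lifetime_from_modulation(m.modulation_m, OMEGA_40MHZ)
        assert tau_phi < tau_m


class TestCalibration:
    settings_40 = FDSettings()

    def test_self_calibration_recovers_reference(self):
        raw = FDMeasurement(0.9, 0.4)  # arbitrary raw instrument reading
        cal = calibrate_reference(raw, raw, self.settings_40)
        tau = lifetime_from_phase(cal.phase_phi, self.settings_40.omega)
        assert tau == pytest.approx(4.000, rel=1e-12)

    def test_common_instrument_offsets_cancel(self):
        omega = self.settings_40.omega
        true_sample = fd_response([(1.0, 3.12)], omega)
        true_ref = fd_response([(1.0, 4.000)], omega)
        phi0, gain = 0.3, 0.8
        raw_sample = FDMeasurement(true_sample.phase_phi + phi0, true_sample.modulation_m * gain)
        raw_ref = FDMeasurement(true_ref.phase_phi + phi0, true_ref.modulation_m * gain)
        cal = calibrate_reference(raw_sample, raw_ref, self.settings_40)
        assert lifetime_from_phase(cal.phase_phi, omega) == pytest.approx(3.12, abs=1e-9)
        assert lifetime_from_modulation(cal.modulation_m, omega) == pytest.approx(
            3.12, abs=1e-9
        )

    def test_cross_reference_consistency(self):
        # measure fluorescein using erythrosin B as the reference
        settings = FDSettings(reference_name="erythrosinB")
        omega = settings.omega
        sample = fd_response([(1.0, 4.000)], omega)
        ref = fd_response([(1.0, 0.086)], omega)
        cal = calibrate_reference(sample, ref, settings)
        assert lifetime_from_phase(cal.phase_phi, omega) == pytest.approx(4.000, abs=1e-9)


class TestPhasor:
    def test_zero_lifetime_maps_to_one_zero(self):
        pt = phasor_coordinates(fd_response([(1.0, 0.0)], OMEGA_40MHZ))
        assert (pt.g, pt.s) == pytest.approx((1.0, 0.0))

    def test_infinite_lifetime_maps_to_origin(self):
        pt = phasor_coordinates(fd_response([(1.0, 1e6)], OMEGA_40MHZ))
        assert pt.g == pytest.approx(0.0, abs=1e-6)
        assert pt.s == pytest.approx(0.0, abs=1e-3)

    def test_apex_at_inverse_omega(self):
        tau_apex = 1e9 / OMEGA_40MHZ  # ns
        pt = phasor_coordinates(fd_response([(1.0, tau_apex)], OMEGA_40MHZ))
        assert (pt.g, pt.s) == pytest.approx((0.5, 0.5), abs=1e-12)

    @given(tau=st.floats(0.0, 50.0))
    @settings(derandomize=True, max_examples=80)
    def test_mono_exponentials_lie_on_universal_semicircle(self, tau):
        pt = phasor_coordinates(fd_response([(1.0, tau)], OMEGA_40MHZ))
        assert abs(pt.semicircle_residual()) < 1e-12

    @given(
        tau1=st.floats(0.1, 2.0),
        dtau=st.floats(1.0, 20.0),
        frac=st.floats(0.1, 0.9),
    )
    @settings(derandomize=True, max_examples=60)
    def test_mixtures_fall_strictly_inside_semicircle(self, tau1, dtau, frac):
        pt = phasor_coordinates(
            fd_response([(frac, tau1), (1 - frac, tau1 + dtau)], OMEGA_40MHZ)
        )
        assert pt.semicircle_residual() < -1e-12

    def test_uncalibrated_measurement_rejected(self):
        with pytest.raises(ValueError, match="calibrated"):
            phasor_coordinates(FDMeasurement(0.5, 0.5, calibrated=False))


class TestSimulatedMeasurement:
    def test_infinite_photons_is_noiseless(self):
        exact = fd_response([(1.0, 4.0)], OMEGA_40MHZ)
        sim = simulate_fd_measurement([(1.0, 4.0)], OMEGA_40MHZ, math.inf, rng=0)
        assert sim.phase_phi == exact.phase_phi
        assert sim.modulation_m == exact.modulation_m

    def test_seed_determinism(self):
        a = simulate_fd_measurement([(1.0, 4.0)], OMEGA_40MHZ, 1e5, rng=42)
        b = simulate_fd_measurement([(1.0, 4.0)], OMEGA_40MHZ, 1e5, rng=42)
        assert (a.phase_phi, a.modulation_m) == (b.phase_phi, b.modulation_m)

    def test_monte_carlo_mean_recovery(self):
        rng = np.random.default_rng(5)
        taus = [
            lifetime_from_phase(
                simulate_fd_measurement([(1.0, 4.0)], OMEGA_40MHZ, 1e6, rng).phase_phi,
                OMEGA_40MHZ,
            )
            for _ in range(500)
        ]
        taus = np.asarray(taus)
        se = taus.std(ddof=1) / math.sqrt(len(taus))
        assert abs(taus.mean() - 4.0) < 3 * se
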