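"""FRET efficiency, Z'-factor and assay-evaluation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_cells, stack
from flimpair.metrics import (
    concordance,
    efficiency_from_lifetimes,
    empirical_sensitivity_ps_per_percent,
    evaluate_assay,
    sensitivity_ps_per_percent,
    significance_stars,
    stimulation_response,
    z_factor,
)
from flimpair.spectra import expected_lifetime_shift
from flimpair.synthetic import SyntheticStudyConfig, generate_timecourse


class TestEfficiencyFromLifetimes:
    def test_equal_lifetimes_give_zero(self):
        assert efficiency_from_lifetimes(3.12, 3.12) == 0.0

    def test_half_lifetime_gives_half_efficiency(self):
        assert efficiency_from_lifetimes(4.0, 2.0) == pytest.approx(0.5)

    def test_published_pair_lifetime(self):
        assert efficiency_from_lifetimes(3.12, 2.368) == pytest.approx(0.241, abs=5e-4)

    def test_round_trip_with_lifetime_shift(self):
        for E in (0.0, 0.1, 0.241, 0.64, 0.95):
            tau_fret, _ = expected_lifetime_shift(3.2, E)
            assert efficiency_from_lifetimes(3.2, tau_fret) == pytest.approx(E, abs=1e-12)

    def test_negative_efficiency_warns_not_raises(self):
        with pytest.warns(UserWarning, match="negative"):
            E = efficiency_from_lifetimes(3.0, 3.3)
        assert E == pytest.approx(-0.1)


class TestZFactor:
    def test_perfect_assay(self):
        assert z_factor(4.0, 0.0, 2.8, 0.0) == 1.0

    def test_forced_arithmetic(self):
        assert z_factor(4.04, 0.08, 2.80, 0.08) == pytest.approx(1 - 0.48 / 1.24)

    def test_equal_means_undefined(self):
        with pytest.raises(ValueError, match="separation"):
            z_factor(3.0, 0.1, 3.0, 0.1)

    @given(
        c=st.floats(0.01, 100.0),
        mu_max=st.floats(2.0, 5.0),
        sep=st.floats(0.2, 2.0),
        s1=st.floats(0.0, 0.3),
        s2=st.floats(0.0, 0.3),
    )
    @settings(derandomize=True, max_examples=60)
    def test_scale_invariance(self, c, mu_max, sep, s1, s2):
        base = z_factor(mu_max, s1, mu_max - sep, s2)
        scaled = z_factor(c * mu_max, c * s1, c * (mu_max - sep), c * s2)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert base <= 1.0

    def test_monotone_decreasing_in_sigma(self):
        zs = [z_factor(4.0, s, 2.8, 0.05) for s in (0.0, 0.05, 0.1, 0.2)]
        assert all(a > b for a, b in zip(zs, zs[1:]))


class TestEvaluateAssay:
    def _study(self, E=0.241, n=30, days=3, drift=0.0, seed=0, timepoints=(0.0,)):
        rng = np.random.default_rng(seed)
        frames = []
        for day in range(1, days + 1):
            for t in timepoints:
                donor_taus = rng.normal(3.12, 0.05, n)
                pair_taus = rng.normal(3.12 * (1 - E) * (1 + drift * t), 0.07, n)
                frames.append(make_cells(donor_taus, "Clv", day=day, timepoint=t))
                frames.append(make_cells(pair_taus, "Clv-mCh", day=day, timepoint=t))
        return stack(*frames)

    def test_null_assay_is_deeply_negative(self):
        cells = self._study(E=0.0)
        ev = evaluate_assay(
            cells[cells.construct == "Clv"],
            cells[cells.construct == "Clv-mCh"],
            mode="static",
        )
        assert abs(ev.E_mean) < 0.05
        assert ev.Zprime_mean < -1.0

    def test_recovers_generating_efficiency(self):
        cells = self._study(E=0.241, n=50, seed=3)
        ev = evaluate_assay(
            cells[cells.construct == "Clv"],
            cells[cells.construct == "Clv-mCh"],
            mode="static",
        )
        se = ev.E_sd / math.sqrt(ev.n_days)
        assert abs(ev.E_mean - 0.241) < 3 * max(se, 0.003)
        assert ev.n_days == 3

    def test_static_equals_dynamic_on_single_timepoint(self):
        cells = self._study(E=0.2, seed=5)
        donor = cells[cells.construct == "Clv"]
        pair = cells[cells.construct == "Clv-mCh"]
        a = evaluate_assay(donor, pair, mode="static")
        b = evaluate_assay(donor, pair, mode="dynamic")
        assert a.E_mean == b.E_mean and a.Zprime_mean == b.Zprime_mean

    def test_drift_degrades_dynamic_zprime(self):
        cells = self._study(E=0.3, drift=0.02, timepoints=tuple(range(11)), seed=8)
        donor = cells[cells.construct == "Clv"]
        pair = cells[cells.construct == "Clv-mCh"]
        static = evaluate_assay(donor, pair, mode="static")
        dynamic = evaluate_assay(donor, pair, mode="dynamic")
        assert dynamic.Zprime_mean < static.Zprime_mean

    def test_unpaired_days_are_skipped(self):
        donor = stack(
            make_cells([3.1] * 5 + [3.2] * 5, "Clv", day=1),
            make_cells([3.1] * 5 + [3.2] * 5, "Clv", day=2),
        )
        pair = make_cells(np.linspace(2.3, 2.5, 10), "Clv-mCh", day=1)
        with pytest.warns(UserWarning, match="skipped"):
            ev = evaluate_assay(donor, pair, mode="static")
        assert ev.n_days == 1

    def test_platform_mismatch_rejected(self):
        donor = make_cells([3.1, 3.2, 3.15], "Clv", platform="FD")
        pair = make_cells([2.4, 2.5, 2.45], "Clv-mCh", platform="TD")
        with pytest.raises(ValueError, match="platform"):
            evaluate_assay(donor, pair)


class TestConcordance:
    def _eval(self, z, pair="Clv-mCh", platform="FD"):
        from flimpair.metrics import AssayEvaluation

        return AssayEvaluation(pair, platform, "static", 0.24, 0.02, z, 0.05, 3)

    def test_equal_zprime_is_perfectly_concordant(self):
        _, d = concordance(self._eval(0.62), self._eval(0.62, platform="TD"))
        assert d == 0.0

    def test_forced_arithmetic(self):
        _, d = concordance(self._eval(0.6), self._eval(0.4, platform="TD"))
        assert d == pytest.approx(0.2 / math.sqrt(2), abs=1e-6)

    def test_ranking_invariant_to_common_offset(self):
        pairs = [(0.6, 0.4), (0.3, 0.28), (0.9, 0.1)]
        base = [
            concordance(self._eval(a), self._eval(b, platform="TD"))[1]
            for a, b in pairs
        ]
        shifted = [
            concordance(self._eval(a - 0.5), self._eval(b - 0.5, platform="TD"))[1]
            for a, b in pairs
        ]
        assert np.argsort(base).tolist() == np.argsort(shifted).tolist()


class TestSensitivity:
    @pytest.mark.parametrize("tau,expected", [(4.0, 40.0), (2.4, 24.0), (1.0, 10.0)])
    def test_analytic_ps_per_percent(self, tau, expected):
        assert sensitivity_ps_per_percent(tau) == pytest.approx(expected)

    def test_empirical_matches_analytic_on_exact_data(self):
        tau_d = 4.0
        dE = np.array([0.01, 0.03, 0.05])
        dtau = -tau_d * dE  # ns
        assert empirical_sensitivity_ps_per_percent(dtau, dE) == pytest.approx(40.0)


class TestStimulationResponse:
    def _timecourse(self, step_E=0.0, n=20, tau_d=4.0, E0=0.25, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for t in (-2, -1, 0, 1, 2):
            E = E0 + (step_E if t > 0 else 0.0)
            taus = rng.normal(tau_d * (1 - E), noise, n)
            frames.append(make_cells(taus, "sensor", timepoint=float(t)))
            frames.append(make_cells(rng.normal(tau_d, noise, n), "mTq2", timepoint=float(t)))
        cells = stack(*frames)
        return cells[cells.construct == "sensor"], cells[cells.construct == "mTq2"]

    def test_null_sensor_shows_no_change_or_significance(self):
        sensor, donor = self._timecourse(step_E=0.0)
        resp = stimulation_response(sensor, donor)
        assert np.all(np.abs(resp["delta_tau_ns"]) < 0.05)
        post = resp.loc[resp.index > 0, "p_value"]
        assert (post > 0.05).all()

    def test_recovers_post_stimulation_step(self):
        sensor, donor = self._timecourse(step_E=0.05, seed=2)
        resp = stimulation_response(sensor, donor)
        post = resp.loc[resp.index > 0]
        se = post["delta_tau_sd"].mean() / math.sqrt(20)
        # E step of +0.05 on a 4 ns donor shortens the lifetime by 0.20 ns
        assert post["delta_tau_ns"].mean() == pytest.approx(-0.20, abs=3 * se)
        assert (post["p_value"] < 0.005).all()
        assert set(post["stars"]) == {"***"}

    def test_more_cells_shrink_standard_error(self):
        _, resp_small = None, stimulation_response(*self._timecourse(0.0, n=20, seed=4))
        resp_big = stimulation_response(*self._timecourse(0.0, n=80, seed=4))
        # quadrupling n halves the SE of the mean change (SD is n-independent)
        se_small = resp_small.loc[1, "delta_tau_sd"] / math.sqrt(20)
        se_big = resp_big.loc[1, "delta_tau_sd"] / math.sqrt(80)
        assert se_big == pytest.approx(se_small / 2, rel=0.5)

    def test_missing_baseline_rejected(self):
        sensor, donor = self._timecourse()
        with pytest.raises(ValueError, match="t = 0"):
            stimulation_response(sensor[sensor.timepoint_min != 0], donor)


def test_significance_star_convention():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.008) == "**"
    assert significance_stars(0.001) == "***"


def test_dynamic_zprime_drops_under_acceptor_drift_via_generator():
    cfg = SyntheticStudyConfig(
        pair_name="mTq2-YPet",
        tau_donor_true=4.04,
        tau_donor_cell_sd=0.08,
        E_true=0.33,
        lifetime_drift_per_min=0.01,
        days=3,
        dishes_per_day=1,
        cells_per_dish=12,
        noise_mode="gaussian",
        rng_seed=13,
    )
    cells = generate_timecourse(cfg)
    donor = cells[cells.construct == "mTq2"]
    pair = cells[cells.construct == "mTq2-YPet"]
    static = evaluate_assay(donor, pair, mode="static")
    dynamic = evaluate_assay(donor, pair, mode="dynamic")
    assert dynamic.Zprime_mean < static.Zprime_mean
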