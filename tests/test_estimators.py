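import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gatedflim import (
    GatePair,
    SaturationError,
    empirical_f_value,
    f_value_theory,
    fret_efficiencies,
    gate_scan_lifetime,
    pileup_correct,
    predicted_rel_error,
    two_gate_lifetime,
)
from gatedflim.estimators import (
    CENSOR_NEGATIVE_RATE,
    CENSOR_NONPOS_GATE0,
    CENSOR_NONPOS_GATE1,
    lifetime_series,
)

from conftest import poisson_gate_pairs


class TestPileupCorrect:
    def test_zero_is_fixed_point(self):
        assert pileup_correct(0, 8) == 0.0

    def test_operating_ceiling_value(self):
        # frozen from an independent high-precision evaluation of
        # -ln(1 - 25/255) * 255
        assert pileup_correct(25, 8) == pytest.approx(26.3119802399838, rel=1e-12)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            pileup_correct(255, 8)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pileup_correct(-1, 8)

    @given(st.integers(0, 253), st.integers(0, 253))
    def test_strictly_increasing_and_expanding(self, a, b):
        fa, fb = pileup_correct(a, 8), pileup_correct(b, 8)
        assert fa >= a
        if a < b:
            assert fa < fb

    def test_array_input(self):
        out = pileup_correct(np.array([0, 25, 100]), 8)
        assert out.shape == (3,)
        assert out[0] == 0.0

    @pytest.mark.parametrize("lam", [1.0, 10.0, 25.0, 100.0])
    def test_inverts_binomial_binary_frame_mean(self, lam):
        # the binary-frame camera model drawn independently of the simulator
        rng = np.random.default_rng(123)
        m = 255
        counts = rng.binomial(m, 1.0 - np.exp(-lam / m), size=100_000)
        corrected = pileup_correct(np.minimum(counts, m - 1), 8)
        assert np.mean(corrected) == pytest.approx(lam, rel=0.01)


class TestTwoGateLifetime:
    def test_ratio_e_gives_tau_equal_T(self):
        pair = GatePair(n0=1000.0, n1=1000.0 * math.exp(-1), gate_separation=2.5)
        assert two_gate_lifetime(pair).tau == pytest.approx(2.5, rel=1e-12)

    def test_background_subtracted_example(self):
        # inverse-constructed: N1 - B1 = 1000 * exp(-2.5/2.1)
        pair = GatePair(
            n0=1100.0,
            n1=1000.0 * math.exp(-2.5 / 2.1) + 100.0,
            b0=100.0,
            b1=100.0,
            gate_separation=2.5,
        )
        assert two_gate_lifetime(pair).tau == pytest.approx(2.1, rel=1e-12)

    def test_photon_budget_reported(self):
        pair = GatePair(n0=1000.0, n1=300.0, gate_separation=2.5)
        assert two_gate_lifetime(pair).n_photons == 2000.0

    @pytest.mark.parametrize(
        "n0,n1,b0,b1,reason",
        [
            (500.0, 600.0, 0.0, 0.0, CENSOR_NEGATIVE_RATE),
            (50.0, 10.0, 100.0, 0.0, CENSOR_NONPOS_GATE0),
            (500.0, 10.0, 0.0, 50.0, CENSOR_NONPOS_GATE1),
        ],
    )
    def test_censoring_reasons(self, n0, n1, b0, b1, reason):
        res = two_gate_lifetime(GatePair(n0=n0, n1=n1, b0=b0, b1=b1, gate_separation=2.5))
        assert res.censored
        assert res.censor_reason == reason
        assert math.isnan(res.tau)

    @given(
        c=st.floats(1e-3, 1e3),
        n0=st.floats(500.0, 2000.0),
        ratio=st.floats(0.05, 0.95),
        b=st.floats(0.0, 100.0),
    )
    def test_exact_scale_invariance(self, c, n0, ratio, b):
        n1 = b + ratio * (n0 - b) if n0 > b else None
        if n1 is None:
            return
        base = two_gate_lifetime(GatePair(n0=n0, n1=n1, b0=b, b1=b, gate_separation=2.5))
        scaled = two_gate_lifetime(
            GatePair(n0=c * n0, n1=c * n1, b0=c * b, b1=c * b, gate_separation=2.5)
        )
        assert scaled.tau == pytest.approx(base.tau, rel=1e-9)

    @pytest.mark.parametrize("u", [0.5, 1.5, 3.0])
    def test_consistency_high_budget(self, u):
        # bias < 1% at S = 1e5, b = 0
        rng = np.random.default_rng(7)
        n0, n1 = poisson_gate_pairs(rng, 1e5, u, 0.0, 2000)
        tau, n_cens = lifetime_series(n0, n1, 0.0, 0.0, gate_separation=u * 2.0)
        assert n_cens == 0
        assert np.mean(tau) == pytest.approx(2.0, rel=0.01)

    def test_invalid_gate_separation(self):
        with pytest.raises(ValueError):
            GatePair(n0=10, n1=5, gate_separation=0.0)


class TestEmpiricalFValue:
    def test_arithmetic(self):
        samples = [1.9, 2.1]  # mean 2.0, sample std sqrt(0.02)
        res = empirical_f_value(samples, 1000.0)
        assert res.f == pytest.approx(
            math.sqrt(1000.0) * np.std(samples, ddof=1) / 2.0
        )

    def test_constant_samples(self):
        assert empirical_f_value([2.0, 2.0, 2.0], 500.0).f == 0.0

    def test_censored_samples_excluded_and_counted(self):
        res = empirical_f_value([2.0, np.nan, 2.2, np.nan], 500.0)
        assert res.n_used == 2
        assert res.n_censored == 2

    def test_all_censored_errors(self):
        with pytest.raises(ValueError):
            empirical_f_value([np.nan, np.nan], 500.0)

    def test_monte_carlo_matches_theory_at_optimalish_delay(self):
        rng = np.random.default_rng(42)
        n0, n1 = poisson_gate_pairs(rng, 500.0, 2.0, 0.0, 10_000)
        tau, _ = lifetime_series(n0, n1, 0.0, 0.0, gate_separation=2.0)
        f = empirical_f_value(tau, 2 * 500.0).f
        assert f == pytest.approx(f_value_theory(2.0, 0.0), rel=0.05)

    @pytest.mark.parametrize("u", [1.0, 2.0, 3.0])
    @pytest.mark.parametrize("b", [0.0, 0.5, 2.0])
    def test_monte_carlo_grid_agrees_with_closed_form(self, u, b):
        # The closed form is a small-noise linearization; S is chosen large
        # enough that censoring is negligible on the whole grid.
        rng = np.random.default_rng(int(100 * u + 10 * b))
        s = 10_000.0
        n0, n1 = poisson_gate_pairs(rng, s, u, b, 10_000)
        tau, n_cens = lifetime_series(n0, n1, b * s, b * s, gate_separation=u)
        f = empirical_f_value(tau, 2 * s * (1 + b)).f
        assert n_cens < 100
        assert f == pytest.approx(f_value_theory(u, b), rel=0.05)

    @pytest.mark.parametrize("u,b", [(1.0, 0.0), (2.0, 0.0), (1.0, 0.5), (2.0, 0.5)])
    def test_monte_carlo_single_molecule_budget(self, u, b):
        # at a realistic 500-photon first-gate signal the agreement holds
        # wherever censoring stays negligible
        rng = np.random.default_rng(int(77 + 100 * u + 10 * b))
        s = 500.0
        n0, n1 = poisson_gate_pairs(rng, s, u, b, 10_000)
        tau, _ = lifetime_series(n0, n1, b * s, b * s, gate_separation=u)
        f = empirical_f_value(tau, 2 * s * (1 + b)).f
        assert f == pytest.approx(f_value_theory(u, b), rel=0.05)


class TestPredictedRelError:
    def test_thousand_photons_is_three_percent_per_unit_f(self):
        assert predicted_rel_error(1.0, 1000.0) == pytest.approx(0.0316, abs=5e-4)

    def test_arithmetic(self):
        assert predicted_rel_error(3.0, 900.0) == pytest.approx(0.1)
        assert predicted_rel_error(2.048, 2 * 500.0) == pytest.approx(0.0648, abs=5e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            predicted_rel_error(0.0, 100.0)
        with pytest.raises(ValueError):
            predicted_rel_error(1.0, 0.0)


class TestFretEfficiencies:
    def test_no_transfer(self):
        assert fret_efficiencies(3.4, 3.4, 500, 500).e_lifetime == 0.0

    def test_two_population_lifetimes(self):
        est = fret_efficiencies(2.1, 3.4, 600, 1000)
        assert est.e_lifetime == pytest.approx(1 - 2.1 / 3.4)
        assert est.e_lifetime == pytest.approx(0.382, abs=1e-3)
        assert est.e_intensity == pytest.approx(0.4)

    def test_not_clipped(self):
        est = fret_efficiencies(3.6, 3.4, 1100, 1000)
        assert est.e_lifetime < 0
        assert est.e_intensity < 0

    def test_nonpositive_denominators(self):
        with pytest.raises(ValueError):
            fret_efficiencies(2.1, 0.0, 600, 1000)
        with pytest.raises(ValueError):
            fret_efficiencies(2.1, 3.4, 600, 0.0)


class TestGateScanLifetime:
    def test_exact_exponential(self):
        delays = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        counts = 1e4 * np.exp(-delays / 3.0)
        assert gate_scan_lifetime(delays, counts) == pytest.approx(3.0, rel=1e-9)

    def test_poisson_noise_recovery(self):
        # simulation oracle: repeated noisy scans recover tau within 0.05
        rng = np.random.default_rng(11)
        delays = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        expected = 1e5 * np.exp(-delays / 3.0)
        taus = [
            gate_scan_lifetime(delays, rng.poisson(expected)) for _ in range(1000)
        ]
        assert np.mean(taus) == pytest.approx(3.0, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            gate_scan_lifetime([0.0, 1.0], [100.0, 50.0])

    def test_nonpositive_counts_dropped(self):
        delays = [0.0, 1.0, 2.0, 3.0]
        counts = [100.0, 50.0, 0.0, 12.0]  # zero-count point dropped, 3 remain
        assert gate_scan_lifetime(delays, counts) > 0

    def test_rising_counts_rejected(self):
        with pytest.raises(ValueError):
            gate_scan_lifetime([0.0, 1.0, 2.0], [10.0, 20.0, 40.0])
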