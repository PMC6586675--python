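"""Ground-truth generators: determinism, kinetics, noise model."""

import numpy as np
import pytest
from scipy import stats

from ribotrace.synthetic_data import (KineticScheme, NoiseModel, Transition,
                                      rnc_misfold_scheme, sample_delays,
                                      simulate_hopping_trace,
                                      simulate_translation_trace)


class TestNoiseModel:
    def test_bandwidth_scaling(self):
        nm = NoiseModel(0.25, 1333.0)
        assert nm.sd_at(13.33) == pytest.approx(0.025, rel=1e-3)
        assert nm.sd_at(1333.0) == 0.25


class TestSchemeValidation:
    def test_negative_sequestration_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(states=(("U", -1.0),), transitions=())

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(states=(("U", 0.0),),
                          transitions=(Transition("U", "X", 0.0, 1.0, 1),))

    def test_rates_positive_finite_over_force_range(self, misfold_scheme):
        for tr in misfold_scheme.transitions:
            rates = [tr.rate(f, 4.11) for f in np.linspace(0, 15, 16)]
            assert all(np.isfinite(r) and r > 0 for r in rates)


class TestHoppingTrace:
    def test_single_state_zero_noise_is_constant(self, model, quiet):
        scheme = KineticScheme(states=(("U", 0.0),), transitions=())
        trace, truth = simulate_hopping_trace(scheme, model, 4.0, 5.0, 100.0,
                                              quiet, seed=0)
        assert np.ptp(trace.force) == 0.0
        assert trace.force[0] == pytest.approx(4.0, abs=1e-9)

    def test_deterministic_given_seed(self, model, noise, misfold_scheme):
        a, _ = simulate_hopping_trace(misfold_scheme, model, 4.0, 10.0, 200.0,
                                      noise, seed=42)
        b, _ = simulate_hopping_trace(misfold_scheme, model, 4.0, 10.0, 200.0,
                                      noise, seed=42)
        np.testing.assert_array_equal(a.force, b.force)

    def test_stripping_noise_recovers_state_path(self, model, noise,
                                                 misfold_scheme):
        trace, truth = simulate_hopping_trace(misfold_scheme, model, 4.0,
                                              20.0, 500.0, noise, seed=3)
        resid = trace.force - truth.clean_force
        # residual is pure white noise at the sampling bandwidth
        assert np.std(resid) == pytest.approx(noise.sd_at(500.0), rel=0.05)
        assert len(set(np.round(truth.clean_force, 12))) <= 2

    def test_unfolded_lifetime_at_4pN(self, model, quiet, misfold_scheme):
        """Unfolded-state dwells at 4.0 pN average 1.5 s (the equilibrium
        lifetime before misfolding measured on stalled complexes)."""
        dwells = []
        seed = 0
        while len(dwells) < 500:
            trace, truth = simulate_hopping_trace(
                misfold_scheme, model, 4.0, 400.0, 50.0, quiet, seed=seed)
            dwells.extend(truth.dwell_durations("U", trace.duration))
            seed += 1
        d = np.asarray(dwells)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - 1.5) < 2 * se

    def test_dwell_count_matches_markov_expectation(self, model, quiet,
                                                    misfold_scheme):
        """Transitions per unit time follow the two-state renewal rate."""
        forces = {"U": 4.0}
        from ribotrace.tether_mechanics import aa_to_contour, equilibrium_force
        forces["M"] = equilibrium_force(model, 4.0, aa_to_contour(164),
                                        -aa_to_contour(130))
        kU = misfold_scheme.transitions[0].rate(forces["U"], model.kBT)
        kM = misfold_scheme.transitions[1].rate(forces["M"], model.kBT)
        T = 2000.0
        expected = 2 * T / (1 / kU + 1 / kM)
        trace, truth = simulate_hopping_trace(misfold_scheme, model, 4.0, T,
                                              20.0, quiet, seed=9)
        n = len(truth.state_path) - 1
        assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_dwells_are_exponential(self, model, quiet, misfold_scheme):
        """KS test fails to reject exponentiality in >= 9/10 repetitions."""
        passes = 0
        for rep in range(10):
            dwells = []
            seed = 100 * rep
            while len(dwells) < 100:
                trace, truth = simulate_hopping_trace(
                    misfold_scheme, model, 4.0, 200.0, 50.0, quiet, seed=seed)
                dwells.extend(truth.dwell_durations("U", trace.duration))
                seed += 1
            d = np.asarray(dwells[:100])
            p = stats.kstest(d, "expon", args=(0, d.mean())).pvalue
            passes += p > 0.01
        assert passes >= 9


class TestTranslationTrace:
    def test_no_stepping_no_folding_is_flat(self, model, noise,
                                            cdomain_scheme):
        trace, truth = simulate_translation_trace(
            model, 0.0, cdomain_scheme, 167, 0.0, 222, 200.0, noise, seed=0,
            max_duration=5.0)
        assert np.ptp(truth.clean_force) == 0.0
        assert truth.aa_position_path == [(0.0, 0)]

    def test_force_levels_nonincreasing_without_folding(self, model, quiet,
                                                        cdomain_scheme):
        trace, truth = simulate_translation_trace(
            model, 2.0, cdomain_scheme, 222, 1e9, 222, 100.0, quiet, seed=1,
            max_duration=150.0)
        assert np.all(np.diff(truth.clean_force) <= 1e-12)

    def test_deterministic_given_seed(self, model, noise, cdomain_scheme):
        a, ta = simulate_translation_trace(model, 1.0, cdomain_scheme, 167,
                                           63.0, 222, 100.0, noise, seed=5)
        b, tb = simulate_translation_trace(model, 1.0, cdomain_scheme, 167,
                                           63.0, 222, 100.0, noise, seed=5)
        np.testing.assert_array_equal(a.force, b.force)
        assert ta.true_delay == tb.true_delay

    def test_delay_gate_precedes_first_fold(self, model, quiet,
                                            cdomain_scheme):
        trace, truth = simulate_translation_trace(
            model, 1.0, cdomain_scheme, 167, 63.0, 222, 50.0, quiet, seed=7)
        arrival = [t for t, c in truth.aa_position_path if c == 167][0]
        folds = [t for t, s in truth.state_path if s != "U"]
        assert folds, "molecule should eventually fold"
        assert folds[0] >= arrival + truth.true_delay - 1e-9


class TestSampleDelays:
    def test_exponential_law_of_large_numbers(self):
        m, n = 63.0, 100_000
        taus = sample_delays("exponential", {"mean": m}, n, seed=0)
        assert abs(taus.mean() - m) < 3 * m / np.sqrt(n)

    def test_erlang2_mean(self):
        taus = sample_delays("erlang2", {"rate": 0.5}, 100_000, seed=1)
        assert taus.mean() == pytest.approx(4.0, rel=0.02)

    def test_double_exponential_mean(self):
        p = {"w": 0.3, "tau1": 10.0, "tau2": 100.0}
        taus = sample_delays("double_exponential", p, 200_000, seed=2)
        assert taus.mean() == pytest.approx(0.3 * 10 + 0.7 * 100, rel=0.02)

    def test_byte_identical_given_seed(self):
        a = sample_delays("exponential", {"mean": 5.0}, 100, seed=3)
        b = sample_delays("exponential", {"mean": 5.0}, 100, seed=3)
        assert a.tobytes() == b.tobytes()

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            sample_delays("weibull", {}, 10, seed=0)
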