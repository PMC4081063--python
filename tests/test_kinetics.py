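"""Branched kinetics: propagation, chase simulation and decay fitting."""

from dataclasses import replace

import numpy as np
import pytest

import tbplattice as tl
from tbplattice.errors import InputError
from tbplattice.kinetics import (
    ChaseTrace,
    ExponentialDecayModel,
    build_rate_matrix,
    gillespie_occupancy,
    propagate,
    state_proximities,
)


@pytest.fixture
def scheme14E(tata14E):
    return tl.KineticScheme(lattice=tata14E)


def biexp_trace(times, offset, amp, ff, k_fast, k_slow, sigma=0.0, seed=0):
    y = offset + amp * (
        ff * np.exp(-k_fast * times) + (1 - ff) * np.exp(-k_slow * times)
    )
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0, sigma, times.size)
    return ChaseTrace(times, y)


class TestRateMatrix:
    @pytest.mark.parametrize("k_slide", [0.0, 0.05])
    def test_generator_columns_sum_to_zero(self, scheme14E, k_slide):
        a = build_rate_matrix(replace(scheme14E, k_slide_per_s=k_slide))
        np.testing.assert_allclose(a.sum(axis=0), 0.0, atol=1e-12)

    def test_two_state_analytic_relaxation(self):
        lat = tl.LatticeSpec(length_bp=1, specific_register=0)
        scheme = tl.KineticScheme(
            lattice=lat, tbp_nM=30.0, k_off_specific_per_s=0.01
        )
        k_on = scheme.k_on_per_M_s * 30e-9
        k_rel = k_on + 0.01
        p_eq = k_on / k_rel
        a = build_rate_matrix(scheme)
        for t in (5.0, 20.0, 100.0):
            p = propagate(a, np.array([1.0, 0.0]), t)
            assert p[1] == pytest.approx(p_eq * (1 - np.exp(-k_rel * t)), abs=1e-12)

    def test_probability_conserved_under_propagation(self, scheme14E):
        a = build_rate_matrix(scheme14E)
        p = np.zeros(a.shape[0])
        p[0] = 1.0
        for t in (1.0, 60.0, 600.0):
            assert propagate(a, p, t).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matrix_exponential_matches_gillespie(self):
        lat = tl.LatticeSpec(
            length_bp=3, specific_register=1, footprint_bp=1, contact_span_bp=1
        )
        scheme = tl.KineticScheme(
            lattice=lat,
            k_slide_per_s=0.01,
            k_off_specific_per_s=0.01,
            k_off_nonspecific_per_s=0.05,
        )
        n_traj = 50_000
        t_grid = np.array([0.0, 10.0, 30.0, 60.0])
        mc = gillespie_occupancy(scheme, t_grid, n_traj=n_traj, seed=12)
        a = build_rate_matrix(scheme)
        p0 = np.array([1.0, 0.0, 0.0, 0.0])
        for i, t in enumerate(t_grid):
            ode = propagate(a, p0, t)
            se = np.sqrt(np.maximum(ode * (1 - ode) / n_traj, 1e-12))
            assert (np.abs(mc[i] - ode) <= 3.5 * se + 1e-9).all()


class TestChaseSimulation:
    def test_long_incubation_chase_is_exact_biexponential(self, scheme14E):
        # with k_slide = 0 every bound state decays independently, so the
        # post-chase trace is analytically a sum of exponentials at the two
        # k_off values, weighted by the incubation-end state distribution
        scheme = replace(scheme14E, incubation_s=3600.0, observation_s=600.0)
        a_inc = build_rate_matrix(scheme, association=True)
        p = np.zeros(a_inc.shape[0])
        p[0] = 1.0
        p = propagate(a_inc, p, scheme.incubation_s)
        pvals = state_proximities(scheme)
        regs = scheme.states
        k_off = np.array(
            [
                scheme.k_off_specific_per_s
                if r == scheme.lattice.specific_register
                else scheme.k_off_nonspecific_per_s
                for r in regs
            ]
        )
        trace = tl.simulate_chase(scheme)
        expected = pvals[0] + np.array(
            [
                np.sum(p[1:] * (pvals[1:] - pvals[0]) * np.exp(-k_off * t))
                for t in trace.times
            ]
        )
        np.testing.assert_allclose(trace.proximity_ratio, expected, atol=1e-9)

    def test_degenerate_rates_collapse_to_single_phase(self, tata14E):
        scheme = tl.KineticScheme(
            lattice=tata14E,
            k_off_specific_per_s=0.01,
            k_off_nonspecific_per_s=0.01,
            incubation_s=300.0,
            observation_s=900.0,
        )
        fit = tl.fit_exponential(tl.simulate_chase(scheme), phases=2)
        total = fit.a_fast + fit.a_slow
        for k, a in zip(fit.rates, fit.amplitudes):
            if a > 0.05 * total:
                assert k == pytest.approx(0.01, rel=0.05)

    def test_fast_fraction_decreases_with_incubation_rates_stable(self, scheme14E):
        fits = []
        for inc in (60.0, 300.0, 1200.0):
            trace = tl.simulate_chase(replace(scheme14E, incubation_s=inc))
            fits.append(tl.fit_exponential(trace, phases=2))
        fractions = [f.fast_fraction for f in fits]
        assert fractions[0] > fractions[1] > fractions[2]
        for f in fits[1:]:
            assert f.k_fast == pytest.approx(fits[0].k_fast, rel=0.05)
            assert f.k_slow == pytest.approx(fits[0].k_slow, rel=0.05)

    def test_sliding_preserves_equilibrium_occupancies(self, scheme14E):
        # detailed-balance-consistent hops leave the stationary state alone
        p0 = np.zeros(len(scheme14E.states) + 1)
        p0[0] = 1.0
        eq_still = propagate(build_rate_matrix(scheme14E), p0, 100_000.0)
        eq_slide = propagate(
            build_rate_matrix(replace(scheme14E, k_slide_per_s=0.05)), p0, 100_000.0
        )
        np.testing.assert_allclose(eq_still, eq_slide, atol=1e-7)

    def test_sliding_accelerates_relaxation_to_specific_site(self, scheme14E):
        p0 = np.zeros(len(scheme14E.states) + 1)
        p0[0] = 1.0
        t_probe = 300.0
        slow = propagate(build_rate_matrix(scheme14E), p0, t_probe)
        fast = propagate(
            build_rate_matrix(replace(scheme14E, k_slide_per_s=0.1)), p0, t_probe
        )
        spec_state = 1 + scheme14E.states.index(scheme14E.lattice.specific_register)
        assert fast[spec_state] > slow[spec_state]


class TestDecayFitting:
    def test_single_phase_exact_recovery(self):
        t = np.arange(0.0, 1800.0, 1.0)
        trace = ChaseTrace(t, 0.3 + 0.2 * np.exp(-0.01 * t))
        fit = tl.fit_exponential(trace, phases=1)
        assert fit.rates[0] == pytest.approx(0.01, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(0.2, rel=1e-6)
        assert fit.offset == pytest.approx(0.3, abs=1e-8)

    def test_two_phase_exact_recovery(self):
        t = np.arange(0.0, 1800.0, 1.0)
        trace = biexp_trace(t, 0.30, 0.30, 0.38, 0.02, 0.0014)
        fit = tl.fit_exponential(trace, phases=2)
        assert fit.k_fast == pytest.approx(0.02, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.0014, rel=1e-4)
        assert fit.fast_fraction == pytest.approx(0.38, rel=1e-4)

    def test_single_phase_fit_of_biexponential_leaves_structured_residuals(self):
        t = np.arange(0.0, 1800.0, 1.0)
        trace = biexp_trace(t, 0.30, 0.30, 0.38, 0.02, 0.0014)
        rss1 = tl.fit_exponential(trace, phases=1).residual_sumsq
        rss2 = tl.fit_exponential(trace, phases=2).residual_sumsq
        assert rss1 > 5 * rss2

    def test_fast_fraction_equal_amplitudes(self):
        t = np.arange(0.0, 1800.0, 1.0)
        fit = tl.fit_exponential(biexp_trace(t, 0.3, 0.3, 0.5, 0.02, 0.0014), phases=2)
        assert tl.fast_fraction(fit) == pytest.approx(0.5, abs=1e-4)

    def test_fast_fraction_absent_fast_phase(self):
        t = np.arange(0.0, 1800.0, 1.0)
        fit = tl.fit_exponential(biexp_trace(t, 0.3, 0.3, 0.0, 0.02, 0.0014), phases=2)
        assert tl.fast_fraction(fit) < 0.02

    def test_summary_reports_parameters(self):
        t = np.arange(0.0, 900.0, 1.0)
        fit = tl.fit_exponential(biexp_trace(t, 0.3, 0.3, 0.38, 0.02, 0.0014,
                                             sigma=0.01, seed=3), phases=2)
        text = fit.summary()
        assert "k_fast" in text and "fast fraction" in text

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            ExponentialDecayModel(np.arange(5.0), np.zeros(5), phases=2)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(InputError):
            ChaseTrace(np.array([0.0, 2.0, 1.0]), np.zeros(3))
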