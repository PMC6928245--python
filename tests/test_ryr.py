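import math

import numpy as np
import pytest

from purkinje_ca.ryr import (
    RyRPopulation,
    km_ryr,
    mc_step,
    mc_update,
    open_prob_ode_rhs,
    ryr_flux,
    stationary_open_fraction,
    transition_probs,
)


class TestKmRyr:
    def test_midpoint(self):
        # at the sigmoid midpoint the exponential term is 1
        assert km_ryr(530.0) == pytest.approx(3.51 / 2 + 0.25, abs=1e-12)

    def test_overload_asymptote(self):
        assert km_ryr(1e9) == pytest.approx(0.25)

    def test_one_slope_unit_above_midpoint(self):
        assert km_ryr(730.0) == pytest.approx(3.51 / (1 + math.e) + 0.25, rel=1e-12)

    def test_strictly_decreasing(self):
        ca = np.linspace(0.0, 2000.0, 200)
        vals = [km_ryr(c) for c in ca]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.25 < v < 3.76 + 1e-9 for v in vals)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            km_ryr(-1.0)


class TestTransitionProbs:
    def test_half_saturation(self):
        pop = RyRPopulation(n_total=10, n_open=4)
        km = km_ryr(600.0)
        pt_open, _ = transition_probs(pop, ca_subsr=km, ca_jsr=600.0, dt=0.01)
        assert pt_open == pytest.approx(0.5 * pop.k_open * 6 * 0.01)

    def test_no_closed_channels(self):
        pop = RyRPopulation(n_total=10, n_open=10)
        pt_open, pt_close = transition_probs(pop, 5.0, 600.0, 0.01)
        assert pt_open == 0.0
        assert pt_close == pytest.approx(pop.k_close * 10 * 0.01)

    def test_saturating_calcium(self):
        pop = RyRPopulation(n_total=10, n_open=0)
        pt_open, _ = transition_probs(pop, 1e9, 600.0, 0.01)
        assert pt_open == pytest.approx(pop.k_open * 10 * 0.01, rel=1e-6)


class TestMcUpdate:
    def test_opening(self):
        pop = RyRPopulation(n_total=20, n_open=5)
        assert mc_update(pop, 0.2, 0.1, u=0.1).n_open == 6

    def test_closing(self):
        pop = RyRPopulation(n_total=20, n_open=5)
        assert mc_update(pop, 0.2, 0.1, u=0.25).n_open == 4

    def test_no_change(self):
        pop = RyRPopulation(n_total=20, n_open=5)
        assert mc_update(pop, 0.0, 0.0, u=0.5).n_open == 5

    def test_boundary_clamps(self):
        full = RyRPopulation(n_total=5, n_open=5)
        assert mc_update(full, 0.5, 0.0, u=0.1).n_open == 5
        empty = RyRPopulation(n_total=5, n_open=0)
        assert mc_update(empty, 0.0, 0.5, u=0.3).n_open == 0

    def test_at_most_one_transition(self, rng):
        pop = RyRPopulation(n_total=50, n_open=25)
        for _ in range(500):
            new = mc_step(pop, ca_subsr=1.0, ca_jsr=600.0, dt=0.02, rng=rng)
            assert abs(new.n_open - pop.n_open) <= 1
            pop = new

    def test_invalid_probabilities_rejected(self):
        pop = RyRPopulation(n_total=5, n_open=2)
        with pytest.raises(ValueError):
            mc_update(pop, 0.8, 0.4, u=0.5)


class TestRyRFlux:
    def test_closed_population_no_flux(self):
        pop = RyRPopulation(n_total=10, n_open=0)
        assert ryr_flux(pop, 600.0, 0.1, g_rel=1.0) == 0.0

    def test_no_gradient_no_flux(self):
        pop = RyRPopulation(n_total=10, n_open=10)
        assert ryr_flux(pop, 5.0, 5.0, g_rel=1.0) == 0.0

    def test_linear_driving_force(self):
        assert ryr_flux(1.0, 600.0, 0.1, g_rel=2.0) == pytest.approx(2.0 * 599.9)


class TestStationaryDistribution:
    def test_mc_matches_two_state_closed_form(self, rng):
        """Long-run open fraction at clamped Ca matches k'o/(k'o + kc)."""
        pop = RyRPopulation(n_total=50, n_open=0, k_open=1.4, k_close=1.0)
        ca_subsr, ca_jsr = 2.5, 600.0
        expected = stationary_open_fraction(ca_subsr, ca_jsr, pop.k_open, pop.k_close)
        n_steps, dt = 60_000, 0.05
        total = 0
        for _ in range(n_steps):
            pop = mc_step(pop, ca_subsr, ca_jsr, dt, rng)
            total += pop.n_open
        observed = total / (n_steps * pop.n_total)
        # SE of the time-averaged open fraction; generous factor for
        # autocorrelation of the birth-death chain
        assert observed == pytest.approx(expected, abs=0.05 * max(expected, 0.1) + 0.01)

    def test_ode_rhs_fixed_point(self):
        p_star = stationary_open_fraction(2.5, 600.0, 1.4, 1.0)
        assert open_prob_ode_rhs(p_star, 2.5, 600.0, 1.4, 1.0) == pytest.approx(0.0, abs=1e-12)


def test_mc_ensemble_mean_tracks_ode(rng):
    """Small-scale mean-field check; the full N-scaling run lives in acceptance."""
    from scipy.integrate import solve_ivp

    k_open, k_close = 1.4, 1.0
    ca_subsr, ca_jsr = 1.5, 600.0
    n, reps, t_end, dt = 100, 200, 5.0, 0.01
    sols = np.zeros(reps)
    for r in range(reps):
        pop = RyRPopulation(n_total=n, n_open=0, k_open=k_open, k_close=k_close)
        for _ in range(int(t_end / dt)):
            pop = mc_step(pop, ca_subsr, ca_jsr, dt, rng)
        sols[r] = pop.p_open
    ode = solve_ivp(
        lambda t, p: open_prob_ode_rhs(p[0], ca_subsr, ca_jsr, k_open, k_close),
        (0, t_end), [0.0], rtol=1e-8,
    )
    expected = ode.y[0, -1]
    se = sols.std(ddof=1) / np.sqrt(reps)
    assert abs(sols.mean() - expected) < 3 * se + 0.005
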