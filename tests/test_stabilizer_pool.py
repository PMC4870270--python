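import numpy as np
import pytest

from synrecon.stabilizer_pool import (PoolParams, PoolState, set_psi,
                                      step_pool, unbinding_rate)

WP = PoolParams.write_protected()


class TestUnbindingRate:
    def test_half_activation(self):
        # at I_A = I0 the logistic sits at its midpoint: k0 + m/2
        assert unbinding_rate(WP.I0_2, "k2", WP) == pytest.approx(1.5e-3)

    def test_baseline_at_zero_activity(self):
        # (I0 - 0)/r = 19 e-folds: indistinguishable from k0
        k = unbinding_rate(0.0, "k2", WP)
        assert k == pytest.approx(WP.k0, abs=WP.m * np.exp(-18.0))

    def test_saturation(self):
        assert unbinding_rate(10.0, "k4", WP) == pytest.approx(WP.k0 + WP.m)

    def test_monotone_in_activity(self):
        I = np.linspace(0, 0.2, 50)
        k = unbinding_rate(I, "k2", WP)
        assert np.all(np.diff(k) >= 0)
        assert k[-1] > k[0]

    def test_extreme_activity_no_overflow(self):
        assert np.isfinite(unbinding_rate(1e6, "k2", WP))
        assert np.isfinite(unbinding_rate(-1e6, "k2", WP))


class TestStepPool:
    def test_no_big_synapses_pool_unchanged(self):
        rng = np.random.default_rng(0)
        pool = PoolState(N_A=1000, N_A_star=50)
        b = np.zeros(20, np.int8)
        out = step_pool(pool, np.zeros(20, bool), b, np.zeros(20), WP, 0.1, rng)
        assert (out.N_A, out.N_A_star) == (1000, 50)
        assert b.sum() == 0

    def test_conservation_without_psi(self):
        # N_A + N_A* + N_bound is conserved exactly at every step
        rng = np.random.default_rng(1)
        params = PoolParams.write_protected(N_A_tot=2000)
        n = 100
        b = np.ones(n, np.int8)
        pool = PoolState.full(params, n_bound=n)
        is_big = np.ones(n, bool)
        I_A = np.full(n, 0.08)  # elevated activity: plenty of transitions
        for _ in range(2000):
            pool = step_pool(pool, is_big, b, I_A, params, 0.1, rng)
            assert pool.N_A + pool.N_A_star + int(b.sum()) == 2000

    def test_psi_discards_susceptible_releases(self):
        rng = np.random.default_rng(2)
        params = PoolParams.write_protected(N_A_tot=2000)
        n = 100
        b = np.ones(n, np.int8)
        pool = PoolState(N_A=0, N_A_star=500, psi_active=True)
        is_big = np.ones(n, bool)
        totals = []
        for _ in range(3000):
            pool = step_pool(pool, is_big, b, np.full(n, 0.08), params, 0.1, rng)
            assert pool.N_A == 0
            totals.append(pool.N_A_star + int(b.sum()))
        # the total only ever decreases under PSI (k2-branch losses)
        assert np.all(np.diff(totals) <= 0)
        assert totals[-1] < totals[0]

    def test_probability_overflow_raises(self):
        rng = np.random.default_rng(3)
        params = PoolParams.write_protected(k1=1.0)
        pool = PoolState(N_A=1000, N_A_star=0)
        b = np.zeros(5, np.int8)
        with pytest.raises(ValueError, match="smaller dt"):
            step_pool(pool, np.ones(5, bool), b, np.zeros(5), params, 0.1, rng)
        # exact probabilities are always valid
        step_pool(pool, np.ones(5, bool), b, np.zeros(5), params, 0.1, rng,
                  exact_prob=True)
        assert b.sum() > 0

    def test_two_state_markov_equilibrium(self):
        # single synapse against frozen pool counts: long-run bound fraction
        # equals r_on / (r_on + r_off)
        params = PoolParams.write_protected(k1=5e-4, k3=0.0, k0=0.125,
                                            m=0.125, N_A_tot=2000)
        # r_on = k1 * N_A = 0.5/s; r_off(I_A=0) = 2 k0 = 0.25/s
        N_A0 = 1000
        rng = np.random.default_rng(4)
        b = np.zeros(1, np.int8)
        occupied = 0
        n_steps = 100_000
        for _ in range(n_steps):
            pool = PoolState(N_A=N_A0, N_A_star=0)  # frozen rates
            step_pool(pool, np.ones(1, bool), b, np.zeros(1), params, 0.1, rng)
            occupied += int(b[0])
        f_expected = 0.5 / (0.5 + 0.25)
        # correlation-corrected Monte-Carlo error of the occupancy average
        tau_corr = 1.0 / ((0.5 + 0.25) * 0.1)
        se = np.sqrt(2 * f_expected * (1 - f_expected) * tau_corr / n_steps)
        assert occupied / n_steps == pytest.approx(f_expected, abs=4 * se)


class TestSetPsi:
    def test_activation_empties_susceptible_pool(self):
        pool = PoolState(N_A=5000, N_A_star=300)
        out = set_psi(pool, True, n_bound=120, params=WP)
        assert out.N_A == 0 and out.psi_active

    def test_deactivation_replenishes_by_conservation(self):
        pool = PoolState(N_A=0, N_A_star=300, psi_active=True)
        out = set_psi(pool, False, n_bound=120, params=WP)
        assert out.N_A == 20000 - 300 - 120
        assert not out.psi_active

    def test_activation_idempotent(self):
        pool = PoolState(N_A=5000, N_A_star=300)
        once = set_psi(pool, True, 0, WP)
        twice = set_psi(once, True, 0, WP)
        assert once == twice

    def test_reservoir_starts_empty(self):
        pool = PoolState.full(WP, n_bound=67)
        assert pool.N_A_star == 0
        assert pool.N_A == WP.N_A_tot - 67


class TestReservoirLaws:
    """Closed-form reservoir fluxes (ensemble means over stochastic runs)."""

    N_REPEATS = 100

    def _ensemble(self, params, psi, I_A_val, n_syn, n_steps, seed,
                  preload=0, n_burn=200):
        # the closed-form fluxes hold in the quasi-stationary binding cycle;
        # the initial equilibration of the unbound population is excluded
        growth = np.empty(self.N_REPEATS)
        mean_bound = np.empty(self.N_REPEATS)
        for rep in range(self.N_REPEATS):
            rng = np.random.default_rng(seed + rep)
            b = np.ones(n_syn, np.int8)
            pool = PoolState(N_A=0 if psi else params.N_A_tot - n_syn - preload,
                             N_A_star=preload, psi_active=psi)
            is_big = np.ones(n_syn, bool)
            I_A = np.full(n_syn, I_A_val)
            start = None
            bound = 0
            for i in range(n_burn + n_steps):
                if i == n_burn:
                    start = pool.N_A_star
                pool = step_pool(pool, is_big, b, I_A, params, 0.1, rng)
                if i >= n_burn:
                    bound += int(b.sum())
            growth[rep] = pool.N_A_star - start
            mean_bound[rep] = bound / n_steps
        return growth, mean_bound

    def test_rising_phase_slope_is_k4_times_Nbig(self):
        # all big synapses bound, no PSI: d n_A*/dt = k4(I_A) N_big.  The
        # closed form assumes rebinding is susceptible-dominated (k1 N_A >>
        # k3 N_A*) and binding-tight (k1 N_A >> k2 + k4), so the test uses
        # sped-up unbinding with binding constants deep in that regime.
        params = PoolParams.write_protected(k0=5e-3, m=2e-2, k1=2e-3,
                                            k3=1e-5, N_A_tot=2000)
        n_syn, T = 100, 100.0
        growth, mean_bound = self._ensemble(
            params, psi=False, I_A_val=0.2, n_syn=n_syn,
            n_steps=int(T / 0.1), seed=100)
        expected = unbinding_rate(0.2, "k4", params) * mean_bound.mean() * T
        assert growth.mean() == pytest.approx(expected, rel=0.05)
        assert mean_bound.mean() == pytest.approx(n_syn, rel=0.05)

    def test_psi_no_stim_decay_slope_is_k0_times_bound(self):
        # PSI, zero activity, reservoir preloaded: d n_A*/dt = -k0 n_ASyn
        params = PoolParams.write_protected(k0=5e-3, m=2e-2, N_A_tot=2000)
        n_syn, T = 100, 100.0
        decay, mean_bound = self._ensemble(
            params, psi=True, I_A_val=0.0, n_syn=n_syn,
            n_steps=int(T / 0.1), seed=200, preload=800)
        expected = -params.k0 * mean_bound.mean() * T
        assert decay.mean() == pytest.approx(expected, rel=0.05)
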