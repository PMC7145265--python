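"""MSM estimation: counting, connectivity, reversible MLE, timescales,
bootstrap, free energies and 1-D landscapes."""

import numpy as np
import pytest
import scipy.optimize

import clcgating as cg
from clcgating.constants import KT_300K
from clcgating.msm import (bootstrap_msms, chapman_kolmogorov,
                           count_transitions, frame_weights, free_energy,
                           implied_timescales, largest_connected_set,
                           mle_reversible, project_free_energy)


class TestCountTransitions:
    def test_enumerated_example(self):
        c = count_transitions([np.array([0, 0, 1, 1])], lag=1)
        np.testing.assert_array_equal(c, [[1, 1], [0, 1]])

    def test_lag_equal_to_length_minus_one_gives_single_count(self):
        c = count_transitions([np.array([0, 1, 1, 2])], lag=3)
        assert c.sum() == 1 and c[0, 2] == 1

    def test_total_counts_combinatorial_identity(self, rng):
        dtrajs = [rng.integers(0, 5, size=n) for n in (100, 57, 23)]
        lag = 4
        c = count_transitions(dtrajs, lag)
        assert c.sum() == sum(len(d) - lag for d in dtrajs)

    def test_lag_longer_than_all_trajectories_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions([np.array([0, 1])], lag=5)


class TestLargestConnectedSet:
    def test_fully_connected_returns_all(self):
        c = np.ones((4, 4), dtype=int)
        np.testing.assert_array_equal(largest_connected_set(c), np.arange(4))

    def test_two_disjoint_blocks_picks_heavier(self):
        c = np.zeros((5, 5), dtype=int)
        c[np.ix_([0, 1, 2], [0, 1, 2])] = 5
        c[np.ix_([3, 4], [3, 4])] = 3
        np.testing.assert_array_equal(largest_connected_set(c), [0, 1, 2])

    def test_directed_chain_vs_networkx_oracle(self, rng):
        import networkx as nx

        c = (rng.random((12, 12)) < 0.15).astype(int) * \
            rng.integers(1, 10, (12, 12))
        np.fill_diagonal(c, rng.integers(1, 5, 12))
        ours = largest_connected_set(c)
        g = nx.from_numpy_array((c > 0).astype(int),
                                create_using=nx.DiGraph)
        best, best_w = None, -1
        for comp in nx.strongly_connected_components(g):
            comp = sorted(comp)
            w = c[np.ix_(comp, comp)].sum()
            if w > best_w or (w == best_w and len(comp) > len(best)):
                best, best_w = comp, w
        np.testing.assert_array_equal(ours, best)


class TestMleReversible:
    def test_symmetric_counts_trivial_mle(self):
        m = mle_reversible(np.array([[90, 10], [10, 90]]))
        np.testing.assert_allclose(m.transition_matrix,
                                   [[0.9, 0.1], [0.1, 0.9]], atol=1e-10)
        np.testing.assert_allclose(m.stationary, [0.5, 0.5], atol=1e-10)

    def test_three_state_matches_brute_force_likelihood_oracle(self, rng):
        """Direct constrained likelihood maximization over 3-state models."""
        C = np.array([[70, 10, 3], [6, 50, 12], [5, 9, 40]], dtype=float)

        # parametrize by symmetric positive x (6 free entries), T = x / rowsum
        def negll(z):
            x = np.zeros((3, 3))
            iu = np.triu_indices(3)
            x[iu] = np.exp(z)
            x = x + np.triu(x, 1).T
            T = x / x.sum(axis=1, keepdims=True)
            return -np.sum(C * np.log(T))

        z0 = np.log((C + C.T)[np.triu_indices(3)] / C.sum())
        best = None
        for attempt in range(3):
            res = scipy.optimize.minimize(
                negll, z0 + attempt * 0.01, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        x = np.zeros((3, 3))
        x[np.triu_indices(3)] = np.exp(best.x)
        x = x + np.triu(x, 1).T
        T_oracle = x / x.sum(axis=1, keepdims=True)

        m = mle_reversible(C, tol=1e-14)
        np.testing.assert_allclose(m.transition_matrix, T_oracle, atol=1e-6)

    def test_detailed_balance_and_row_sums(self, rng):
        C = rng.integers(1, 50, size=(6, 6))
        m = mle_reversible(C)
        T, pi = m.transition_matrix, m.stationary
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-8
        assert m.eigenvalues()[0] == pytest.approx(1.0, abs=1e-10)

    def test_disconnected_states_trimmed(self):
        C = np.zeros((4, 4), dtype=int)
        C[np.ix_([0, 1], [0, 1])] = 20
        C[2, 3] = 1  # one-way, not strongly connected
        m = mle_reversible(C)
        np.testing.assert_array_equal(m.active_set, [0, 1])
        assert m.n_states_full == 4


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # T eigenvalue 0.9 at lag 1 -> t2 = -1/ln(0.9) = 9.491
        rng = np.random.default_rng(0)
        # build a long trajectory from T directly
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        n = 200_000
        d = np.empty(n, dtype=int)
        d[0] = 0
        u = rng.random(n)
        for i in range(1, n):
            d[i] = d[i - 1] if u[i] > 0.05 else 1 - d[i - 1]
        df = implied_timescales([d], lags=[1], n_timescales=1)
        t2 = df.timescale_frames.iloc[0]
        assert t2 == pytest.approx(-1 / np.log(0.9), rel=0.1)

    def test_markovian_data_flat_in_lag(self, protonated_model):
        paths = cg.sample_ctmc(protonated_model, 40, 5000, seed=21)
        df = implied_timescales(paths, lags=[1, 2, 4, 8], n_timescales=1)
        ts = df[df.process == 2].set_index("lag").timescale_frames
        ref = -1 / np.sort(np.linalg.eigvals(
            protonated_model.rate_matrix).real)[::-1][1]
        for lag in (1, 2, 4, 8):
            assert ts[lag] == pytest.approx(ref, rel=0.25)
        assert df[df.process == 2].converged.all()

    def test_timescale_in_physical_units(self):
        d = np.repeat(np.arange(400) % 2, 10)  # blocky two-state sequence
        df = implied_timescales([d], lags=[1], frame_time=9.6)
        row = df.iloc[0]
        assert np.isfinite(row.timescale_frames)
        assert row.timescale_time == pytest.approx(
            row.timescale_frames * 9.6)


class TestBootstrap:
    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError, match="trajectories"):
            bootstrap_msms([np.array([0, 1, 0, 1])], lag=1)

    def test_identity_multiset_equals_mle(self, rng):
        # a "bootstrap" that happens to redraw every trajectory once
        d = [rng.integers(0, 3, 500) for _ in range(2)]
        # force the identity resample by seeding until it occurs is fragile;
        # instead check the estimator agrees when all trajectories coincide
        d = [d[0].copy(), d[0].copy()]
        boots = bootstrap_msms(d, lag=1, n_boot=3, seed=0)
        ref = mle_reversible(count_transitions(d, 1))
        for b in boots:
            np.testing.assert_allclose(b.transition_matrix,
                                       ref.transition_matrix, atol=1e-8)

    def test_error_bars_shrink_with_more_trajectories(self, protonated_model):
        def pop_sd(n_traj, seed):
            paths = cg.sample_ctmc(protonated_model, n_traj, 300, seed=seed)
            boots = bootstrap_msms(paths, lag=2, n_boot=40, seed=seed)
            pops = np.stack([
                np.bincount(b.active_set, weights=b.stationary,
                            minlength=4)[:4] for b in boots])
            return pops.std(axis=0)[0]

        sd_small = pop_sd(100, 31)
        sd_large = pop_sd(400, 32)
        # ~1/sqrt(4) shrinkage, generously banded against SD-of-SD noise
        assert sd_large < 0.70 * sd_small


class TestFreeEnergy:
    def test_uniform_populations_all_zero(self):
        np.testing.assert_allclose(free_energy(np.full(4, 0.25)), 0.0,
                                   atol=1e-12)

    def test_scalar_arithmetic_oracle(self):
        g = free_energy(np.array([0.99, 0.01]), kT=KT_300K)
        assert g[0] == 0.0
        assert g[1] == pytest.approx(-KT_300K * np.log(0.01 / 0.99), abs=1e-9)
        assert g[1] == pytest.approx(2.74, abs=0.01)

    def test_one_percent_state_sits_in_2_to_3_kcal_band(self):
        g = free_energy(np.array([0.72, 0.27, 0.01]), kT=KT_300K)
        assert 2.0 < g[2] < 3.0

    def test_zero_population_flagged_infinite(self):
        g = free_energy(np.array([1.0, 0.0]))
        assert np.isinf(g[1])


class TestProjectFreeEnergy:
    def test_single_basin_has_no_barrier_annotation(self, rng):
        x = rng.normal(size=20_000)
        prof = project_free_energy(x, bins=40)
        assert len(prof.minima()) >= 1
        with pytest.raises(ValueError, match="same basin"):
            prof.barrier(-0.1, 0.1)

    def test_unsampled_interior_flagged(self, rng):
        x = np.concatenate([rng.normal(-5, 0.3, 10_000),
                            rng.normal(5, 0.3, 10_000)])
        prof = project_free_energy(x, bins=60)
        assert not prof.valid.all()
        with pytest.raises(ValueError, match="unsampled"):
            prof.barrier(-5.0, 5.0)

    def test_msm_weighted_profile_recovers_boltzmann_gap(self, rng):
        """Two-state chain: reweighted histogram gives the free-energy gap."""
        T = np.array([[0.98, 0.02], [0.04, 0.96]])  # pi = (2/3, 1/3)
        n = 60_000
        d = np.empty(n, dtype=int)
        d[0] = 0
        u = rng.random(n)
        for i in range(1, n):
            d[i] = (d[i - 1] if u[i] > T[d[i - 1], 1 - d[i - 1]]
                    else 1 - d[i - 1])
        model = mle_reversible(count_transitions([d], 1), lag=1)
        w = frame_weights([d], model)
        y = d * 4.0 - 2.0 + rng.normal(size=n) * 0.4
        prof = project_free_energy([y], weights=w, kT=KT_300K, bins=50)
        mins = prof.minima()
        f_at = {round(prof.centers[i]): prof.f[i] for i in mins}
        gap_est = f_at[2] - f_at[-2]
        gap_true = -KT_300K * np.log(model.stationary[1] /
                                     model.stationary[0])
        assert gap_est == pytest.approx(gap_true, abs=0.1)


class TestChapmanKolmogorov:
    def test_residence_probabilities_consistent_on_markovian_data(
            self, protonated_model):
        paths = cg.sample_ctmc(protonated_model, 30, 4000, seed=9)
        pairs = chapman_kolmogorov(paths, lag=3, sets=[[0], [1], [2, 3]])
        for pred, est in pairs:
            assert est == pytest.approx(pred, abs=0.02)


def test_free_energy_profile_tidy_export(rng):
    prof = project_free_energy(rng.normal(size=5000), bins=30)
    df = prof.to_dataframe()
    assert list(df.columns) == ["coordinate", "free_energy_kcal_mol",
                                "counts", "sampled"]
    assert len(df) == 30


def test_implied_timescale_robust_to_microstate_doubling():
    """Hopping timescale of a double well is stable (+-20%) when the
    1-D state decomposition is refined from 162 to 324 microstates."""
    from clcgating.cluster import fit_minibatch_kmeans

    spec = cg.LangevinSpec(cg.DoubleWellPotential(1.5), timestep=1e-3,
                           n_steps=400_000, seed=13)
    x = cg.sample_langevin(spec)[:, None]
    lag = 500
    ts = {}
    for k in (162, 324):
        cl = fit_minibatch_kmeans(x, k=k, n_iter=150, seed=1)
        m = mle_reversible(count_transitions(cl.assignments, lag), lag=lag)
        ts[k] = m.timescales(1)[0]
    assert ts[324] == pytest.approx(ts[162], rel=0.2)
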