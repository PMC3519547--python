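"""ODE compilation, spline-collocation fitting and the integration cross-check."""

import numpy as np
import pytest

from lipidremodel import (
    OdeSystem,
    RemodelingNetwork,
    SimulationSpec,
    SplineModel,
    build_ode,
    compute_errors,
    fit_dynamics,
    parse_species,
    simulate_pulse_chase,
    verify_by_integration,
)
from lipidremodel.lipid_model import Edge, TimeCourse
from lipidremodel.network_inference import bidirectionalize

A = parse_species("18:3-18:3")
B = parse_species("18:1-18:3")
C = parse_species("18:1-18:1")


def _edge(s, t):
    from lipidremodel import differs_at_one_position

    return Edge(source=s, target=t, position=differs_at_one_position(s, t))


def _constant_tc(species, value=5.0, times=(0.0, 2.0, 4.0, 8.0)):
    values = {s: tuple(np.array([value, value]) for _ in times) for s in species}
    return TimeCourse(species=tuple(species), times=times, values=values)


class TestBuildOde:
    def test_two_species_exchange_structure(self):
        net = RemodelingNetwork.from_edges([_edge(A, B), _edge(B, A)])
        sys = build_ode(net)
        theta = np.array([0.3, 0.1])  # edge order follows the network
        M = sys.rate_matrix(theta)
        ia, ib = sys.index(A), sys.index(B)
        rate = {e.key: th for e, th in zip(sys.edges, theta)}
        assert M[ia, ia] == pytest.approx(-rate[(A, B)])
        assert M[ib, ia] == pytest.approx(rate[(A, B)])
        assert M[ib, ib] == pytest.approx(-rate[(B, A)])
        assert M[ia, ib] == pytest.approx(rate[(B, A)])

    def test_isolated_species_has_zero_derivative(self):
        net = RemodelingNetwork.from_edges([_edge(A, B), _edge(B, A)], extra_nodes=[C])
        sys = build_ode(net)
        x = np.array([1.0, 2.0, 3.0])
        f = sys.f(x, np.array([0.3, 0.1]))
        assert f[sys.index(C)] == 0.0

    def test_mass_conservation_for_any_theta(self):
        net = bidirectionalize(RemodelingNetwork.from_edges([_edge(A, B), _edge(B, C)]))
        sys = build_ode(net)
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = rng.uniform(0, 1, sys.n_parameters)
            x = rng.uniform(0, 50, sys.n_species)
            assert abs(np.sum(sys.f(x, theta))) < 1e-12

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            build_ode(RemodelingNetwork(nodes=frozenset(), edges=()))
        with pytest.raises(ValueError, match="no edges"):
            build_ode(RemodelingNetwork(nodes=frozenset({A}), edges=()))


class TestComputeErrors:
    def test_exact_constant_solution_has_zero_error(self):
        net = RemodelingNetwork.from_edges([_edge(A, B), _edge(B, A)])
        sys = build_ode(net)
        spline = SplineModel()
        tc = _constant_tc([A, B], value=5.0)
        # constant spline: all coefficients equal (partition of unity)
        beta = np.full((2, spline.n_basis), 5.0)
        e_obs, e_ode, e_tot = compute_errors(tc, sys, spline, np.zeros(2), beta, 1.0)
        assert e_obs == pytest.approx(0.0, abs=1e-18)
        assert e_ode == pytest.approx(0.0, abs=1e-18)
        assert e_tot == pytest.approx(0.0, abs=1e-18)

    def test_lambda_zero_reduces_to_observation_error(self, noiseless_path):
        tc, truth = noiseless_path
        sys = truth.system
        spline = SplineModel()
        rng = np.random.default_rng(3)
        beta = rng.normal(size=(sys.n_species, spline.n_basis))
        theta = rng.uniform(0, 1, sys.n_parameters)
        e_obs, _, e_tot = compute_errors(tc, sys, spline, theta, beta, 0.0)
        assert e_tot == pytest.approx(e_obs, rel=1e-14)

    def test_matches_term_by_term_oracle(self, noiseless_path):
        """Vectorized errors equal an explicit double-loop summation."""
        tc, truth = noiseless_path
        sys = truth.system
        spline = SplineModel()
        rng = np.random.default_rng(4)
        beta = rng.normal(size=(sys.n_species, spline.n_basis))
        theta = rng.uniform(0, 1, sys.n_parameters)
        lam = 2.5
        e_obs, e_ode, e_tot = compute_errors(tc, sys, spline, theta, beta, lam)

        times = np.asarray(tc.times)
        t0, t1 = times[0], times[-1]
        y = tc.mean_matrix(order=sys.species)
        Amat = sys.rate_matrix(theta)
        o_obs = 0.0
        for i in range(sys.n_species):
            for h, t in enumerate(times):
                xhat = float((spline.basis_matrix(np.array([t]), t0, t1) @ beta[i])[0])
                o_obs += (xhat - y[i, h]) ** 2
        o_ode = 0.0
        for tau in spline.collocation_points(t0, t1):
            x = np.array([
                float((spline.basis_matrix(np.array([tau]), t0, t1) @ beta[i])[0])
                for i in range(sys.n_species)
            ])
            xdot = np.array([
                float((spline.basis_matrix(np.array([tau]), t0, t1, deriv=1) @ beta[i])[0])
                for i in range(sys.n_species)
            ])
            o_ode += float(np.sum((xdot - Amat @ x) ** 2))
        assert e_obs == pytest.approx(o_obs, abs=1e-10)
        assert e_ode == pytest.approx(o_ode, abs=1e-10)
        assert e_tot == pytest.approx(o_obs + lam * o_ode, abs=1e-10)


class TestFitDynamics:
    def test_constant_data_zero_rates_fixed_point(self):
        net = RemodelingNetwork.from_edges([_edge(A, B), _edge(B, A)])
        sys = build_ode(net)
        tc = _constant_tc([A, B], value=5.0, times=(0.0, 4.0, 12.0, 24.0))
        fit = fit_dynamics(tc, sys)
        assert fit.final_errors[2] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.theta, 0.0, atol=1e-6)

    def test_noiseless_chain_rates_within_ten_percent(self, fitted_noiseless_path):
        tc, truth, net, sys, fit = fitted_noiseless_path
        rates = {e.key: th for e, th in zip(sys.edges, fit.theta)}
        for e, true_rate in zip(truth.network.edges, truth.theta):
            assert rates[e.key] == pytest.approx(true_rate, rel=0.10)

    def test_noisy_chain_dominant_rates_within_thirty_percent(self, noisy_path):
        tc, truth = noisy_path
        from lipidremodel import InferenceConfig, infer_network

        net = bidirectionalize(infer_network(tc, InferenceConfig()))
        sys = build_ode(net)
        fit = fit_dynamics(tc, sys)
        rates = {e.key: th for e, th in zip(sys.edges, fit.theta)}
        for e, true_rate in zip(truth.network.edges, truth.theta):
            assert rates[e.key] == pytest.approx(true_rate, rel=0.30)

    def test_one_parameter_solution_matches_grid_search(self):
        """theta subproblem equals a zoomed brute-force grid argmin (3 s.f.)."""
        net = RemodelingNetwork.from_edges([_edge(A, B)])
        spec = SimulationSpec(
            network=net, theta=np.array([0.25]), x0={A: 100.0, B: 0.0}, noise_cv=0.0
        )
        tc, _ = simulate_pulse_chase(spec)
        sys = OdeSystem(species=(A, B), edges=net.edges)
        spline = SplineModel()
        fit = fit_dynamics(tc, sys, spline=spline)
        lo, hi = 0.0, 1.0
        for _ in range(4):
            grid = np.linspace(lo, hi, 201)
            errs = [
                compute_errors(tc, sys, spline, np.array([t]), fit.beta, 1.0)[2]
                for t in grid
            ]
            i = int(np.argmin(errs))
            lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
        assert fit.theta[0] == pytest.approx((lo + hi) / 2, rel=1e-3)

    def test_error_total_quadratic_in_theta(self, fitted_noiseless_path):
        """Third differences of E_total along any theta direction vanish."""
        tc, truth, net, sys, fit = fitted_noiseless_path
        spline = SplineModel()
        rng = np.random.default_rng(5)
        d = rng.normal(size=sys.n_parameters)
        vals = [
            compute_errors(tc, sys, spline, fit.theta + t * d, fit.beta, 1.0)[2]
            for t in (0.0, 1.0, 2.0, 3.0)
        ]
        third = vals[3] - 3 * vals[2] + 3 * vals[1] - vals[0]
        scale = max(abs(v) for v in vals)
        assert abs(third) < 1e-8 * scale

    def test_rejects_species_without_observations(self):
        net = bidirectionalize(RemodelingNetwork.from_edges([_edge(A, B)]))
        sys = build_ode(net)
        tc = _constant_tc([A])
        with pytest.raises(ValueError, match="without observations"):
            fit_dynamics(tc, sys)

    def test_error_trace_recorded_per_iteration(self, fitted_noiseless_path):
        *_, fit = fitted_noiseless_path
        assert len(fit.error_total) == fit.iterations
        assert len(fit.error_obs) == len(fit.error_ode) == fit.iterations
        best = fit.best_iteration
        assert fit.error_total[best] == pytest.approx(min(fit.error_total))


class TestVerifyByIntegration:
    def test_zero_rates_hold_initial_state(self):
        net = RemodelingNetwork.from_edges([_edge(A, B), _edge(B, A)])
        sys = build_ode(net)
        x0 = np.array([7.0, 3.0])
        traj = verify_by_integration(sys, np.zeros(2), x0, [0.0, 5.0, 24.0])
        np.testing.assert_allclose(traj, np.tile(x0, (3, 1)), atol=1e-9)

    def test_symmetric_exchange_reaches_even_equilibrium(self):
        net = RemodelingNetwork.from_edges([_edge(A, B), _edge(B, A)])
        sys = build_ode(net)
        traj = verify_by_integration(
            sys, np.array([0.5, 0.5]), np.array([10.0, 0.0]), [0.0, 200.0]
        )
        np.testing.assert_allclose(traj[-1], [5.0, 5.0], atol=1e-6)

    def test_irreversible_decay_matches_closed_form(self):
        net = RemodelingNetwork.from_edges([_edge(A, B)])
        sys = OdeSystem(species=(A, B), edges=net.edges)
        k = 0.25
        times = np.array([0.0, 1.0, 4.0, 12.0, 24.0])
        traj = verify_by_integration(sys, np.array([k]), np.array([100.0, 0.0]), times)
        ia = sys.index(A)
        np.testing.assert_allclose(traj[:, ia], 100.0 * np.exp(-k * times), atol=1e-6)

    def test_mass_conserved_along_trajectory(self, fitted_noiseless_path):
        tc, truth, net, sys, fit = fitted_noiseless_path
        x0 = tc.mean_matrix(order=sys.species)[:, 0]
        traj = verify_by_integration(sys, np.clip(fit.theta, 0, None), x0, tc.times)
        totals = traj.sum(axis=1)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-8)

    def test_collocation_and_integration_agree_on_fit(self, fitted_noiseless_path):
        """The spline trajectory solves the fitted ODE to good accuracy."""
        tc, truth, net, sys, fit = fitted_noiseless_path
        spline = SplineModel()
        times = np.asarray(tc.times)
        Bmat = spline.basis_matrix(times, times[0], times[-1])
        spline_traj = Bmat @ fit.beta.T
        # the spline may dip infinitesimally below zero where the data are zero
        x0 = np.clip(spline_traj[0], 0.0, None)
        integ = verify_by_integration(sys, fit.theta, x0, tc.times)
        scale = np.max(np.abs(spline_traj))
        assert np.max(np.abs(spline_traj - integ)) < 0.02 * scale

    def test_rejects_bad_inputs(self):
        net = RemodelingNetwork.from_edges([_edge(A, B)])
        sys = OdeSystem(species=(A, B), edges=net.edges)
        with pytest.raises(ValueError):
            verify_by_integration(sys, np.array([np.nan]), np.array([1.0, 0.0]), [0, 1, 2])
        with pytest.raises(ValueError):
            verify_by_integration(sys, np.array([0.1]), np.array([-1.0, 0.0]), [0, 1, 2])
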