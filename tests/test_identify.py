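import math

import numpy as np
import pytest

from latentid import (
    InfeasibleFrequencies,
    InterventionRegime,
    LCAParameters,
    cell_probabilities,
    check_feasibility,
    compute_frequencies,
    dof_analysis,
    double_labelled_demo,
    grid_min_residual,
    simulate_intervention_study,
    solution_manifold,
    solve_moment_system,
)

from conftest import EXAMPLE, EXAMPLE_REGIME


def forward_pair(params: LCAParameters, delta_prime: float):
    return (
        cell_probabilities(params, params.delta),
        cell_probabilities(params, delta_prime),
    )


class TestSolveMomentSystem:
    def test_exact_recovery_of_the_worked_example(self, exact_pre, exact_post):
        sol = solve_moment_system(exact_pre, exact_post, direction="reduced")
        assert sol.status == "identified_pair"
        assert len(sol.branches) == 2
        params, regime = sol.branches[0]
        assert np.max(np.abs(params.as_array() - EXAMPLE.as_array())) <= 1e-6
        assert regime.delta_prime == pytest.approx(
            EXAMPLE_REGIME.delta_prime, abs=1e-6
        )
        assert sol.residual <= 1e-9

    def test_mirror_pair_closure(self, exact_pre, exact_post):
        sol = solve_moment_system(exact_pre, exact_post, direction="reduced")
        (p1, r1), (p2, r2) = sol.branches
        assert np.max(np.abs(p1.label_swap().as_array() - p2.as_array())) <= 1e-10
        assert abs((1 - r1.delta_prime) - r2.delta_prime) <= 1e-10
        # canonical branch obeys the assumed direction delta' < delta
        assert r1.delta_prime < p1.delta
        assert r2.delta_prime > p2.delta

    def test_unconstrained_direction_warns(self, exact_pre, exact_post):
        with pytest.warns(UserWarning, match="arbitrary"):
            sol = solve_moment_system(exact_pre, exact_post, direction="unconstrained")
        assert sol.status == "identified_pair"

    def test_null_intervention_is_degenerate(self, exact_pre):
        sol = solve_moment_system(exact_pre, exact_pre.as_array())
        assert sol.status == "degenerate_infinite"
        assert sol.residual <= 1e-9

    def test_disconnected_latent_is_degenerate(self):
        # F independent of L in both regimes at identical values: phi0=phi1,
        # lambda0=lambda1 solutions exist for every delta
        p = LCAParameters(0.4, 0.3, 0.3, 0.6, 0.6)
        pre, post = forward_pair(p, 0.8)
        sol = solve_moment_system(pre, post)
        assert sol.status == "degenerate_infinite"

    def test_infeasible_pair_detected(self, exact_pre):
        # positive F-L covariance pre, negative post: impossible, since both
        # regimes share sign((phi1-phi0)(lambda1-lambda0))
        post = np.array([0.05, 0.45, 0.45, 0.05])
        sol = solve_moment_system(exact_pre, post)
        assert sol.status == "infeasible"
        assert sol.branches == ()
        assert sol.residual > 0.05

    def test_noisy_recovery_at_large_n(self):
        # sampling noise: recovered parameters within 0.02 of the generator
        frame = simulate_intervention_study(
            EXAMPLE, EXAMPLE_REGIME, 100_000, 100_000, seed=13
        )
        sol = solve_moment_system(
            compute_frequencies(frame, "pre"),
            compute_frequencies(frame, "post"),
            direction="reduced",
        )
        assert sol.status == "identified_pair"
        params, regime = sol.branches[0]
        assert np.max(np.abs(params.as_array() - EXAMPLE.as_array())) < 0.02
        assert abs(regime.delta_prime - EXAMPLE_REGIME.delta_prime) < 0.02

    def test_regime_tags_enforced(self, exact_pre, exact_post):
        from latentid import ObservedFrequencies

        wrong = ObservedFrequencies.from_counts([324, 176, 156, 344], "post")
        with pytest.raises(ValueError, match="pre"):
            solve_moment_system(wrong, exact_post)


class TestSolutionManifold:
    def test_points_lie_on_the_manifold(self, exact_pre):
        pts = solution_manifold(exact_pre, 20, seed=5)
        assert len(pts) == 20
        target = exact_pre.as_array()
        for p in pts:
            got = cell_probabilities(p, p.delta).as_array()
            assert np.max(np.abs(got - target)) <= 1e-8
        # distinct tuples
        arrays = [p.as_array() for p in pts]
        for i, a in enumerate(arrays):
            for b in arrays[i + 1 :]:
                assert np.max(np.abs(a - b)) > 1e-6

    def test_local_dimension_is_two(self, exact_pre):
        pts = solution_manifold(exact_pre, 5, seed=6)
        interior = [
            p for p in pts if np.all(p.as_array() > 0.01) and np.all(p.as_array() < 0.99)
        ]
        report = dof_analysis(interior[0])
        assert report.solution_dimension == 2

    def test_uniform_frequencies_include_disconnected_family(self):
        # all cells 0.25: every tuple with phi0=phi1=0.5, lambda0=lambda1=0.5
        # solves the equations, for any delta
        for delta in (0.1, 0.5, 0.9):
            p = LCAParameters(delta, 0.5, 0.5, 0.5, 0.5)
            assert np.allclose(cell_probabilities(p, delta).as_array(), 0.25)
        pts = solution_manifold(np.full(4, 0.25), 8, seed=8)
        assert len(pts) == 8

    def test_any_single_regime_table_is_feasible(self):
        # a two-class model saturates a single 2x2 table: even a strongly
        # negatively correlated table has a 2-D family of solutions
        pts = solution_manifold(np.array([0.05, 0.45, 0.45, 0.05]), 3, seed=2)
        assert len(pts) == 3


class TestDofAnalysis:
    def test_observational_accounting(self, example_params):
        report = dof_analysis(example_params)
        assert (report.n_parameters, report.n_constraints) == (5, 3)
        assert report.jacobian_rank == 3
        assert report.solution_dimension == 2
        assert report.status == "generic"

    def test_combined_accounting(self, example_params, example_regime):
        report = dof_analysis(example_params, example_regime)
        assert (report.n_parameters, report.n_constraints) == (6, 6)
        assert report.jacobian_rank == 6
        assert report.solution_dimension == 0

    def test_null_intervention_rank_deficiency_reported(self, example_params):
        report = dof_analysis(
            example_params, InterventionRegime(delta_prime=example_params.delta)
        )
        assert report.status == "rank_deficient"
        # the pre and post constraint blocks differ only in which column
        # carries the prevalence derivative, so the rank drops from 6 to 4
        # and the solution family keeps the observational dimension 2
        assert report.jacobian_rank == 4
        assert report.solution_dimension == 2

    def test_boundary_point_flagged(self):
        report = dof_analysis(LCAParameters(1.0, 0.2, 0.7, 0.1, 0.8))
        assert report.status == "boundary"


class TestCheckFeasibility:
    def test_forward_generated_pair_is_feasible(self, exact_pre, exact_post):
        result = check_feasibility(exact_pre, exact_post)
        assert result.status == "feasible"
        assert result.residual <= 1e-9
        got = np.append(result.witness.as_array(), result.witness_delta_prime)
        want = np.append(EXAMPLE.as_array(), EXAMPLE_REGIME.delta_prime)
        mirrored = np.append(
            EXAMPLE.label_swap().as_array(), 1 - EXAMPLE_REGIME.delta_prime
        )
        assert (
            np.max(np.abs(got - want)) <= 1e-6 or np.max(np.abs(got - mirrored)) <= 1e-6
        )

    def test_extremal_frequencies_are_boundary(self):
        result = check_feasibility(np.array([0.0, 0.0, 0.0, 1.0]))
        assert result.status == "boundary_extremal"

    def test_constructed_infeasible_pair(self, exact_pre):
        result = check_feasibility(exact_pre, np.array([0.05, 0.45, 0.45, 0.05]))
        assert result.status == "infeasible"
        assert result.witness is None

    def test_grid_oracle_agrees_on_feasibility(self, exact_pre, exact_post):
        # feasible pair: some coarse grid point is nearly consistent;
        # infeasible pair: the whole grid stays above the tolerance.
        # With an 11-point grid the max-abs cell deviation within half a
        # step (0.05) of a solution is bounded by 3 * 0.05 = 0.15.
        grid_tol = 0.15
        res_ok, _ = grid_min_residual(exact_pre, exact_post, resolution=11)
        assert res_ok < grid_tol
        res_bad, _ = grid_min_residual(
            exact_pre, np.array([0.05, 0.45, 0.45, 0.05]), resolution=11
        )
        assert res_bad > grid_tol


class TestDoubleLabelledDemo:
    @pytest.mark.parametrize("xi", [0.0, 0.3, -0.7, 1.0])
    def test_mirror_hypotheses_have_equal_likelihood(self, xi):
        demo = double_labelled_demo(xi, successes=4, trials=9)
        assert demo.log_likelihood_pos == demo.log_likelihood_neg

    def test_mle_set_is_the_mirror_pair(self):
        demo = double_labelled_demo(0.1, successes=25, trials=100)
        assert demo.mle_set == (0.5, -0.5)
        # oracle: 1-D grid over xi
        grid = np.linspace(-1, 1, 2001)
        lls = [double_labelled_demo(x, 25, 100).log_likelihood_pos for x in grid]
        best = grid[np.argmax(lls)]
        assert min(abs(best - m) for m in demo.mle_set) < 1e-3

    def test_zero_successes_identify_the_origin(self):
        assert double_labelled_demo(0.4, 0, 7).mle_set == (0.0,)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            double_labelled_demo(0.2, 0, 0)


class TestRoundTripRecoverySample:
    def test_random_interior_generators_recover(self):
        # a small slice of the full acceptance sweep, kept here so module
        # tests alone exercise the recovery property
        from conftest import random_delta_prime, random_interior_params

        rng = np.random.default_rng(99)
        for _ in range(10):
            gen = random_interior_params(rng)
            dp = random_delta_prime(rng, gen.delta)
            pre, post = forward_pair(gen, dp)
            direction = "reduced" if dp < gen.delta else "increased"
            sol = solve_moment_system(pre, post, direction=direction)
            assert sol.status == "identified_pair"
            params, regime = sol.branches[0]
            got = np.append(params.as_array(), regime.delta_prime)
            want = np.append(gen.as_array(), dp)
            assert np.max(np.abs(got - want)) <= 1e-6
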