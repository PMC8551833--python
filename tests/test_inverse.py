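"""Inverse estimation: losses, schedule, stopping rule, optimiser and the
frozen-weight contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvestim import mechanics as M
from lvestim.experiments import (make_contour_observation,
                                 make_full_field_observation)
from lvestim.inverse import (COUNTERS, ContourMatchingEstimator,
                             ContourObservation, FullFieldEstimator,
                             FullFieldObservation, MultiFrameObservation,
                             OptimSchedule, _ContourBatch, _FullFieldBatch,
                             contour_loss, contour_loss_gradient,
                             directed_mean_nn_distance, estimate_parameters,
                             full_field_loss, full_field_loss_gradient,
                             has_converged, learning_rate, multi_frame_loss,
                             optimise_inputs)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 1.0), (10, 0.985),
                                                (20, 0.985 ** 2)])
    def test_exponential_decay_values(self, epoch, expected):
        assert learning_rate(OptimSchedule(), epoch) == pytest.approx(
            expected, rel=1e-12)

    def test_strictly_decreasing_and_continuous(self):
        sched = OptimSchedule()
        rates = [learning_rate(sched, i) for i in range(0, 100)]
        assert np.all(np.diff(rates) < 0)
        assert learning_rate(sched, 5) == pytest.approx(
            1.0 * 0.985 ** 0.5, rel=1e-12)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            OptimSchedule(decay=1.5)


class TestStoppingRule:
    def test_no_change_converges(self):
        assert has_converged([1.0, 2.0], [1.0, 2.0], [1.0, 1.0])

    def test_change_twice_tolerance_does_not(self):
        assert not has_converged([1.0], [1.0 + 2e-5], [1.0], tol=1e-5)

    def test_max_norm_governs(self):
        prev = np.array([1.0, 1.0])
        nxt = prev + np.array([0.9e-5, 1.1e-5])
        assert not has_converged(prev, nxt, np.ones(2), tol=1e-5)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            has_converged([1.0], [1.0], [0.0])


class TestDirectedDistance:
    def test_self_distance_is_zero(self):
        pts = np.random.default_rng(0).random((30, 3))
        assert directed_mean_nn_distance(pts, pts) == 0.0

    def test_single_pair(self):
        assert directed_mean_nn_distance([[0, 0, 0]], [[3, 4, 0]]) == 5.0

    def test_asymmetry(self):
        s1 = [[0.0, 0, 0], [1.0, 0, 0]]
        s2 = [[0.0, 0, 0]]
        assert directed_mean_nn_distance(s1, s2) == pytest.approx(0.5)
        assert directed_mean_nn_distance(s2, s1) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            directed_mean_nn_distance(np.zeros((0, 3)), np.zeros((2, 3)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 20), st.integers(1, 20), st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = rng.random((n1, 3)), rng.random((n2, 3))
        brute = np.mean([min(np.linalg.norm(x - y) for y in s2) for x in s1])
        assert directed_mean_nn_distance(s1, s2) == pytest.approx(brute,
                                                                  rel=1e-12)


class TestLosses:
    def test_full_field_euclidean_norm(self, unit_surrogate, geometry):
        pts = M.sample_wall_points(geometry, 1, seed=0)
        theta = {"c1": 3.5, "c2": 22.0}
        pred = unit_surrogate.predict(
            np.array([[*pts[0], 0.9, 3.5, 22.0]]))
        obs = FullFieldObservation(points=pts,
                                   displacements=pred + [[3.0, 4.0, 0.0]],
                                   pressure=0.9)
        assert full_field_loss(unit_surrogate, obs, theta) == pytest.approx(5.0)

    def test_self_consistent_observation_gives_zero(self, unit_surrogate,
                                                    geometry):
        pts = M.sample_wall_points(geometry, 20, seed=1)
        X = np.hstack([pts, np.broadcast_to([0.9, 3.5, 22.0], (20, 3))])
        obs = FullFieldObservation(points=pts,
                                   displacements=unit_surrogate.predict(X),
                                   pressure=0.9)
        assert full_field_loss(unit_surrogate, obs,
                               {"c1": 3.5, "c2": 22.0}) == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            FullFieldObservation(points=np.zeros((3, 3)),
                                 displacements=np.zeros((2, 3)), pressure=0.9)

    def test_full_field_gradient_matches_finite_differences(
            self, unit_surrogate, geometry):
        m = M.MaterialParams(c1=3.0, c2=18.0)
        pts = M.sample_wall_points(geometry, 40, seed=2)
        obs = make_full_field_observation(geometry, m, [0.9], pts).frames[0]
        theta = {"p": 0.8, "c1": 3.2, "c2": 20.0}
        grad = full_field_loss_gradient(unit_surrogate, obs, theta)
        for j, name in enumerate(("p", "c1", "c2")):
            eps = 1e-4 * theta[name]
            hi = dict(theta); hi[name] += eps
            lo = dict(theta); lo[name] -= eps
            fd = (full_field_loss(unit_surrogate, obs, hi)
                  - full_field_loss(unit_surrogate, obs, lo)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-4)

    def test_contour_gradient_matches_finite_differences(
            self, unit_surrogate, geometry):
        m = M.MaterialParams(c1=3.0, c2=18.0)
        obs = make_contour_observation(geometry, m, [0.9], 60, 150,
                                       seed=3).frames[0]
        theta = {"p": 0.85, "c1": 3.3, "c2": 19.0}
        for dense_first in (True, False):
            grad = contour_loss_gradient(unit_surrogate, obs, theta,
                                         dense_first=dense_first)
            for j, name in enumerate(("p", "c1", "c2")):
                eps = 1e-5 * theta[name]
                hi = dict(theta); hi[name] += eps
                lo = dict(theta); lo[name] -= eps
                fd = (contour_loss(unit_surrogate, obs, hi, dense_first)
                      - contour_loss(unit_surrogate, obs, lo, dense_first)) \
                    / (2 * eps)
                assert grad[j] == pytest.approx(fd, rel=1e-3)

    def test_coincident_surfaces_zero_in_both_orders(self, unit_surrogate,
                                                     geometry):
        # observed surfaces displaced by the surrogate itself, matched sampling
        ref_endo = M.sample_surface(geometry, "endo", 50, seed=4)
        ref_epi = M.sample_surface(geometry, "epi", 50, seed=5)
        theta = {"p": 0.9, "c1": 3.5, "c2": 22.0}

        def displaced(ref):
            X = np.hstack([ref.points,
                           np.broadcast_to([0.9, 3.5, 22.0], (50, 3))])
            return M.Surface(label=ref.label, time_tag="loaded",
                             points=ref.points + unit_surrogate.predict(X))

        obs = ContourObservation(ref_endo, ref_epi, displaced(ref_endo),
                                 displaced(ref_epi), 0.9)
        for dense_first in (True, False):
            assert contour_loss(unit_surrogate, obs, theta,
                                dense_first) == pytest.approx(0.0, abs=1e-9)

    def test_translation_raises_contour_loss(self, unit_surrogate, geometry):
        m = M.MaterialParams()
        obs = make_contour_observation(geometry, m, [0.9], 80, 200,
                                       seed=6).frames[0]
        theta = {"c1": 3.5, "c2": 22.0}
        base = contour_loss(unit_surrogate, obs, theta)
        shifted = ContourObservation(
            obs.reference_endo, obs.reference_epi,
            M.Surface("endo", obs.observed_endo.points + [0.5, 0, 0], "loaded"),
            M.Surface("epi", obs.observed_epi.points + [0.5, 0, 0], "loaded"),
            obs.pressure)
        assert contour_loss(unit_surrogate, shifted, theta) > base

    def test_multi_frame_is_sum_of_frames(self, unit_surrogate, geometry):
        m = M.MaterialParams()
        pts = M.sample_wall_points(geometry, 15, seed=7)
        obs = make_full_field_observation(geometry, m, [0.4, 0.9], pts)
        theta = {"c1": 3.5, "c2": 22.0}
        total = multi_frame_loss(unit_surrogate, obs, theta)
        parts = [full_field_loss(unit_surrogate, f, theta) for f in obs.frames]
        assert total == pytest.approx(sum(parts), rel=1e-12)
        single = multi_frame_loss(unit_surrogate, obs.frames[0], theta)
        assert single == pytest.approx(parts[0], rel=1e-12)

    def test_frame_pressures_must_increase(self, geometry):
        m = M.MaterialParams()
        pts = M.sample_wall_points(geometry, 5, seed=8)
        f = make_full_field_observation(geometry, m, [0.9], pts).frames[0]
        with pytest.raises(ValueError):
            MultiFrameObservation([f, f])

    def test_inconsistent_frame_types_rejected(self, geometry):
        m = M.MaterialParams()
        pts = M.sample_wall_points(geometry, 5, seed=9)
        ff = make_full_field_observation(geometry, m, [0.4], pts).frames[0]
        ct = make_contour_observation(geometry, m, [0.9], 10, 20,
                                      seed=10).frames[0]
        with pytest.raises(ValueError):
            MultiFrameObservation([ff, ct])


class TestEngines:
    """The fast float32 batch engines agree with the float64 reference."""

    def test_full_field_engine_matches_reference(self, unit_surrogate,
                                                 geometry):
        m = M.MaterialParams(c1=3.0, c2=15.0)
        pts = M.sample_wall_points(geometry, 60, seed=11)
        trace = M.make_pressure_trace(0.9, 3)
        obs = make_full_field_observation(geometry, m, trace, pts)
        eng = _FullFieldBatch(
            unit_surrogate, np.stack([f.points for f in obs.frames])[None],
            np.stack([f.displacements for f in obs.frames])[None],
            trace, ("c1", "c2"), {})
        theta = {"c1": 3.2, "c2": 18.0}
        L, G = eng.value_and_grad(np.array([[3.2, 18.0]]))
        ref = multi_frame_loss(unit_surrogate, obs, theta)
        assert L[0] == pytest.approx(ref, rel=1e-4)
        ref_grad = sum(full_field_loss_gradient(unit_surrogate, f,
                                                {**theta, "p": f.pressure},
                                                names=("c1", "c2"))
                       for f in obs.frames)
        assert np.allclose(G[0], ref_grad, rtol=1e-3)

    @pytest.mark.parametrize("dense_first", [True, False])
    def test_contour_engine_candidate_pruning_is_exact(self, unit_surrogate,
                                                       geometry, dense_first):
        m = M.MaterialParams(c1=4.0, c2=30.0)
        trace = M.make_pressure_trace(0.9, 2)
        obs = make_contour_observation(geometry, m, trace, 80, 200, seed=12)
        sparse = {"endo": obs.frames[0].reference_endo.points[None],
                  "epi": obs.frames[0].reference_epi.points[None]}
        dense = {"endo": np.stack([f.observed_endo.points
                                   for f in obs.frames])[None],
                 "epi": np.stack([f.observed_epi.points
                                  for f in obs.frames])[None]}
        exact = _ContourBatch(unit_surrogate, sparse, dense, trace,
                              ("c1", "c2"), {}, n_candidates=None,
                              dense_first=dense_first)
        pruned = _ContourBatch(unit_surrogate, sparse, dense, trace,
                               ("c1", "c2"), {}, n_candidates=8,
                               dense_first=dense_first)
        theta = np.array([[3.8, 27.0]])
        L1, G1 = exact.value_and_grad(theta)
        L2, G2 = pruned.value_and_grad(theta)
        assert L1[0] == pytest.approx(L2[0], rel=1e-6)
        assert np.allclose(G1, G2, rtol=1e-4)


class TestOptimiser:
    def test_quadratic_loss_recovers_analytic_minimiser(self):
        # u linear in theta -> least-squares minimiser in closed form
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 2))
        b = rng.standard_normal(6)
        target = np.linalg.lstsq(A, b, rcond=None)[0]

        class Quadratic:
            names = ("c1", "c2")
            n_runs = 1

            def value_and_grad(self, theta):
                r = A @ theta[0] - b
                return (np.array([0.5 * r @ r]), (A.T @ r)[None, :])

        theta, _, _, _, _, _ = optimise_inputs(
            Quadratic(), OptimSchedule(max_epochs=2500), center=np.zeros(2),
            halfwidth=np.ones(2), theta0=np.zeros(2))
        assert np.allclose(theta[0], target, atol=2e-3)

    def test_start_at_exact_optimum_stays_there(self, unit_surrogate,
                                                geometry):
        # observations produced by the surrogate itself: zero loss, zero
        # gradient, so the stopping rule fires immediately
        pts = M.sample_wall_points(geometry, 20, seed=13)
        X = np.hstack([pts, np.broadcast_to([0.9, 3.5, 22.0], (20, 3))])
        obs = FullFieldObservation(points=pts,
                                   displacements=unit_surrogate.predict(X),
                                   pressure=0.9)
        result = estimate_parameters(
            unit_surrogate, obs, names=("c1", "c2"),
            schedule=OptimSchedule(max_epochs=50),
            init={"c1": 3.5, "c2": 22.0})
        assert result.converged and result.n_epochs <= 3
        assert result.estimates["c1"] == pytest.approx(3.5, abs=1e-6)

    def test_estimation_never_mutates_weights(self, unit_surrogate, geometry):
        m = M.MaterialParams()
        pts = M.sample_wall_points(geometry, 50, seed=14)
        obs = make_full_field_observation(geometry, m, [0.9], pts).frames[0]
        before = unit_surrogate.net_.weight_hash()
        estimate_parameters(unit_surrogate, obs, names=("p",),
                            fixed={"c1": 3.5, "c2": 22.0},
                            schedule=OptimSchedule(max_epochs=100))
        assert unit_surrogate.net_.weight_hash() == before

    def test_noise_free_pressure_recovery(self, unit_surrogate, geometry):
        m = M.MaterialParams(c1=3.5, c2=22.0)
        pts = M.sample_wall_points(geometry, 300, seed=15)
        obs = make_full_field_observation(geometry, m, [0.9], pts).frames[0]
        est = FullFieldEstimator(model=unit_surrogate, params=("p",),
                                 fixed={"c1": 3.5, "c2": 22.0},
                                 max_epochs=800).fit(obs)
        assert abs(est.theta_["p"] - 0.9) / 0.9 < 0.03

    def test_trajectory_shape_and_result_invariants(self, unit_surrogate,
                                                    geometry):
        m = M.MaterialParams()
        pts = M.sample_wall_points(geometry, 30, seed=16)
        obs = make_full_field_observation(geometry, m, [0.9], pts).frames[0]
        result = estimate_parameters(unit_surrogate, obs, names=("p",),
                                     fixed={"c1": 3.5, "c2": 22.0},
                                     schedule=OptimSchedule(max_epochs=40))
        assert result.trajectory.shape == (result.n_epochs + 1, 1)
        assert len(result.loss_history) == result.n_epochs
        assert np.all(np.isfinite(result.loss_history))

    def test_sklearn_param_interface(self, unit_surrogate):
        est = FullFieldEstimator(model=unit_surrogate, params=("p",),
                                 fixed={"c1": 3.5, "c2": 22.0})
        assert est.get_params()["tau0"] == 1.0
        est.set_params(max_epochs=10)
        assert est.max_epochs == 10

    def test_missing_fixed_parameter_rejected(self, unit_surrogate):
        with pytest.raises(ValueError):
            FullFieldEstimator(model=unit_surrogate, params=("p",)).fit(None)


class TestComplexityScaling:
    def test_full_field_cost_linear_in_points(self, unit_surrogate, geometry):
        m = M.MaterialParams()
        counts = {}
        for n in (50, 100):
            pts = M.sample_wall_points(geometry, n, seed=17)
            obs = make_full_field_observation(geometry, m, [0.9], pts).frames[0]
            COUNTERS["surrogate_rows"] = 0
            estimate_parameters(unit_surrogate, obs, names=("p",),
                                fixed={"c1": 3.5, "c2": 22.0},
                                schedule=OptimSchedule(max_epochs=20))
            counts[n] = COUNTERS["surrogate_rows"]
        assert counts[100] == 2 * counts[50]

    def test_contour_cost_scales_with_surface_product(self, unit_surrogate,
                                                      geometry):
        m = M.MaterialParams()
        counts = {}
        for n1, n2 in ((40, 80), (80, 160)):
            obs = make_contour_observation(geometry, m, [0.9], n1, n2,
                                           seed=18).frames[0]
            COUNTERS["pair_distances"] = 0
            estimate_parameters(unit_surrogate, obs, names=("p",),
                                fixed={"c1": 3.5, "c2": 22.0},
                                schedule=OptimSchedule(max_epochs=10))
            counts[(n1, n2)] = COUNTERS["pair_distances"]
        assert counts[(80, 160)] == 4 * counts[(40, 80)]
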