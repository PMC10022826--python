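import numpy as np
import pytest

from formuqbd import mixture_design as mx
from formuqbd.fixtures import load_fixture


class TestConstraints:
    def test_defaults(self, constraints):
        assert constraints.lower == (34.0, 0.0, 5.0)
        assert constraints.upper == (45.0, 10.0, 15.0)
        assert constraints.total == 59.0
        assert sum(constraints.fixed.values()) == pytest.approx(41.0)

    def test_infeasible_total(self):
        with pytest.raises(ValueError, match="empty region"):
            mx.MixtureConstraints(
                lower=(50.0, 50.0, 50.0), upper=(60.0, 60.0, 60.0),
                fixed={"drug": 40.0, "lubricant": 1.0}, total=59.0,
            )

    def test_fixed_must_complete_100(self):
        with pytest.raises(ValueError, match="100"):
            mx.MixtureConstraints(fixed={"drug": 30.0})


class TestPseudoCoding:
    def test_f2_row(self, constraints):
        coded = mx.pseudo_code((36.6, 10.0, 12.4), constraints)
        assert coded == pytest.approx([0.13, 0.50, 0.37])
        assert coded.sum() == pytest.approx(1.0, abs=1e-9)

    def test_f11_row(self, constraints):
        coded = mx.pseudo_code((34.0, 10.0, 15.0), constraints)
        assert coded == pytest.approx([0.0, 0.5, 0.5])

    def test_vertex(self, constraints):
        coded = mx.pseudo_code((45.0, 0.0, 14.0), constraints)
        assert coded == pytest.approx([0.55, 0.0, 0.45])

    def test_out_of_bounds_rejected(self, constraints):
        with pytest.raises(ValueError, match="bounds"):
            mx.pseudo_code((50.0, 0.0, 9.0), constraints)

    def test_wrong_total_rejected(self, constraints):
        with pytest.raises(ValueError, match="sums"):
            mx.pseudo_code((34.0, 0.0, 5.0), constraints)

    def test_round_trip(self, constraints):
        comp = np.array([39.3, 9.6, 10.1])
        back = mx.decode_pseudo(mx.pseudo_code(comp, constraints), constraints)
        assert back == pytest.approx(comp, abs=1e-9)


class TestCandidates:
    def test_pure_vertices_on_unconstrained_simplex(self, unconstrained_simplex):
        cands = mx.generate_candidates(unconstrained_simplex)
        as_set = {tuple(np.round(c, 6)) for c in cands}
        for vertex in [(59.0, 0.0, 0.0), (0.0, 59.0, 0.0), (0.0, 0.0, 59.0)]:
            assert vertex in as_set

    def test_all_candidates_feasible(self, constraints):
        cands = mx.generate_candidates(constraints)
        assert len(cands) >= 7
        for c in cands:
            assert constraints.contains(c, tol=1e-6)
            assert 34.0 - 1e-9 <= c[0] <= 45.0 + 1e-9
            assert 0.0 - 1e-9 <= c[1] <= 10.0 + 1e-9
            assert 5.0 - 1e-9 <= c[2] <= 15.0 + 1e-9
            assert c.sum() == pytest.approx(59.0, abs=1e-6)

    def test_degenerate_region_single_point(self):
        c = mx.MixtureConstraints(
            lower=(30.0, 10.0, 19.0), upper=(40.0, 20.0, 29.0),
            fixed={"drug": 40.0, "lubricant": 1.0}, total=59.0,
        )
        cands = mx.generate_candidates(
            mx.MixtureConstraints(
                lower=(30.0, 10.0, 19.0), upper=(30.0, 10.0, 19.0),
                fixed={"drug": 40.0, "lubricant": 1.0}, total=59.0,
            )
        )
        assert len(cands) == 1


class TestIOptimalDesign:
    def test_linear_unconstrained_gives_vertices(self, unconstrained_simplex):
        runs = mx.i_optimal_design(
            unconstrained_simplex, order="linear", n_runs=3, seed=1
        )
        comps = {tuple(np.round(r.composition, 6)) for r in runs}
        assert comps == {(59.0, 0.0, 0.0), (0.0, 59.0, 0.0), (0.0, 0.0, 59.0)}

    def test_linear_beats_brute_force_triples(self, unconstrained_simplex):
        # exchange result matches exhaustive minimization over all
        # candidate triples under the same region sample
        cands = mx.generate_candidates(unconstrained_simplex)
        rng = np.random.default_rng(42)
        sample = mx._region_sample(unconstrained_simplex, 500, rng)
        sample_coded = np.array(
            [mx.pseudo_code(s, unconstrained_simplex) for s in sample]
        )
        cand_coded = np.array(
            [mx.pseudo_code(c, unconstrained_simplex) for c in cands]
        )
        from itertools import combinations

        brute = min(
            mx.i_criterion(cand_coded[list(trip)], sample_coded, "linear")
            for trip in combinations(range(len(cands)), 3)
        )
        runs = mx.i_optimal_design(
            unconstrained_simplex, order="linear", n_runs=3, seed=1
        )
        run_coded = np.array(
            [mx.pseudo_code(r.composition, unconstrained_simplex) for r in runs]
        )
        assert mx.i_criterion(run_coded, sample_coded, "linear") <= brute + 1e-9

    def test_replicate_structure(self, constraints):
        runs = mx.i_optimal_design(
            constraints, order="quadratic", n_runs=16, n_replicates=5, seed=7
        )
        assert len(runs) == 16
        comps = [tuple(np.round(r.composition, 8)) for r in runs]
        assert len(set(comps)) == 11
        from collections import Counter

        counts = Counter(comps)
        assert sorted(counts.values()) == [1] * 6 + [2] * 5

    def test_moment_matrix_invertible(self, constraints):
        runs = mx.i_optimal_design(
            constraints, order="quadratic", n_runs=12, seed=3
        )
        F = mx._design_matrix(np.array([r.coded for r in runs]), "quadratic")
        assert np.isfinite(np.linalg.cond(F.T @ F))

    def test_deterministic_under_seed(self, constraints):
        a = mx.i_optimal_design(constraints, "quadratic", 12, 2, seed=11)
        b = mx.i_optimal_design(constraints, "quadratic", 12, 2, seed=11)
        assert [r.composition for r in a] == [r.composition for r in b]

    def test_beats_random_designs(self, constraints):
        order = "quadratic"
        cands = mx.generate_candidates(constraints)
        rng = np.random.default_rng(5)
        sample = mx._region_sample(constraints, 500, rng)
        sample_coded = np.array([mx.pseudo_code(s, constraints) for s in sample])
        cand_coded = np.array([mx.pseudo_code(c, constraints) for c in cands])
        runs = mx.i_optimal_design(constraints, order, n_runs=10, seed=5)
        crit = mx.i_criterion(
            np.array([r.coded for r in runs]), sample_coded, order
        )
        for _ in range(100):
            idx = rng.choice(len(cands), size=10, replace=False)
            rand_crit = mx.i_criterion(cand_coded[idx], sample_coded, order)
            assert crit <= rand_crit + 1e-9

    def test_underdetermined_rejected(self, constraints):
        with pytest.raises(ValueError, match="terms"):
            mx.i_optimal_design(constraints, "quadratic", n_runs=5, seed=0)


class TestScheffeFit:
    @pytest.mark.parametrize("order", mx.MODEL_ORDERS)
    def test_exact_recovery_noiseless(self, order, constraints):
        rng = np.random.default_rng(17)
        cands = mx.generate_candidates(constraints)
        extra = mx._region_sample(constraints, 10, rng)
        comps = np.vstack([cands, extra])
        beta = rng.normal(0, 50, size=mx.n_terms(order))
        coded = np.array([mx.pseudo_code(c, constraints) for c in comps])
        y = mx._design_matrix(coded, order) @ beta
        model = mx.fit_scheffe(comps, y, order, constraints)
        assert np.asarray(model.coefficients) == pytest.approx(beta, abs=1e-8)

    def test_lag_time_sign_pattern(self, constraints):
        table3, table6 = load_fixture("table3"), load_fixture("table6")
        comps = table3[["X1", "X2", "X3"]].to_numpy()
        model = mx.fit_scheffe(
            comps, table6["lag_time_s"].to_numpy(), "linear", constraints
        )
        b1, b2, b3 = model.coefficients
        assert b1 > 0 and b2 > 0 and b3 < 0

    def test_constant_response(self, constraints):
        table3 = load_fixture("table3")
        comps = table3[["X1", "X2", "X3"]].to_numpy()
        model = mx.fit_scheffe(comps, np.full(len(comps), 7.5), "linear", constraints)
        assert np.asarray(model.coefficients) == pytest.approx(7.5, abs=1e-8)
        assert np.isnan(model.r_squared)

    def test_collinearity_error_names_terms(self, constraints):
        # 6 distinct points cannot support a 10-term cubic
        comps = mx.generate_candidates(constraints)[:10]
        # duplicate a single point 10 times -> rank 1
        dup = np.tile(comps[0], (10, 1))
        with pytest.raises(mx.CollinearityError) as exc:
            mx.fit_scheffe(dup, np.arange(10.0), "linear", constraints)
        assert exc.value.aliased

    def test_residual_identity(self, constraints):
        table3, table6 = load_fixture("table3"), load_fixture("table6")
        comps = table3[["X1", "X2", "X3"]].to_numpy()
        y = table6["float_time_h"].to_numpy()
        model = mx.fit_scheffe(comps, y, "quadratic", constraints)
        preds = np.array([mx.predict(model, c) for c in comps])
        assert preds + np.asarray(model.residuals) == pytest.approx(y, abs=1e-9)


class TestPredict:
    def test_vertex_returns_coefficient(self, unconstrained_simplex):
        comps = np.array(
            [[59.0, 0, 0], [0, 59.0, 0], [0, 0, 59.0], [29.5, 29.5, 0],
             [29.5, 0, 29.5], [0, 29.5, 29.5]]
        )
        y = np.array([10.0, 20.0, 30.0, 14.0, 22.0, 26.0])
        model = mx.fit_scheffe(comps, y, "linear", unconstrained_simplex)
        assert mx.predict(model, (59.0, 0.0, 0.0)) == pytest.approx(
            model.coefficients[0]
        )

    def test_centroid_is_mean_of_linear_coefficients(self, unconstrained_simplex):
        comps = np.array([[59.0, 0, 0], [0, 59.0, 0], [0, 0, 59.0]])
        y = np.array([12.0, 18.0, 30.0])
        model = mx.fit_scheffe(comps, y, "linear", unconstrained_simplex)
        centroid = (59 / 3, 59 / 3, 59 / 3)
        assert mx.predict(model, centroid) == pytest.approx(np.mean(y))

    def test_training_points_reproduced(self, constraints):
        table3, table6 = load_fixture("table3"), load_fixture("table6")
        comps = table3[["X1", "X2", "X3"]].to_numpy()
        y = table6["lag_time_s"].to_numpy()
        model = mx.fit_scheffe(comps, y, "linear", constraints)
        fitted = y - np.asarray(model.residuals)
        for c, f in zip(comps, fitted):
            assert mx.predict(model, c) == pytest.approx(f, abs=1e-9)
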