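"""The surrogate-assisted search: acceptance probability, constraint
schedule, PSO and ensemble selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jumppower.optimizer import (
    OptimizationTrace,
    SearchState,
    acceptance_probability,
    alpha_schedule,
    constrained_random_search,
    pso_minimize,
    select_ensemble,
)
from jumppower.params import ParamDef, ParamSpace


def two_real_space():
    return ParamSpace(params=[
        ParamDef("x1", "R", (-1.0, 11.0), (0.0, 10.0)),
        ParamDef("x2", "R", (-1.0, 11.0), (0.0, 10.0)),
    ])


class TestAcceptanceProbability:
    def test_unity_at_ceiling(self):
        assert acceptance_probability(2.5, 2.5, 0.4) == 1.0

    def test_one_delta_above_ceiling(self):
        assert acceptance_probability(2.9, 2.5, 0.4) == pytest.approx(
            np.exp(-0.5)
        )

    def test_worked_example(self):
        # L0=2.0, SD=0.8, alpha=0 -> L_max=2.0, delta=0.4; L=3.0
        state = SearchState(j=10, n_refits=20, l0=2.0, sd_loss=0.8)
        assert state.l_max == 2.0 and state.delta == 0.4
        p = acceptance_probability(3.0, state.l_max, state.delta)
        assert p == pytest.approx(np.exp(-1.0 / (2 * 0.4**2)), rel=1e-12)
        assert p == pytest.approx(0.0439, abs=2e-4)

    def test_degenerate_zero_delta(self):
        assert acceptance_probability(3.0, 2.0, 0.0) == 0.0
        assert acceptance_probability(1.9, 2.0, 0.0) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0), st.floats(0.01, 5.0))
    def test_monotone_nonincreasing_above_ceiling(self, l1, dl, delta):
        l_max = 1.0
        p1 = acceptance_probability(l_max + l1, l_max, delta)
        p2 = acceptance_probability(l_max + l1 + dl, l_max, delta)
        assert p2 <= p1


class TestAlphaSchedule:
    @pytest.mark.parametrize("j,n,expected", [
        (1, 20, 0.5), (10, 20, 0.0), (15, 20, 0.0), (20, 20, 0.0),
    ])
    def test_endpoints(self, j, n, expected):
        assert alpha_schedule(j, n) == pytest.approx(expected)

    def test_linear_descent_and_monotonicity(self):
        vals = [alpha_schedule(j, 20) for j in range(1, 21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.5
        # linear over the ramp
        diffs = np.diff(vals[:10])
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            alpha_schedule(0, 20)


class TestPSO:
    def test_paraboloid_vertex_found(self, rng):
        space = two_real_space()

        def predict(X):
            X = np.atleast_2d(X)
            return (X[:, 0] - 4.2) ** 2 + 2 * (X[:, 1] - 6.3) ** 2

        opt, val = pso_minimize(predict, space, rng, n_particles=30, tol=1e-4)
        assert np.allclose(opt, [4.2, 6.3], atol=0.05)

    def test_integer_bounds_round_within_range(self, rng):
        space = ParamSpace(params=[
            ParamDef("k", "I", (0, 31), (0.51, 30.49)),
        ])

        def predict(X):
            return (np.atleast_2d(X)[:, 0] - 0.1) ** 2  # pulls to low edge

        opt, _ = pso_minimize(predict, space, rng, n_particles=20)
        assert opt[0] == 1.0  # rounded, never 0

    def test_categorical_rounding(self, rng):
        space = ParamSpace(params=[
            ParamDef("c", "C", (0.51, 3.49), (0.51, 3.49),
                     categories=("a", "b", "c")),
        ])

        def predict(X):
            return (np.atleast_2d(X)[:, 0] - 2.4) ** 2

        opt, _ = pso_minimize(predict, space, rng, n_particles=20)
        assert opt[0] == 2.0

    def test_nonfinite_surrogate_rejected(self, rng):
        space = two_real_space()
        with pytest.raises(FloatingPointError):
            pso_minimize(lambda X: np.full(len(np.atleast_2d(X)), np.nan),
                         space, rng)


class TestConstrainedRandomSearch:
    def test_bookkeeping_counts(self):
        space = two_real_space()
        calls = []

        def objective(x):
            calls.append(x)
            return float((x[0] - 3) ** 2 + (x[1] - 7) ** 2)

        trace, surrogate = constrained_random_search(
            objective, space, n_obs=60, refit_every=20, seed=0, n_particles=10
        )
        assert len(calls) == 60
        assert len(trace.X) == 60
        assert len(trace.refits) == 3
        assert surrogate is not None

    def test_quadratic_noiseless_recovery(self):
        space = two_real_space()

        def objective(x):
            return 0.1 * ((x[0] - 3.0) ** 2 + (x[1] - 7.0) ** 2)

        trace, _ = constrained_random_search(
            objective, space, n_obs=100, refit_every=20, seed=3, n_particles=25
        )
        final = trace.refits[-1].optimum
        assert abs(final[0] - 3.0) / 10 < 0.05
        assert abs(final[1] - 7.0) / 10 < 0.05

    def test_screening_never_calls_objective(self):
        # the surrogate screens candidates; only accepted points reach the
        # true objective, exactly n_obs times
        space = two_real_space()
        n_calls = 0

        def objective(x):
            nonlocal n_calls
            n_calls += 1
            return float(x[0] + np.random.default_rng(n_calls).normal(0, 0.1))

        trace, _ = constrained_random_search(
            objective, space, n_obs=40, refit_every=20, seed=5, n_particles=10
        )
        assert n_calls == 40
        assert trace.n_screened >= 20  # screening happened after refit 1

    def test_eligible_optima_from_zero_alpha_phase(self):
        space = two_real_space()
        trace, _ = constrained_random_search(
            lambda x: float(x[0] ** 2 + x[1] ** 2), space,
            n_obs=80, refit_every=20, seed=6, n_particles=10,
        )
        n_zero = sum(1 for r in trace.refits if r.alpha == 0.0)
        assert len(trace.eligible_optima()) == n_zero
        assert n_zero >= 2

    def test_seeded_determinism(self):
        space = two_real_space()

        def make_obj(seed):
            rng = np.random.default_rng(seed)
            return lambda x: float(x[0] ** 2 + rng.normal(0, 0.2))

        t1, _ = constrained_random_search(make_obj(1), space, n_obs=40,
                                          refit_every=20, seed=7, n_particles=8)
        t2, _ = constrained_random_search(make_obj(1), space, n_obs=40,
                                          refit_every=20, seed=7, n_particles=8)
        np.testing.assert_array_equal(np.array(t1.X), np.array(t2.X))
        np.testing.assert_array_equal(t1.losses, t2.losses)

    def test_trace_serialises(self, tmp_path):
        space = two_real_space()
        trace, _ = constrained_random_search(
            lambda x: float(x[0]), space, n_obs=20, refit_every=20, seed=8,
            n_particles=5,
        )
        trace.to_json(tmp_path / "trace.json")
        assert (tmp_path / "trace.json").stat().st_size > 0


class TestEnsembleSelection:
    def test_categorical_mode(self):
        space = ParamSpace(params=[
            ParamDef("k", "C", (0.51, 2.49), (0.51, 2.49),
                     categories=("Gaussian", "Linear")),
        ])
        optima = [np.array([1.0])] * 7 + [np.array([2.0])] * 3
        assert select_ensemble(optima, space)[0] == 1.0

    def test_categorical_tie_breaks_low(self):
        space = ParamSpace(params=[
            ParamDef("k", "C", (0.51, 2.49), (0.51, 2.49),
                     categories=("a", "b")),
        ])
        optima = [np.array([2.0]), np.array([1.0])]
        assert select_ensemble(optima, space)[0] == 1.0

    def test_numeric_kde_peak_at_major_mode(self, rng):
        space = ParamSpace(params=[ParamDef("x", "R", (0, 10), (0.0, 10.0))])
        vals = np.concatenate([
            rng.normal(2.0, 0.15, 80), rng.normal(8.0, 0.15, 20)
        ])
        optima = [np.array([v]) for v in vals]
        picked = select_ensemble(optima, space)[0]
        assert 1.5 <= picked <= 2.5
        # histogram oracle agrees on the major mode
        hist, edges = np.histogram(vals, bins=20)
        centre = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(picked - centre) < 0.5

    def test_single_repeated_value(self):
        space = ParamSpace(params=[ParamDef("x", "R", (0, 10), (0.0, 10.0))])
        optima = [np.array([4.2])] * 5
        assert select_ensemble(optima, space)[0] == 4.2

    def test_empty_eligible_rejected(self):
        space = two_real_space()
        with pytest.raises(ValueError):
            select_ensemble([], space)

    def test_validity_filter_applied(self):
        space = ParamSpace(params=[ParamDef("x", "R", (0, 10), (0.0, 10.0))])
        optima = [np.array([1.0]), np.array([9.0]), np.array([9.1])]
        picked = select_ensemble(optima, space,
                                 validity_fn=lambda x: x[0] < 5.0)
        assert picked[0] == 1.0
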