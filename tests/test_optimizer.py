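"""Dominance, archives, Darwinian rules and full swarm runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcfuse.fractional import FractionalSchedule
from gcfuse.metrics import hypervolume, igd
from gcfuse.optimizer import (
    OptimizerConfig,
    ParetoArchive,
    dominates,
    nondominated_filter,
    run_modpso,
    run_vf_modpso,
    selection_coefficient,
)
from gcfuse.phantoms import analytic_front, schaffer_problem

obj2 = st.tuples(
    st.floats(-10, 10, allow_nan=False), st.floats(-10, 10, allow_nan=False)
).map(np.array)


class TestDominance:
    def test_basic_cases(self):
        assert dominates(np.array([0.1, 5.0]), np.array([0.2, 5.0]))
        assert not dominates(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
        assert not dominates(np.array([2.0, 1.0]), np.array([1.0, 2.0]))
        a = np.array([1.0, 1.0])
        assert not dominates(a, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates(np.array([1.0]), np.array([1.0, 2.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=obj2, b=obj2, c=obj2)
    def test_strict_partial_order(self, a, b, c):
        # irreflexive + asymmetric + transitive
        assert not dominates(a, a)
        if dominates(a, b):
            assert not dominates(b, a)
        if dominates(a, b) and dominates(b, c):
            assert dominates(a, c)


class TestNondominatedFilter:
    def test_small_example(self):
        pts = np.array([[0, 1], [1, 0], [1, 1]], float)
        out = nondominated_filter(pts)
        np.testing.assert_array_equal(out, [[0, 1], [1, 0]])

    def test_single_point(self):
        np.testing.assert_array_equal(
            nondominated_filter(np.array([[3.0, 4.0]])), [[3.0, 4.0]]
        )

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.uniform(size=(200, 2))
        out = nondominated_filter(pts)
        expected = []
        for p in pts:
            if not any(
                np.all(q <= p) and np.any(q < p) for q in pts
            ):
                expected.append(p)
        expected = np.unique(np.array(expected), axis=0)
        np.testing.assert_array_equal(out, expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nondominated_filter(np.empty((0, 2)))


class TestSelectionCoefficient:
    def test_values_and_limit(self):
        assert selection_coefficient(0, 0.9) == 0.0
        assert selection_coefficient(1, 0.9) == pytest.approx(0.45)
        assert selection_coefficient(10**6, 0.9) == pytest.approx(0.9, abs=1e-5)
        vals = [selection_coefficient(k, 0.9) for k in range(20)]
        assert np.all(np.diff(vals) > 0)
        assert max(vals) < 0.9

    def test_negative_kill_count(self):
        with pytest.raises(ValueError):
            selection_coefficient(-1, 0.9)


class TestParetoArchive:
    def test_dominated_candidate_rejected(self):
        a = ParetoArchive(10)
        a.add(np.array([0.0]), np.array([0.0, 0.0]))
        assert not a.add(np.array([1.0]), np.array([1.0, 1.0]))
        assert len(a) == 1

    def test_dominating_candidate_sweeps(self):
        a = ParetoArchive(10)
        a.add(np.array([0.0]), np.array([1.0, 2.0]))
        a.add(np.array([1.0]), np.array([2.0, 1.0]))
        a.add(np.array([2.0]), np.array([0.5, 0.5]))
        assert len(a) == 1
        np.testing.assert_array_equal(a.objectives[0], [0.5, 0.5])

    def test_equals_filter_at_large_capacity(self, rng):
        pts = rng.uniform(size=(150, 2))
        a = ParetoArchive(10_000)
        for i, p in enumerate(pts):
            a.add(np.array([float(i)]), p)
        np.testing.assert_array_equal(
            np.unique(a.objs_array(), axis=0), nondominated_filter(pts)
        )

    def test_capacity_enforced_mutually_nondominated(self, rng):
        a = ParetoArchive(8)
        for i in range(300):
            a.add(np.array([float(i)]), rng.uniform(size=2))
            assert len(a) <= 8
        objs = a.objs_array()
        for i in range(len(a)):
            for j in range(len(a)):
                if i != j:
                    assert not dominates(objs[i], objs[j])


TOY_CFG = OptimizerConfig(
    pop_size=30, max_iter=60, bounds=((-2.0, 4.0),), seed=0, archive_capacity=30
)


class TestRuns:
    def test_archive_invariants_and_positive_objectives(self):
        archive, log = run_modpso(schaffer_problem, TOY_CFG)
        objs = archive.objs_array()
        assert np.all(objs >= 0)
        for i in range(len(archive)):
            for j in range(len(archive)):
                if i != j:
                    assert not dominates(objs[i], objs[j])

    def test_seeded_determinism(self):
        a1, l1 = run_vf_modpso(schaffer_problem, TOY_CFG)
        a2, l2 = run_vf_modpso(schaffer_problem, TOY_CFG)
        np.testing.assert_array_equal(a1.objs_array(), a2.objs_array())
        assert l1.hv == l2.hv and l1.n_kill == l2.n_kill

    def test_zero_iterations_returns_initial_nondominated(self):
        cfg = OptimizerConfig(
            pop_size=20, max_iter=0, bounds=((-2.0, 4.0),), seed=3,
            archive_capacity=100,
        )
        archive, _ = run_modpso(schaffer_problem, cfg)
        objs = archive.objs_array()
        # reconstruct the initial population from the same seed
        rng = np.random.default_rng(3)
        xs = rng.uniform(-2.0, 4.0, size=20)
        pop = np.array([schaffer_problem(np.array([x])) for x in xs])
        np.testing.assert_array_equal(
            np.unique(objs, axis=0), nondominated_filter(pop)
        )

    def test_vf_reduction_bit_identical_to_modpso(self):
        cfg = OptimizerConfig(
            pop_size=25, max_iter=40, bounds=((-2.0, 4.0),), seed=9,
            archive_capacity=25,
            schedule=FractionalSchedule(1.0, 1.0, 40),
            memory_depth=1,
            darwinian=False,
        )
        a1, l1 = run_modpso(schaffer_problem, cfg)
        a2, l2 = run_vf_modpso(schaffer_problem, cfg)
        np.testing.assert_array_equal(a1.objs_array(), a2.objs_array())
        assert l1.hv == l2.hv

    def test_nkill_non_decreasing(self):
        _, log = run_vf_modpso(schaffer_problem, TOY_CFG)
        assert np.all(np.diff(log.n_kill) >= 0)

    def test_hv_trace_non_decreasing_at_unbounded_capacity(self):
        cfg = OptimizerConfig(
            pop_size=20, max_iter=40, bounds=((-2.0, 4.0),), seed=5,
            archive_capacity=100_000,
        )
        _, log = run_modpso(schaffer_problem, cfg)
        assert np.all(np.diff(log.hv) >= -1e-12)

    def test_nonfinite_objective_resampled(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 7 == 0:
                return np.array([np.nan, 1.0])
            return schaffer_problem(x)

        cfg = OptimizerConfig(
            pop_size=10, max_iter=10, bounds=((-2.0, 4.0),), seed=2,
            archive_capacity=10,
        )
        archive, _ = run_modpso(flaky, cfg)
        assert np.all(np.isfinite(archive.objs_array()))

    def test_convergence_to_analytic_front(self):
        front = analytic_front("sch", 300)
        archive, _ = run_vf_modpso(schaffer_problem, TOY_CFG)
        assert igd(archive.objs_array(), front) < 0.1
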