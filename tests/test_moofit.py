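"""Evolutionary fitting engine: sorting oracle, determinism, elitism,
bounds, acceptance filtering, parameter ranges, two-stage masking."""

import numpy as np
import pytest

from dendrofit.moofit import (
    AcceptableSet, Individual, PARAM_BOUNDS, TABLE3_PARAMS, WORST_OBJECTIVE,
    compare_ranges, crowding_distance, nondominated_sort, parameter_ranges,
    run_moo, select_acceptable, table2_space, two_stage_fit, evaluate,
    DENDRITIC_PARAMS,
)


def brute_force_fronts(objs):
    """Independent O(n^2 m) domination oracle."""
    objs = np.asarray(objs, float)
    n = len(objs)
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                np.all(objs[j] <= objs[i]) and np.any(objs[j] < objs[i])
                for j in remaining if j != i)
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestParameterSpace:
    def test_table2_bounds(self):
        space = table2_space()
        assert space.n == 22
        assert PARAM_BOUNDS["s.gbar_Na_t"] == (0.0, 40000.0)
        assert PARAM_BOUNDS["a.gbar_Ca_LVA"] == (0.0, 1000.0)
        assert PARAM_BOUNDS["s.gamma"] == (0.0005, 0.05)

    def test_published_parameters_lie_within_bounds(self):
        space = table2_space()
        x = np.array([TABLE3_PARAMS[n] for n in space.names])
        assert space.contains(x)

    def test_normalization_by_upper_limit(self):
        space = table2_space()
        x = np.array([TABLE3_PARAMS[n] for n in space.names])
        norm = space.normalize(x)
        i = space.names.index("a.gbar_Na_t")
        assert norm[i] == pytest.approx(107.0 / 200.0)  # 0.535
        hi = space.upper.copy()
        assert space.normalize(hi)[i] == pytest.approx(1.0)
        assert space.normalize(np.zeros(22))[i] == 0.0

    def test_seeded_sampling_in_bounds(self):
        space = table2_space()
        x = space.sample(np.random.default_rng(5), 100)
        assert np.all(x >= space.lower) and np.all(x <= space.upper)
        y = space.sample(np.random.default_rng(5), 100)
        np.testing.assert_array_equal(x, y)


class TestNondominatedSort:
    def test_single_individual_single_front(self):
        fronts = nondominated_sort(np.array([[1.0, 2.0]]))
        assert len(fronts) == 1

    def test_simple_domination(self):
        fronts = nondominated_sort(np.array([[1.0, 1.0], [2.0, 2.0]]))
        assert list(fronts[0]) == [0]
        assert list(fronts[1]) == [1]

    def test_matches_brute_force_oracle_many_instances(self):
        """Front partition identical to the brute-force oracle on random
        many-objective instances."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n = int(rng.integers(2, 60))
            m = int(rng.integers(2, 6))
            objs = rng.uniform(0.0, 1.0, size=(n, m))
            if trial % 3 == 0:  # inject duplicates and ties
                objs[rng.integers(n)] = objs[rng.integers(n)]
            fronts = nondominated_sort(objs)
            oracle = brute_force_fronts(objs)
            assert [list(f) for f in fronts] == oracle

    def test_crowding_boundary_infinite(self):
        objs = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0]])
        d = crowding_distance(objs)
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1]) and np.isfinite(d[2])


def sphere_evaluator(x):
    """Cheap 2-objective test problem on the 22-parameter space."""
    z = x / (np.abs(x).max() + 1.0)
    f1 = float(np.mean((z - 0.1) ** 2))
    f2 = float(np.mean((z - 0.3) ** 2))
    errs = np.array([f1, f2]) * 10.0
    return np.array([f1, f2]), errs


class TestRunMoo:
    def test_zero_generations_returns_initial_population(self):
        space = table2_space()
        res = run_moo(space, sphere_evaluator, 8, 0, seed=3)
        assert len(res.populations) == 1
        assert all(ind.objectives is not None for ind in res.final)

    def test_seeded_determinism(self):
        space = table2_space()
        a = run_moo(space, sphere_evaluator, 12, 4, seed=11)
        b = run_moo(space, sphere_evaluator, 12, 4, seed=11)
        for pa, pb in zip(a.populations, b.populations):
            np.testing.assert_array_equal(
                np.array([i.params for i in pa]),
                np.array([i.params for i in pb]))

    def test_elitism_front_minimum_never_degrades(self):
        space = table2_space()
        res = run_moo(space, sphere_evaluator, 16, 8, seed=7)
        prev = None
        for pop in res.populations:
            objs = np.array([i.objectives for i in pop])
            best = objs.min(axis=0)
            if prev is not None:
                assert np.all(best <= prev + 1e-15)
            prev = best

    def test_all_archived_individuals_in_bounds(self):
        space = table2_space()
        res = run_moo(space, sphere_evaluator, 12, 5, seed=9)
        for ind in res.all_individuals():
            assert space.contains(ind.params)

    def test_failed_evaluations_quarantined(self):
        space = table2_space()
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("simulation blew up")
            return sphere_evaluator(x)

        res = run_moo(space, flaky, 10, 3, seed=1)
        failed = [i for i in res.all_individuals() if i.failed]
        assert failed
        for ind in failed:
            assert np.all(ind.objectives == WORST_OBJECTIVE)

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            run_moo(table2_space(), sphere_evaluator, 7, 1, seed=0)


class TestSelectAcceptable:
    def _pop(self, errors):
        space = table2_space()
        rng = np.random.default_rng(0)
        pop = []
        for e in errors:
            ind = Individual(space.sample(rng, 1)[0])
            ind.objectives = np.array([1.0])
            ind.feature_errors = np.asarray(e, float)
            pop.append(ind)
        return space, pop

    def test_zero_error_accepted(self):
        space, pop = self._pop([[0.0, 0.0]])
        assert len(select_acceptable([pop], space, 3.0)) == 1

    def test_single_feature_over_cutoff_rejected(self):
        space, pop = self._pop([[1.0, 3.5]])
        assert len(select_acceptable([pop], space, 3.0)) == 0
        assert len(select_acceptable([pop], space, 4.0)) == 1

    def test_counts_match_hand_enumeration(self):
        errors = [[0.5, 2.9], [3.1, 0.1], [2.99, 2.99], [0.0, 3.0],
                  [250.0, 0.0]]
        space, pop = self._pop(errors)
        acc = select_acceptable([pop], space, 3.0)
        assert len(acc) == 3  # rows 0, 2 and 3

    def test_duplicates_removed(self):
        space, pop = self._pop([[0.0], [0.0]])
        pop[1].params = pop[0].params.copy()
        assert len(select_acceptable([pop], space, 3.0)) == 1


class TestParameterRanges:
    def test_limits_normalize_to_unit(self):
        space = table2_space()
        hi = Individual(space.upper.copy(), feature_errors=np.array([0.0]))
        lo = Individual(space.lower.copy(), feature_errors=np.array([0.0]))
        acc = AcceptableSet([hi, lo], space, 3.0)
        r = parameter_ranges(acc).set_index("parameter")
        assert r.loc["a.gbar_Na_t", "max_normalized"] == pytest.approx(1.0)
        assert r.loc["a.gbar_Na_t", "min_normalized"] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            parameter_ranges(AcceptableSet([], table2_space(), 3.0))

    def test_compare_ranges_overlap(self):
        space = table2_space()
        mid = space.lower + 0.5 * (space.upper - space.lower)
        a = AcceptableSet([Individual(space.lower.copy()),
                           Individual(mid)], space, 3.0)
        b = AcceptableSet([Individual(mid),
                           Individual(space.upper.copy())], space, 3.0)
        cmp = compare_ranges(a, b).set_index("parameter")
        assert (cmp["overlap"] >= 0.0).all()


class TestEvaluateValidation:
    def test_out_of_bounds_parameters_rejected(self, ref_cell):
        bad = dict(TABLE3_PARAMS)
        bad["s.gbar_Na_t"] = 50000.0  # above the 40000 limit
        with pytest.raises(ValueError, match="outside bounds"):
            evaluate(bad, ref_cell, "bac")


class TestTwoStageFit:
    def test_stage2_freezes_dendritic_partition(self):
        """Stage-2 individuals never mutate the apical + basal-leak
        parameters donated by the stage-1 winner."""
        space = table2_space()
        apical_idx = [space.names.index(n) for n in DENDRITIC_PARAMS]

        def eval_bac(x):
            errs = np.abs(space.normalize(x)[apical_idx][:5] - 0.4) * 5.0
            return errs, errs

        def eval_step(x):
            errs = np.abs(space.normalize(x)[:5] - 0.5) * 5.0
            return errs, errs

        def eval_both_factory(frozen_space):
            def ev(x):
                e1, _ = eval_bac(x)
                e2, _ = eval_step(x)
                errs = np.concatenate([e1, e2])
                return errs, errs
            return ev

        acc2, res1, res2 = two_stage_fit(
            space, eval_bac, eval_step, eval_both_factory,
            pop_size=16, n_gen=6, seed=5, cutoff_sd=3.0,
            max_rank_candidates=4)
        frozen_vals = res2.space.frozen_values[res2.space.frozen]
        assert res2.space.frozen.sum() == len(DENDRITIC_PARAMS)
        for pop in res2.populations:
            for ind in pop:
                np.testing.assert_array_equal(
                    ind.params[res2.space.frozen], frozen_vals)
        assert len(acc2) >= 1
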