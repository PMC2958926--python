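import numpy as np
import pytest

from ebca.data import Distribution, StochasticSpec
from ebca.dea import (ConvergenceSettings, DEAInstance, DEAModelConfig,
                      Scenario, TierThresholds, classify_tiers,
                      enumerate_scenarios, run_monte_carlo, solve_dea,
                      transform_nonstandard)
from ebca.rules import IOAnnotation

from oracles import ccr_multiplier_oracle


class TestTransform:
    def annotation(self):
        return IOAnnotation("v", "input", "non-standard")

    def test_worked_example(self):
        out = transform_nonstandard(np.array([3.0, 5.0, 9.0]), self.annotation())
        assert out == pytest.approx([6.6, 4.6, 0.6])

    def test_constant_column_floors_positive(self):
        out = transform_nonstandard(np.array([4.0, 4.0, 4.0]), self.annotation())
        assert (out > 0).all()
        assert len(set(out)) == 1

    def test_rank_reversal(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(1, 10, size=20)
        out = transform_nonstandard(col, self.annotation())
        assert (np.argsort(out) == np.argsort(-col)).all()
        assert (out > 0).all()

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            transform_nonstandard(np.array([1.0, -2.0]), self.annotation())

    def test_standard_annotation_rejected(self):
        with pytest.raises(ValueError):
            transform_nonstandard(np.array([1.0]), IOAnnotation("v", "input"))


class TestSolveDEA:
    def test_identical_dmus_both_efficient(self):
        inst = DEAInstance(["A", "B"], [[2.0, 3.0]] * 2, [[5.0]] * 2)
        for u in ("A", "B"):
            assert solve_dea(inst, DEAModelConfig(), u) == pytest.approx(1.0, abs=1e-7)

    def test_closed_form_1x1_ccr(self):
        inst = DEAInstance(["A", "B"], [[1.0], [2.0]], [[1.0], [1.0]])
        assert solve_dea(inst, DEAModelConfig(), "B") == pytest.approx(0.5, abs=1e-7)

    def test_vrs_vs_crs_small_example(self):
        inst = DEAInstance(["A", "B"], [[1.0], [3.0]], [[1.0], [2.0]])
        vrs = solve_dea(inst, DEAModelConfig(returns_to_scale="variable"), "B")
        crs = solve_dea(inst, DEAModelConfig(), "B")
        assert vrs == pytest.approx(1.0, abs=1e-7)
        assert crs == pytest.approx(2.0 / 3.0, abs=1e-7)

    def test_output_orientation_on_single_ratio_case(self):
        # with 1 input / 1 output under CRS, input and output oriented scores agree
        inst = DEAInstance(["A", "B", "C"], [[1.0], [2.0], [4.0]],
                          [[2.0], [2.0], [3.0]])
        for u in inst.units:
            a = solve_dea(inst, DEAModelConfig(orientation="input"), u)
            b = solve_dea(inst, DEAModelConfig(orientation="output"), u)
            assert a == pytest.approx(b, abs=1e-6)

    def test_invalid_instances_rejected(self):
        with pytest.raises(ValueError):
            DEAInstance(["A"], [[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            DEAInstance(["A", "B"], [[1.0], [0.0]], [[1.0], [1.0]])

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        inst = DEAInstance(
            [f"D{i}" for i in range(5)],
            rng.uniform(1, 10, size=(5, 2)),
            rng.uniform(1, 10, size=(5, 1)),
        )
        for i, u in enumerate(inst.units):
            env = solve_dea(inst, DEAModelConfig(), u)
            assert env == pytest.approx(ccr_multiplier_oracle(inst, i), abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_frontier_and_rts_properties(self, seed):
        rng = np.random.default_rng(100 + seed)
        inst = DEAInstance(
            [f"D{i}" for i in range(6)],
            rng.uniform(1, 10, size=(6, 2)),
            rng.uniform(1, 10, size=(6, 2)),
        )
        crs = [solve_dea(inst, DEAModelConfig(), u) for u in inst.units]
        vrs = [solve_dea(inst, DEAModelConfig(returns_to_scale="variable"), u)
               for u in inst.units]
        assert max(crs) >= 1 - 1e-6  # someone defines the frontier
        assert all(v >= c - 1e-7 for v, c in zip(vrs, crs))
        assert all(0 < s <= 1 for s in crs + vrs)

    def test_unit_invariance_of_crs_scores(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(1, 10, size=(5, 2))
        Y = rng.uniform(1, 10, size=(5, 1))
        inst = DEAInstance(list("ABCDE"), X, Y)
        scaled = DEAInstance(list("ABCDE"), X * np.array([100.0, 0.01]), Y)
        for u in inst.units:
            assert solve_dea(inst, DEAModelConfig(), u) == pytest.approx(
                solve_dea(scaled, DEAModelConfig(), u), abs=1e-6)

    def test_dominance_monotonicity(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(1, 10, size=(5, 2))
        Y = rng.uniform(1, 10, size=(5, 2))
        inst = DEAInstance(list("ABCDE"), X, Y)
        before = [solve_dea(inst, DEAModelConfig(), u) for u in inst.units]
        # dominating newcomer: fewer inputs, more outputs than unit A
        X2 = np.vstack([X, X[0] * 0.8])
        Y2 = np.vstack([Y, Y[0] * 1.2])
        inst2 = DEAInstance(list("ABCDE") + ["F"], X2, Y2)
        after = [solve_dea(inst2, DEAModelConfig(), u) for u in inst.units]
        assert all(a <= b + 1e-7 for a, b in zip(after, before))


def small_mc_setup(families="uniform"):
    units = ["A", "B", "C", "D"]
    variables = ["in1", "in2", "out1"]
    rng = np.random.default_rng(42)
    entries = {}
    for u in units:
        for v in variables:
            c = rng.uniform(2, 10)
            if families == "point":
                entries[(u, v)] = Distribution("point-mass", (c,))
            else:
                entries[(u, v)] = Distribution("uniform", (0.9 * c, 1.1 * c))
    spec = StochasticSpec(entries)
    annotations = {
        "in1": IOAnnotation("in1", "input"),
        "in2": IOAnnotation("in2", "input", "non-standard"),
        "out1": IOAnnotation("out1", "output"),
    }
    scenario = Scenario("S1", ["in1", "in2"], ["out1"])
    return spec, annotations, scenario, units


class TestMonteCarlo:
    def test_point_mass_two_blocks_zero_variance(self):
        spec, ann, scenario, units = small_mc_setup("point")
        pool = run_monte_carlo(spec, ann, DEAModelConfig(), scenario, units,
                               seed=1, convergence=ConvergenceSettings(20, 0.005, 200))
        assert pool.converged
        assert pool.n_runs == 40  # exactly two blocks
        assert np.allclose(pool.summary()["sd"], 0.0)

    def test_seeded_reproducibility_bit_exact(self):
        spec, ann, scenario, units = small_mc_setup()
        kwargs = dict(convergence=ConvergenceSettings(25, 0.01, 500))
        a = run_monte_carlo(spec, ann, DEAModelConfig(), scenario, units, 7, **kwargs)
        b = run_monte_carlo(spec, ann, DEAModelConfig(), scenario, units, 7, **kwargs)
        assert np.array_equal(a.scores, b.scores)

    def test_scores_in_unit_interval_and_frontier(self):
        spec, ann, scenario, units = small_mc_setup()
        pool = run_monte_carlo(spec, ann, DEAModelConfig(), scenario, units,
                               seed=3, convergence=ConvergenceSettings(25, 0.01, 500))
        assert ((pool.scores > 0) & (pool.scores <= 1)).all()
        # every run has a frontier unit
        assert (pool.scores.max(axis=1) >= 1 - 1e-6).all()

    def test_missing_annotation_rejected(self):
        spec, ann, scenario, units = small_mc_setup()
        del ann["out1"]
        with pytest.raises(ValueError, match="annotation"):
            run_monte_carlo(spec, ann, DEAModelConfig(), scenario, units, 1)


class TestTiers:
    def pool_with(self, scores):
        from ebca.dea import EfficiencyPool
        arr = np.array(scores, dtype=float).T
        return EfficiencyPool(units=list(range(arr.shape[1])), scores=arr,
                              seed=0, converged=True,
                              block_means=arr.mean(axis=0, keepdims=True),
                              epsilon=0.01)

    def test_all_ones_efficient(self):
        pool = self.pool_with([[1.0] * 10])
        tiers = classify_tiers(pool)
        assert tiers.tiers[0] == "efficient"
        assert tiers.binary[0] == "efficient-group"

    def test_low_mean_inefficient(self):
        pool = self.pool_with([[0.6] * 10])
        tiers = classify_tiers(pool)
        assert tiers.tiers[0] == "inefficient"
        assert tiers.binary[0] == "inefficient-group"

    def test_nearly_efficient_collapses_to_efficient_group(self):
        scores = [0.92] * 9 + [1.0]  # mean 0.928, fraction-efficient 0.1
        pool = self.pool_with([scores])
        tiers = classify_tiers(pool)
        assert tiers.tiers[0] == "nearly-efficient"
        assert tiers.binary[0] == "efficient-group"

    def test_uncertain_tier(self):
        pool = self.pool_with([[0.8] * 10])
        assert classify_tiers(pool).tiers[0] == "uncertain"

    def test_binary_collapse_invariant(self):
        rng = np.random.default_rng(0)
        pool = self.pool_with(rng.uniform(0.5, 1.0, size=(6, 50)).tolist())
        tiers = classify_tiers(pool)
        for u, t in tiers.tiers.items():
            expected = "efficient-group" if t in ("efficient", "nearly-efficient") \
                else "inefficient-group"
            assert tiers.binary[u] == expected

    def test_empty_pool_rejected(self):
        from ebca.dea import EfficiencyPool
        pool = EfficiencyPool([], np.empty((0, 0)), 0, False,
                              np.empty((0, 0)), 0.01)
        with pytest.raises(ValueError):
            classify_tiers(pool)


class TestScenarios:
    def test_expert_list_verbatim(self):
        combos = [(["a"], ["y"]), (["a", "b"], ["y"]), (["b"], ["y", "z"])] * 2 \
            + [(["a"], ["z"])]
        scenarios = enumerate_scenarios(["a", "b"], ["y", "z"], mode="expert",
                                        expert_list=combos)
        assert len(scenarios) == 7
        assert all(s.provenance == "expert" for s in scenarios)
        assert scenarios[0].inputs == ["a"] and scenarios[0].outputs == ["y"]

    def test_exhaustive_count_2x2(self):
        scenarios = enumerate_scenarios(["a", "b"], ["y", "z"], mode="automatic")
        assert len(scenarios) == 9  # (2^2-1)^2

    def test_correlated_outputs_never_together(self):
        import pandas as pd
        corr = pd.DataFrame([{"var_a": "y", "var_b": "z", "pearson": 1.0,
                              "redundant": True}])
        scenarios = enumerate_scenarios(["a"], ["y", "z"], mode="automatic",
                                        correlations=corr, threshold=0.9)
        assert all(not ({"y", "z"} <= set(s.outputs)) for s in scenarios)

    def test_pruning_keeps_singletons(self):
        import pandas as pd
        corr = pd.DataFrame([{"var_a": "a", "var_b": "b", "pearson": 0.99,
                              "redundant": True},
                             {"var_a": "y", "var_b": "z", "pearson": 0.99,
                              "redundant": True}])
        scenarios = enumerate_scenarios(["a", "b"], ["y", "z"], mode="automatic",
                                        correlations=corr)
        # singleton subsets survive, pairs are pruned
        assert len(scenarios) == 4
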