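from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import sigflow as sf
from sigflow.evaluate import accuracy


def cascade_bundle(signs, readouts, actual_rows, conditions):
    net = sf.make_cascade(len(signs) + 1, signs=signs)
    panel = sf.ConditionPanel(tuple(conditions))
    dac = sf.DACPanel(
        pd.DataFrame(actual_rows, index=[c.label for c in conditions], columns=readouts)
    )
    return sf.DatasetBundle(network=net, panel=panel, actual=dac)


class TestPredictCondition:
    def test_all_positive_cascade_up_regulates_downstream(self):
        cond = sf.Condition({"A"}, (), "stim")
        bundle = cascade_bundle([1, 1], ["B", "C"], [[1.0, 1.0]], [cond])
        # control is "same stimuli, no perturbation" == the condition itself,
        # so compare against an explicit unstimulated control instead
        panel = sf.ConditionPanel((cond,), control=sf.Condition(label="ctl"))
        bundle = sf.DatasetBundle(bundle.network, panel, bundle.actual)
        dac, _ = sf.predict_condition(bundle, cond)
        assert dac.values.tolist() == [1, 1]

    def test_inhibitory_last_link_flips_terminal_dac(self):
        cond = sf.Condition({"A"}, (), "stim")
        panel = sf.ConditionPanel((cond,), control=sf.Condition(label="ctl"))
        net = sf.make_cascade(3, signs=[1, -1])
        dacp = sf.DACPanel(pd.DataFrame([[1.0, -1.0]], index=["stim"], columns=["B", "C"]))
        bundle = sf.DatasetBundle(net, panel, dacp)
        dac, _ = sf.predict_condition(bundle, cond)
        assert dac.values.tolist() == [1, -1]

    def test_unreachable_readout_predicted_zero(self):
        # perturb the sink: nothing flows back to the upstream readout
        cond = sf.Condition({"A"}, {"C"}, "p_C")
        net = sf.make_cascade(3)
        panel = sf.ConditionPanel((cond,))
        dacp = sf.DACPanel(pd.DataFrame([[0.0]], index=["p_C"], columns=["B"]))
        bundle = sf.DatasetBundle(net, panel, dacp)
        dac, _ = sf.predict_condition(bundle, cond)
        assert dac.values.tolist() == [0]


class TestAccuracy:
    def test_perfect_match(self):
        acc, n = accuracy(np.array([1, -1, 1]), np.array([1, -1, 1]))
        assert acc == 1.0 and n == 3

    def test_half_match(self):
        acc, _ = accuracy(np.array([1, 1]), np.array([1, -1]))
        assert acc == 0.5

    def test_negation_scores_zero(self):
        acc, _ = accuracy(np.array([1, -1]), np.array([-1, 1]))
        assert acc == 0.0

    def test_real_valued_actuals_signed_before_scoring(self):
        acc, _ = accuracy(np.array([1, -1]), np.array([2.7, -0.3]))
        assert acc == 1.0

    def test_zero_policy_exclude_drops_no_change_readouts(self):
        acc, n = accuracy(np.array([1, 1, -1]), np.array([1.0, 0.0, -1.0]))
        assert acc == 1.0 and n == 2

    def test_zero_policy_strict_requires_zero_match(self):
        acc, n = accuracy(
            np.array([1, 0, -1]), np.array([1.0, 0.0, -1.0]), zero_policy="strict"
        )
        assert acc == 1.0 and n == 3
        acc, _ = accuracy(
            np.array([1, 1, -1]), np.array([1.0, 0.0, -1.0]), zero_policy="strict"
        )
        assert acc == pytest.approx(2 / 3)

    def test_empty_readout_set_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))


class TestEvaluateDataset:
    def test_perfect_predictions_report(self):
        bundles = sf.make_benchmark_dataset(
            sf.GeneratorSpec(seed=31, n_sub_datasets=1),
            weight_spread=0.0,
            noise_scale=0.0,
        )
        report = sf.evaluate_dataset(bundles)
        assert report.median == 1.0
        assert set(report.matrix.stack().dropna().unique()) == {1.0}

    def test_duplicated_bundles_identical_accuracies(self):
        bundles = sf.make_benchmark_dataset(
            sf.GeneratorSpec(seed=32, n_sub_datasets=1), weight_spread=0.8
        )
        twice = [bundles[0], bundles[0]]
        report = sf.evaluate_dataset(twice)
        by_cond = report.per_condition.groupby("condition")["accuracy"].nunique()
        assert (by_cond == 1).all()

    def test_replicate_count(self):
        bundles = sf.make_benchmark_dataset(
            sf.GeneratorSpec(seed=33, n_sub_datasets=3, n_conditions=20,
                             n_perturbation_targets=8)
        )
        report = sf.evaluate_dataset(bundles)
        # one accuracy per (sub-dataset, scorable condition)
        assert len(report.per_condition) <= 3 * 20
        assert len(report.per_condition) > 0
        assert report.per_condition["n_evaluated"].le(len(bundles[0].readouts)).all()


class TestClusterAccuracy:
    def test_identical_rows_merge_at_zero_distance(self):
        mat = pd.DataFrame(
            [[0.1, 0.9, 0.5], [0.1, 0.9, 0.5], [0.9, 0.1, 0.2]],
            index=["r1", "r2", "r3"],
        )
        res = sf.cluster_accuracy(mat)
        assert res.row_cophenetic.loc["r1", "r2"] == 0.0

    def test_manhattan_distance_of_opposite_rows(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]], index=["a", "b"])
        res = sf.cluster_accuracy(mat)
        assert res.row_cophenetic.loc["a", "b"] == pytest.approx(3.0)

    def test_two_tight_pairs_recovered(self):
        """The dendrogram's first merges match the brute-force best 2+2
        partition of four rows."""
        rows = {
            "a1": [0.0, 0.0, 0.1],
            "a2": [0.05, 0.0, 0.1],
            "b1": [1.0, 1.0, 0.9],
            "b2": [1.0, 0.95, 0.9],
        }
        mat = pd.DataFrame.from_dict(rows, orient="index")

        def manhattan(u, v):
            return sum(abs(x - y) for x, y in zip(rows[u], rows[v]))

        labels = list(rows)
        best = min(
            (
                (frozenset(pair), frozenset(set(labels) - set(pair)))
                for pair in combinations(labels, 2)
            ),
            key=lambda p: sum(manhattan(*sorted(g)) for g in p),
        )
        res = sf.cluster_accuracy(mat)
        coph = res.row_cophenetic
        for group in best:
            u, v = sorted(group)
            others = set(labels) - group
            assert all(
                coph.loc[u, v] < coph.loc[u, o] for o in others
            )

    def test_single_row_trivial(self):
        mat = pd.DataFrame([[0.5, 0.5]], index=["only"])
        res = sf.cluster_accuracy(mat)
        assert res.row_order == ("only",)
        assert res.row_cophenetic is None


class TestTopologyCorrelation:
    def _coph(self, readouts, values):
        df = pd.DataFrame(values, index=readouts, columns=readouts, dtype=float)
        return df

    def test_proportional_distances_give_r_one(self):
        net = sf.make_cascade(4)
        nodes = list(net.nodes)
        path = {(u, v): abs(nodes.index(u) - nodes.index(v)) for u in nodes for v in nodes}
        vals = [[2.0 * path[(u, v)] for v in nodes] for u in nodes]
        r = sf.topology_dendrogram_correlation(net, self._coph(nodes, vals))
        assert r == pytest.approx(1.0)

    def test_anti_proportional_distances_give_r_minus_one(self):
        net = sf.make_cascade(4)
        nodes = list(net.nodes)
        path = {(u, v): abs(nodes.index(u) - nodes.index(v)) for u in nodes for v in nodes}
        vals = [[10.0 - path[(u, v)] for v in nodes] for u in nodes]
        r = sf.topology_dendrogram_correlation(net, self._coph(nodes, vals))
        assert r == pytest.approx(-1.0)

    def test_independent_distances_give_small_r(self):
        net = sf.make_random_network(15, n_links=40, seed=50)
        nodes = list(net.nodes)
        rng = np.random.default_rng(50)
        sym = rng.random((15, 15))
        sym = sym + sym.T
        np.fill_diagonal(sym, 0.0)
        r = sf.topology_dendrogram_correlation(net, self._coph(nodes, sym))
        assert abs(r) < 0.3

    def test_too_few_pairs_rejected(self):
        net = sf.make_cascade(2)
        with pytest.raises(ValueError):
            sf.topology_dendrogram_correlation(
                net, self._coph(["A", "B"], [[0.0, 1.0], [1.0, 0.0]])
            )


class TestRunBenchmark:
    def test_tidy_output_and_determinism(self):
        spec = sf.GeneratorSpec(
            seed=0, n_sub_datasets=1, n_conditions=10, n_perturbation_targets=5
        )
        a = sf.run_benchmark(spec, n_replicates=2, arms=("true", "random"), seed=9)
        b = sf.run_benchmark(spec, n_replicates=2, arms=("true", "random"), seed=9)
        assert a.equals(b)
        assert set(a["arm"]) == {"true", "random"}
        assert len(a) == 4

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            sf.run_benchmark(sf.GeneratorSpec(seed=0), n_replicates=1, arms=("bogus",))
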