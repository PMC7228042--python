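"""Parameter fitting, scoring, greedy search and bootstrap arc strength."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from endorisk.bn import CategoricalVariable, NetworkError, NetworkStructure, forward_sample
from endorisk.learning import (
    ArcConstraintSet,
    ArcStrengthTable,
    bootstrap_arc_strengths,
    fit_cpts,
    hill_climb,
    score_network,
    tabu_search,
    threshold_arcs,
)

from conftest import make_bn, random_binary_bn

BIN2 = [CategoricalVariable(n, ("0", "1")) for n in "AB"]
BIN3 = [CategoricalVariable(n, ("0", "1")) for n in "ABC"]


def all_dags(names):
    """Every DAG over the given nodes (exhaustive oracle for tiny searches)."""
    pairs = [(a, b) for a in names for b in names if a != b]
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        arcs = {p for p, m in zip(pairs, mask) if m}
        try:
            yield NetworkStructure(
                [CategoricalVariable(n, ("0", "1")) for n in names], arcs
            )
        except NetworkError:
            continue


class TestFitCpts:
    def test_empirical_frequencies(self):
        data = pd.DataFrame(
            {"A": ["1"] * 10 + ["0"] * 2, "B": ["0"] * 3 + ["1"] * 7 + ["0", "1"]}
        )
        structure = NetworkStructure(BIN2, {("A", "B")})
        bn = fit_cpts(structure, data, ess=0.0)
        np.testing.assert_allclose(bn.cpts["B"].table[1], [0.3, 0.7])

    def test_unseen_configuration_smoothing(self):
        data = pd.DataFrame({"A": ["1"] * 4, "B": ["0", "0", "1", "1"]})
        structure = NetworkStructure(BIN2, {("A", "B")})
        bn = fit_cpts(structure, data, ess=1.0)
        np.testing.assert_allclose(bn.cpts["B"].table[0], [0.5, 0.5])  # A=0 never seen

    def test_unseen_configuration_without_smoothing_raises(self):
        data = pd.DataFrame({"A": ["1"] * 4, "B": ["0", "0", "1", "1"]})
        structure = NetworkStructure(BIN2, {("A", "B")})
        with pytest.raises(NetworkError, match="ess"):
            fit_cpts(structure, data, ess=0.0)

    def test_parent_axis_order_matches_declaration(self):
        # C | A, B with asymmetric dependence distinguishes the parent axes
        bn_true = make_bn(
            {"A": "01", "B": "01", "C": "01"},
            {("A", "C"), ("B", "C")},
            {
                "A": [0.5, 0.5],
                "B": [0.5, 0.5],
                "C": [[[0.9, 0.1], [0.8, 0.2]], [[0.3, 0.7], [0.1, 0.9]]],
            },
        )
        data = forward_sample(bn_true, 30_000, seed=4)
        fitted = fit_cpts(bn_true.structure, data, ess=1.0)
        np.testing.assert_allclose(
            fitted.cpts["C"].table, bn_true.cpts["C"].table, atol=0.03
        )

    def test_parameter_recovery_on_well_visited_rows(self):
        truth = random_binary_bn(np.random.default_rng(5), n_nodes=4, edge_prob=0.5)
        n = 10_000
        data = forward_sample(truth, n, seed=6)
        fitted = fit_cpts(truth.structure, data, ess=1.0)
        counts = data.value_counts()
        for name in truth.structure.names:
            cpt = truth.cpts[name]
            fit = fitted.cpts[name]
            for cfg in np.ndindex(*cpt.table.shape[:-1]):
                visits = sum(
                    c
                    for combo, c in counts.items()
                    if all(
                        combo[truth.structure.names.index(p)] == str(i)
                        for p, i in zip(cpt.parents, cfg)
                    )
                )
                if visits >= 100:
                    tv = 0.5 * np.abs(fit.table[cfg] - cpt.table[cfg]).sum()
                    assert tv < 0.05, (name, cfg, visits)


class TestScoreNetwork:
    def test_balanced_coins_closed_form(self):
        # perfectly balanced data: empirical entropy equals log 2 per coin
        rows = list(itertools.product("01", repeat=3)) * 10
        data = pd.DataFrame(rows, columns=["A", "B", "C"]).astype(str)
        structure = NetworkStructure(BIN3)
        n = len(data)
        assert score_network(structure, data, "loglik") == pytest.approx(
            -n * 3 * math.log(2)
        )

    def test_adding_arc_never_decreases_loglik(self):
        truth = random_binary_bn(np.random.default_rng(8), n_nodes=3, names="ABC")
        data = forward_sample(truth, 400, seed=9)
        empty = NetworkStructure(BIN3)
        one_arc = NetworkStructure(BIN3, {("A", "B")})
        assert score_network(one_arc, data, "loglik") >= score_network(
            empty, data, "loglik"
        ) - 1e-9

    def test_nodewise_decomposition(self):
        truth = random_binary_bn(np.random.default_rng(10), n_nodes=3, names="ABC")
        data = forward_sample(truth, 300, seed=11)
        full = NetworkStructure(BIN3, {("A", "B"), ("A", "C"), ("B", "C")})
        empty = NetworkStructure(BIN3)
        base = score_network(empty, data, "bic")
        # per-node contribution: only that node's incoming arcs present
        total = base
        for node, parents in (("B", {("A", "B")}), ("C", {("A", "C"), ("B", "C")})):
            only = NetworkStructure(BIN3, parents)
            total += score_network(only, data, "bic") - base
        assert total == pytest.approx(score_network(full, data, "bic"), abs=1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(NetworkError, match="empty"):
            score_network(NetworkStructure(BIN2), pd.DataFrame({"A": [], "B": []}), "bic")


class TestHillClimb:
    def test_strong_dependence_recovers_the_edge(self):
        truth = make_bn(
            {"A": "01", "B": "01"},
            {("A", "B")},
            {"A": [0.5, 0.5], "B": [[0.95, 0.05], [0.05, 0.95]]},
        )
        data = forward_sample(truth, 5_000, seed=12)
        learned = hill_climb(data, BIN2)
        assert learned.arcs in ({("A", "B")}, {("B", "A")}) or learned.arcs == {("A", "B")}
        assert len(learned.arcs) == 1
        # exhaustive oracle: learned graph is the BIC argmax over all 2-node DAGs
        best = max(all_dags("AB"), key=lambda s: score_network(s, data, "bic"))
        assert score_network(learned, data, "bic") == pytest.approx(
            score_network(best, data, "bic")
        )

    def test_independent_triple_yields_empty_graph(self):
        truth = make_bn(
            {"A": "01", "B": "01", "C": "01"},
            set(),
            {"A": [0.5, 0.5], "B": [0.4, 0.6], "C": [0.7, 0.3]},
        )
        data = forward_sample(truth, 5_000, seed=13)
        learned = hill_climb(data, BIN3)
        assert learned.arcs == set()
        best = max(all_dags("ABC"), key=lambda s: score_network(s, data, "bic"))
        assert best.arcs == set()

    def test_whitelist_forced_regardless_of_data(self):
        truth = make_bn(
            {"A": "01", "B": "01"}, set(), {"A": [0.5, 0.5], "B": [0.5, 0.5]}
        )
        data = forward_sample(truth, 1_000, seed=14)
        constraints = ArcConstraintSet(whitelist=frozenset({("A", "B")}))
        learned = hill_climb(data, BIN2, constraints)
        assert ("A", "B") in learned.arcs

    def test_blacklist_respected(self):
        truth = make_bn(
            {"A": "01", "B": "01"},
            {("A", "B")},
            {"A": [0.5, 0.5], "B": [[0.95, 0.05], [0.05, 0.95]]},
        )
        data = forward_sample(truth, 5_000, seed=15)
        constraints = ArcConstraintSet(
            blacklist=frozenset({("A", "B"), ("B", "A")})
        )
        learned = hill_climb(data, BIN2, constraints)
        assert learned.arcs == set()

    def test_conflicting_constraints_rejected(self):
        with pytest.raises(NetworkError, match="whitelisted and blacklisted"):
            ArcConstraintSet(
                whitelist=frozenset({("A", "B")}), blacklist=frozenset({("A", "B")})
            )


class TestTabuSearch:
    def test_zero_tabu_length_reduces_to_hill_climb(self):
        truth = random_binary_bn(np.random.default_rng(16), n_nodes=3, names="ABC")
        data = forward_sample(truth, 800, seed=17)
        hc = hill_climb(data, BIN3)
        tb = tabu_search(data, BIN3, tabu_len=0)
        assert score_network(tb, data, "bic") == pytest.approx(
            score_network(hc, data, "bic")
        )

    def test_score_at_least_hill_climb(self):
        truth = random_binary_bn(np.random.default_rng(18), n_nodes=4, edge_prob=0.6)
        data = forward_sample(truth, 600, seed=19)
        variables = truth.structure.variables
        hc = score_network(hill_climb(data, variables), data, "bic")
        tb = score_network(tabu_search(data, variables), data, "bic")
        assert tb >= hc - 1e-9

    def test_finds_global_optimum_on_most_replicates(self):
        """Exhaustive 3-node oracle: tabu hits the global BIC optimum >= 95/100."""
        hits = 0
        for rep in range(100):
            truth = random_binary_bn(np.random.default_rng(300 + rep), n_nodes=3, edge_prob=0.5, names="ABC")
            data = forward_sample(truth, 400, seed=600 + rep)
            learned = tabu_search(data, BIN3)
            got = score_network(learned, data, "bic")
            best = max(score_network(s, data, "bic") for s in all_dags("ABC"))
            if got >= best - 1e-9:
                hits += 1
        assert hits >= 95

    def test_constraints_respected(self):
        truth = random_binary_bn(np.random.default_rng(20), n_nodes=3, names="ABC")
        data = forward_sample(truth, 500, seed=21)
        constraints = ArcConstraintSet(
            whitelist=frozenset({("A", "C")}), blacklist=frozenset({("B", "C")})
        )
        learned = tabu_search(data, BIN3, constraints)
        assert ("A", "C") in learned.arcs and ("B", "C") not in learned.arcs


class TestBootstrapArcStrengths:
    def test_deterministic_relationship_always_detected(self):
        rng = np.random.default_rng(22)
        a = rng.integers(0, 2, size=400).astype(str)
        data = pd.DataFrame({"A": a, "B": a})
        table = bootstrap_arc_strengths(data, BIN2, n_bootstrap=10, seed=23)
        assert table.strength("A", "B") == 1.0

    def test_independent_variables_have_weak_arcs(self):
        truth = make_bn(
            {"A": "01", "B": "01", "C": "01"},
            set(),
            {"A": [0.5, 0.5], "B": [0.5, 0.5], "C": [0.5, 0.5]},
        )
        data = forward_sample(truth, 5_000, seed=24)
        table = bootstrap_arc_strengths(data, BIN3, n_bootstrap=50, seed=25)
        for a, b in itertools.combinations("ABC", 2):
            assert table.strength(a, b) < 0.3

    def test_strengths_bounded_and_seed_reproducible(self):
        truth = random_binary_bn(np.random.default_rng(26), n_nodes=3, names="ABC")
        data = forward_sample(truth, 300, seed=27)
        t1 = bootstrap_arc_strengths(data, BIN3, n_bootstrap=20, seed=28)
        t2 = bootstrap_arc_strengths(data, BIN3, n_bootstrap=20, seed=28)
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())
        assert ((t1.to_frame()["strength"] >= 0) & (t1.to_frame()["strength"] <= 1)).all()


def _table_from_inclusion(names, inclusion, B=100):
    """Build an ArcStrengthTable by replaying synthetic bootstrap structures."""
    table = ArcStrengthTable(names, B)
    for i in range(B):
        table.record([arc for arc, upto in inclusion.items() if i < upto])
    return table


class TestThresholdArcs:
    def test_strictly_above_rule(self):
        table = _table_from_inclusion(
            ["A", "B", "C"], {("A", "B"): 90, ("B", "C"): 71, ("C", "A"): 69}
        )
        assert threshold_arcs(table, 0.7) == {("A", "B"), ("B", "C")}

    def test_empty_table(self):
        table = ArcStrengthTable(["A", "B"], 10)
        assert threshold_arcs(table, 0.7) == set()

    def test_threshold_one_keeps_unanimous_arcs(self):
        table = _table_from_inclusion(["A", "B", "C"], {("A", "B"): 100, ("B", "C"): 99})
        assert threshold_arcs(table, 1.0) == {("A", "B")}

    def test_cycle_broken_at_weakest_arc(self):
        table = _table_from_inclusion(
            ["A", "B", "C"],
            {("A", "B"): 95, ("B", "C"): 90, ("C", "A"): 80},
        )
        arcs = threshold_arcs(table, 0.7)
        assert arcs == {("A", "B"), ("B", "C")}  # C->A was the weakest on the cycle

    def test_direction_chosen_by_majority(self):
        table = ArcStrengthTable(["A", "B"], 10)
        for i in range(10):
            table.record([("A", "B") if i < 7 else ("B", "A")])
        assert threshold_arcs(table, 0.5) == {("A", "B")}

    def test_invalid_threshold_rejected(self):
        table = ArcStrengthTable(["A", "B"], 10)
        with pytest.raises(NetworkError):
            threshold_arcs(table, 1.5)
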