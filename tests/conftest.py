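"""Shared fixtures and independent brute-force oracles.

The oracles here enumerate full assignments and read CPT entries directly,
deliberately bypassing the package's inference/likelihood code paths so they
remain independent checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from endorisk.bn import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    NetworkStructure,
)


def make_bn(level_spec, arcs, tables) -> BayesianNetwork:
    """Build a network from {name: levels}, arc pairs, and {name: table}."""
    variables = [CategoricalVariable(n, tuple(ls)) for n, ls in level_spec.items()]
    structure = NetworkStructure(variables, arcs)
    cpts = {
        name: ConditionalProbabilityTable(
            name, tuple(structure.parents(name)), np.asarray(tables[name], float)
        )
        for name in structure.names
    }
    return BayesianNetwork(structure, cpts)


def random_binary_bn(
    rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.4, names=None
):
    """A random DAG over binary nodes with Dirichlet CPT rows."""
    names = list(names) if names is not None else [f"v{i}" for i in range(n_nodes)]
    arcs = set()
    for j in range(n_nodes):
        for i in range(j):
            if rng.random() < edge_prob:
                arcs.add((names[i], names[j]))
    variables = [CategoricalVariable(n, ("0", "1")) for n in names]
    structure = NetworkStructure(variables, arcs)
    cpts = {}
    for name in names:
        parents = tuple(structure.parents(name))
        shape = (2,) * len(parents) + (2,)
        rows = rng.dirichlet([1.0, 1.0], size=int(np.prod(shape[:-1]) or 1))
        cpts[name] = ConditionalProbabilityTable(name, parents, rows.reshape(shape))
    return BayesianNetwork(structure, cpts)


def brute_force_joint(bn: BayesianNetwork, assignment: dict[str, str]) -> float:
    """Chain-rule product computed by direct CPT lookups (no package calls)."""
    prob = 1.0
    for name in bn.structure.names:
        cpt = bn.cpts[name]
        var = bn.structure.variable(name)
        ci = var.levels.index(assignment[name])
        pi = tuple(
            bn.structure.variable(p).levels.index(assignment[p]) for p in cpt.parents
        )
        prob *= float(cpt.table[pi + (ci,)])
    return prob


def all_assignments(bn: BayesianNetwork):
    names = bn.structure.names
    level_sets = [bn.structure.variable(n).levels for n in names]
    for combo in itertools.product(*level_sets):
        yield dict(zip(names, combo))


def brute_force_marginals(
    bn: BayesianNetwork, evidence: dict[str, str]
) -> dict[str, np.ndarray]:
    """Exact posteriors by exhaustive enumeration over all full assignments."""
    names = bn.structure.names
    accum = {
        n: np.zeros(bn.structure.variable(n).cardinality) for n in names
    }
    z = 0.0
    for assignment in all_assignments(bn):
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        p = brute_force_joint(bn, assignment)
        z += p
        for n in names:
            accum[n][bn.structure.variable(n).levels.index(assignment[n])] += p
    if z == 0.0:
        raise ZeroDivisionError("evidence impossible under the model")
    return {n: v / z for n, v in accum.items()}


@pytest.fixture
def two_node_bn() -> BayesianNetwork:
    """A -> B with P(A=1)=0.3, P(B=1|A=1)=0.5, P(B=1|A=0)=0.2."""
    return make_bn(
        {"A": ("0", "1"), "B": ("0", "1")},
        {("A", "B")},
        {"A": [0.7, 0.3], "B": [[0.8, 0.2], [0.5, 0.5]]},
    )


@pytest.fixture
def chain3_bn() -> BayesianNetwork:
    """A -> B -> C, asymmetric CPTs."""
    return make_bn(
        {"A": ("0", "1"), "B": ("0", "1"), "C": ("0", "1")},
        {("A", "B"), ("B", "C")},
        {
            "A": [0.6, 0.4],
            "B": [[0.9, 0.1], [0.3, 0.7]],
            "C": [[0.75, 0.25], [0.2, 0.8]],
        },
    )
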