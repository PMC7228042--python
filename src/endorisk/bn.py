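"""Discrete Bayesian networks: variables, structure, CPTs, sampling and likelihood.

A network is a directed acyclic graph over categorical variables, with one
conditional probability table (CPT) per node.  The joint distribution
factorizes by the chain rule: P(x) = prod_v P(x_v | x_parents(v)).

Conventions used throughout the package:

* level order is the declaration order of the variable and is canonical;
  CPT probability vectors are stored in that order;
* cohorts are pandas DataFrames of level labels (strings), with missing
  cells encoded as the :data:`MISSING` sentinel (pandas ``NA`` on IO
  boundaries is translated to it);
* CPT rows must sum to 1 within ``ROW_SUM_ATOL``; rows off by at most
  ``ROW_SUM_RENORM_ATOL`` are renormalized on load, anything worse is
  rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# -- module-wide numeric policy ------------------------------------------------

#: CPT rows must sum to one within this tolerance once loaded.
ROW_SUM_ATOL = 1e-9
#: rows off by at most this much are renormalized by readers; worse is an error.
ROW_SUM_RENORM_ATOL = 1e-6
#: internal sentinel for a missing cell, distinct from any admissible level.
MISSING = "\0missing"
#: explicit sentinel returned by log_likelihood when a row has probability 0.
NEG_INF = float("-inf")


class NetworkError(ValueError):
    """Raised on structurally invalid networks or inconsistent inputs."""


# -- domain types --------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalVariable:
    """A named categorical variable with an ordered, fixed set of levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if len(self.levels) < 2:
            raise NetworkError(f"variable {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise NetworkError(f"variable {self.name!r} has duplicate levels")

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def index_of(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise NetworkError(
                f"{level!r} is not a level of {self.name!r} (levels: {self.levels})"
            ) from None


class NetworkStructure:
    """A DAG over declared categorical variables.

    Arcs are ordered (parent, child) pairs.  Variable declaration order is
    preserved and used for deterministic tie-breaking everywhere.
    """

    def __init__(
        self,
        variables: Sequence[CategoricalVariable],
        arcs: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.variables: list[CategoricalVariable] = list(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate variable names")
        self._by_name = {v.name: v for v in self.variables}
        self.arcs: set[tuple[str, str]] = set()
        for parent, child in arcs:
            self.add_arc(parent, child, _check_cycle=False)
        cycle_arc = self._find_cycle_arc()
        if cycle_arc is not None:
            raise NetworkError(f"arc set contains a cycle through {cycle_arc}")

    # - introspection -

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> CategoricalVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise NetworkError(f"unknown variable {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def parents(self, name: str) -> list[str]:
        self.variable(name)
        order = {n: i for i, n in enumerate(self.names)}
        return sorted((p for p, c in self.arcs if c == name), key=order.__getitem__)

    def children(self, name: str) -> list[str]:
        self.variable(name)
        order = {n: i for i, n in enumerate(self.names)}
        return sorted((c for p, c in self.arcs if p == name), key=order.__getitem__)

    # - mutation -

    def add_arc(self, parent: str, child: str, _check_cycle: bool = True) -> None:
        if parent not in self._by_name or child not in self._by_name:
            raise NetworkError(f"arc ({parent!r}, {child!r}) references undeclared variable")
        if parent == child:
            raise NetworkError(f"self-loop on {parent!r}")
        if (parent, child) in self.arcs:
            raise NetworkError(f"duplicate arc ({parent!r}, {child!r})")
        self.arcs.add((parent, child))
        if _check_cycle and self._find_cycle_arc() is not None:
            self.arcs.discard((parent, child))
            raise NetworkError(f"adding ({parent!r}, {child!r}) creates a cycle")

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(self.variables, set(self.arcs))

    # - graph algorithms -

    def _find_cycle_arc(self) -> tuple[str, str] | None:
        """Return one arc lying on a directed cycle, or None if acyclic."""
        color: dict[str, int] = {n: 0 for n in self.names}  # 0 white 1 gray 2 black
        succ: dict[str, list[str]] = {n: [] for n in self.names}
        for p, c in sorted(self.arcs):
            succ[p].append(c)
        result: list[tuple[str, str]] = []

        def visit(u: str) -> bool:
            color[u] = 1
            for v in succ[u]:
                if color[v] == 1:
                    result.append((u, v))
                    return True
                if color[v] == 0 and visit(v):
                    return True
            color[u] = 2
            return False

        for n in self.names:
            if color[n] == 0 and visit(n):
                return result[0]
        return None

    def is_acyclic(self) -> bool:
        return self._find_cycle_arc() is None


def topological_order(structure: NetworkStructure) -> list[str]:
    """Kahn topological sort; ties broken by variable declaration order."""
    cycle_arc = structure._find_cycle_arc()
    if cycle_arc is not None:
        raise NetworkError(f"structure is cyclic (arc {cycle_arc} lies on a cycle)")
    indeg = {n: 0 for n in structure.names}
    for _, c in structure.arcs:
        indeg[c] += 1
    order: list[str] = []
    ready = [n for n in structure.names if indeg[n] == 0]
    while ready:
        n = ready.pop(0)  # declaration order preserved: ready is scanned FIFO
        order.append(n)
        newly = []
        for c in structure.children(n):
            indeg[c] -= 1
            if indeg[c] == 0:
                newly.append(c)
        decl = {m: i for i, m in enumerate(structure.names)}
        ready = sorted(ready + newly, key=decl.__getitem__)
    return order


@dataclass
class ConditionalProbabilityTable:
    """P(child | parents) as an ndarray of shape (*parent_cards, child_card).

    Parent axes follow the declared ``parents`` order; the last axis runs over
    the child's levels in declaration order.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)

    def row(self, parent_levels_idx: tuple[int, ...]) -> np.ndarray:
        return self.table[parent_levels_idx]

    def violations(self, structure: NetworkStructure) -> list[str]:
        out: list[str] = []
        var = structure.variable(self.child)
        expected_shape = tuple(
            structure.variable(p).cardinality for p in self.parents
        ) + (var.cardinality,)
        if self.table.shape != expected_shape:
            out.append(
                f"CPT of {self.child!r}: table shape {self.table.shape} != "
                f"expected {expected_shape}"
            )
            return out
        if np.any(self.table < 0):
            out.append(f"CPT of {self.child!r}: negative probability entries")
        sums = self.table.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_ATOL)
        for idx in bad:
            cfg = {
                p: structure.variable(p).levels[i]
                for p, i in zip(self.parents, idx)
            }
            out.append(
                f"CPT of {self.child!r}: row {cfg} sums to {sums[tuple(idx)]:.10g}"
            )
        return out


class BayesianNetwork:
    """A structure plus one CPT per variable: the full generative model."""

    def __init__(
        self,
        structure: NetworkStructure,
        cpts: Mapping[str, ConditionalProbabilityTable],
        arc_metadata: Mapping[tuple[str, str], dict] | None = None,
    ) -> None:
        self.structure = structure
        self.cpts: dict[str, ConditionalProbabilityTable] = dict(cpts)
        #: optional per-arc annotations (bootstrap strength, provenance, ...)
        self.arc_metadata: dict[tuple[str, str], dict] = dict(arc_metadata or {})

    @property
    def variables(self) -> list[CategoricalVariable]:
        return self.structure.variables

    def variable(self, name: str) -> CategoricalVariable:
        return self.structure.variable(name)


def validate_network(bn: BayesianNetwork) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    out: list[str] = []
    structure = bn.structure
    names = set(structure.names)
    for p, c in sorted(structure.arcs):
        if p not in names or c not in names:
            out.append(f"arc ({p!r}, {c!r}) references an undeclared variable")
        if p == c:
            out.append(f"self-loop on {p!r}")
    cycle_arc = structure._find_cycle_arc()
    if cycle_arc is not None:
        out.append(f"cycle detected through arc {cycle_arc}")
    for name in structure.names:
        cpt = bn.cpts.get(name)
        if cpt is None:
            out.append(f"no CPT for variable {name!r}")
            continue
        declared_parents = tuple(structure.parents(name))
        if tuple(sorted(cpt.parents)) != tuple(sorted(declared_parents)):
            out.append(
                f"CPT of {name!r} conditions on {cpt.parents}, structure "
                f"declares parents {declared_parents}"
            )
            continue
        out.extend(cpt.violations(structure))
    for name in bn.cpts:
        if name not in names:
            out.append(f"CPT for undeclared variable {name!r}")
    return out


# -- encoding helpers ----------------------------------------------------------


def encode_table(data: pd.DataFrame, structure: NetworkStructure) -> np.ndarray:
    """Encode a cohort as an int matrix; missing -> -1.

    Columns are taken in structure declaration order; undeclared levels raise.
    """
    n = len(data)
    k = len(structure.names)
    codes = np.full((n, k), -1, dtype=np.int64)
    for j, name in enumerate(structure.names):
        if name not in data.columns:
            raise NetworkError(f"cohort lacks column {name!r}")
        var = structure.variable(name)
        col = data[name].astype(object)
        mapping = {lvl: i for i, lvl in enumerate(var.levels)}
        for i, val in enumerate(col):
            if val is None or (isinstance(val, float) and math.isnan(val)) or val is pd.NA:
                continue
            if val == MISSING or val == "":
                continue
            try:
                codes[i, j] = mapping[str(val)]
            except KeyError:
                raise NetworkError(
                    f"row {i}, column {name!r}: undeclared level {val!r}"
                ) from None
    return codes


def decode_table(codes: np.ndarray, structure: NetworkStructure) -> pd.DataFrame:
    """Inverse of :func:`encode_table`; -1 becomes the MISSING sentinel."""
    cols = {}
    for j, name in enumerate(structure.names):
        levels = structure.variable(name).levels
        cols[name] = [MISSING if c < 0 else levels[c] for c in codes[:, j]]
    return pd.DataFrame(cols, columns=structure.names)


# -- probability computations --------------------------------------------------


def joint_probability(bn: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """Chain-rule joint probability of a full assignment."""
    structure = bn.structure
    for name in structure.names:
        if name not in assignment:
            raise NetworkError(f"assignment misses variable {name!r}")
    prob = 1.0
    for name in structure.names:
        var = structure.variable(name)
        cpt = bn.cpts[name]
        child_idx = var.index_of(assignment[name])
        parent_idx = tuple(
            structure.variable(p).index_of(assignment[p]) for p in cpt.parents
        )
        prob *= float(cpt.table[parent_idx + (child_idx,)])
        if prob == 0.0:
            return 0.0
    return prob


def log_likelihood(bn: BayesianNetwork, data: pd.DataFrame) -> float:
    """Sum of log joint probabilities over rows; -inf if any row is impossible.

    Requires complete data: missing cells are a usage error (impute first).
    """
    codes = encode_table(data, bn.structure)
    if (codes < 0).any():
        rows = np.unique(np.argwhere(codes < 0)[:, 0])
        raise NetworkError(
            f"data has missing cells (rows {rows[:5].tolist()}...); impute before "
            "computing the log-likelihood"
        )
    return float(log_likelihood_codes(bn, codes))


def log_likelihood_codes(bn: BayesianNetwork, codes: np.ndarray) -> float:
    """Vectorized log-likelihood on an encoded (complete) cohort matrix."""
    structure = bn.structure
    col = {n: j for j, n in enumerate(structure.names)}
    total = 0.0
    for name in structure.names:
        cpt = bn.cpts[name]
        idx = tuple(codes[:, col[p]] for p in cpt.parents) + (codes[:, col[name]],)
        probs = cpt.table[idx]
        if np.any(probs <= 0.0):
            return NEG_INF
        total += float(np.log(probs).sum())
    return total


def forward_sample(bn: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling of ``n`` complete rows; deterministic per seed."""
    if n < 0:
        raise NetworkError("n must be >= 0")
    structure = bn.structure
    rng = np.random.default_rng(seed)
    order = topological_order(structure)
    col = {name: j for j, name in enumerate(structure.names)}
    codes = np.empty((n, len(structure.names)), dtype=np.int64)
    for name in order:
        cpt = bn.cpts[name]
        card = structure.variable(name).cardinality
        u = rng.random(n)
        if not cpt.parents:
            cdf = np.cumsum(cpt.table)
            codes[:, col[name]] = np.searchsorted(cdf, u, side="right").clip(0, card - 1)
        else:
            parent_codes = tuple(codes[:, col[p]] for p in cpt.parents)
            rows = cpt.table[parent_codes]  # (n, card)
            cdf = np.cumsum(rows, axis=1)
            codes[:, col[name]] = (u[:, None] >= cdf).sum(axis=1).clip(0, card - 1)
    return decode_table(codes, structure)


def enumerate_assignments(structure: NetworkStructure):
    """Yield every full assignment dict (test/oracle utility; exponential)."""
    names = structure.names
    cards = [structure.variable(n).cardinality for n in names]
    for flat in np.ndindex(*cards):
        yield {
            n: structure.variable(n).levels[i] for n, i in zip(names, flat)
        }
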