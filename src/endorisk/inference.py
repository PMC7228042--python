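"""Exact inference by variable elimination.

Posterior marginals P(target | evidence) are computed exactly by reducing
every CPT factor on the evidence, eliminating the remaining non-query
variables in min-fill order, and normalizing.  The normalization constant of
the final factor is P(evidence); if it is zero the evidence is impossible
and an error is raised rather than returning a zero vector — silent zeros
would be dangerous in a clinical tool.

Factor arithmetic is done in linear space with a renormalization guard per
elimination step (the running normalizer is accumulated so posteriors stay
exact); at the ~14-node scale of the networks handled here log-space is not
needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bn import BayesianNetwork, NetworkError, NetworkStructure

__all__ = [
    "Factor",
    "elimination_order",
    "posterior_marginals",
    "prior_marginals",
    "evidence_probability",
    "joint_posterior_factor",
]


class ImpossibleEvidenceError(NetworkError):
    """The supplied evidence has probability zero under the model."""


@dataclass
class Factor:
    """A nonnegative table over a tuple of variables (axes in ``names`` order)."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.names):
            raise ValueError("factor rank does not match its scope")


def _multiply(a: Factor, b: Factor) -> Factor:
    names = list(a.names) + [n for n in b.names if n not in a.names]
    a_shape = a.values.shape + (1,) * (len(names) - len(a.names))
    av = a.values.reshape(a_shape)
    # transpose b into the union's axis order, then broadcast
    b_axes = [names.index(n) for n in b.names]
    perm = np.argsort(b_axes)
    bv = np.transpose(b.values, axes=perm).reshape(
        [b.values.shape[b.names.index(names[ax])] if ax in b_axes else 1
         for ax in range(len(names))]
    )
    return Factor(tuple(names), av * bv)


def _sum_out(f: Factor, name: str) -> Factor:
    if name not in f.names:
        return f
    ax = f.names.index(name)
    return Factor(
        tuple(n for n in f.names if n != name), f.values.sum(axis=ax)
    )


def _reduce(f: Factor, name: str, idx: int) -> Factor:
    if name not in f.names:
        return f
    ax = f.names.index(name)
    return Factor(
        tuple(n for n in f.names if n != name),
        np.take(f.values, idx, axis=ax),
    )


def _cpt_factor(bn: BayesianNetwork, name: str) -> Factor:
    cpt = bn.cpts[name]
    return Factor(cpt.parents + (name,), cpt.table)


def _check_evidence(structure: NetworkStructure, evidence: Mapping[str, str]) -> dict[str, int]:
    ev_idx: dict[str, int] = {}
    for name, level in evidence.items():
        var = structure.variable(name)  # raises on unknown variable
        ev_idx[name] = var.index_of(level)  # raises on unknown level
    return ev_idx


def elimination_order(
    structure: NetworkStructure,
    evidence_vars: Iterable[str] = (),
    targets: Iterable[str] = (),
) -> list[str]:
    """Min-fill heuristic order over variables not in targets or evidence.

    Deterministic: ties are broken by declaration order.
    """
    keep = set(evidence_vars) | set(targets)
    decl = {n: i for i, n in enumerate(structure.names)}
    # moral graph restricted to surviving scopes
    neighbors: dict[str, set[str]] = {n: set() for n in structure.names}
    scopes = []
    for name in structure.names:
        scope = set(structure.parents(name)) | {name}
        scopes.append(scope)
    for scope in scopes:
        for a in scope:
            for b in scope:
                if a != b:
                    neighbors[a].add(b)
    to_eliminate = [n for n in structure.names if n not in keep]
    order: list[str] = []
    remaining = set(to_eliminate)
    while remaining:
        best = None
        best_fill = None
        for n in sorted(remaining, key=decl.__getitem__):
            nbrs = [m for m in neighbors[n] if m != n]
            fill = 0
            for i, a in enumerate(nbrs):
                for b in nbrs[i + 1:]:
                    if b not in neighbors[a]:
                        fill += 1
            if best_fill is None or fill < best_fill:
                best, best_fill = n, fill
        assert best is not None
        order.append(best)
        nbrs = list(neighbors[best])
        for a in nbrs:
            for b in nbrs:
                if a != b:
                    neighbors[a].add(b)
            neighbors[a].discard(best)
        neighbors.pop(best)
        remaining.discard(best)
    return order


def _run_elimination(
    bn: BayesianNetwork,
    ev_idx: Mapping[str, int],
    keep: Sequence[str],
    order: Sequence[str] | None = None,
) -> tuple[Factor, float]:
    """Eliminate everything outside ``keep``; return (joint factor, log-normalizer).

    The returned factor is over ``keep`` variables (in an arbitrary axis
    order) and, multiplied by exp(log_norm), equals P(keep, evidence).
    """
    structure = bn.structure
    factors = []
    for name in structure.names:
        f = _cpt_factor(bn, name)
        for ev_name, idx in ev_idx.items():
            f = _reduce(f, ev_name, idx)
        factors.append(f)
    if order is None:
        order = elimination_order(structure, ev_idx.keys(), keep)
    log_norm = 0.0
    for name in order:
        involved = [f for f in factors if name in f.names]
        factors = [f for f in factors if name not in f.names]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        summed = _sum_out(prod, name)
        total = float(summed.values.sum())
        if total > 0:
            # renormalization guard: keep magnitudes near 1, track the scale
            summed = Factor(summed.names, summed.values / total)
            log_norm += np.log(total)
        factors.append(summed)
    result = Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    return result, log_norm


def evidence_probability(bn: BayesianNetwork, evidence: Mapping[str, str]) -> float:
    """Exact P(evidence) via elimination of every other variable."""
    ev_idx = _check_evidence(bn.structure, evidence)
    factor, log_norm = _run_elimination(bn, ev_idx, keep=())
    total = float(factor.values.sum())
    if total <= 0.0:
        return 0.0
    return float(np.exp(np.log(total) + log_norm))


def posterior_marginals(
    bn: BayesianNetwork,
    evidence: Mapping[str, str],
    targets: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Exact P(target | evidence) for each target variable.

    Evidence variables among the targets are returned as point masses.
    Raises :class:`ImpossibleEvidenceError` when P(evidence) = 0.
    """
    structure = bn.structure
    ev_idx = _check_evidence(structure, evidence)
    if targets is None:
        target_list = list(structure.names)
    else:
        target_list = [n for n in structure.names if n in set(targets)]
        unknown = set(targets) - set(structure.names)
        if unknown:
            raise NetworkError(f"unknown target variables {sorted(unknown)}")
    out: dict[str, np.ndarray] = {}
    for name in target_list:
        var = structure.variable(name)
        if name in ev_idx:
            vec = np.zeros(var.cardinality)
            vec[ev_idx[name]] = 1.0
            out[name] = vec
            continue
        factor, _ = _run_elimination(bn, ev_idx, keep=(name,))
        # remaining scope may include only `name`
        f = factor
        for other in f.names:
            if other != name:
                f = _sum_out(f, other)
        vec = f.values if f.names == (name,) else np.asarray(f.values).reshape(-1)
        total = float(vec.sum())
        if total <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {dict(evidence)!r} has probability zero"
            )
        out[name] = vec / total
    return out


def prior_marginals(bn: BayesianNetwork) -> dict[str, np.ndarray]:
    """Marginals with no evidence (the no-findings state of the network)."""
    return posterior_marginals(bn, {}, None)


def joint_posterior_factor(
    bn: BayesianNetwork,
    evidence: Mapping[str, str],
    targets: Sequence[str],
    max_cells: int = 1 << 22,
) -> Factor:
    """Exact joint posterior P(targets | evidence) as a normalized factor.

    Used by the imputation module to draw coherent per-record samples.
    The factor's axes follow declaration order of the target variables.
    """
    structure = bn.structure
    ev_idx = _check_evidence(structure, evidence)
    target_list = [n for n in structure.names if n in set(targets)]
    cells = 1
    for n in target_list:
        cells *= structure.variable(n).cardinality
    if cells > max_cells:
        raise NetworkError(
            f"joint posterior over {len(target_list)} variables has {cells} cells"
        )
    factor, _ = _run_elimination(bn, ev_idx, keep=target_list)
    # order axes canonically
    perm = [factor.names.index(n) for n in target_list]
    values = np.transpose(factor.values, axes=perm) if factor.names else factor.values
    total = float(values.sum())
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(evidence)!r} has probability zero"
        )
    return Factor(tuple(target_list), values / total)
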