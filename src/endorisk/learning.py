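"""Parameter fitting and score-based structure learning.

Structure search is greedy over single-arc moves (add / delete / reverse)
scored by a decomposable criterion — BIC by default, raw log-likelihood
optionally.  Expert knowledge enters through an :class:`ArcConstraintSet`
(whitelisted arcs are always present, blacklisted arcs never).  Robustness
of arcs is assessed by nonparametric bootstrap: structures are re-learned on
row resamples and each edge's selection frequency ("arc strength") is
recorded, with a separate direction-agreement fraction; edges above a
strength threshold (0.7 by default) form the consensus structure.

Scores are cached per (child, parent set) family, so the search only ever
rescoreds the one or two families a move touches.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    NetworkError,
    NetworkStructure,
    encode_table,
)

__all__ = [
    "ArcConstraintSet",
    "ArcStrengthTable",
    "fit_cpts",
    "score_network",
    "hill_climb",
    "tabu_search",
    "bootstrap_arc_strengths",
    "threshold_arcs",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ArcConstraintSet:
    """Expert constraints: forced (whitelist) and forbidden (blacklist) arcs."""

    whitelist: frozenset[tuple[str, str]] = frozenset()
    blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "whitelist", frozenset(tuple(a) for a in self.whitelist))
        object.__setattr__(self, "blacklist", frozenset(tuple(a) for a in self.blacklist))
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise NetworkError(f"arcs both whitelisted and blacklisted: {sorted(overlap)}")

    def check_acyclic(self, variables: Sequence[CategoricalVariable]) -> None:
        NetworkStructure(variables, self.whitelist)  # raises if cyclic


EMPTY_CONSTRAINTS = ArcConstraintSet()


# -- decomposable scores --------------------------------------------------------


class _ScoreCache:
    """Per-family local scores on an encoded complete data matrix."""

    def __init__(self, codes: np.ndarray, cards: Sequence[int], score_type: str):
        if score_type not in ("bic", "loglik"):
            raise NetworkError(f"unknown score type {score_type!r}")
        if codes.shape[0] == 0:
            raise NetworkError("cannot score a network on empty data")
        if (codes < 0).any():
            raise NetworkError("data has missing cells; impute before scoring")
        self.codes = codes
        self.cards = list(cards)
        self.n = codes.shape[0]
        self.score_type = score_type
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_counts(self, child: int, parents: tuple[int, ...]) -> np.ndarray:
        """Count matrix of shape (#parent configs, child cardinality)."""
        r = self.cards[child]
        if not parents:
            return np.bincount(self.codes[:, child], minlength=r)[None, :]
        q = 1
        key = np.zeros(self.n, dtype=np.int64)
        for p in parents:
            key = key * self.cards[p] + self.codes[:, p]
            q *= self.cards[p]
        flat = key * r + self.codes[:, child]
        return np.bincount(flat, minlength=q * r).reshape(q, r)

    def local(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts = self.family_counts(child, key[1])
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0, counts * np.log(counts / row_tot), 0.0)
        score = float(ll.sum())
        if self.score_type == "bic":
            r = self.cards[child]
            q = counts.shape[0]
            score -= 0.5 * math.log(self.n) * (r - 1) * q
        self._cache[key] = score
        return score


def fit_cpts(
    structure: NetworkStructure,
    data: pd.DataFrame,
    ess: float = 1.0,
) -> BayesianNetwork:
    """Fit all CPTs by (smoothed) relative frequencies.

    Each row of a CPT is ``(count + ess/r) / (row_total + ess)`` where ``r``
    is the child's cardinality — a symmetric-Dirichlet posterior mean with
    equivalent sample size ``ess``.  With ``ess=0`` the raw maximum-likelihood
    frequencies are used, and any parent configuration never observed is an
    error (its distribution would be undefined).
    """
    if ess < 0:
        raise NetworkError("ess must be >= 0")
    codes = encode_table(data, structure)
    if (codes < 0).any():
        raise NetworkError("data has missing cells; impute before fitting CPTs")
    return fit_cpts_codes(structure, codes, ess)


def fit_cpts_codes(
    structure: NetworkStructure, codes: np.ndarray, ess: float = 1.0
) -> BayesianNetwork:
    """:func:`fit_cpts` on an already-encoded complete matrix."""
    names = structure.names
    cards = [structure.variable(n).cardinality for n in names]
    cache = _ScoreCache(codes, cards, "loglik")
    col = {n: j for j, n in enumerate(names)}
    cpts = {}
    for name in names:
        parents = tuple(structure.parents(name))
        pidx = tuple(col[p] for p in parents)
        counts = cache.family_counts(col[name], pidx)
        # family_counts sorts parent axes by column index; rearrange to the
        # declared parent order before reshaping
        sorted_parents = tuple(sorted(pidx))
        shape = tuple(cards[p] for p in sorted_parents) + (cards[col[name]],)
        table = counts.reshape(shape)
        if parents:
            perm = [sorted_parents.index(col[p]) for p in parents] + [len(parents)]
            table = np.transpose(table, axes=perm)
        r = cards[col[name]]
        row_tot = table.sum(axis=-1, keepdims=True)
        if ess == 0.0:
            if np.any(row_tot == 0):
                raise NetworkError(
                    f"unseen parent configuration for {name!r} with ess=0; "
                    "use ess > 0 for smoothing"
                )
            probs = table / row_tot
        else:
            probs = (table + ess / r) / (row_tot + ess)
        cpts[name] = ConditionalProbabilityTable(name, parents, probs)
    return BayesianNetwork(structure.copy(), cpts)


def score_network(
    structure: NetworkStructure, data: pd.DataFrame, score_type: str = "bic"
) -> float:
    """Decomposable network score: sum of per-family local scores.

    ``loglik`` is the maximized log-likelihood; ``bic`` penalizes it by
    (free parameters) * log(n) / 2.
    """
    codes = encode_table(data, structure)
    cards = [structure.variable(n).cardinality for n in structure.names]
    cache = _ScoreCache(codes, cards, score_type)
    col = {n: j for j, n in enumerate(structure.names)}
    return sum(
        cache.local(col[name], tuple(col[p] for p in structure.parents(name)))
        for name in structure.names
    )


# -- greedy search --------------------------------------------------------------


def _reachable(parents_of: dict[int, set[int]], src: int, dst: int, k: int) -> bool:
    """True if dst is reachable from src following child->... edges.

    ``parents_of`` maps child -> parent set, so we walk the reverse relation.
    """
    children_of: dict[int, list[int]] = {i: [] for i in range(k)}
    for c, ps in parents_of.items():
        for p in ps:
            children_of[p].append(c)
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for v in children_of[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


class _Searcher:
    """Shared move machinery for hill-climbing and tabu search on encoded data."""

    def __init__(
        self,
        codes: np.ndarray,
        variables: Sequence[CategoricalVariable],
        constraints: ArcConstraintSet,
        score_type: str,
    ):
        self.variables = list(variables)
        self.names = [v.name for v in self.variables]
        self.k = len(self.names)
        self.idx = {n: i for i, n in enumerate(self.names)}
        cards = [v.cardinality for v in self.variables]
        self.cache = _ScoreCache(codes, cards, score_type)
        constraints.check_acyclic(self.variables)
        for p, c in constraints.whitelist | constraints.blacklist:
            if p not in self.idx or c not in self.idx:
                raise NetworkError(f"constraint arc ({p!r}, {c!r}) references unknown variable")
        self.white = {(self.idx[p], self.idx[c]) for p, c in constraints.whitelist}
        self.black = {(self.idx[p], self.idx[c]) for p, c in constraints.blacklist}
        # start from the whitelist-only graph
        self.parents: dict[int, set[int]] = {i: set() for i in range(self.k)}
        for p, c in sorted(self.white):
            self.parents[c].add(p)

    # - state -

    def local(self, child: int) -> float:
        return self.cache.local(child, tuple(sorted(self.parents[child])))

    def total_score(self) -> float:
        return sum(self.local(c) for c in range(self.k))

    def arcs(self) -> set[tuple[int, int]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    def structure(self) -> NetworkStructure:
        return NetworkStructure(
            self.variables,
            {(self.names[p], self.names[c]) for p, c in self.arcs()},
        )

    # - moves: ("add"|"del"|"rev", parent, child) -

    def candidate_moves(self):
        """All legal moves in canonical order (op, then arc lexicographic)."""
        arcs = self.arcs()
        for u in range(self.k):
            for v in range(self.k):
                if u == v:
                    continue
                if (u, v) not in arcs and (u, v) not in self.black:
                    if (v, u) not in arcs and not _reachable(self.parents, v, u, self.k):
                        yield ("add", u, v)
        for u, v in sorted(arcs):
            if (u, v) not in self.white:
                yield ("del", u, v)
        for u, v in sorted(arcs):
            if (u, v) in self.white or (v, u) in self.black:
                continue
            self.parents[v].discard(u)
            ok = not _reachable(self.parents, u, v, self.k)
            self.parents[v].add(u)
            if ok:
                yield ("rev", u, v)

    def move_delta(self, move) -> float:
        op, u, v = move
        if op == "add":
            before = self.local(v)
            after = self.cache.local(v, tuple(sorted(self.parents[v] | {u})))
            return after - before
        if op == "del":
            before = self.local(v)
            after = self.cache.local(v, tuple(sorted(self.parents[v] - {u})))
            return after - before
        d = 0.0
        d += self.cache.local(v, tuple(sorted(self.parents[v] - {u}))) - self.local(v)
        d += self.cache.local(u, tuple(sorted(self.parents[u] | {v}))) - self.local(u)
        return d

    def apply(self, move) -> None:
        op, u, v = move
        if op == "add":
            self.parents[v].add(u)
        elif op == "del":
            self.parents[v].discard(u)
        else:
            self.parents[v].discard(u)
            self.parents[u].add(v)

    @staticmethod
    def inverse(move):
        op, u, v = move
        if op == "add":
            return ("del", u, v)
        if op == "del":
            return ("add", u, v)
        return ("rev", v, u)


def _prepare(data, variables):
    if variables is None:
        raise NetworkError("structure learning needs the declared variables")
    structure = NetworkStructure(variables)
    codes = encode_table(data, structure)
    return codes


def hill_climb(
    data: pd.DataFrame,
    variables: Sequence[CategoricalVariable],
    constraints: ArcConstraintSet = EMPTY_CONSTRAINTS,
    score_type: str = "bic",
    max_iter: int | None = None,
    seed: int = 0,
) -> NetworkStructure:
    """Greedy single-arc search to a local score optimum.

    Starts from the whitelist-only graph and repeatedly applies the best
    strictly-improving add/delete/reverse move; deterministic (ties broken by
    canonical move order; the seed is accepted for interface symmetry but the
    procedure involves no randomness).
    """
    del seed
    codes = _prepare(data, variables)
    return _hill_climb_codes(codes, variables, constraints, score_type, max_iter)


def _hill_climb_codes(codes, variables, constraints, score_type="bic", max_iter=None):
    s = _Searcher(codes, variables, constraints, score_type)
    if max_iter is None:
        max_iter = 100 * s.k
    for _ in range(max_iter):
        best_move, best_delta = None, _EPS
        for move in s.candidate_moves():
            delta = s.move_delta(move)
            if delta > best_delta:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        s.apply(best_move)
    return s.structure()


def tabu_search(
    data: pd.DataFrame,
    variables: Sequence[CategoricalVariable],
    constraints: ArcConstraintSet = EMPTY_CONSTRAINTS,
    score_type: str = "bic",
    tabu_len: int = 10,
    max_iter: int | None = None,
    seed: int = 0,
    stall_limit: int = 15,
) -> NetworkStructure:
    """Tabu search: best admissible neighbor each step, short move memory.

    Non-improving moves are allowed (that is the point of tabu search), the
    inverses of recent moves are forbidden unless they beat the best score
    seen (aspiration), and the best structure visited is returned.  With
    ``tabu_len=0`` the search cannot escape a local optimum, so it returns
    the hill-climbing solution.
    """
    del seed
    codes = _prepare(data, variables)
    return _tabu_codes(
        codes, variables, constraints, score_type, tabu_len, max_iter, stall_limit
    )


def _tabu_codes(
    codes,
    variables,
    constraints,
    score_type="bic",
    tabu_len=10,
    max_iter=None,
    stall_limit=15,
):
    s = _Searcher(codes, variables, constraints, score_type)
    if max_iter is None:
        max_iter = 100 * s.k
    tabu: deque = deque(maxlen=tabu_len) if tabu_len > 0 else deque(maxlen=1)
    use_tabu = tabu_len > 0
    best_arcs = s.arcs()
    best_score = s.total_score()
    current = best_score
    stall = 0
    for _ in range(max_iter):
        best_move, best_delta = None, None
        for move in s.candidate_moves():
            delta = s.move_delta(move)
            if use_tabu and move in tabu and current + delta <= best_score + _EPS:
                continue  # tabu, and aspiration not met
            if best_delta is None or delta > best_delta + _EPS:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        s.apply(best_move)
        current += best_delta
        if use_tabu:
            tabu.append(s.inverse(best_move))
        if current > best_score + _EPS:
            best_score = current
            best_arcs = s.arcs()
            stall = 0
        else:
            stall += 1
            if stall >= stall_limit:
                break
    names = s.names
    return NetworkStructure(
        s.variables, {(names[p], names[c]) for p, c in best_arcs}
    )


# -- bootstrap arc strength ------------------------------------------------------


class ArcStrengthTable:
    """Bootstrap edge frequencies.

    ``strength`` of a directed arc is the fraction of bootstrap structures
    containing the edge in either direction (undirected presence — the
    inclusion rule is applied to presence); ``direction_agreement`` is the
    fraction of those structures orienting it as stated.
    """

    def __init__(self, names: Sequence[str], n_bootstrap: int):
        self.names = list(names)
        self.n_bootstrap = n_bootstrap
        self._directed: dict[tuple[str, str], int] = {}

    def record(self, arcs: Iterable[tuple[str, str]]) -> None:
        for arc in arcs:
            self._directed[arc] = self._directed.get(arc, 0) + 1

    def _undirected_count(self, a: str, b: str) -> int:
        return self._directed.get((a, b), 0) + self._directed.get((b, a), 0)

    def strength(self, a: str, b: str) -> float:
        return self._undirected_count(a, b) / self.n_bootstrap

    def direction_agreement(self, parent: str, child: str) -> float:
        und = self._undirected_count(parent, child)
        if und == 0:
            return 0.0
        return self._directed.get((parent, child), 0) / und

    def arcs(self) -> list[tuple[str, str]]:
        """Every directed arc that appeared in at least one bootstrap structure."""
        decl = {n: i for i, n in enumerate(self.names)}
        return sorted(self._directed, key=lambda a: (decl[a[0]], decl[a[1]]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from": p,
                "to": c,
                "strength": self.strength(p, c),
                "direction_agreement": self.direction_agreement(p, c),
            }
            for p, c in self.arcs()
        ]
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction_agreement"])

    def to_dict(self) -> dict:
        return {
            "n_bootstrap": self.n_bootstrap,
            "arcs": self.to_frame().to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, payload: Mapping, names: Sequence[str]) -> "ArcStrengthTable":
        table = cls(names, int(payload["n_bootstrap"]))
        for row in payload["arcs"]:
            und = round(row["strength"] * table.n_bootstrap)
            fwd = round(row["direction_agreement"] * und)
            if (row["to"], row["from"]) not in table._directed:
                table._directed[(row["from"], row["to"])] = fwd
                table._directed[(row["to"], row["from"])] = und - fwd
        table._directed = {a: c for a, c in table._directed.items() if c > 0}
        return table


def bootstrap_arc_strengths(
    data: pd.DataFrame,
    variables: Sequence[CategoricalVariable],
    constraints: ArcConstraintSet = EMPTY_CONSTRAINTS,
    algorithm: str = "hill_climb",
    n_bootstrap: int = 500,
    seed: int = 0,
    score_type: str = "bic",
    tabu_len: int = 10,
) -> ArcStrengthTable:
    """Learn one structure per row-resample and tally edge frequencies.

    Resamples are nonparametric (size n, with replacement); the seed governs
    resampling only — the searches themselves are deterministic.
    """
    if n_bootstrap < 1:
        raise NetworkError("n_bootstrap must be >= 1")
    if algorithm not in ("hill_climb", "tabu"):
        raise NetworkError(f"unknown algorithm {algorithm!r}")
    structure = NetworkStructure(variables)
    codes = encode_table(data, structure)
    if (codes < 0).any():
        raise NetworkError("data has missing cells; impute or drop before the bootstrap")
    n = codes.shape[0]
    rng = np.random.default_rng(seed)
    table = ArcStrengthTable([v.name for v in variables], n_bootstrap)
    for _ in range(n_bootstrap):
        rows = rng.integers(0, n, size=n)
        resample = codes[rows]
        if algorithm == "hill_climb":
            learned = _hill_climb_codes(resample, variables, constraints, score_type)
        else:
            learned = _tabu_codes(resample, variables, constraints, score_type, tabu_len)
        table.record(learned.arcs)
    return table


def threshold_arcs(
    strengths: ArcStrengthTable,
    threshold: float = 0.7,
    variables: Sequence[CategoricalVariable] | None = None,
) -> set[tuple[str, str]]:
    """Consensus arcs: undirected strength strictly above the threshold.

    Directions are chosen by majority direction agreement (declaration-order
    tie-break).  If the consensus contains a directed cycle, the weakest arc
    on each cycle (lowest strength, then lowest direction agreement) is
    dropped until the set is acyclic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise NetworkError("threshold must lie in [0, 1]")
    decl = {n: i for i, n in enumerate(strengths.names)}
    seen_pairs: set[frozenset[str]] = set()
    chosen: set[tuple[str, str]] = set()
    for p, c in strengths.arcs():
        pair = frozenset((p, c))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        s = strengths.strength(p, c)
        # strictly above the threshold; at threshold 1.0 this means the arcs
        # present in every bootstrap structure
        if (s <= threshold) if threshold < 1.0 else (s < 1.0):
            continue
        fwd = strengths.direction_agreement(p, c)
        if fwd > 0.5:
            chosen.add((p, c))
        elif fwd < 0.5:
            chosen.add((c, p))
        else:  # exact tie: declaration order decides the parent
            chosen.add((p, c) if decl[p] <= decl[c] else (c, p))

    def find_cycle(arcs: set[tuple[str, str]]) -> list[tuple[str, str]] | None:
        succ: dict[str, list[str]] = {}
        for u, v in sorted(arcs):
            succ.setdefault(u, []).append(v)
        color: dict[str, int] = {}
        stack_path: list[tuple[str, str]] = []

        def visit(u: str):
            color[u] = 1
            for v in succ.get(u, []):
                if color.get(v, 0) == 1:
                    i = next(i for i, (a, _) in enumerate(stack_path) if a == v)
                    return stack_path[i:] + [(u, v)]
                if color.get(v, 0) == 0:
                    stack_path.append((u, v))
                    got = visit(v)
                    if got:
                        return got
                    stack_path.pop()
            color[u] = 2
            return None

        for node in sorted(succ):
            if color.get(node, 0) == 0:
                got = visit(node)
                if got:
                    return got
        return None

    while True:
        cycle = find_cycle(chosen)
        if cycle is None:
            break
        weakest = min(
            cycle,
            key=lambda a: (
                strengths.strength(*a),
                strengths.direction_agreement(*a),
                -decl[a[0]],
                -decl[a[1]],
            ),
        )
        chosen.discard(weakest)
    return chosen
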