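"""Network and cohort file formats, plus run manifests.

The native network format is a JSON dialect that carries everything the
in-memory model holds — variables with ordered levels, arcs with optional
metadata (bootstrap strength, provenance), and CPTs as nested lists whose
axes follow the declared parent order.  BIF (Bayesian Interchange Format)
is provided for interchange with the wider BN ecosystem; the reader
tolerates the common dialect variations (quoted or unquoted identifiers,
``table`` or per-row entries).

CPT rows are renormalized on load when they sum to 1 within 1e-6 and
rejected otherwise; silently repairing badly broken files would mask errors.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import (
    MISSING,
    ROW_SUM_ATOL,
    ROW_SUM_RENORM_ATOL,
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    NetworkError,
    NetworkStructure,
    encode_table,
)

__all__ = [
    "read_network",
    "write_network",
    "read_cohort",
    "write_cohort",
    "RunManifest",
]


def _renormalize(table: np.ndarray, child: str) -> np.ndarray:
    sums = table.sum(axis=-1)
    off = np.abs(sums - 1.0)
    if np.any(off > ROW_SUM_RENORM_ATOL):
        idx = tuple(np.argwhere(off > ROW_SUM_RENORM_ATOL)[0])
        raise NetworkError(
            f"CPT of {child!r}: row {idx} sums to {sums[idx]:.10g}, beyond the "
            f"renormalization tolerance {ROW_SUM_RENORM_ATOL}"
        )
    if np.any(off > ROW_SUM_ATOL):
        table = table / sums[..., None]
    return table


# -- JSON dialect ------------------------------------------------------------------


def _network_to_dict(bn: BayesianNetwork) -> dict:
    return {
        "format": "endorisk-network",
        "version": 1,
        "variables": [
            {"name": v.name, "levels": list(v.levels)} for v in bn.structure.variables
        ],
        "arcs": [
            {"from": p, "to": c, **bn.arc_metadata.get((p, c), {})}
            for p, c in sorted(bn.structure.arcs)
        ],
        "cpts": [
            {
                "child": name,
                "parents": list(bn.cpts[name].parents),
                "table": bn.cpts[name].table.tolist(),
            }
            for name in bn.structure.names
        ],
    }


def _network_from_dict(payload: Mapping) -> BayesianNetwork:
    try:
        variables = [
            CategoricalVariable(v["name"], tuple(v["levels"]))
            for v in payload["variables"]
        ]
        arc_entries = payload["arcs"]
        cpt_entries = payload["cpts"]
    except (KeyError, TypeError) as exc:
        raise NetworkError(f"malformed network JSON: missing section {exc}") from None
    names = {v.name for v in variables}
    arcs = set()
    metadata = {}
    for entry in arc_entries:
        p, c = entry["from"], entry["to"]
        if p not in names or c not in names:
            raise NetworkError(f"arc ({p!r}, {c!r}) references an undeclared variable")
        arcs.add((p, c))
        extra = {k: v for k, v in entry.items() if k not in ("from", "to")}
        if extra:
            metadata[(p, c)] = extra
    structure = NetworkStructure(variables, arcs)
    cpts = {}
    for entry in cpt_entries:
        child = entry["child"]
        parents = tuple(entry["parents"])
        if child not in names:
            raise NetworkError(f"CPT for undeclared node {child!r}")
        for p in parents:
            if p not in names:
                raise NetworkError(f"CPT of {child!r}: undeclared parent {p!r}")
        table = _renormalize(np.asarray(entry["table"], dtype=float), child)
        cpts[child] = ConditionalProbabilityTable(child, parents, table)
    return BayesianNetwork(structure, cpts, metadata)


# -- BIF ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r'"[^"]*"|[(){}\[\],;|]|[^\s(){}\[\],;|]+')


def _bif_quote(token: str) -> str:
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_\-]*", token):
        return token
    return f'"{token}"'


def _bif_unquote(token: str) -> str:
    if token.startswith('"') and token.endswith('"'):
        return token[1:-1]
    return token


def _network_to_bif(bn: BayesianNetwork) -> str:
    lines = ["network unnamed {", "}"]
    for v in bn.structure.variables:
        levels = ", ".join(_bif_quote(l) for l in v.levels)
        lines += [
            f"variable {_bif_quote(v.name)} {{",
            f"  type discrete [ {v.cardinality} ] {{ {levels} }};",
            "}",
        ]
    for name in bn.structure.names:
        cpt = bn.cpts[name]
        head = _bif_quote(name)
        if cpt.parents:
            head += " | " + ", ".join(_bif_quote(p) for p in cpt.parents)
        lines.append(f"probability ( {head} ) {{")
        if not cpt.parents:
            vals = ", ".join(f"{x:.12g}" for x in cpt.table)
            lines.append(f"  table {vals};")
        else:
            cards = [bn.variable(p).cardinality for p in cpt.parents]
            for cfg in np.ndindex(*cards):
                labels = ", ".join(
                    _bif_quote(bn.variable(p).levels[i])
                    for p, i in zip(cpt.parents, cfg)
                )
                vals = ", ".join(f"{x:.12g}" for x in cpt.table[cfg])
                lines.append(f"  ( {labels} ) {vals};")
        lines.append("}")
    return "\n".join(lines) + "\n"


class _BifParser:
    def __init__(self, text: str):
        # strip // and # comments
        text = re.sub(r"//[^\n]*", "", text)
        self.tokens = _TOKEN_RE.findall(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise NetworkError("BIF: unexpected end of file")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise NetworkError(
                f"BIF: expected {tok!r}, got {got!r} at token {self.pos - 1}"
            )

    def skip_block(self) -> None:
        self.expect("{")
        depth = 1
        while depth:
            tok = self.next()
            if tok == "{":
                depth += 1
            elif tok == "}":
                depth -= 1

    def collect_until(self, stop: str) -> list[str]:
        out = []
        while True:
            tok = self.next()
            if tok == stop:
                return out
            out.append(tok)


def _network_from_bif(text: str) -> BayesianNetwork:
    p = _BifParser(text)
    variables: list[CategoricalVariable] = []
    raw_cpts: list[tuple[str, tuple[str, ...], dict, list]] = []
    while p.peek() is not None:
        kw = p.next()
        if kw == "network":
            while p.peek() != "{":
                p.next()
            p.skip_block()
        elif kw == "variable":
            name = _bif_unquote(p.next())
            p.expect("{")
            levels: tuple[str, ...] | None = None
            while p.peek() != "}":
                tok = p.next()
                if tok == "type":
                    p.expect("discrete")
                    p.expect("[")
                    p.next()  # cardinality (redundant with the level list)
                    p.expect("]")
                    p.expect("{")
                    toks = p.collect_until("}")
                    levels = tuple(_bif_unquote(t) for t in toks if t != ",")
                    if p.peek() == ";":
                        p.next()
            p.expect("}")
            if levels is None:
                raise NetworkError(f"BIF: variable {name!r} has no discrete type")
            variables.append(CategoricalVariable(name, levels))
        elif kw == "probability":
            p.expect("(")
            head = p.collect_until(")")
            names = [_bif_unquote(t) for t in head if t not in (",", "|")]
            pipe = "|" in head
            child, parents = names[0], tuple(names[1:]) if pipe else ()
            if not pipe and len(names) > 1:
                parents = tuple(names[1:])  # "( A B )" dialect
            rows: dict[tuple[str, ...], list[float]] = {}
            table_row: list[float] | None = None
            p.expect("{")
            while p.peek() != "}":
                tok = p.next()
                if tok == "table":
                    vals = p.collect_until(";")
                    table_row = [float(v) for v in vals if v != ","]
                elif tok == "(":
                    cfg = tuple(
                        _bif_unquote(t) for t in p.collect_until(")") if t != ","
                    )
                    vals = p.collect_until(";")
                    rows[cfg] = [float(v) for v in vals if v != ","]
                elif tok == ";":
                    continue
                else:
                    raise NetworkError(f"BIF: unexpected token {tok!r} in probability block")
            p.expect("}")
            raw_cpts.append((child, parents, rows, table_row))
        else:
            raise NetworkError(f"BIF: unexpected keyword {kw!r} at token {p.pos - 1}")
    by_name = {v.name: v for v in variables}
    arcs = set()
    cpts = {}
    for child, parents, rows, table_row in raw_cpts:
        if child not in by_name:
            raise NetworkError(f"BIF: probability block for undeclared node {child!r}")
        for parent in parents:
            if parent not in by_name:
                raise NetworkError(f"BIF: CPT of {child!r} names undeclared parent {parent!r}")
            arcs.add((parent, child))
        card = by_name[child].cardinality
        if not parents:
            if table_row is None:
                raise NetworkError(f"BIF: root {child!r} lacks a table row")
            table = np.asarray(table_row, dtype=float)
        else:
            cards = [by_name[q].cardinality for q in parents]
            table = np.full(tuple(cards) + (card,), np.nan)
            if table_row is not None:
                table = np.asarray(table_row, dtype=float).reshape(tuple(cards) + (card,))
            for cfg, vals in rows.items():
                idx = tuple(by_name[q].index_of(l) for q, l in zip(parents, cfg))
                table[idx] = vals
            if np.isnan(table).any():
                raise NetworkError(f"BIF: CPT of {child!r} misses parent configurations")
        table = _renormalize(table, child)
        cpts[child] = ConditionalProbabilityTable(child, parents, table)
    structure = NetworkStructure(variables, arcs)
    return BayesianNetwork(structure, cpts)


# -- public network IO --------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".bif":
        return "bif"
    raise NetworkError(f"cannot infer network format from {path.name!r}; pass format=")


def read_network(path: str | Path, format: str | None = None) -> BayesianNetwork:
    """Read a network from JSON (native dialect) or BIF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from None
        return _network_from_dict(payload)
    if fmt == "bif":
        return _network_from_bif(text)
    raise NetworkError(f"unknown network format {fmt!r}")


def write_network(bn: BayesianNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a network as JSON (native) or BIF (interchange)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_network_to_dict(bn), indent=1, sort_keys=True) + "\n")
    elif fmt == "bif":
        path.write_text(_network_to_bif(bn))
    else:
        raise NetworkError(f"unknown network format {fmt!r}")


# -- cohort IO -----------------------------------------------------------------------


def read_cohort(
    path: str | Path,
    schema: Sequence[CategoricalVariable],
    missing_token: str = "",
    sep: str = ",",
) -> pd.DataFrame:
    """Read a cohort CSV/TSV; header order-insensitive, levels validated.

    Missing cells (the missing token, default empty string) become the
    internal sentinel.  Undeclared levels raise with row/column coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    names = [v.name for v in schema]
    absent = [n for n in names if n not in df.columns]
    if absent:
        raise NetworkError(f"{path}: header lacks columns {absent}")
    out = df.copy()
    for name in names:
        out[name] = out[name].map(lambda v: MISSING if v == missing_token else v)
    structure = NetworkStructure(schema)
    encode_table(out[names], structure)  # validates levels with coordinates
    ordered = names + [c for c in df.columns if c not in names]
    return out[ordered]


def write_cohort(
    data: pd.DataFrame,
    path: str | Path,
    missing_token: str = "",
    sep: str = ",",
) -> None:
    """Write a cohort; internal missing sentinels become the missing token."""
    out = data.replace({MISSING: missing_token})
    out.to_csv(path, sep=sep, index=False)


# -- run manifests -------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record emitted alongside every CLI run."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""
    input_digests: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def add_input(self, label: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[label] = {"path": str(path), "sha256": digest}

    def time_stage(self, stage: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings[stage] = round(time.perf_counter() - self.t0, 4)
                return False

        return _Timer()

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "version": self.version,
            "inputs": self.input_digests,
            "timings": self.timings,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
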