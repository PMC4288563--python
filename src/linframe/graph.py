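"""Labelled directed graphs of DNA microstates.

A graph holds vertices (microstates, indexed 1..n with index 1 the
reference microstate by convention) and directed edges carrying rate
labels.  Labels are sympy expressions over positively-valued rate symbols
— a bare symbol like ``k_plus``, or a compound such as
``kmax*P^2/(K^2+P^2)`` for concentration-dependent binding.  Every label
must evaluate to a strictly positive real under any positive assignment
of its symbols; this is checked at build time by evaluation at a
randomised positive environment rather than by symbolic proof.

The Laplacian here is the column-conservative generator: entry (j, i) for
j != i is the label of edge i -> j, and each diagonal entry is minus the
total rate out of that vertex, so columns sum to zero exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import sympy as sp

__all__ = [
    "GraphValidationError",
    "LabelParseError",
    "Vertex",
    "LabelledDigraph",
    "SCCDecomposition",
    "build_graph",
    "parse_label",
    "format_label",
    "laplacian",
    "scc_decomposition",
    "is_strongly_connected",
    "is_reversible",
]


class GraphValidationError(ValueError):
    pass


class LabelParseError(ValueError):
    pass


def parse_label(text) -> sp.Expr:
    """Parse a canonical label string (``^`` means power) to a sympy
    expression with positive symbols."""
    if isinstance(text, sp.Expr):
        return text
    if isinstance(text, (int, float)):
        if text <= 0:
            raise GraphValidationError(f"label must be positive, got {text}")
        return sp.Float(text) if isinstance(text, float) else sp.Integer(text)
    try:
        expr = sp.sympify(str(text).replace("^", "**"))
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise LabelParseError(f"cannot parse label {text!r}: {exc}") from exc
    # rebuild symbols with positivity assumptions for safe simplification
    return expr.xreplace(
        {s: sp.Symbol(s.name, positive=True) for s in expr.free_symbols}
    )


def format_label(expr: sp.Expr) -> str:
    return str(expr).replace("**", "^").replace(" ", "")


@dataclass
class Vertex:
    index: int
    name: str
    attributes: dict = field(default_factory=dict)


class LabelledDigraph:
    """Vertices plus labelled directed edges; no self-loops, at most one
    edge per ordered pair (parallel edges are merged by summing labels),
    and connected when edge directions are ignored."""

    def __init__(self, vertices: Sequence[Vertex], edges: Mapping[tuple[int, int], sp.Expr]):
        self.vertices = list(vertices)
        self.edges = dict(edges)
        self._validate()

    # -- construction helpers -----------------------------------------
    def _validate(self):
        n = len(self.vertices)
        indices = [v.index for v in self.vertices]
        if indices != list(range(1, n + 1)):
            raise GraphValidationError("vertex indices must be contiguous and 1-based")
        names = [v.name for v in self.vertices]
        if len(set(names)) != n:
            raise GraphValidationError("vertex names must be unique")
        for (i, j) in self.edges:
            if i == j:
                raise GraphValidationError(f"self-loop at vertex {i} is not allowed")
            if not (1 <= i <= n and 1 <= j <= n):
                raise GraphValidationError(f"edge ({i},{j}) references an unknown vertex")
        if n > 1:
            und = nx.Graph()
            und.add_nodes_from(range(1, n + 1))
            und.add_edges_from(self.edges)
            comps = list(nx.connected_components(und))
            if len(comps) > 1:
                # name the pieces not containing the reference vertex
                detached = sorted(v for c in comps if 1 not in c for v in c)
                raise GraphValidationError(
                    f"graph is disconnected; isolated vertex set {detached}"
                )
        self._check_label_positivity()

    def _check_label_positivity(self):
        rng = np.random.default_rng(20141205)
        syms = sorted(self.symbols)
        env = {s: float(v) for s, v in zip(syms, rng.uniform(0.1, 10.0, len(syms)))}
        for (i, j), lab in self.edges.items():
            val = _eval_label(lab, env)
            if not val > 0:
                raise GraphValidationError(
                    f"label on edge {i}->{j} is not positive at a positive environment: {format_label(lab)}"
                )

    # -- basic queries --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def symbols(self) -> set[str]:
        out: set[str] = set()
        for lab in self.edges.values():
            out.update(s.name for s in lab.free_symbols)
        return out

    def label(self, i: int, j: int) -> sp.Expr | None:
        return self.edges.get((i, j))

    def out_edges(self, i: int) -> list[tuple[int, sp.Expr]]:
        return [(j, lab) for (s, j), lab in self.edges.items() if s == i]

    def vertex(self, index: int) -> Vertex:
        return self.vertices[index - 1]

    def vertex_by_name(self, name: str) -> Vertex:
        for v in self.vertices:
            if v.name == name:
                return v
        raise KeyError(name)

    def edge_list(self) -> list[tuple[int, int, sp.Expr]]:
        return [(i, j, lab) for (i, j), lab in sorted(self.edges.items())]

    def subgraph(self, indices: Iterable[int]) -> tuple["LabelledDigraph", dict[int, int]]:
        """Induced subgraph on ``indices``; returns the graph (re-indexed
        1..m preserving order) and the old->new index mapping."""
        keep = sorted(set(indices))
        mapping = {old: new for new, old in enumerate(keep, start=1)}
        verts = [
            Vertex(mapping[v.index], v.name, dict(v.attributes))
            for v in self.vertices
            if v.index in mapping
        ]
        edges = {
            (mapping[i], mapping[j]): lab
            for (i, j), lab in self.edges.items()
            if i in mapping and j in mapping
        }
        return LabelledDigraph(verts, edges), mapping

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(v.index for v in self.vertices)
        g.add_edges_from(self.edges)
        return g

    # -- environments ---------------------------------------------------
    def check_env(self, env: Mapping[str, float]):
        missing = self.symbols - set(env)
        if missing:
            raise KeyError(f"environment missing symbols: {sorted(missing)}")
        bad = [s for s in self.symbols if not env[s] > 0]
        if bad:
            raise GraphValidationError(f"environment values must be positive: {bad}")

    def numeric_edges(self, env: Mapping[str, float]) -> dict[tuple[int, int], float]:
        self.check_env(env)
        return {(i, j): _eval_label(lab, env) for (i, j), lab in self.edges.items()}

    # -- serialisation --------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "vertices": [
                {"index": v.index, "name": v.name, "attributes": v.attributes}
                for v in self.vertices
            ],
            "edges": [
                {"from": i, "to": j, "label": format_label(lab)}
                for (i, j), lab in sorted(self.edges.items())
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LabelledDigraph":
        doc = json.loads(text)
        verts = [
            Vertex(v["index"], v.get("name", str(v["index"])), v.get("attributes", {}))
            for v in doc["vertices"]
        ]
        return build_graph(
            verts, [(e["from"], e["to"], e["label"]) for e in doc["edges"]]
        )

    def to_tsv(self) -> str:
        lines = ["from\tto\tlabel"]
        for (i, j), lab in sorted(self.edges.items()):
            lines.append(f"{i}\t{j}\t{format_label(lab)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "LabelledDigraph":
        rows = []
        for lineno, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("from\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LabelParseError(f"line {lineno + 1}: expected 3 columns")
            rows.append((int(parts[0]), int(parts[1]), parts[2]))
        nmax = max(max(i, j) for i, j, _ in rows)
        verts = [Vertex(k, str(k)) for k in range(1, nmax + 1)]
        return build_graph(verts, rows)

    def __repr__(self):
        return f"LabelledDigraph(n={self.n}, edges={len(self.edges)})"


def _eval_label(expr: sp.Expr, env: Mapping[str, float]) -> float:
    subs = {s: env[s.name] for s in expr.free_symbols}
    return float(expr.evalf(subs=subs))


def build_graph(vertices, edges) -> LabelledDigraph:
    """Validated construction.  ``vertices`` may be Vertex objects, bare
    names, or an integer count; ``edges`` are (source, target, label)
    triples with labels as strings, numbers or sympy expressions.
    Parallel edges between the same ordered pair are merged by summing
    their labels, which leaves the Laplacian dynamics unchanged."""
    if isinstance(vertices, int):
        vertices = [Vertex(k, str(k)) for k in range(1, vertices + 1)]
    else:
        vertices = [
            v if isinstance(v, Vertex) else Vertex(k, str(v))
            for k, v in enumerate(vertices, start=1)
        ]
    merged: dict[tuple[int, int], sp.Expr] = {}
    for (i, j, lab) in edges:
        expr = parse_label(lab)
        key = (int(i), int(j))
        merged[key] = merged[key] + expr if key in merged else expr
    return LabelledDigraph(vertices, merged)


# -- Laplacian ----------------------------------------------------------

def laplacian(G: LabelledDigraph, env: Mapping[str, float] | None = None):
    """Column-Laplacian of ``G``: numpy array in numeric mode (``env``
    given), sympy Matrix in symbolic mode.  Columns sum to zero by
    construction."""
    n = G.n
    if env is not None:
        L = np.zeros((n, n))
        for (i, j), rate in G.numeric_edges(env).items():
            L[j - 1, i - 1] += rate
            L[i - 1, i - 1] -= rate
        return L
    L = sp.zeros(n, n)
    for (i, j), lab in G.edges.items():
        L[j - 1, i - 1] += lab
        L[i - 1, i - 1] -= lab
    return L


# -- structural analysis ------------------------------------------------

@dataclass
class SCCDecomposition:
    components: list[frozenset[int]]
    precedence: set[tuple[int, int]]  # (i, j): component i precedes component j
    terminal: list[bool]

    @property
    def terminal_components(self) -> list[frozenset[int]]:
        return [c for c, t in zip(self.components, self.terminal) if t]

    def component_of(self, vertex: int) -> int:
        for k, c in enumerate(self.components):
            if vertex in c:
                return k
        raise KeyError(vertex)


def scc_decomposition(G: LabelledDigraph) -> SCCDecomposition:
    """Strongly connected components with their precedence partial order
    and terminal flags.  Components are sorted by smallest member so the
    result is independent of vertex ordering."""
    g = G.to_networkx()
    comps = sorted((frozenset(c) for c in nx.strongly_connected_components(g)), key=min)
    comp_index = {v: k for k, c in enumerate(comps) for v in c}
    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(comps)))
    for (i, j) in G.edges:
        ci, cj = comp_index[i], comp_index[j]
        if ci != cj:
            cond.add_edge(ci, cj)
    closure = nx.transitive_closure(cond)
    precedence = set(closure.edges())
    terminal = [cond.out_degree(k) == 0 for k in range(len(comps))]
    return SCCDecomposition(comps, precedence, terminal)


def is_strongly_connected(G: LabelledDigraph) -> bool:
    return nx.is_strongly_connected(G.to_networkx())


def is_reversible(G: LabelledDigraph) -> bool:
    """True iff every edge i->j has a companion edge j->i."""
    return all((j, i) in G.edges for (i, j) in G.edges)
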