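"""Exact steady states of Laplacian dynamics.

For a strongly connected graph the Laplacian kernel is one-dimensional
and a canonical basis vector rho is given by the matrix-tree theorem:
rho_j is the sum, over all spanning trees rooted at j (in-trees: every
non-root vertex has exactly one outgoing tree edge and all paths lead to
the root), of the product of the tree's edge labels.  Normalising rho
gives the steady-state probabilities.

For a general graph the kernel has one basis vector per terminal
strongly connected component: the matrix-tree vector of the component's
induced subgraph, padded with zeros elsewhere.  The steady state reached
from an initial condition is the combination of these basis vectors
whose coefficients are the graph's conservation laws evaluated at the
initial condition.

Two computational routes are provided and cross-checked in the test
suite: explicit tree enumeration (exact, symbolic or numeric) and the
determinant route via principal minors of the negated Laplacian (numeric,
no enumeration, usable when the tree count is astronomically large).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .graph import LabelledDigraph, laplacian, scc_decomposition, is_strongly_connected
from .poly import LabelPolynomial

__all__ = [
    "SpanningTree",
    "SteadyState",
    "enumerate_rooted_spanning_trees",
    "count_rooted_spanning_trees",
    "rho_matrix_tree",
    "steady_state_probabilities",
    "kernel_basis",
    "steady_state_from_initial",
]


@dataclass(frozen=True)
class SpanningTree:
    root: int
    edges: frozenset[tuple[int, int]]

    def label_product(self, G: LabelledDigraph) -> LabelPolynomial:
        out = LabelPolynomial.constant(1)
        for (i, j) in self.edges:
            out = out * LabelPolynomial.from_expr(G.edges[(i, j)])
        return out


@dataclass
class SteadyState:
    basis: list  # one rho vector (list/array) per terminal SCC
    probabilities: np.ndarray | None = None
    conservation_values: np.ndarray | None = None
    state: np.ndarray | None = None  # unnormalised x*, total mass = total of x0


# -- spanning-tree enumeration ------------------------------------------

def enumerate_rooted_spanning_trees(G: LabelledDigraph, root: int) -> list[SpanningTree]:
    """Complete, duplicate-free enumeration of the in-trees rooted at
    ``root``.  Backtracking over out-edge choices with reverse-reachability
    pruning; the count is cross-checked against the determinant route in
    the tests.  Empty list iff some vertex cannot reach the root."""
    n = G.n
    if not 1 <= root <= n:
        raise ValueError(f"invalid root index {root}")
    out: dict[int, list[int]] = {v.index: [] for v in G.vertices}
    for (i, j) in G.edges:
        out[i].append(j)
    # vertices that can reach the root (reverse reachability)
    rev: dict[int, list[int]] = {v.index: [] for v in G.vertices}
    for (i, j) in G.edges:
        rev[j].append(i)
    reach = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for u in rev[v]:
            if u not in reach:
                reach.add(u)
                stack.append(u)
    if len(reach) < n:
        return []

    return [
        SpanningTree(root, frozenset(tree.items()))
        for tree in _iter_out_choices(G, root)
    ]


def _iter_out_choices(G: LabelledDigraph, root: int):
    """Yield in-trees rooted at ``root`` as {vertex: successor} maps.
    Backtracking over the out-edge choice of each non-root vertex with a
    cycle walk as the pruning test."""
    out: dict[int, list[int]] = {v.index: [] for v in G.vertices}
    for (i, j) in G.edges:
        out[i].append(j)
    verts = [v.index for v in G.vertices if v.index != root]
    nverts = len(verts)
    choice: dict[int, int] = {}

    def acyclic_through(v: int) -> bool:
        seen = {v}
        w = choice[v]
        while w != root:
            if w not in choice:
                return True
            if w in seen:
                return False
            seen.add(w)
            w = choice[w]
        return True

    def rec(k: int):
        if k == nverts:
            yield dict(choice)
            return
        v = verts[k]
        for t in out[v]:
            choice[v] = t
            if acyclic_through(v):
                yield from rec(k + 1)
            del choice[v]

    yield from rec(0)


def count_rooted_spanning_trees(G: LabelledDigraph, root: int | None = None) -> int:
    """Exact tree count via the determinant of the all-ones Laplacian with
    the root's row and column deleted; ``root=None`` sums over all roots."""
    env = {s: 1.0 for s in G.symbols}
    M = sp.Matrix(G.n, G.n, lambda a, b: 0)
    for (i, j), rate in G.numeric_edges(env).items():
        r = sp.Rational(round(rate)) if abs(rate - round(rate)) < 1e-12 else sp.Rational(rate)
        M[j - 1, i - 1] += r
        M[i - 1, i - 1] -= r
    roots = range(1, G.n + 1) if root is None else [root]
    total = 0
    for r in roots:
        sub = (-M).copy()
        sub.col_del(r - 1)
        sub.row_del(r - 1)
        total += int(sub.det())
    return total


# -- matrix-tree basis vector -------------------------------------------

def rho_matrix_tree(
    G: LabelledDigraph,
    mode: str = "symbolic",
    env: Mapping[str, float] | None = None,
):
    """Matrix-tree kernel basis vector of a strongly connected graph.

    ``mode='symbolic'`` enumerates trees and returns LabelPolynomial
    entries (all labels must be polynomial in the rate symbols); the
    entries are homogeneous of total degree n-1.  ``mode='numeric'``
    computes each entry as the principal minor of the negated numeric
    Laplacian, avoiding enumeration."""
    if not is_strongly_connected(G):
        raise ValueError(
            "graph is not strongly connected; use kernel_basis for the general case"
        )
    if mode == "symbolic":
        edge_polys = {
            key: LabelPolynomial.from_expr(lab) for key, lab in G.edges.items()
        }
        monomial_labels = all(len(p.terms) == 1 for p in edge_polys.values())
        out = []
        for r in range(1, G.n + 1):
            if monomial_labels:
                out.append(_rho_entry_monomial(G, r, edge_polys))
            else:
                entry = LabelPolynomial.zero()
                for tree in _iter_out_choices(G, r):
                    prod = LabelPolynomial.constant(1)
                    for i, j in tree.items():
                        prod = prod * edge_polys[(i, j)]
                    entry = entry + prod
                out.append(entry)
        return out
    if mode == "numeric":
        if env is None:
            raise ValueError("numeric mode requires an environment")
        L = laplacian(G, env)
        return _minor_vector(L)
    raise ValueError(f"unknown mode {mode!r}")


def _rho_entry_monomial(G: LabelledDigraph, root: int, edge_polys) -> LabelPolynomial:
    """Fast path when every edge label is a single monomial (the common
    case of bare rate symbols): each tree contributes one monomial, so
    exponent vectors are just summed and tallied."""
    edge_terms = {k: next(iter(p.terms.items())) for k, p in edge_polys.items()}
    acc: dict = {}
    for tree in _iter_out_choices(G, root):
        exps: dict[str, int] = {}
        coeff = Fraction(1)
        for i, j in tree.items():
            key, c = edge_terms[(i, j)]
            coeff *= c
            for s, e in key:
                exps[s] = exps.get(s, 0) + e
        k = tuple(sorted(exps.items()))
        acc[k] = acc.get(k, Fraction(0)) + coeff
    return LabelPolynomial(acc)


def _minor_vector(L: np.ndarray) -> np.ndarray:
    n = L.shape[0]
    out = np.empty(n)
    for r in range(n):
        sub = np.delete(np.delete(-L, r, axis=0), r, axis=1)
        sign, logdet = np.linalg.slogdet(sub)
        out[r] = 0.0 if sign == 0 else sign * np.exp(logdet)
    return out


def steady_state_probabilities(G: LabelledDigraph, env: Mapping[str, float]) -> SteadyState:
    """Normalised steady state of a strongly connected graph: u*_j =
    rho_j / sum_k rho_k; every entry is strictly positive.

    Small graphs go through the exact principal-minor route; larger ones
    (where n determinants become expensive) solve the kernel directly
    with the conservation law as the closing equation."""
    if G.n <= 64:
        rho = rho_matrix_tree(G, mode="numeric", env=env)
    else:
        if not is_strongly_connected(G):
            raise ValueError(
                "graph is not strongly connected; use kernel_basis for the general case"
            )
        L = laplacian(G, env)
        A = np.vstack([L[1:], np.ones(G.n)])
        b = np.zeros(G.n)
        b[-1] = 1.0
        rho, *_ = np.linalg.lstsq(A, b, rcond=None)
    total = rho.sum()
    if not total > 0:
        raise ArithmeticError("degenerate rho vector; check the environment scale")
    return SteadyState(basis=[rho], probabilities=rho / total)


# -- general graphs ------------------------------------------------------

def kernel_basis(
    G: LabelledDigraph,
    mode: str = "symbolic",
    env: Mapping[str, float] | None = None,
) -> list:
    """One kernel basis vector per terminal SCC: the matrix-tree vector of
    the induced subgraph, embedded with zeros on all other vertices.
    Vertices outside every terminal SCC therefore carry zero steady-state
    probability."""
    dec = scc_decomposition(G)
    basis = []
    for comp in dec.terminal_components:
        members = sorted(comp)
        if len(members) == 1:
            rho_sub = [LabelPolynomial.constant(1)] if mode == "symbolic" else np.array([1.0])
        else:
            sub, mapping = G.subgraph(members)
            rho_sub = rho_matrix_tree(sub, mode=mode, env=env)
        if mode == "symbolic":
            vec = [LabelPolynomial.zero()] * G.n
            for local, v in enumerate(members):
                vec[v - 1] = rho_sub[local]
        else:
            vec = np.zeros(G.n)
            for local, v in enumerate(members):
                vec[v - 1] = rho_sub[local]
        basis.append(vec)
    return basis


def steady_state_from_initial(
    G: LabelledDigraph,
    env: Mapping[str, float],
    x0: Sequence[float],
) -> SteadyState:
    """Steady state reached from ``x0``: x* = sum_k z_k rho^k / (1.rho^k)
    where the coefficients z_k are the graph's conservation laws evaluated
    at x0.  The conservation laws are the left-kernel basis of the
    Laplacian dualised against the normalised right basis."""
    x0 = np.asarray(x0, dtype=float)
    if (x0 < 0).any():
        raise ValueError("initial condition must be non-negative")
    if not x0.sum() > 0:
        raise ValueError("initial condition must have positive total mass")
    basis = kernel_basis(G, mode="numeric", env=env)
    R = np.column_stack([b / b.sum() for b in basis])  # n x t, columns normalised
    L = laplacian(G, env)
    # left kernel of L == null space of L^T
    u, s, vt = np.linalg.svd(L.T)
    t = R.shape[1]
    tol = max(L.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    null_dim = int((s <= max(tol, 1e-12 * (s[0] if len(s) else 1.0))).sum())
    if null_dim != t:
        raise ArithmeticError(
            f"left-kernel dimension {null_dim} does not match terminal SCC count {t}"
        )
    L0 = vt[-t:, :]  # t x n, rows span the left kernel
    M = L0 @ R  # t x t
    ell = np.linalg.solve(M, L0)  # rows satisfy ell_k . R[:,j] = delta_kj
    z = ell @ x0
    x_star = R @ z
    return SteadyState(
        basis=basis,
        probabilities=x_star / x_star.sum() if x_star.sum() else x_star,
        conservation_values=z,
        state=x_star,
    )


def rho_entries_positive(rho) -> bool:
    """True when every entry of a symbolic or numeric rho vector is
    non-zero (for strongly connected graphs they are strictly positive)."""
    if isinstance(rho, np.ndarray):
        return bool((rho > 0).all())
    return all(bool(entry) for entry in rho)
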