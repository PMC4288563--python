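"""Product graphs: the independence construction.

When two regulatory modules operate independently, the graph of the
joint system is the product G x H: vertices are pairs (i, j), and each
factor edge is copied once per vertex of the other factor, keeping its
label.  The kernel basis of the product Laplacian is then spanned by the
Kronecker products of the factors' basis vectors — so independent
modules multiply rather than compound their steady-state complexity.
Product vertices are enumerated lexicographically, (i, j) before
(i', j') iff i < i' or (i = i' and j < j'), and flattened to 1-based
indices in that order.
"""

from __future__ import annotations

import numpy as np

from .graph import LabelledDigraph, Vertex, build_graph
from .poly import LabelPolynomial
from .steady import kernel_basis

__all__ = ["product", "product_index", "kronecker", "product_kernel_basis"]


def product_index(i: int, j: int, n_h: int) -> int:
    """Flattened 1-based index of product vertex (i, j) under the
    lexicographic enumeration."""
    return (i - 1) * n_h + j


def product(G: LabelledDigraph, H: LabelledDigraph) -> LabelledDigraph:
    """The product graph G x H.  |V| = |V_G| * |V_H| and
    |E| = |E_G| * |V_H| + |V_G| * |E_H|; these are the only edges."""
    n_h = H.n
    verts = []
    for gi in G.vertices:
        for hj in H.vertices:
            attrs = {f"G.{k}": v for k, v in gi.attributes.items()}
            attrs.update({f"H.{k}": v for k, v in hj.attributes.items()})
            verts.append(
                Vertex(
                    product_index(gi.index, hj.index, n_h),
                    f"({gi.name},{hj.name})",
                    attrs,
                )
            )
    edges = []
    for (i1, i2), lab in G.edges.items():
        for j in range(1, n_h + 1):
            edges.append((product_index(i1, j, n_h), product_index(i2, j, n_h), lab))
    for (j1, j2), lab in H.edges.items():
        for i in range(1, G.n + 1):
            edges.append((product_index(i, j1, n_h), product_index(i, j2, n_h), lab))
    return build_graph(verts, edges)


def kronecker(x, y):
    """Kronecker product of two rho vectors: (x (x) y)_(i,j) = x_i * y_j,
    laid out in the lexicographic product order.  Works entrywise for
    numeric arrays and LabelPolynomial lists alike."""
    if isinstance(x, np.ndarray) and isinstance(y, np.ndarray):
        return np.kron(x, y)
    out = []
    for xi in x:
        for yj in y:
            if isinstance(xi, LabelPolynomial) or isinstance(yj, LabelPolynomial):
                out.append(LabelPolynomial.from_expr(xi) * LabelPolynomial.from_expr(yj))
            else:
                out.append(xi * yj)
    return out


def product_kernel_basis(G: LabelledDigraph, H: LabelledDigraph, mode: str = "symbolic",
                         env=None) -> list:
    """Kernel basis of L(G x H) as the pairwise Kronecker products of the
    factors' terminal-SCC basis vectors; the list has length t_G * t_H and
    reduces to a singleton when both factors are strongly connected."""
    bg = kernel_basis(G, mode=mode, env=env)
    bh = kernel_basis(H, mode=mode, env=env)
    return [kronecker(x, y) for x in bg for y in bh]
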