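"""Random and canonical test graphs with known properties.

Generation is a pure function of (family, size, seed): equal specs give
identical graphs.  Numeric labels are drawn log-uniformly over
[1e-2, 1e2] to stress conditioning; symbolic labels are fresh symbols
``x1, x2, ...`` so matrix-tree outputs stay polynomial.
"""

from __future__ import annotations

import bisect

import numpy as np

from .graph import LabelledDigraph, build_graph

__all__ = [
    "random_strongly_connected",
    "random_reversible_tree",
    "balanced_cycle",
]


def _labels(count: int, regime: str, rng) -> list:
    if regime == "symbolic":
        return [f"x{k}" for k in range(1, count + 1)]
    if regime == "numeric":
        return [float(10.0 ** rng.uniform(-2, 2)) for _ in range(count)]
    raise ValueError(f"unknown label regime {regime!r}")


def random_strongly_connected(
    n: int,
    edge_density: float = 0.3,
    seed: int = 0,
    labels: str = "numeric",
) -> LabelledDigraph:
    """Strongly connected by construction: a random Hamiltonian cycle
    plus extra random edges at the requested density."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if n == 1:
        return build_graph(1, [])
    perm = list(rng.permutation(np.arange(1, n + 1)))
    pairs = [(int(perm[k]), int(perm[(k + 1) % n])) for k in range(n)]
    extra = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(1, n + 1)
        if i != j and (i, j) not in set(pairs) and rng.random() < edge_density
    ]
    pairs += extra
    labs = _labels(len(pairs), labels, rng)
    return build_graph(n, [(i, j, lab) for (i, j), lab in zip(pairs, labs)])


def random_reversible_tree(n: int, seed: int = 0, labels: str = "numeric") -> LabelledDigraph:
    """A uniform random labelled tree with every edge made reversible
    with independent labels.  Trees have no reversible cycles, so the
    cycle condition holds vacuously and detailed balance is automatic."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    # random Pruefer sequence -> uniform random tree on n labelled vertices
    if n == 2:
        und = [(1, 2)]
    else:
        prufer = [int(rng.integers(1, n + 1)) for _ in range(n - 2)]
        degree = {v: 1 for v in range(1, n + 1)}
        for v in prufer:
            degree[v] += 1
        und = []
        leaves = sorted(v for v in degree if degree[v] == 1)
        for v in prufer:
            leaf = leaves.pop(0)
            und.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                bisect.insort(leaves, v)
        und.append((leaves[0], leaves[1]))
    pairs = [(i, j) for (i, j) in und] + [(j, i) for (i, j) in und]
    labs = _labels(len(pairs), labels, rng)
    return build_graph(n, [(i, j, lab) for (i, j), lab in zip(pairs, labs)])


def balanced_cycle(n: int, seed: int = 0) -> LabelledDigraph:
    """A reversible n-cycle whose labels are random positive numbers
    except one, solved so the two direction products are equal — the
    smallest family that satisfies the cycle condition non-vacuously."""
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    fwd = [10.0 ** rng.uniform(-1, 1) for _ in range(n)]
    rev = [10.0 ** rng.uniform(-1, 1) for _ in range(n)]
    # solve the last reverse label so prod(fwd) == prod(rev)
    rev[-1] = float(np.prod(fwd) / np.prod(rev[:-1]))
    edges = []
    for k in range(n):
        i, j = k + 1, (k + 1) % n + 1
        edges.append((i, j, fwd[k]))
        edges.append((j, i, rev[k]))
    return build_graph(n, edges)
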