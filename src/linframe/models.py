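"""Builders for the model systems: nucleosome-mark arrays, the yeast
PHO5 promoter, and detailed-balance graphs with titratable components.

Nucleosome arrays (chromatin-domain model)
------------------------------------------
An array of n nucleosomes carries a binary mark per site; microstates
are bit strings (leftmost character = leftmost nucleosome) indexed by
reading the string as a base-2 number and adding 1.  Nucleation (rate
``k_plus``) happens only at the nucleation site, placed at the
right-hand end; propagation (also ``k_plus``) marks an unmarked site
with a marked immediate neighbour; turnover (``k_minus``) unmarks any
marked site.  Turnover of an isolated mark has no reverse edge, so the
graph is irreversible (for n >= 2) while remaining strongly connected.
The stabilised variant adds a third per-site state, digit 2, reached
from digit 1 at rate ``k_star``; a stabilised mark has no outgoing
transitions for that site, which destroys strong connectivity.

PHO5 promoter
-------------
Twelve microstates over: Pho4 at UASp1 (exposed, low-affinity site),
the UASp2 position (occluded by nucleosome -2, or exposed, or
Pho4-bound), and nucleosome -1 (occludes the TATA box; the gene is
transcribed exactly when it is absent).  Five rate symbols:

=======  ==============  ==============================================
symbol   rate            transition
=======  ==============  ==============================================
``a``    k*_assoc        Pho4 association (concentration-dependent,
                         Hill-saturating) to either exposed site
``b``    k_exp_dissoc    Pho4 dissociation from the low-affinity site
``c``    k_nuc_dissoc    Pho4 dissociation from the high-affinity site
``d``    k_remod         nucleosome disassembly
``e``    k_reass         nucleosome reassembly
=======  ==============  ==============================================

Nucleosome -2 disassembly requires Pho4 at UASp1; nucleosome -1
disassembly requires the promoter already opened at -2 (nucleosome -2
absent) with Pho4 bound at either site; reassembly is unconditional
(nucleosome -2 only when UASp2 is unoccupied).  This
transition scheme reproduces, exactly, the model's published summary
statistics: 53,376 rooted spanning trees, monomials all of total degree
11, maximal ``a``-degree 8 with leading terms 4*d^2*(d+e)*a^8 (numerator)
and 4*d*(d+e)^2*a^8 (denominator), and 261/500 distinct monomials in
the regulation function's numerator/denominator.  Nucleosome -3 and the
sites it occludes are outside the model.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import networkx as nx
import sympy as sp

from .graph import LabelledDigraph, Vertex, build_graph

__all__ = [
    "build_nucleosome_array",
    "build_equilibrium_array",
    "build_stabilized_array",
    "equilibrium_array_probability",
    "build_pho5_graph",
    "pho5_transcribing_indicator",
    "hill_association",
    "rapid_equilibrium_label",
    "build_titratable_graph",
    "PHO5_VARIANTS",
]


# ----------------------------------------------------------------------
# two-state nucleosome arrays
# ----------------------------------------------------------------------

def _array_vertices(n: int, base: int):
    """Microstates as digit strings; index = base-``base`` value + 1."""
    verts = []
    for digits in itertools.product(range(base), repeat=n):
        s = "".join(str(d) for d in digits)
        index = int(s, base) + 1
        beta = sum(1 for d in digits if d != 0)
        verts.append(Vertex(index, s, {"beta": beta}))
    verts.sort(key=lambda v: v.index)
    return verts


def build_nucleosome_array(n: int) -> LabelledDigraph:
    """The 2-state marking model on ``n`` sites.  Nucleation is confined
    to the rightmost site; every bit-increasing edge has label ``k_plus``
    and every bit-decreasing edge ``k_minus``, one edge per flip however
    many causes apply."""
    if not 1 <= n <= 20:
        raise ValueError("n must be between 1 and 20 for exact methods")
    verts = _array_vertices(n, 2)
    nucleation = n - 1  # rightmost character
    edges = []
    for v in verts:
        bits = v.name
        for s in range(n):
            if bits[s] == "0":
                neighbours_marked = (s > 0 and bits[s - 1] != "0") or (
                    s < n - 1 and bits[s + 1] != "0"
                )
                if s == nucleation or neighbours_marked:
                    tgt = bits[:s] + "1" + bits[s + 1:]
                    edges.append((v.index, int(tgt, 2) + 1, "k_plus"))
            else:
                tgt = bits[:s] + "0" + bits[s + 1:]
                edges.append((v.index, int(tgt, 2) + 1, "k_minus"))
    return build_graph(verts, edges)


def build_equilibrium_array(n: int) -> LabelledDigraph:
    """The reversibilised array: every single-bit flip is allowed, up at
    ``k_plus`` and down at ``k_minus``.  This graph is reversible,
    satisfies the cycle condition, and its equilibrium probabilities are
    K^beta(j) / (1+K)^n with K = k_plus/k_minus — each site marks
    independently, so there is no positional structure and no inherent
    bound on the marked domain."""
    if not 1 <= n <= 20:
        raise ValueError("n must be between 1 and 20 for exact methods")
    verts = _array_vertices(n, 2)
    edges = []
    for v in verts:
        bits = v.name
        for s in range(n):
            flip = ("1" if bits[s] == "0" else "0")
            tgt = bits[:s] + flip + bits[s + 1:]
            label = "k_plus" if flip == "1" else "k_minus"
            edges.append((v.index, int(tgt, 2) + 1, label))
    return build_graph(verts, edges)


def equilibrium_array_probability(n: int, K: float, j) -> float:
    """Equilibrium probability K^beta(j) / (1+K)^n of array microstate
    ``j`` (a digit string, or an integer number of marked sites beta)."""
    if not K > 0:
        raise ValueError("K must be positive")
    beta = j if isinstance(j, int) else sum(1 for ch in str(j) if ch != "0")
    return K**beta / (1.0 + K) ** n


# ----------------------------------------------------------------------
# stabilised (3-state) arrays
# ----------------------------------------------------------------------

def build_stabilized_array(n: int, nucleation_on: bool = True) -> LabelledDigraph:
    """Mark stabilisation model: per-site states 0 (unmarked), 1 (marked),
    2 (stably marked).  Marking edges follow the 2-state rules with a
    site counting as marked for propagation when its digit is 1 or 2;
    nucleation edges exist only when ``nucleation_on``.  Turnover
    (``k_minus``) applies to digit-1 sites only; stabilisation 1 -> 2 at
    ``k_star``; no transitions leave digit 2."""
    if not 1 <= n <= 12:
        raise ValueError("n must be between 1 and 12")
    verts = _array_vertices(n, 3)
    nucleation = n - 1
    edges = []
    for v in verts:
        digs = v.name
        for s in range(n):
            if digs[s] == "0":
                neighbours_marked = (s > 0 and digs[s - 1] != "0") or (
                    s < n - 1 and digs[s + 1] != "0"
                )
                allowed = neighbours_marked or (s == nucleation and nucleation_on)
                if allowed:
                    tgt = digs[:s] + "1" + digs[s + 1:]
                    edges.append((v.index, int(tgt, 3) + 1, "k_plus"))
            elif digs[s] == "1":
                down = digs[:s] + "0" + digs[s + 1:]
                edges.append((v.index, int(down, 3) + 1, "k_minus"))
                up = digs[:s] + "2" + digs[s + 1:]
                edges.append((v.index, int(up, 3) + 1, "k_star"))
    return build_graph(verts, edges)


# ----------------------------------------------------------------------
# PHO5
# ----------------------------------------------------------------------

#: the variant codes analysed against single-cell data (wild type first);
#: first letter = UASp1 position, second = UASp2 position.
PHO5_VARIANTS = ("LH", "HL", "HH", "LL", "LX", "HX", "XH", "XL", "XX")

# microstate components: p1 (Pho4 at UASp1), s2 (UASp2 position:
# N = nucleosome -2 present, E = exposed/empty, P = Pho4 bound),
# n1 (nucleosome -1 present -> TATA occluded, not transcribing)
_S2_ORDER = {"N": 0, "E": 1, "P": 2}


def _pho5_states(site1: str, site2: str):
    p1_vals = (0,) if site1 == "X" else (0, 1)
    s2_vals = ("N", "E") if site2 == "X" else ("N", "E", "P")
    states = [
        (p1, s2, n1) for p1 in p1_vals for s2 in s2_vals for n1 in (1, 0)
    ]
    # reference microstate first: no Pho4 bound, both nucleosomes present
    states.sort(key=lambda s: (s[0], _S2_ORDER[s[1]], -s[2]))
    return states


def build_pho5_graph(variant: str = "LH") -> LabelledDigraph:
    """The PHO5 promoter graph for a variant code.

    The code is a pair over {H, L, X}: affinities of the UASp1 and UASp2
    positions (wild type ``LH``).  Site affinity moves only the
    dissociation labels — ``b`` for a low-affinity site, ``c`` for a
    high-affinity one — while the association label ``a`` is shared.
    ``X`` deletes a site: its binding/unbinding edges and every
    microstate with that site bound disappear.  Deleting the nucleosomal
    (UASp2) site leaves the 8-vertex graph used for the measured
    X variants; deleting the exposed (UASp1) site leaves 6 vertices and
    a promoter that can never open, since nucleosome -2 removal needs
    Pho4 at UASp1 — such graphs are not strongly connected and predict
    no expression."""
    variant = variant.upper()
    if len(variant) != 2 or any(ch not in "HLX" for ch in variant):
        raise ValueError(f"invalid variant code {variant!r}")
    site1, site2 = variant
    dissoc = {"H": "c", "L": "b"}
    states = _pho5_states(site1, site2)
    idx = {s: k + 1 for k, s in enumerate(states)}
    verts = [
        Vertex(
            idx[s],
            f"p1={s[0]},uasp2={s[1]},nuc1={s[2]}",
            {
                "pho4_uasp1": bool(s[0]),
                "uasp2": {"N": "nucleosome", "E": "empty", "P": "pho4"}[s[1]],
                "nuc1": bool(s[2]),
                "transcribing": s[2] == 0,
            },
        )
        for s in states
    ]
    edges = []
    for (p1, s2, n1) in states:
        src = idx[(p1, s2, n1)]
        if site1 != "X":
            if p1 == 0:
                edges.append((src, idx[(1, s2, n1)], "a"))
            else:
                edges.append((src, idx[(0, s2, n1)], dissoc[site1]))
        if site2 != "X":
            if s2 == "E":
                edges.append((src, idx[(p1, "P", n1)], "a"))
            elif s2 == "P":
                edges.append((src, idx[(p1, "E", n1)], dissoc[site2]))
        # nucleosome -2: disassembly needs Pho4 at UASp1; reassembly
        # whenever the UASp2 position is unoccupied
        if s2 == "N" and p1 == 1:
            edges.append((src, idx[(p1, "E", n1)], "d"))
        if s2 == "E":
            edges.append((src, idx[(p1, "N", n1)], "e"))
        # nucleosome -1: disassembly needs the promoter opened at -2
        # (UASp2 position unoccluded) with Pho4 bound at either site
        if n1 == 1 and s2 != "N" and (p1 == 1 or s2 == "P"):
            edges.append((src, idx[(p1, s2, 0)], "d"))
        if n1 == 0:
            edges.append((src, idx[(p1, s2, 1)], "e"))
    return build_graph(verts, edges)


def pho5_transcribing_indicator(G: LabelledDigraph) -> list[int]:
    """0/1 expression rates: 1 on microstates without nucleosome -1."""
    return [1 if v.attributes.get("transcribing") else 0 for v in G.vertices]


def hill_association(P: float, K: float, kmax: float) -> float:
    """Hill-saturating Pho4 association rate kmax * P^2 / (K^2 + P^2)."""
    if P < 0:
        raise ValueError("concentration must be non-negative")
    if not (K > 0 and kmax > 0):
        raise ValueError("K and kmax must be positive")
    if P == 0:
        return 0.0
    return kmax * P * P / (K * K + P * P)


def rapid_equilibrium_label(L: float, Mtot: float, b: float, c: float) -> float:
    """Concentration of the DNA-binding complex LM under rapid
    equilibrium of L + M <-> LM: Mtot*L / ((c/b) + L), a first-order
    Hill curve in L with maximum Mtot and half-point c/b."""
    if L < 0 or not (Mtot > 0 and b > 0 and c > 0):
        raise ValueError("require L >= 0 and Mtot, b, c > 0")
    return Mtot * L / (c / b + L)


# ----------------------------------------------------------------------
# titratable detailed-balance graphs (hormone-receptor style)
# ----------------------------------------------------------------------

def build_titratable_graph(
    edge_specs: Sequence[tuple[int, int, str, float, float]],
    K_R: float = 1.0,
    R_tot: float = 1.0,
    saturated: bool = False,
) -> LabelledDigraph:
    """A reversible sequence/tree graph with titratable components R
    (hormone-receptor complex) and U (co-regulator), each binding at most
    once along any path from the reference vertex.

    ``edge_specs`` rows are ``(i, j, kind, k_forward, k_reverse)`` with
    ``kind`` in {'R', 'U', 'const'}.  The undirected skeleton must be a
    tree containing vertex 1 (so detailed balance holds for any labels).
    An R edge's forward label carries the factor [RS] = R_tot*S/(K_R+S),
    a first-order Hill curve in the hormone concentration S (symbolic in
    ``S``; with ``saturated=True`` the factor is frozen at R_tot).  U and
    const edges have constant labels (any co-regulator concentration is
    absorbed into k_forward).  Vertex attributes record R/U occupancy by
    path accumulation from vertex 1."""
    skel = nx.Graph()
    for (i, j, kind, kf, kr) in edge_specs:
        if kind not in ("R", "U", "const"):
            raise ValueError(f"unknown edge kind {kind!r}")
        if skel.has_edge(i, j):
            raise ValueError(f"duplicate edge {i}-{j}")
        skel.add_edge(i, j, kind=kind, kf=kf, kr=kr)
    nverts = max(skel.nodes)
    if set(skel.nodes) != set(range(1, nverts + 1)):
        raise ValueError("vertices must be 1..n")
    if not nx.is_tree(skel):
        raise ValueError("shape must be a sequence or tree of reversible edges")

    S = sp.Symbol("S", positive=True)
    rs_factor = sp.Float(R_tot) if saturated else R_tot * S / (K_R + S)

    # occupancy by path accumulation from the reference vertex
    occ = {1: (False, False)}  # (R_bound, U_bound)
    for (u, v) in nx.bfs_edges(skel, 1):
        kind = skel.edges[u, v]["kind"]
        r, w = occ[u]
        if kind == "R":
            if r:
                raise ValueError(f"R binds twice along the path to vertex {v}")
            r = True
        elif kind == "U":
            if w:
                raise ValueError(f"U binds twice along the path to vertex {v}")
            w = True
        occ[v] = (r, w)

    verts = [
        Vertex(k, f"v{k}", {"R_bound": occ[k][0], "U_bound": occ[k][1]})
        for k in range(1, nverts + 1)
    ]
    edges = []
    for (u, v) in nx.bfs_edges(skel, 1):
        data = skel.edges[u, v]
        kf, kr, kind = data["kf"], data["kr"], data["kind"]
        fwd = sp.Float(kf) * rs_factor if kind == "R" else sp.Float(kf)
        edges.append((u, v, fwd))
        edges.append((v, u, sp.Float(kr)))
    return build_graph(verts, edges)
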