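"""Time-domain semantics: master-equation integration and exact
continuous-time Markov-chain simulation.

The edge labels are infinitesimal transition rates, so the graph defines
a continuous-time finite-state Markov process whose master equation is
the Laplacian dynamics du/dt = L(G) u.  These routines serve as
independent oracles for the exact steady-state machinery: the integrated
solution must converge to the kernel combination selected by the initial
condition, and time-weighted Gillespie occupancies must match the
matrix-tree probabilities within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .graph import LabelledDigraph, laplacian

__all__ = [
    "integrate_master_equation",
    "Trajectory",
    "gillespie",
    "empirical_frequencies",
]


def integrate_master_equation(
    G: LabelledDigraph,
    env: Mapping[str, float],
    u0: Sequence[float],
    t_grid: Sequence[float],
) -> np.ndarray:
    """Probability vectors u(t) = exp(L t) u0 on ``t_grid`` (rows).

    The dynamics is linear, so the matrix exponential is both exact and
    stiffness-proof; each row is non-negative and sums to 1."""
    u0 = np.asarray(u0, dtype=float)
    if (u0 < 0).any() or not np.isclose(u0.sum(), 1.0):
        raise ValueError("u0 must be a probability vector")
    L = laplacian(G, env)
    return np.vstack([expm(L * float(t)) @ u0 for t in t_grid])


@dataclass
class Trajectory:
    """A sampled path: jump times (starting at 0) and visited vertices;
    the final entry of ``times`` is the simulation horizon."""

    times: np.ndarray
    states: np.ndarray
    seed: int
    t_end: float


def gillespie(
    G: LabelledDigraph,
    env: Mapping[str, float],
    start: int,
    t_end: float,
    seed: int,
) -> Trajectory:
    """Exact stochastic simulation: exponential holding times with rate
    equal to the total outgoing label, successor chosen proportionally to
    edge labels.  A vertex with no outgoing edges absorbs the trajectory."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rates = G.numeric_edges(env)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v in G.vertices:
        tgts = [(j, r) for (i, j), r in rates.items() if i == v.index]
        if tgts:
            js = np.array([t[0] for t in tgts])
            rs = np.array([t[1] for t in tgts])
            out[v.index] = (js, rs)
    rng = np.random.default_rng(seed)
    t, v = 0.0, int(start)
    times, states = [0.0], [v]
    while True:
        if v not in out:
            break  # absorbing vertex
        js, rs = out[v]
        total = rs.sum()
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_end:
            break
        t += dt
        v = int(rng.choice(js, p=rs / total))
        times.append(t)
        states.append(v)
    return Trajectory(np.array(times), np.array(states), seed, float(t_end))


def empirical_frequencies(
    traj: Trajectory,
    burn_in: float | None = None,
    n_vertices: int | None = None,
    n_batches: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-weighted occupancy fractions after ``burn_in`` (default 10%
    of the horizon), with standard errors from ``n_batches`` batch means."""
    t_end = traj.t_end
    if burn_in is None:
        burn_in = 0.1 * t_end
    if not t_end - burn_in > 0:
        raise ValueError("empty post-burn-in window")
    n = n_vertices or int(traj.states.max())
    edges = np.linspace(burn_in, t_end, n_batches + 1)
    batch = np.zeros((n_batches, n))
    # dwell intervals: [times[k], times[k+1]) in state states[k]
    starts = traj.times
    ends = np.append(traj.times[1:], t_end)
    for s, e, v in zip(starts, ends, traj.states):
        if e <= burn_in:
            continue
        s = max(s, burn_in)
        b0 = np.searchsorted(edges, s, side="right") - 1
        b1 = np.searchsorted(edges, e, side="left") - 1
        for b in range(max(b0, 0), min(b1, n_batches - 1) + 1):
            lo, hi = edges[b], edges[b + 1]
            batch[b, v - 1] += max(0.0, min(e, hi) - max(s, lo))
    widths = np.diff(edges)[:, None]
    frac = batch / widths
    occupancy = frac.mean(axis=0)
    se = frac.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return occupancy, se
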