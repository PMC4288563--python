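"""Gene-regulation functions (GRFs).

The expression rate of a gene is the average of per-microstate rates
g_i over the steady-state probabilities: g_1 u*_1 + ... + g_n u*_n.
With binary g the GRF is a ratio of label polynomials — numerator the
sum of matrix-tree rho entries over expressing microstates, denominator
the full sum (the non-equilibrium partition function) — kept fully
expanded with like terms collected and no common factor cancelled, so
monomial counts measure the intrinsic complexity of the mechanism.

For detailed-balance graphs with a titratable receptor that binds at
most once per microstate and expression confined to receptor-bound
states, the GRF in hormone concentration S collapses to a first-order
Hill dose-response curve (FHDC) M*S/(K+S); ``fhdc_extract`` fits and
certifies that shape numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .graph import LabelledDigraph
from .poly import LabelPolynomial
from .steady import rho_matrix_tree, steady_state_probabilities

__all__ = [
    "gene_regulation_function",
    "RationalGRF",
    "rational_grf",
    "FHDCParameters",
    "fhdc_extract",
]


def gene_regulation_function(
    G: LabelledDigraph,
    g: Sequence[float],
    env: Mapping[str, float],
) -> float:
    """Average expression rate sum_i g_i u*_i at the steady state of a
    strongly connected graph; bounded by [min g, max g]."""
    g = np.asarray(g, dtype=float)
    if g.shape != (G.n,):
        raise ValueError(f"expected {G.n} expression rates, got {g.shape}")
    u = steady_state_probabilities(G, env).probabilities
    return float(g @ u)


@dataclass
class RationalGRF:
    """Symbolic GRF as numerator/denominator label polynomials."""

    numerator: LabelPolynomial
    denominator: LabelPolynomial

    def evaluate(self, env: Mapping[str, float]) -> float:
        return float(self.numerator.evaluate(env)) / float(self.denominator.evaluate(env))

    def eval_along(
        self,
        symbol: str,
        values: np.ndarray,
        consts: Mapping[str, float],
    ) -> np.ndarray:
        """Vectorised evaluation along one symbol with the others fixed.

        Both polynomials collapse to univariate polynomials in ``symbol``
        whose coefficients depend on ``consts``; this makes per-cell GRF
        evaluation cheap inside fitting loops."""
        num = _collapse(self.numerator, symbol, consts)
        den = _collapse(self.denominator, symbol, consts)
        values = np.asarray(values, dtype=float)
        return np.polyval(num[::-1], values) / np.polyval(den[::-1], values)


def _collapse(p: LabelPolynomial, symbol: str, consts: Mapping[str, float]) -> np.ndarray:
    deg = p.max_degree(symbol)
    coeffs = np.zeros(deg + 1)
    for key, c in p.terms.items():
        w = float(c)
        k = 0
        for s, e in key:
            if s == symbol:
                k = e
            else:
                w *= consts[s] ** e
        coeffs[k] += w
    return coeffs


def rational_grf(G: LabelledDigraph, g: Sequence[int]) -> RationalGRF:
    """Symbolic rational GRF for binary expression rates.

    numerator = sum of rho entries with g_i = 1; denominator = 1.rho.
    Both are fully expanded, like terms collected, nothing cancelled."""
    g = list(g)
    if len(g) != G.n:
        raise ValueError(f"expected {G.n} expression rates")
    if any(x not in (0, 1) for x in g):
        raise ValueError("symbolic GRFs take binary g; use the numeric path otherwise")
    rho = rho_matrix_tree(G, mode="symbolic")
    num = LabelPolynomial.zero()
    den = LabelPolynomial.zero()
    for gi, entry in zip(g, rho):
        den = den + entry
        if gi:
            num = num + entry
    return RationalGRF(num, den)


@dataclass
class FHDCParameters:
    """Fitted first-order Hill curve g(S) = M*S/(K+S)."""

    M: float
    K: float
    max_relative_residual: float
    fhdc_consistent: bool
    tolerance: float


def fhdc_extract(
    samples: Sequence[tuple[float, float]],
    tolerance: float = 1e-6,
) -> FHDCParameters:
    """Least-squares fit of M*S/(K+S) to sampled (S, g(S)) pairs.

    Requires at least 8 points spanning both sides of the apparent
    half-point of an increasing curve.  ``fhdc_consistent`` is set when
    the maximal relative residual falls below ``tolerance`` (1e-6 is the
    exact-model verification regime; pass a looser value for noisy
    data)."""
    pts = sorted((float(s), float(v)) for s, v in samples)
    S = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(S) < 8:
        raise ValueError("need at least 8 sample points")
    if np.ptp(y) <= 0 or not (y[-1] > y[0]):
        raise ValueError("degenerate or non-increasing curve; not fittable as an FHDC")
    half = y.max() / 2.0
    if not (y.min() < half < y.max()):
        raise ValueError("samples must span the apparent half-point")
    m0 = y.max()
    k0 = float(S[np.argmin(np.abs(y - half))])

    def resid(theta):
        m, k = np.exp(theta)
        return m * S / (k + S) - y

    sol = least_squares(resid, np.log([m0, max(k0, 1e-12)]), method="lm")
    m, k = np.exp(sol.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(m * S / (k + S) - y) / np.maximum(np.abs(y), np.finfo(float).tiny)
    max_rel = float(rel.max())
    return FHDCParameters(
        M=float(m),
        K=float(k),
        max_relative_residual=max_rel,
        fhdc_consistent=max_rel < tolerance,
        tolerance=tolerance,
    )
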