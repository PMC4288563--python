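"""Exact multivariate polynomials over rate symbols.

Steady-state basis vectors produced by the matrix-tree theorem are sums of
spanning-tree label products: every tree contributes one monomial with
coefficient 1, so the natural representation is a mapping from exponent
vectors to integer (more generally rational) coefficients.  This module
implements that representation directly, which keeps monomial counting,
degree bookkeeping and all-ones evaluation exact and fast even for the
~50,000-tree polynomials that arise in the PHO5 promoter model.

Symbols are ordered lexicographically by name; printed output lists
monomials in graded-lexicographic order (total degree first), descending,
which fixes a canonical string form.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import sympy as sp

__all__ = [
    "LabelPolynomial",
    "MonomialStatistics",
    "poly_add",
    "poly_mul",
    "poly_eval",
    "monomial_statistics",
    "common_scalar_factor",
    "parse_polynomial",
]

# exponent key: tuple of (symbol, exponent) pairs, sorted by symbol name,
# zero exponents omitted; () is the constant monomial
ExpKey = tuple[tuple[str, int], ...]


def _normalize_key(exponents: Mapping[str, int]) -> ExpKey:
    return tuple(sorted((s, int(e)) for s, e in exponents.items() if e))


class LabelPolynomial:
    """A multivariate polynomial with rational coefficients.

    The empty term-set represents zero.  Like terms are always collected;
    terms with coefficient zero are dropped eagerly.
    """

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[ExpKey, Fraction] | None = None):
        self.terms: dict[ExpKey, Fraction] = {}
        if terms:
            for k, c in terms.items():
                c = Fraction(c)
                if c:
                    self.terms[k] = c

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "LabelPolynomial":
        return cls()

    @classmethod
    def constant(cls, c) -> "LabelPolynomial":
        return cls({(): Fraction(c)})

    @classmethod
    def symbol(cls, name: str) -> "LabelPolynomial":
        return cls({((name, 1),): Fraction(1)})

    @classmethod
    def monomial(cls, coeff, exponents: Mapping[str, int]) -> "LabelPolynomial":
        return cls({_normalize_key(exponents): Fraction(coeff)})

    @classmethod
    def from_expr(cls, expr) -> "LabelPolynomial":
        """Convert a sympy expression (or number) to a LabelPolynomial.

        Raises ``ValueError`` if the expression is not polynomial in its
        free symbols (e.g. contains a ratio of symbols).
        """
        if isinstance(expr, LabelPolynomial):
            return expr
        if isinstance(expr, numbers.Number):
            return cls.constant(Fraction(expr))
        expr = sp.sympify(expr)
        syms = sorted(expr.free_symbols, key=lambda s: s.name)
        if not syms:
            return cls.constant(Fraction(sp.Rational(expr)))
        try:
            poly = sp.Poly(sp.expand(expr), *syms)
        except sp.PolynomialError as exc:
            raise ValueError(f"not a polynomial in its symbols: {expr}") from exc
        names = [s.name for s in syms]
        terms: dict[ExpKey, Fraction] = {}
        for exps, coeff in poly.terms():
            key = _normalize_key(dict(zip(names, exps)))
            terms[key] = terms.get(key, Fraction(0)) + Fraction(sp.Rational(coeff))
        return cls(terms)

    # -- ring operations ----------------------------------------------
    def __add__(self, other) -> "LabelPolynomial":
        other = _coerce(other)
        out = dict(self.terms)
        for k, c in other.terms.items():
            s = out.get(k, Fraction(0)) + c
            if s:
                out[k] = s
            else:
                out.pop(k, None)
        return LabelPolynomial(out)

    __radd__ = __add__

    def __neg__(self) -> "LabelPolynomial":
        return LabelPolynomial({k: -c for k, c in self.terms.items()})

    def __sub__(self, other) -> "LabelPolynomial":
        return self + (-_coerce(other))

    def __mul__(self, other) -> "LabelPolynomial":
        other = _coerce(other)
        out: dict[ExpKey, Fraction] = {}
        for k1, c1 in self.terms.items():
            d1 = dict(k1)
            for k2, c2 in other.terms.items():
                merged = dict(d1)
                for s, e in k2:
                    merged[s] = merged.get(s, 0) + e
                key = _normalize_key(merged)
                s_ = out.get(key, Fraction(0)) + c1 * c2
                if s_:
                    out[key] = s_
                else:
                    out.pop(key, None)
        return LabelPolynomial(out)

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "LabelPolynomial":
        if n < 0:
            raise ValueError("negative powers are not polynomials")
        result = LabelPolynomial.constant(1)
        base = self
        while n:
            if n & 1:
                result = result * base
            base = base * base
            n >>= 1
        return result

    def __eq__(self, other) -> bool:
        if isinstance(other, numbers.Number):
            other = LabelPolynomial.constant(other)
        if not isinstance(other, LabelPolynomial):
            return NotImplemented
        return self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    def __bool__(self) -> bool:
        return bool(self.terms)

    # -- queries -------------------------------------------------------
    @property
    def symbols(self) -> set[str]:
        out: set[str] = set()
        for k in self.terms:
            out.update(s for s, _ in k)
        return out

    def total_degrees(self) -> set[int]:
        return {sum(e for _, e in k) for k in self.terms}

    def degree(self) -> int:
        """Maximum total degree; -1 for the zero polynomial."""
        if not self.terms:
            return -1
        return max(sum(e for _, e in k) for k in self.terms)

    def max_degree(self, symbol: str) -> int:
        best = 0
        for k in self.terms:
            for s, e in k:
                if s == symbol and e > best:
                    best = e
        return best

    def evaluate(self, env: Mapping[str, float]):
        missing = self.symbols - set(env)
        if missing:
            raise KeyError(f"environment missing symbols: {sorted(missing)}")
        total = 0
        for k, c in self.terms.items():
            term = c if c.denominator != 1 else c.numerator
            for s, e in k:
                term = term * env[s] ** e
            total = total + term
        return total

    # -- conversion ----------------------------------------------------
    def to_expr(self) -> sp.Expr:
        out = sp.Integer(0)
        for k, c in self.terms.items():
            term = sp.Rational(c.numerator, c.denominator)
            for s, e in k:
                term *= sp.Symbol(s, positive=True) ** e
            out += term
        return out

    def sorted_terms(self) -> list[tuple[ExpKey, Fraction]]:
        """Graded-lex descending: higher total degree first, then by the
        exponent vector over lexicographically ordered symbols."""
        syms = sorted(self.symbols)

        def rank(item):
            key, _ = item
            d = dict(key)
            return (sum(d.values()), tuple(d.get(s, 0) for s in syms))

        return sorted(self.terms.items(), key=rank, reverse=True)

    def __str__(self) -> str:
        if not self.terms:
            return "0"
        parts = []
        for key, c in self.sorted_terms():
            factors = []
            if c != 1 or not key:
                factors.append(str(c))
            for s, e in key:
                factors.append(s if e == 1 else f"{s}^{e}")
            parts.append("*".join(factors))
        return " + ".join(parts)

    def __repr__(self) -> str:
        return f"LabelPolynomial({self})"

    def to_table(self) -> str:
        """TSV of (coefficient, exponent vector) rows, header first."""
        syms = sorted(self.symbols)
        lines = ["\t".join(["coefficient"] + syms)]
        for key, c in self.sorted_terms():
            d = dict(key)
            lines.append("\t".join([str(c)] + [str(d.get(s, 0)) for s in syms]))
        return "\n".join(lines)


def _coerce(x) -> LabelPolynomial:
    if isinstance(x, LabelPolynomial):
        return x
    if isinstance(x, numbers.Number):
        return LabelPolynomial.constant(x)
    raise TypeError(f"cannot coerce {type(x)!r} to LabelPolynomial")


def parse_polynomial(text: str) -> LabelPolynomial:
    """Parse the canonical string form (``^`` denotes powers)."""
    return LabelPolynomial.from_expr(sp.sympify(text.replace("^", "**")))


# -- module-level operations (thin wrappers) ---------------------------

def poly_add(p: LabelPolynomial, q: LabelPolynomial) -> LabelPolynomial:
    return _coerce(p) + _coerce(q)


def poly_mul(p: LabelPolynomial, q: LabelPolynomial) -> LabelPolynomial:
    return _coerce(p) * _coerce(q)


def poly_eval(p: LabelPolynomial, env: Mapping[str, float]):
    return _coerce(p).evaluate(env)


@dataclass(frozen=True)
class MonomialStatistics:
    distinct_count: int
    total_degrees: frozenset[int]
    max_degree_per_symbol: dict[str, int] = field(hash=False)
    coefficient_sum: Fraction = Fraction(0)


def monomial_statistics(p: LabelPolynomial) -> MonomialStatistics:
    """Counts of distinct monomials (like terms collected, nothing
    cancelled or factored out), the set of total degrees, the maximal
    exponent per symbol, and the sum of coefficients.

    For a matrix-tree polynomial the coefficient sum equals the number of
    spanning trees, since each tree contributes coefficient 1."""
    p = _coerce(p)
    return MonomialStatistics(
        distinct_count=len(p.terms),
        total_degrees=frozenset(p.total_degrees()),
        max_degree_per_symbol={s: p.max_degree(s) for s in sorted(p.symbols)},
        coefficient_sum=sum(p.terms.values(), Fraction(0)),
    )


def common_scalar_factor(ps: Iterable[LabelPolynomial]) -> LabelPolynomial:
    """Greatest common polynomial divisor of a list of non-zero polynomials.

    Normalised so that the leading coefficient under the canonical
    graded-lex term order is positive.  GCD extraction itself is delegated
    to sympy's multivariate polynomial GCD.
    """
    ps = [_coerce(p) for p in ps]
    if not ps:
        raise ValueError("empty polynomial list")
    if any(not p for p in ps):
        raise ValueError("zero polynomial has no well-defined scalar factor")
    g = ps[0].to_expr()
    for p in ps[1:]:
        g = sp.gcd(g, p.to_expr())
    out = LabelPolynomial.from_expr(sp.expand(g))
    lead = out.sorted_terms()[0][1]
    if lead < 0:
        out = -out
    return out


def exact_divide(p: LabelPolynomial, d: LabelPolynomial) -> LabelPolynomial:
    """Divide ``p`` by ``d``; raises ``ValueError`` on a non-zero remainder."""
    p, d = _coerce(p), _coerce(d)
    syms = sorted(p.symbols | d.symbols)
    gens = [sp.Symbol(s, positive=True) for s in syms] or [sp.Symbol("_x")]
    q, r = sp.div(p.to_expr(), d.to_expr(), *gens)
    if sp.expand(r) != 0:
        raise ValueError("division leaves a remainder")
    return LabelPolynomial.from_expr(sp.expand(q))
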