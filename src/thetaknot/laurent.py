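"""Integer Laurent polynomials in one formal variable A.

The value domain of every invariant in this package.  Arithmetic is exact
(Python integers); equality is coefficient-map equality.  Zero coefficients
are never stored.
"""

from __future__ import annotations

from typing import Iterable, Mapping


class LaurentPoly:
    """Immutable Laurent polynomial ``sum c_e * A**e`` with integer ``c_e``."""

    __slots__ = ("_c",)

    def __init__(self, coeffs: Mapping[int, int] | Iterable[tuple[int, int]] = ()):
        items = coeffs.items() if isinstance(coeffs, Mapping) else coeffs
        c: dict[int, int] = {}
        for e, v in items:
            if v:
                c[int(e)] = c.get(int(e), 0) + int(v)
                if not c[int(e)]:
                    del c[int(e)]
        self._c = c

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "LaurentPoly":
        return cls()

    @classmethod
    def one(cls) -> "LaurentPoly":
        return cls({0: 1})

    @classmethod
    def monomial(cls, exp: int, coef: int = 1) -> "LaurentPoly":
        return cls({exp: coef})

    # -- accessors ----------------------------------------------------
    def coeffs(self) -> dict[int, int]:
        return dict(self._c)

    def __bool__(self) -> bool:
        return bool(self._c)

    def is_zero(self) -> bool:
        return not self._c

    @property
    def min_exp(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return min(self._c)

    @property
    def max_exp(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return max(self._c)

    def __getitem__(self, exp: int) -> int:
        return self._c.get(exp, 0)

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "LaurentPoly | int") -> "LaurentPoly":
        other = _coerce(other)
        c = dict(self._c)
        for e, v in other._c.items():
            c[e] = c.get(e, 0) + v
            if not c[e]:
                del c[e]
        out = LaurentPoly.__new__(LaurentPoly)
        out._c = c
        return out

    __radd__ = __add__

    def __neg__(self) -> "LaurentPoly":
        out = LaurentPoly.__new__(LaurentPoly)
        out._c = {e: -v for e, v in self._c.items()}
        return out

    def __sub__(self, other: "LaurentPoly | int") -> "LaurentPoly":
        return self + (-_coerce(other))

    def __rsub__(self, other: int) -> "LaurentPoly":
        return _coerce(other) - self

    def __mul__(self, other: "LaurentPoly | int") -> "LaurentPoly":
        other = _coerce(other)
        c: dict[int, int] = {}
        for e1, v1 in self._c.items():
            for e2, v2 in other._c.items():
                e = e1 + e2
                c[e] = c.get(e, 0) + v1 * v2
        out = LaurentPoly.__new__(LaurentPoly)
        out._c = {e: v for e, v in c.items() if v}
        return out

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "LaurentPoly":
        if n < 0:
            raise ValueError("negative powers of polynomials are not defined")
        out = LaurentPoly.one()
        base = self
        while n:
            if n & 1:
                out = out * base
            base = base * base
            n >>= 1
        return out

    def shift(self, exp: int) -> "LaurentPoly":
        """Multiply by the monomial A**exp."""
        out = LaurentPoly.__new__(LaurentPoly)
        out._c = {e + exp: v for e, v in self._c.items()}
        return out

    def involution(self) -> "LaurentPoly":
        """The substitution A -> A**-1 (the mirror map on invariants)."""
        out = LaurentPoly.__new__(LaurentPoly)
        out._c = {-e: v for e, v in self._c.items()}
        return out

    def normalized(self) -> "LaurentPoly":
        """Quotient by units: divide by +/- A**n so the lowest exponent is 0
        and the lowest-degree coefficient is positive."""
        if not self._c:
            return self
        m = self.min_exp
        sgn = 1 if self._c[m] > 0 else -1
        out = LaurentPoly.__new__(LaurentPoly)
        out._c = {e - m: sgn * v for e, v in self._c.items()}
        return out

    # -- comparisons & hashing ---------------------------------------
    def key(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self._c.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, int):
            other = _coerce(other)
        if not isinstance(other, LaurentPoly):
            return NotImplemented
        return self._c == other._c

    def __hash__(self) -> int:
        return hash(self.key())

    # -- serialization ------------------------------------------------
    def to_json(self) -> dict[str, int]:
        return {str(e): v for e, v in sorted(self._c.items())}

    @classmethod
    def from_json(cls, d: Mapping[str, int]) -> "LaurentPoly":
        return cls({int(e): int(v) for e, v in d.items()})

    def __repr__(self) -> str:
        if not self._c:
            return "0"
        parts = []
        for e, v in sorted(self._c.items()):
            if e == 0:
                parts.append(f"{v:+d}")
            elif e == 1:
                parts.append(f"{v:+d}*A")
            else:
                parts.append(f"{v:+d}*A^{e}")
        return "".join(parts)


def _coerce(x: "LaurentPoly | int") -> LaurentPoly:
    if isinstance(x, LaurentPoly):
        return x
    return LaurentPoly({0: x})


#: A + A**-1, used throughout the state sums.
def a_plus_ainv() -> LaurentPoly:
    return LaurentPoly({1: 1, -1: 1})
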