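"""Table-driven arithmetic in the binary extension fields GF(2^m).

All element-wise operations accept plain integers or numpy integer arrays and
broadcast like numpy ufuncs.  Multiplication and division go through exp/log
tables, so a field instance supports vectorised work on whole codewords; this
is what makes the long outer Reed-Solomon code (m = 14, n = 16383) tractable.

Polynomials over the field are represented as 1-D integer arrays in
*ascending* power order (``p[i]`` is the coefficient of ``x**i``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["GF", "DEFAULT_PRIMITIVE_POLYS"]

#: Standard primitive polynomials, as integer bit masks (bit i = coeff of x^i).
DEFAULT_PRIMITIVE_POLYS = {
    2: 0b111,                # x^2+x+1
    3: 0b1011,               # x^3+x+1
    4: 0b10011,              # x^4+x+1
    6: 0b1000011,            # x^6+x+1
    8: 0x11D,                # x^8+x^4+x^3+x^2+1
    10: 0x409,               # x^10+x^3+1
    14: 0x4443,              # x^14+x^10+x^6+x+1
}


class GF:
    """The field GF(2^m) generated by a primitive polynomial.

    Parameters
    ----------
    m:
        Extension degree; symbols are m-bit integers in ``[0, 2^m)``.
    primitive_poly:
        Bit mask of a degree-m polynomial primitive over GF(2).  Defaults to a
        standard choice for the supported degrees.  Construction fails if the
        polynomial is not primitive (the generator must have order 2^m - 1).
    """

    def __init__(self, m: int, primitive_poly: int | None = None):
        if m < 2:
            raise ValueError("extension degree m must be >= 2")
        if primitive_poly is None:
            try:
                primitive_poly = DEFAULT_PRIMITIVE_POLYS[m]
            except KeyError:
                raise ValueError(f"no default primitive polynomial for m={m}")
        if primitive_poly.bit_length() != m + 1:
            raise ValueError("primitive_poly must have degree exactly m")
        self.m = m
        self.order = 1 << m
        self.q1 = self.order - 1  # multiplicative group size
        self.primitive_poly = primitive_poly

        exp = np.zeros(2 * self.q1, dtype=np.int64)
        log = np.full(self.order, -1, dtype=np.int64)
        x = 1
        for i in range(self.q1):
            if log[x] != -1:  # cycle shorter than 2^m - 1
                raise ValueError(f"polynomial {primitive_poly:#x} is not primitive")
            exp[i] = x
            log[x] = i
            x <<= 1
            if x & self.order:
                x ^= primitive_poly
        if x != 1:
            raise ValueError(f"polynomial {primitive_poly:#x} is not primitive")
        exp[self.q1:] = exp[: self.q1]
        log[0] = 0  # sentinel; zero operands are masked in mul/div
        self.exp = exp
        self.log = log

    # ------------------------------------------------------------------
    # element-wise arithmetic (addition is plain XOR, left to the caller)
    # ------------------------------------------------------------------
    def _check(self, a) -> np.ndarray:
        a = np.asarray(a, dtype=np.int64)
        if a.size and (a.min() < 0 or a.max() >= self.order):
            raise ValueError(f"element out of range for GF(2^{self.m})")
        return a

    def mul(self, a, b):
        """Product a*b, broadcasting over arrays; integer in → integer out."""
        a = self._check(a)
        b = self._check(b)
        out = self.exp[self.log[a] + self.log[b]]
        out = np.where((a == 0) | (b == 0), 0, out)
        return int(out) if out.ndim == 0 else out

    def div(self, a, b):
        a = self._check(a)
        b = self._check(b)
        if np.any(b == 0):
            raise ZeroDivisionError("division by zero in GF")
        out = self.exp[self.log[a] - self.log[b] + self.q1]
        out = np.where(a == 0, 0, out)
        return int(out) if out.ndim == 0 else out

    def inv(self, a):
        return self.div(1, a)

    def pow(self, a, e: int):
        """a**e with integer exponent (negative allowed for nonzero a)."""
        a = self._check(a)
        if np.any(a == 0):
            if np.ndim(a) == 0:
                if e == 0:
                    return 1
                if e < 0:
                    raise ZeroDivisionError("0 to a negative power")
                return 0
        out = self.exp[(self.log[a] * (e % self.q1)) % self.q1]
        out = np.where(np.asarray(a) == 0, 0 if e != 0 else 1, out)
        return int(out) if out.ndim == 0 else out

    def alpha_pow(self, e):
        """alpha**e for the primitive element alpha (e any integer array)."""
        e = np.asarray(e, dtype=np.int64)
        out = self.exp[e % self.q1]
        return int(out) if out.ndim == 0 else out

    # ------------------------------------------------------------------
    # polynomial helpers (ascending coefficient order)
    # ------------------------------------------------------------------
    def poly_eval(self, p, xs):
        """Evaluate polynomial ``p`` at each point of ``xs`` (Horner)."""
        xs = np.asarray(xs, dtype=np.int64)
        res = np.zeros_like(xs)
        for c in np.asarray(p, dtype=np.int64)[::-1]:
            res = np.asarray(self.mul(res, xs))
            if c:
                res = res ^ int(c)
        return int(res) if res.ndim == 0 else res

    def poly_mul(self, a, b):
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        res = np.zeros(len(a) + len(b) - 1, dtype=np.int64)
        # iterate over the shorter operand
        if len(a) > len(b):
            a, b = b, a
        for i, c in enumerate(a):
            if c:
                res[i : i + len(b)] ^= np.asarray(self.mul(int(c), b))
        return res

    def poly_mul_mod_xd(self, a, b, d: int):
        """(a*b) mod x^d — truncated product, used for key-equation work."""
        a = np.asarray(a, dtype=np.int64)[:d]
        b = np.asarray(b, dtype=np.int64)[:d]
        res = np.zeros(d, dtype=np.int64)
        if len(a) > len(b):
            a, b = b, a
        for i, c in enumerate(a):
            if c:
                seg = b[: d - i]
                res[i : i + len(seg)] ^= np.asarray(self.mul(int(c), seg))
        return res

    @staticmethod
    def poly_deg(p) -> int:
        """Degree of p (-1 for the zero polynomial)."""
        nz = np.nonzero(np.asarray(p))[0]
        return int(nz[-1]) if len(nz) else -1

    def poly_formal_derivative(self, p):
        """d/dx in characteristic 2: odd-degree terms survive, shifted down."""
        p = np.asarray(p, dtype=np.int64)
        if len(p) <= 1:
            return np.zeros(1, dtype=np.int64)
        d = np.zeros(len(p) - 1, dtype=np.int64)
        d[0::2] = p[1::2]  # coefficient of x^(2j) <- p[2j+1]
        return d

    def __repr__(self):  # pragma: no cover
        return f"GF(2^{self.m}, poly={self.primitive_poly:#x})"
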