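"""Systematic Reed-Solomon codes with errors-and-erasures decoding.

One engine serves both halves of the concatenated scheme: the short inner
code RS(20, 18) over GF(2^6) protecting each 60-nt oligo, and the long outer
code RS(16383, 10977) over GF(2^14) protecting the pool of oligos against
lost and mis-reconstructed sequences.  Codes with n < 2^m - 1 are plain
shortened codes (the generator polynomial only depends on n - k).

Codeword layout is systematic: ``codeword[:k]`` are the message symbols and
``codeword[k:]`` the parity symbols.  Internally ``codeword[i]`` is the
coefficient of ``x^(n-1-i)``, so position i has locator ``alpha^(n-1-i)``.

The decoder is classic Berlekamp-Massey on erasure-modified syndromes with
Forney value computation.  It either returns the corrected message or raises
:class:`RSDecodeError`; it never silently emits a corrupted message, because
the corrected word is re-checked against all syndromes before returning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gf import GF

__all__ = ["ReedSolomon", "RSDecodeError", "DecodeResult"]


class RSDecodeError(Exception):
    """Raised when a received word is outside the decoding radius or the
    key-equation solution is inconsistent."""


@dataclass(frozen=True)
class DecodeResult:
    message: np.ndarray
    n_errors_corrected: int
    n_erasures_filled: int


class ReedSolomon:
    """RS(n, k) over ``field`` with generator roots alpha^b .. alpha^(b+n-k-1).

    Parameters
    ----------
    field:
        A :class:`~oligocode.gf.GF` instance.
    n, k:
        Codeword and message length in symbols, ``1 <= k < n <= 2^m - 1``.
    first_root:
        Offset ``b`` of the first consecutive generator root (1 = narrow
        sense, the conventional default).
    """

    def __init__(self, field: GF, n: int, k: int, first_root: int = 1):
        if not (1 <= k < n <= field.q1):
            raise ValueError(f"need 1 <= k < n <= {field.q1}, got n={n}, k={k}")
        self.field = field
        self.n = n
        self.k = k
        self.d = n - k  # number of parity symbols
        self.b = first_root
        # generator polynomial, ascending order, monic of degree n-k
        g = np.array([1], dtype=np.int64)
        for j in range(first_root, first_root + self.d):
            g = field.poly_mul(g, np.array([field.alpha_pow(j), 1], dtype=np.int64))
        self.generator = g

    # ------------------------------------------------------------------
    def encode(self, message) -> np.ndarray:
        """Systematic encoding: message followed by n-k parity symbols."""
        f = self.field
        msg = np.asarray(message, dtype=np.int64)
        if msg.shape != (self.k,):
            raise ValueError(f"message must have exactly k={self.k} symbols")
        if msg.size and (msg.min() < 0 or msg.max() >= f.order):
            raise ValueError("message symbol out of field range")
        # synthetic division of m(x) * x^(n-k) by the generator; reg holds the
        # running remainder in ascending order
        reg = np.zeros(self.d, dtype=np.int64)
        glow = self.generator[: self.d]
        for s in msg:
            feedback = int(s) ^ int(reg[self.d - 1])
            reg[1:] = reg[:-1]
            reg[0] = 0
            if feedback:
                reg ^= np.asarray(f.mul(feedback, glow))
        cw = np.empty(self.n, dtype=np.int64)
        cw[: self.k] = msg
        cw[self.k :] = reg[::-1]  # parity stored highest power first
        return cw

    def syndromes(self, word) -> np.ndarray:
        """S_j = r(alpha^(b+j)) for j = 0..n-k-1 (all zero for codewords)."""
        f = self.field
        points = f.alpha_pow(np.arange(self.b, self.b + self.d))
        # word[i] is the coefficient of x^(n-1-i): Horner straight down word
        res = np.zeros(self.d, dtype=np.int64)
        for c in np.asarray(word, dtype=np.int64):
            res = np.asarray(f.mul(res, points))
            if c:
                res ^= int(c)
        return res

    # ------------------------------------------------------------------
    def decode(self, received, erasures=()) -> DecodeResult:
        """Correct ``received`` in place of up to e errors and eps erasures
        with ``2e + eps <= n - k``; returns the message or raises.

        ``erasures`` are positions (array indices) whose values are unknown;
        they are zero-filled before decoding.
        """
        f = self.field
        word = np.array(received, dtype=np.int64)
        if word.shape != (self.n,):
            raise ValueError(f"received word must have n={self.n} symbols")
        if word.size and (word.min() < 0 or word.max() >= f.order):
            raise ValueError("received symbol out of field range")
        era = sorted(set(int(p) for p in erasures))
        if era and (era[0] < 0 or era[-1] >= self.n):
            raise ValueError("erasure position out of range")
        eps = len(era)
        if eps > self.d:
            raise RSDecodeError(f"{eps} erasures exceed n-k = {self.d}")
        word[era] = 0

        S = self.syndromes(word)
        if not S.any():
            # already a codeword: zero-filling the erasures was consistent
            return DecodeResult(word[: self.k], 0, eps)

        # erasure locator Gamma(x) = prod (1 + X_i x), X_i = alpha^(n-1-pos)
        era_locs = [f.alpha_pow(self.n - 1 - p) for p in era]
        gamma = np.array([1], dtype=np.int64)
        for X in era_locs:
            gamma = f.poly_mul(gamma, np.array([1, X], dtype=np.int64))

        # modified syndromes Xi = S(x) * Gamma(x) mod x^d
        xi = f.poly_mul_mod_xd(S, gamma, self.d)

        lam = self._berlekamp_massey(xi, eps)
        e_deg = GF.poly_deg(lam)
        if 2 * e_deg > self.d - eps:
            raise RSDecodeError("error locator degree exceeds decoding radius")

        # roots of Lambda give the error positions
        err_locs: list[int] = []
        if e_deg > 0:
            powers = np.arange(self.n, dtype=np.int64)
            vals = f.poly_eval(lam[: e_deg + 1], f.alpha_pow(-powers))
            roots = np.nonzero(np.asarray(vals) == 0)[0]
            if len(roots) != e_deg:
                raise RSDecodeError("error locator has wrong number of roots")
            err_locs = [int(p) for p in roots]  # powers of the locators
            if set(self.n - 1 - p for p in err_locs) & set(era):
                raise RSDecodeError("error location collides with an erasure")

        # Psi = Lambda * Gamma covers both errors and erasures
        psi = f.poly_mul(lam[: max(e_deg + 1, 1)], gamma)
        omega = f.poly_mul_mod_xd(S, psi, self.d)
        dpsi = f.poly_formal_derivative(psi)

        all_powers = np.array(
            err_locs + [self.n - 1 - p for p in era], dtype=np.int64
        )
        inv_locs = f.alpha_pow(-all_powers)
        num = np.asarray(f.poly_eval(omega, inv_locs))
        den = np.asarray(f.poly_eval(dpsi, inv_locs))
        if np.any(den == 0):
            raise RSDecodeError("Forney denominator vanished")
        # narrow-sense (b=1) Forney value: e_i = X_i^(1-b) Omega(1/X_i)/Psi'(1/X_i)
        mags = np.asarray(f.mul(f.div(num, den), f.alpha_pow(all_powers * (1 - self.b))))

        n_err = 0
        for p, mag in zip(all_powers, mags):
            pos = self.n - 1 - int(p)
            word[pos] ^= int(mag)
            if pos not in era and mag:
                n_err += 1

        if self.syndromes(word).any():
            raise RSDecodeError("corrected word fails the syndrome re-check")
        return DecodeResult(word[: self.k], n_err, eps)

    # ------------------------------------------------------------------
    def _berlekamp_massey(self, xi: np.ndarray, eps: int) -> np.ndarray:
        """Find the error locator from erasure-modified syndromes.

        Iterates over xi[eps:], i.e. Berlekamp-Massey started after the
        erasure prefix, so Lambda only locates the unknown-position errors.
        """
        f = self.field
        d = self.d
        lam = np.zeros(d + 1, dtype=np.int64)
        prev = np.zeros(d + 1, dtype=np.int64)
        lam[0] = 1
        prev[0] = 1
        L = 0
        m = 1
        bb = 1
        for r in range(eps, d):
            # discrepancy = sum_j lam[j] * xi[r-j], over the shifted sequence
            # xi[eps:], so indices never reach into the erasure prefix
            hi = min(L, r - eps)
            seg = xi[r - hi : r + 1][::-1]
            delta = 0
            prod = np.asarray(f.mul(lam[: hi + 1], seg))
            for v in prod:
                delta ^= int(v)
            if delta == 0:
                m += 1
                continue
            coef = f.div(delta, bb)
            shifted = np.zeros(d + 1, dtype=np.int64)
            shifted[m:] = prev[: d + 1 - m]
            cand = lam ^ np.asarray(f.mul(coef, shifted))
            if 2 * L <= r - eps:
                prev = lam
                L = r - eps + 1 - L
                bb = delta
                m = 1
            else:
                m += 1
            lam = cand
        return lam
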