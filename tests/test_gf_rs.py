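"""Field arithmetic and Reed-Solomon codec, checked against independent
schoolbook oracles and exhaustive small-instance enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligocode.gf import GF
from oligocode.rs import ReedSolomon, RSDecodeError

# ---------------------------------------------------------------------------
# independent schoolbook GF(2^m) arithmetic (no tables, shared with nothing)
# ---------------------------------------------------------------------------


def slow_gf_mul(a: int, b: int, m: int, poly: int) -> int:
    """Carry-less multiply then reduce modulo the primitive polynomial."""
    a, b = int(a), int(b)
    prod = 0
    while b:
        if b & 1:
            prod ^= a
        a <<= 1
        b >>= 1
    for shift in range(prod.bit_length() - 1, m - 1, -1):
        if prod >> shift & 1:
            prod ^= poly << (shift - m)
    return prod


def slow_poly_divmod(num, den, m, poly):
    """Polynomial long division over GF(2^m); coefficients descending."""
    num = list(num)
    inv_lead = next(
        x for x in range(1, 1 << m) if slow_gf_mul(den[0], x, m, poly) == 1
    )
    for i in range(len(num) - len(den) + 1):
        coef = slow_gf_mul(num[i], inv_lead, m, poly)
        if coef:
            for j, d in enumerate(den):
                num[i + j] ^= slow_gf_mul(coef, d, m, poly)
    sep = len(num) - len(den) + 1
    return num[:sep], num[sep:]


def slow_rs_encode(msg, n, k, m, poly):
    """Systematic RS encoding via explicit polynomial long division."""
    # generator (x + alpha^1)...(x + alpha^(n-k)), coefficients descending
    gen = [1]
    root = 1
    for _ in range(n - k):
        root = slow_gf_mul(root, 2, m, poly)  # next power of alpha
        new = [0] * (len(gen) + 1)
        for i, c in enumerate(gen):
            new[i] ^= c  # times x
            new[i + 1] ^= slow_gf_mul(c, root, m, poly)
        gen = new
    _, rem = slow_poly_divmod(list(msg) + [0] * (n - k), gen, m, poly)
    return list(msg) + rem


@pytest.mark.parametrize("m", [3, 6, 8, 14])
def test_exp_log_roundtrip_and_axioms(m):
    f = GF(m)
    xs = np.arange(1, f.order)
    assert np.array_equal(f.exp[f.log[xs]], xs)
    rng = np.random.default_rng(m)
    a, b, c = (rng.integers(0, f.order, 300) for _ in range(3))
    assert np.array_equal(f.mul(a, f.mul(b, c)), f.mul(f.mul(a, b), c))
    assert np.array_equal(f.mul(a, b ^ c), f.mul(a, b) ^ f.mul(a, c))
    assert np.array_equal(f.mul(a, np.ones_like(a)), a)
    assert np.all(f.mul(a, np.zeros_like(a)) == 0)


def test_alpha_has_full_order_in_gf64():
    """alpha^63 = 1 and alpha^i != 1 for 0 < i < 63, by brute multiplication."""
    f = GF(6)
    x = 2  # alpha
    seen = set()
    for i in range(1, 63):
        assert x != 1
        seen.add(x)
        x = f.mul(x, 2)
    assert x == 1
    assert len(seen) == 62


def test_non_primitive_polynomial_rejected():
    with pytest.raises(ValueError):
        GF(4, 0b11111)  # x^4+x^3+x^2+x+1 divides x^5-1: order 5, not primitive


def test_element_range_checked():
    f = GF(3)
    with pytest.raises(ValueError):
        f.mul(8, 1)


@pytest.mark.parametrize("m,n,k", [(3, 7, 3), (6, 20, 18), (6, 63, 45)])
def test_encode_matches_schoolbook_division(m, n, k):
    f = GF(m)
    rs = ReedSolomon(f, n, k)
    rng = np.random.default_rng(1)
    for _ in range(20):
        msg = rng.integers(0, f.order, k)
        cw = rs.encode(msg)
        ref = slow_rs_encode(list(msg), n, k, m, f.primitive_poly)
        assert list(cw) == ref
        assert not rs.syndromes(cw).any()


def test_encode_agrees_with_oracle_rs255():
    """RS(255,223) over GF(2^8): 100 random messages against the schoolbook
    long-division oracle (the independent reference implementation)."""
    f = GF(8)
    rs = ReedSolomon(f, 255, 223)
    rng = np.random.default_rng(2)
    for _ in range(100):
        msg = rng.integers(0, 256, 223)
        assert list(rs.encode(msg)) == slow_rs_encode(list(msg), 255, 223, 8, f.primitive_poly)


def test_all_zero_message_encodes_to_zero():
    rs = ReedSolomon(GF(3), 7, 3)
    assert not rs.encode(np.zeros(3, dtype=int)).any()


def test_rs73_exhaustive_up_to_two_errors():
    """Every <=2-symbol error pattern on a fixed RS(7,3) codeword corrects."""
    rs = ReedSolomon(GF(3), 7, 3)
    msg = np.array([1, 5, 3])
    cw = rs.encode(msg)
    for npos in (1, 2):
        for poss in itertools.combinations(range(7), npos):
            for vals in itertools.product(range(1, 8), repeat=npos):
                w = cw.copy()
                for p, v in zip(poss, vals):
                    w[p] ^= v
                res = rs.decode(w)
                assert np.array_equal(res.message, msg)
                assert res.n_errors_corrected == npos


def test_rs73_exhaustive_erasures_and_mixes():
    rs = ReedSolomon(GF(3), 7, 3)
    msg = np.array([6, 0, 2])
    cw = rs.encode(msg)
    for poss in itertools.combinations(range(7), 4):  # eps = n-k
        assert np.array_equal(rs.decode(cw.copy(), erasures=poss).message, msg)
    for ep in itertools.combinations(range(7), 2):  # 1 error + 2 erasures
        for p in set(range(7)) - set(ep):
            for v in range(1, 8):
                w = cw.copy()
                w[p] ^= v
                assert np.array_equal(rs.decode(w, erasures=ep).message, msg)


def test_rs2018_exhaustive_single_errors_and_double_erasures():
    """The inner code corrects any single symbol error and fills any two
    erasures (exhaustive over 20*63 single-error patterns)."""
    f = GF(6)
    rs = ReedSolomon(f, 20, 18)
    rng = np.random.default_rng(3)
    msg = rng.integers(0, 64, 18)
    cw = rs.encode(msg)
    for p in range(20):
        for v in range(1, 64):
            w = cw.copy()
            w[p] ^= v
            res = rs.decode(w)
            assert np.array_equal(res.message, msg)
            assert res.n_errors_corrected == 1
    for pp in itertools.combinations(range(20), 2):
        assert np.array_equal(rs.decode(cw.copy(), erasures=pp).message, msg)


def test_decoding_radius_randomized_rs63():
    """RS(63,45): 1000 random error/erasure mixes with 2e + eps <= 18 all
    decode to the transmitted message."""
    f = GF(6)
    rs = ReedSolomon(f, 63, 45)
    rng = np.random.default_rng(4)
    for t in range(1000):
        msg = rng.integers(0, 64, 45)
        cw = rs.encode(msg)
        eps = int(rng.integers(0, 19))
        e = int(rng.integers(0, (18 - eps) // 2 + 1))
        pos = rng.choice(63, eps + e, replace=False)
        w = cw.copy()
        for p in pos[eps:]:
            w[p] ^= rng.integers(1, 64)
        res = rs.decode(w, erasures=pos[:eps])
        assert np.array_equal(res.message, msg)
        assert res.n_erasures_filled == eps


def test_too_many_erasures_fail_immediately():
    rs = ReedSolomon(GF(3), 7, 3)
    with pytest.raises(RSDecodeError):
        rs.decode(rs.encode([1, 2, 3]), erasures=range(5))


def test_failure_is_explicit_not_silent():
    """Far beyond the radius the decoder raises or lands on a *valid*
    codeword (bounded-distance miscorrection); it never returns a word with
    nonzero syndromes."""
    rs = ReedSolomon(GF(3), 7, 3)
    cw = rs.encode(np.array([1, 5, 3]))
    rng = np.random.default_rng(5)
    for _ in range(200):
        w = cw.copy()
        for p in rng.choice(7, 3, replace=False):
            w[p] ^= rng.integers(1, 8)
        try:
            res = rs.decode(w)
        except RSDecodeError:
            continue
        assert not rs.syndromes(rs.encode(res.message)).any()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 63), min_size=18, max_size=18), st.data())
def test_encode_decode_identity_property(msg, data):
    """Noiseless encode-decode identity on random inner-code messages."""
    rs = ReedSolomon(GF(6), 20, 18)
    cw = rs.encode(np.array(msg))
    res = rs.decode(cw)
    assert np.array_equal(res.message, np.array(msg))
    assert res.n_errors_corrected == 0
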