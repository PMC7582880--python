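"""File <-> oligo codec: framing, scrambling, index layout, inner/outer
codes and the noiseless roundtrip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligocode.codec import (
    CapacityError,
    CodeParams,
    assemble_sequence,
    decode_file,
    disassemble_sequence,
    encode_file,
    frame_payload,
    inner_decode,
    inner_decode_batch,
    outer_decode,
    outer_encode,
    scramble,
    unframe_payload,
)
from oligocode.rs import RSDecodeError


def test_default_code_arithmetic():
    p = CodeParams()
    assert p.outer_redundancy == 5406
    assert round(100 * p.erasure_tolerance) == 33
    assert p.raw_capacity_bytes == 245745
    assert round(p.net_density_bits_per_nt, 3) == 0.938
    assert p.inner_n * p.inner_m == 120  # bits per oligo
    assert p.capacity_bits == 922068
    # the printed 99,103-byte file fits: 64 + 8*99103 = 792888 <= 922068
    assert 64 + 8 * 99103 <= p.capacity_bits


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        CodeParams(n_oligos=100, k_oligos=100)
    with pytest.raises(ValueError):
        CodeParams(n_oligos=20000, k_oligos=10977)  # > 2^14 - 1


def test_scramble_is_involution_and_balanced():
    rng = np.random.default_rng(0)
    bits = rng.integers(0, 2, 840).astype(np.uint8)
    assert np.array_equal(scramble(scramble(bits, 7), 7), bits)
    assert not np.array_equal(scramble(bits, 7), bits)
    assert not np.array_equal(scramble(bits, 7), scramble(bits, 8))
    # keystream of the all-zero input is balanced: ~50% ones
    ks = scramble(np.zeros(8400, dtype=np.uint8), 123)
    assert 0.45 < ks.mean() < 0.55


def test_scrambled_rows_near_orthogonal():
    """Distinct rows scrambled with the same seed sit at ~50% Hamming
    distance (pseudorandomization makes oligos pairwise near-orthogonal)."""
    z = np.zeros(84, dtype=np.uint8)
    rows = [scramble(z, 0, first_row=r) for r in range(200)]
    rng = np.random.default_rng(1)
    d = [
        np.mean(rows[i] != rows[j])
        for i, j in rng.integers(0, 200, (300, 2))
        if i != j
    ]
    assert abs(np.mean(d) - 0.5) < 0.02


def test_frame_unframe_roundtrip(small_params):
    rng = np.random.default_rng(2)
    for size in (0, 1, 100, 1000):
        data = rng.integers(0, 256, size, dtype=np.uint8).tobytes()
        frame = frame_payload(data, small_params)
        assert frame.shape == (small_params.total_k, 84)
        assert unframe_payload(frame, small_params) == data
    empty = frame_payload(b"", small_params)
    assert not empty.any()


def test_capacity_error_names_bounds(small_params):
    too_big = bytes(small_params.capacity_bytes + 1)
    with pytest.raises(CapacityError, match="bytes"):
        frame_payload(too_big, small_params)


def test_outer_encode_systematic_and_redundancy(small_params):
    K, N = small_params.k_oligos, small_params.n_oligos
    frame = np.zeros((K, 84), dtype=np.uint8)
    rows = outer_encode(frame, small_params)
    assert rows.shape == (N, 84)
    assert not rows.any()  # linearity: zero in, zero out
    rng = np.random.default_rng(3)
    frame = rng.integers(0, 2, (K, 84)).astype(np.uint8)
    rows = outer_encode(frame, small_params)
    assert np.array_equal(rows[:K], frame)  # systematic
    assert rows.shape[0] - K == small_params.outer_redundancy


def test_index_region_constant_prefix():
    """For any index < 2^14 the first five index nucleotides (nt 40-44) are
    the constant ACAAC; the index occupies nt 40-51."""
    p = CodeParams()
    rng = np.random.default_rng(4)
    row = rng.integers(0, 2, 84).astype(np.uint8)
    for idx in (0, 1, 9999, 16382):
        seq = assemble_sequence(row, idx, p)
        assert len(seq) == 60
        assert seq[39:44] == "ACAAC"
    # two indices differ only inside nt 40-51
    a = assemble_sequence(row, 5, p)
    b = assemble_sequence(row, 6, p)
    diff = [i for i in range(60) if a[i] != b[i]]
    assert diff and all(39 <= i < 52 or i >= 54 for i in diff)  # parity may move too


def test_assemble_disassemble_roundtrip(small_params):
    rng = np.random.default_rng(5)
    for _ in range(20):
        row = rng.integers(0, 2, 84).astype(np.uint8)
        idx = int(rng.integers(0, small_params.total_n))
        seq = assemble_sequence(row, idx, small_params)
        row2, idx2 = disassemble_sequence(seq, small_params)
        assert idx2 == idx
        assert np.array_equal(row2, row)


def test_encode_file_shape_and_gc(small_params, small_file, small_oligos):
    assert len(small_oligos) == small_params.total_n
    assert all(len(s) == 60 for s in small_oligos.sequences)
    assert all(set(s) <= set("ACGT") for s in small_oligos.sequences)
    gc = np.mean(
        [(s.count("G") + s.count("C")) / 60 for s in small_oligos.sequences]
    )
    assert abs(gc - 0.5) < 0.02


def test_homopolymers_stay_short(small_oligos):
    """Randomization alone keeps homopolymer runs short (median max <= 8)."""
    import re

    maxruns = [
        max(len(m.group(0)) for m in re.finditer(r"(.)\1*", s))
        for s in small_oligos.sequences
    ]
    assert np.median(maxruns) <= 8


def test_noiseless_roundtrip(small_params, small_file, small_oligos):
    assert decode_file(small_oligos.sequences, small_params) == small_file


def test_noiseless_roundtrip_empty_and_single_byte(small_params):
    for data in (b"", b"\x42"):
        assert decode_file(encode_file(data, small_params).sequences, small_params) == data


def test_multi_block_roundtrip():
    p = CodeParams(n_oligos=255, k_oligos=171, blocks=2)
    data = np.random.default_rng(6).integers(0, 256, 3000, dtype=np.uint8).tobytes()
    oset = encode_file(data, p)
    assert len(oset) == 510
    _, idx = disassemble_sequence(oset.sequences[300], p)
    assert idx == 300  # block-offset indices are global
    assert decode_file(oset.sequences, p) == data


def test_inner_decode_corrects_any_single_substitution(small_params, small_oligos):
    seq = small_oligos.sequences[10]
    for pos in range(60):
        for b in "ACGT":
            if b == seq[pos]:
                continue
            cand = seq[:pos] + b + seq[pos + 1 :]
            res = inner_decode(cand, small_params)
            assert res is not None and res[0] == 10


def test_inner_decode_rejects_most_frameshifts(small_params, small_oligos):
    """A deleted nucleotide with 3' fill shifts every downstream symbol;
    the 2-parity inner code rejects the vast majority of such reads."""
    seq = small_oligos.sequences[3]
    rejected = 0
    accepted_wrong = 0
    for pos in range(59):
        cand = seq[:pos] + seq[pos + 1 :] + "C"
        res = inner_decode(cand, small_params)
        if res is None:
            rejected += 1
        elif res[0] != 3:
            accepted_wrong += 1
    assert rejected >= 0.9 * 59


def test_inner_decode_rejects_bad_alphabet_and_length(small_params):
    idx, rows, nc, ok = inner_decode_batch(["ACGT", "N" * 60], small_params)
    assert not ok.any()


def test_outer_decode_33pct_erasures(small_params, small_file, small_oligos):
    idx, rows, _, ok = inner_decode_batch(small_oligos.sequences, small_params)
    table = {int(i): rows[t] for t, i in enumerate(idx) if ok[t]}
    rng = np.random.default_rng(7)
    n_drop = int(0.33 * small_params.n_oligos)  # 84 <= n-k = 84
    for d in rng.choice(small_params.n_oligos, n_drop, replace=False):
        table.pop(int(d))
    data, stats = outer_decode(table, small_params)
    assert data == small_file
    assert all(s[1] == n_drop for s in stats)


def test_outer_decode_mixed_errors_and_erasures(small_params, small_file, small_oligos):
    """3.4% erased + 13.3% wrong rows still decode (2e + eps within n-k)."""
    idx, rows, _, ok = inner_decode_batch(small_oligos.sequences, small_params)
    table = {int(i): rows[t] for t, i in enumerate(idx) if ok[t]}
    rng = np.random.default_rng(8)
    N = small_params.n_oligos
    picks = rng.choice(N, int(0.034 * N) + int(0.133 * N), replace=False)
    for d in picks[: int(0.034 * N)]:
        table.pop(int(d))
    for w in picks[int(0.034 * N) :]:
        table[int(w)] = rng.integers(0, 2, 84).astype(np.uint8)
    data, _ = outer_decode(table, small_params)
    assert data == small_file


def test_outer_decode_beyond_radius_fails_with_diagnostics(small_params, small_oligos):
    idx, rows, _, ok = inner_decode_batch(small_oligos.sequences, small_params)
    table = {int(i): rows[t] for t, i in enumerate(idx) if ok[t]}
    rng = np.random.default_rng(9)
    for d in rng.choice(small_params.n_oligos, 100, replace=False):  # > n-k = 84
        table.pop(int(d))
    with pytest.raises(RSDecodeError, match="codeword"):
        outer_decode(table, small_params)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.binary(min_size=0, max_size=300))
def test_roundtrip_property_arbitrary_bytes(data):
    p = CodeParams(n_oligos=63, k_oligos=42)
    assert decode_file(encode_file(data, p).sequences, p) == data
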