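"""File <-> oligo transformation with the concatenated Reed-Solomon scheme.

A file is framed into K rows of 84 payload bits, pseudo-randomized row by
row, and protected by six interleaved outer RS(N, K) codewords over GF(2^14)
(row r contributes its j-th 14-bit block to codeword j).  Each of the N
resulting rows receives a masked 24-bit index and two inner RS(20, 18)
parity symbols over GF(2^6), and the 120 bits are mapped to a 60-nt DNA
sequence via 00->A, 01->C, 10->G, 11->T.

The index sits mid-sequence (nt 40-51), where synthesis error rates are
lower than at the ends; because only indices below 2^14 per block are used,
the first five index nucleotides are the constant ACAAC.  Files larger than
one outer code block are split into independent (N, K) blocks with
block-offset indices.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field, replace

import numpy as np

from .gf import GF
from .rs import ReedSolomon, RSDecodeError

__all__ = [
    "CodeParams",
    "OligoSet",
    "CapacityError",
    "scramble",
    "frame_payload",
    "unframe_payload",
    "outer_encode",
    "assemble_sequence",
    "disassemble_sequence",
    "encode_file",
    "inner_decode",
    "inner_decode_batch",
    "outer_decode",
    "decode_file",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

# Default 24-bit index mask.  The top 10 bits spell ACAAC under the 2-bit
# base map, so any index < 2^14 leaves the first five index nucleotides at
# that constant; the low 14 bits are an arbitrary fixed constant that keeps
# the index region from being a plain counter.
ACAAC_BITS = 0b0001000001
DEFAULT_INDEX_MASK = (ACAAC_BITS << 14) | 0b10101001010101


class CapacityError(ValueError):
    """File does not fit the code's payload capacity."""


@dataclass(frozen=True)
class CodeParams:
    """All code dimensions and layout constants.

    Defaults are the full-scale configuration: N = 16,383 oligos of which
    K = 10,977 carry payload, i.e. 1 - K/N = 33% of the oligos may be lost
    without affecting recovery.  ``blocks`` stacks independent outer code
    blocks for larger files (indices are block-offset).
    """

    n_oligos: int = 16383          # N, per block
    k_oligos: int = 10977          # K, per block
    blocks: int = 1
    scramble_seed: int = 0
    index_mask: int = DEFAULT_INDEX_MASK
    outer_m: int = 14              # outer symbol size (bits)
    inner_m: int = 6               # inner symbol size (bits)
    inner_n: int = 20
    inner_k: int = 18
    index_bits: int = 24
    oligo_len_nt: int = 60
    n_outer_codewords: int = 6

    def __post_init__(self):
        if not (1 <= self.k_oligos < self.n_oligos <= (1 << self.outer_m) - 1):
            raise ValueError("need 1 <= K < N <= 2^outer_m - 1")
        if self.inner_n * self.inner_m != 2 * self.oligo_len_nt:
            raise ValueError("inner code must fill the oligo exactly")
        if self.index_bits + self.payload_bits_per_seq != self.inner_k * self.inner_m:
            raise ValueError("index + payload bits must fill the inner message")
        if self.blocks < 1 or self.blocks * self.n_oligos > 1 << self.index_bits:
            raise ValueError("total oligo count exceeds index space")

    # --- derived quantities -------------------------------------------------
    @property
    def payload_bits_per_seq(self) -> int:
        return self.n_outer_codewords * self.outer_m  # 6 * 14 = 84

    @property
    def total_n(self) -> int:
        return self.blocks * self.n_oligos

    @property
    def total_k(self) -> int:
        return self.blocks * self.k_oligos

    @property
    def outer_redundancy(self) -> int:
        """Redundant oligos per block (5406 for the defaults)."""
        return self.n_oligos - self.k_oligos

    @property
    def erasure_tolerance(self) -> float:
        """Fraction of oligos that may be missing, 1 - K/N."""
        return 1.0 - self.k_oligos / self.n_oligos

    @property
    def capacity_bits(self) -> int:
        return self.total_k * self.payload_bits_per_seq

    @property
    def capacity_bytes(self) -> int:
        """Payload bytes after the 64-bit length header."""
        return (self.capacity_bits - 64) // 8

    @property
    def raw_capacity_bytes(self) -> int:
        """Upper bound without any redundancy: 2 bits per nucleotide."""
        return self.total_n * self.oligo_len_nt * 2 // 8

    @property
    def net_density_bits_per_nt(self) -> float:
        return self.capacity_bits / (self.total_n * self.oligo_len_nt)

    # --- code engines (cached lazily; dataclass is frozen) ------------------
    def outer_code(self) -> ReedSolomon:
        return _outer_code(self.outer_m, self.n_oligos, self.k_oligos)

    def inner_code(self) -> ReedSolomon:
        return _inner_code(self.inner_m, self.inner_n, self.inner_k)


_CODE_CACHE: dict[tuple, ReedSolomon] = {}


def _outer_code(m, n, k):
    key = ("outer", m, n, k)
    if key not in _CODE_CACHE:
        _CODE_CACHE[key] = ReedSolomon(GF(m), n, k)
    return _CODE_CACHE[key]


def _inner_code(m, n, k):
    key = ("inner", m, n, k)
    if key not in _CODE_CACHE:
        _CODE_CACHE[key] = ReedSolomon(GF(m), n, k)
    return _CODE_CACHE[key]


# ---------------------------------------------------------------------------
# bit helpers
# ---------------------------------------------------------------------------

def ints_to_bits(vals, width: int) -> np.ndarray:
    vals = np.asarray(vals, dtype=np.int64)
    shifts = np.arange(width - 1, -1, -1)
    return ((vals[..., None] >> shifts) & 1).astype(np.uint8)


def bits_to_ints(bits, width: int) -> np.ndarray:
    bits = np.asarray(bits, dtype=np.int64)
    w = 1 << np.arange(width - 1, -1, -1)
    return bits @ w


# ---------------------------------------------------------------------------
# pseudo-randomization
# ---------------------------------------------------------------------------

def _row_keystream(seed: int, row: int, nbits: int) -> np.ndarray:
    """Deterministic per-row keystream from a hash in counter mode."""
    out = np.empty(0, dtype=np.uint8)
    counter = 0
    while out.size < nbits:
        digest = hashlib.sha256(
            b"oligocode" + struct.pack(">qqq", seed, row, counter)
        ).digest()
        out = np.concatenate([out, np.unpackbits(np.frombuffer(digest, np.uint8))])
        counter += 1
    return out[:nbits]


def scramble(bits: np.ndarray, seed: int, first_row: int = 0, row_bits: int = 84) -> np.ndarray:
    """XOR ``bits`` with a seeded keystream, in 84-bit row blocks.

    An involution: applying twice with the same seed returns the input.
    Accepts a flat bit vector or an (R, row_bits) array.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    flat = bits.reshape(-1)
    out = flat.copy()
    nrows = -(-flat.size // row_bits)
    for r in range(nrows):
        lo = r * row_bits
        hi = min(lo + row_bits, flat.size)
        out[lo:hi] ^= _row_keystream(seed, first_row + r, hi - lo)
    return out.reshape(bits.shape)


# ---------------------------------------------------------------------------
# framing
# ---------------------------------------------------------------------------

def frame_payload(data: bytes, params: CodeParams) -> np.ndarray:
    """Pack file bytes into (total_K, 84) payload bit rows.

    Row 0 starts with a 64-bit big-endian byte count; trailing bits are
    zero-padded (randomization happens later, so the pad is invisible in
    the synthesized pool).
    """
    nbits = 64 + 8 * len(data)
    if nbits > params.capacity_bits:
        raise CapacityError(
            f"{len(data)} bytes need {nbits} bits but the code holds "
            f"{params.capacity_bits} payload bits ({params.capacity_bytes} bytes "
            f"after the header; raw 2-bit/nt bound {params.raw_capacity_bytes} bytes)"
        )
    header = np.unpackbits(np.frombuffer(struct.pack(">Q", len(data)), np.uint8))
    body = np.unpackbits(np.frombuffer(data, np.uint8))
    bits = np.zeros(params.capacity_bits, dtype=np.uint8)
    bits[:64] = header
    bits[64 : 64 + body.size] = body
    return bits.reshape(params.total_k, params.payload_bits_per_seq)


def unframe_payload(rows: np.ndarray, params: CodeParams) -> bytes:
    bits = np.asarray(rows, dtype=np.uint8).reshape(-1)
    nbytes = int(bits_to_ints(bits[:64], 64))
    if 64 + 8 * nbytes > bits.size:
        raise RSDecodeError(f"decoded length header {nbytes} exceeds capacity")
    body = bits[64 : 64 + 8 * nbytes]
    return np.packbits(body).tobytes()


# ---------------------------------------------------------------------------
# outer code across rows
# ---------------------------------------------------------------------------

def outer_encode(frame_rows: np.ndarray, params: CodeParams) -> np.ndarray:
    """(K, 84) payload bit rows -> (N, 84) rows for one block (systematic).

    Row r is read as six 14-bit symbols; symbol j of row r is message symbol
    r of outer codeword j.  Rows K..N-1 hold the parity symbols.
    """
    K, N = params.k_oligos, params.n_oligos
    ncw, m = params.n_outer_codewords, params.outer_m
    if frame_rows.shape != (K, params.payload_bits_per_seq):
        raise ValueError(f"expected ({K}, {params.payload_bits_per_seq}) bit rows")
    syms = bits_to_ints(frame_rows.reshape(K, ncw, m), m)  # (K, 6)
    code = params.outer_code()
    out = np.empty((N, ncw), dtype=np.int64)
    for j in range(ncw):
        out[:, j] = code.encode(syms[:, j])
    return ints_to_bits(out, m).reshape(N, params.payload_bits_per_seq)


# ---------------------------------------------------------------------------
# inner code, index layout and base mapping
# ---------------------------------------------------------------------------
# Inner message symbol layout (18 six-bit symbols):
#   [0:13]  payload symbols 1-13   (bits 0..77 of the 84-bit row)
#   [13:17] masked 24-bit index, big-endian
#   [17]    payload symbol 14      (bits 78..83)
# followed by 2 parity symbols.  This places the index at nt 40-51.
_PAYLOAD_SYM_COLS = list(range(13)) + [17]
_INDEX_SYM_COLS = [13, 14, 15, 16]


def _inner_encode_rows(data_syms: np.ndarray, params: CodeParams) -> np.ndarray:
    """Vectorised systematic RS(20,18) encoding of many 18-symbol rows."""
    code = params.inner_code()
    f = code.field
    g0, g1 = int(code.generator[0]), int(code.generator[1])
    R = data_syms.shape[0]
    reg0 = np.zeros(R, dtype=np.int64)  # coeff x^0
    reg1 = np.zeros(R, dtype=np.int64)  # coeff x^1
    for t in range(params.inner_k):
        fb = data_syms[:, t] ^ reg1
        reg1 = reg0 ^ np.asarray(f.mul(fb, g1))
        reg0 = np.asarray(f.mul(fb, g0))
    out = np.empty((R, params.inner_n), dtype=np.int64)
    out[:, : params.inner_k] = data_syms
    out[:, params.inner_k] = reg1
    out[:, params.inner_k + 1] = reg0
    return out


def _symbols_to_seqs(symbols: np.ndarray, params: CodeParams) -> list[str]:
    bits = ints_to_bits(symbols, params.inner_m).reshape(symbols.shape[0], -1)
    pairs = bits[:, 0::2] * 2 + bits[:, 1::2]
    chars = BASES[pairs]
    return [row.tobytes().decode("ascii") for row in chars]


def _seqs_to_symbols(seqs: list[str], params: CodeParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (C, 20) symbol array and a validity mask (length & alphabet)."""
    L = params.oligo_len_nt
    C = len(seqs)
    codes = np.full((C, L), 255, dtype=np.uint8)
    ok = np.zeros(C, dtype=bool)
    for i, s in enumerate(seqs):
        if len(s) != L:
            continue
        raw = _BASE_CODE[np.frombuffer(s.encode("ascii"), np.uint8)]
        if raw.max() == 255:
            continue
        codes[i] = raw
        ok[i] = True
    codes[~ok] = 0
    bits = np.empty((C, 2 * L), dtype=np.uint8)
    bits[:, 0::2] = codes >> 1
    bits[:, 1::2] = codes & 1
    syms = bits_to_ints(bits.reshape(C, params.inner_n, params.inner_m), params.inner_m)
    return syms, ok


def assemble_sequence(row_bits: np.ndarray, index: int, params: CodeParams) -> str:
    """Build one 60-nt oligo from an 84-bit payload row and its index."""
    return assemble_sequences(np.asarray(row_bits, np.uint8).reshape(1, -1),
                              np.array([index]), params)[0]


def assemble_sequences(rows_bits: np.ndarray, indices: np.ndarray, params: CodeParams) -> list[str]:
    rows_bits = np.asarray(rows_bits, dtype=np.uint8)
    indices = np.asarray(indices, dtype=np.int64)
    if rows_bits.shape[1] != params.payload_bits_per_seq:
        raise ValueError("payload rows must have 84 bits")
    if indices.min() < 0 or indices.max() >= 1 << params.index_bits:
        raise ValueError("index out of 24-bit range")
    R = rows_bits.shape[0]
    pay_syms = bits_to_ints(
        rows_bits.reshape(R, 14, params.inner_m), params.inner_m
    )  # (R, 14) six-bit symbols
    masked = indices ^ params.index_mask
    data = np.empty((R, params.inner_k), dtype=np.int64)
    data[:, _PAYLOAD_SYM_COLS] = pay_syms
    for t, col in enumerate(_INDEX_SYM_COLS):
        shift = params.inner_m * (3 - t)
        data[:, col] = (masked >> shift) & 0x3F
    cw = _inner_encode_rows(data, params)
    return _symbols_to_seqs(cw, params)


def disassemble_sequence(seq: str, params: CodeParams) -> tuple[np.ndarray, int]:
    """Inverse of :func:`assemble_sequence` for a clean oligo (no decoding)."""
    syms, ok = _seqs_to_symbols([seq], params)
    if not ok[0]:
        raise ValueError("sequence has wrong length or alphabet")
    row, idx, _ = _extract_row_index(syms, params)
    return row[0], int(idx[0])


def _extract_row_index(syms: np.ndarray, params: CodeParams):
    """Split (C, 20) symbols into payload bit rows, indices and parity."""
    C = syms.shape[0]
    pay = syms[:, _PAYLOAD_SYM_COLS]
    rows = ints_to_bits(pay, params.inner_m).reshape(C, -1)
    masked = np.zeros(C, dtype=np.int64)
    for t, col in enumerate(_INDEX_SYM_COLS):
        masked = (masked << params.inner_m) | syms[:, col]
    idx = masked ^ params.index_mask
    return rows, idx, syms[:, params.inner_k :]


# ---------------------------------------------------------------------------
# top-level encode
# ---------------------------------------------------------------------------

@dataclass
class OligoSet:
    """The ordered designed oligo pool; position i carries encoded index i."""

    sequences: list[str]
    params: CodeParams = field(default_factory=CodeParams)

    def __len__(self):
        return len(self.sequences)

    def write_fasta(self, path):
        with open(path, "w") as fh:
            for i, s in enumerate(self.sequences):
                fh.write(f">{i}\n{s}\n")

    @classmethod
    def read_fasta(cls, path, params: CodeParams | None = None) -> "OligoSet":
        from Bio import SeqIO

        records = sorted(SeqIO.parse(str(path), "fasta"), key=lambda r: int(r.id))
        return cls([str(r.seq) for r in records], params or CodeParams())


def encode_file(data: bytes, params: CodeParams | None = None) -> OligoSet:
    """Encode a file into N (per block) 60-nt oligos: frame -> scramble ->
    outer encode -> index + inner encode -> base map."""
    params = params or CodeParams()
    frame = frame_payload(data, params)
    scrambled = scramble(frame, params.scramble_seed)
    K, N = params.k_oligos, params.n_oligos
    seqs: list[str] = []
    for b in range(params.blocks):
        rows_n = outer_encode(scrambled[b * K : (b + 1) * K], params)
        gidx = b * N + np.arange(N, dtype=np.int64)
        seqs.extend(assemble_sequences(rows_n, gidx, params))
    return OligoSet(seqs, params)


# ---------------------------------------------------------------------------
# inner decode
# ---------------------------------------------------------------------------

def inner_decode_batch(candidates: list[str], params: CodeParams):
    """Vectorised inner decode of 60-nt candidates.

    Returns ``(indices, rows, n_corrected, ok)`` where ``ok`` marks
    candidates that decoded to a valid index (< total N).  The RS(20,18)
    inner code corrects at most one 6-bit symbol error; anything worse
    (typically a frameshift from an uncorrected indel) is rejected.
    """
    f = params.inner_code().field
    syms, ok = _seqs_to_symbols(candidates, params)
    C = syms.shape[0]
    # syndromes S1 = r(alpha), S2 = r(alpha^2), Horner down the 20 symbols
    a1 = f.alpha_pow(1)
    a2 = f.alpha_pow(2)
    s1 = np.zeros(C, dtype=np.int64)
    s2 = np.zeros(C, dtype=np.int64)
    for t in range(params.inner_n):
        c = syms[:, t]
        s1 = np.asarray(f.mul(s1, a1)) ^ c
        s2 = np.asarray(f.mul(s2, a2)) ^ c
    clean = (s1 == 0) & (s2 == 0)
    fixable = (s1 != 0) & (s2 != 0)
    # single error at locator X = S2/S1 with magnitude S1/X
    p = (f.log[s2] - f.log[s1]) % f.q1
    in_range = fixable & (p < params.inner_n)
    mag = np.where(in_range, f.exp[(f.log[s1] - p) % f.q1], 0)
    pos = np.where(in_range, params.inner_n - 1 - p, 0)
    rows_idx = np.arange(C)
    corrected = syms.copy()
    corrected[rows_idx[in_range], pos[in_range]] ^= mag[in_range]
    ok = ok & (clean | in_range)
    ncorr = np.where(clean, 0, 1)
    rows, idx, _ = _extract_row_index(corrected, params)
    ok = ok & (idx >= 0) & (idx < params.total_n)
    return idx, rows, ncorr, ok


def inner_decode(candidate: str, params: CodeParams | None = None):
    """Decode one candidate; returns (index, 84-bit row, n_corrected) or None."""
    params = params or CodeParams()
    idx, rows, ncorr, ok = inner_decode_batch([candidate], params)
    if not ok[0]:
        return None
    return int(idx[0]), rows[0], int(ncorr[0])


# ---------------------------------------------------------------------------
# outer decode
# ---------------------------------------------------------------------------

def outer_decode(rows: dict[int, np.ndarray], params: CodeParams | None = None):
    """Decode a partial index -> 84-bit-row table back to file bytes.

    Missing indices become erasures in all six outer codewords of their
    block; present-but-wrong rows are symbol errors.  Succeeds whenever each
    codeword satisfies 2e + erasures <= N - K, else raises
    :class:`~oligocode.rs.RSDecodeError` with per-codeword diagnostics.

    Returns ``(data, stats)`` with ``stats`` a list of per-codeword
    ``(n_errors, n_erasures)`` tuples across blocks.
    """
    params = params or CodeParams()
    K, N = params.k_oligos, params.n_oligos
    ncw, m = params.n_outer_codewords, params.outer_m
    code = params.outer_code()
    message_rows = np.zeros((params.total_k, params.payload_bits_per_seq), dtype=np.uint8)
    stats: list[tuple[int, int]] = []
    failures: list[str] = []
    for b in range(params.blocks):
        received = np.zeros((N, ncw), dtype=np.int64)
        present = np.zeros(N, dtype=bool)
        for gidx, bits in rows.items():
            if b * N <= gidx < (b + 1) * N:
                i = gidx - b * N
                received[i] = bits_to_ints(
                    np.asarray(bits, np.uint8).reshape(ncw, m), m
                )
                present[i] = True
        erasures = np.nonzero(~present)[0]
        msg = np.empty((K, ncw), dtype=np.int64)
        for j in range(ncw):
            try:
                res = code.decode(received[:, j], erasures)
            except RSDecodeError as e:
                stats.append((-1, len(erasures)))
                failures.append(f"block {b} codeword {j}: {e}")
                continue
            msg[:, j] = res.message
            stats.append((res.n_errors_corrected, res.n_erasures_filled))
        if failures:
            raise RSDecodeError(
                "outer decode failed: " + "; ".join(failures)
            )
        message_rows[b * K : (b + 1) * K] = ints_to_bits(msg, m).reshape(K, -1)
    frame = scramble(message_rows, params.scramble_seed)
    return unframe_payload(frame, params), stats


def decode_file(sequences: list[str], params: CodeParams | None = None) -> bytes:
    """Convenience noiseless path: inner-decode clean oligos and outer-decode.

    For noisy reads use :func:`oligocode.pipeline.reconstruct` instead.
    """
    params = params or CodeParams()
    idx, rws, _, ok = inner_decode_batch(sequences, params)
    table = {int(i): rws[t] for t, i in enumerate(idx) if ok[t]}
    data, _ = outer_decode(table, params)
    return data
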