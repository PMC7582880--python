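"""Monte-Carlo model of the synthesis + library-prep + sequencing channel.

Photolithographic (maskless array) synthesis is deletion-dominated:
per-sequence error counts are Poisson with means lambda_del = 7,
lambda_sub = 2 and lambda_ins = 3 over a 60-nt oligo, i.e. per-base
probabilities of 11.7%, 3.3% and 5.0%.  After synthesis one T is appended
(3' linker), and library preparation adds a C-rich tail (C:T = 5:1) that
becomes visible inside the fixed 60-nt sequencing window whenever deletions
have shortened the oligo — this is what produces the apparent 3' error
ramp without any position-dependent error rate.

Error positions are uniform along the sequence; deletions, then
substitutions, then insertions are applied, re-drawing positions on the
current sequence each time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelParams", "ReadSet", "corrupt_read", "sample_reads", "expected_error_rates"]

_BASES = "ACGT"


@dataclass(frozen=True)
class ChannelParams:
    """Channel configuration.  Defaults are the fitted synthesis rates."""

    lambda_del: float = 7.0    # mean deletions per 60-nt sequence
    lambda_sub: float = 2.0    # mean substitutions
    lambda_ins: float = 3.0    # mean insertions
    tail_ct_ratio: float = 5.0  # C:T ratio of the post-synthesis fill
    append_t: bool = True       # 3' T added during synthesis
    tail: bool = True           # C/T fill up to the window
    window_nt: int | None = 60  # fixed sequencing window (None = no truncation)
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_del, self.lambda_sub, self.lambda_ins) < 0:
            raise ValueError("Poisson means must be non-negative")
        if self.tail_ct_ratio <= 0:
            raise ValueError("tail C:T ratio must be positive")


@dataclass
class ReadSet:
    """Noisy reads with optional per-read source oligo id (simulator only)."""

    reads: list[str]
    provenance: np.ndarray | None = None

    def __post_init__(self):
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=np.int64)
            if len(self.provenance) != len(self.reads):
                raise ValueError("provenance must have one id per read")

    def __len__(self):
        return len(self.reads)

    def write_fastq(self, path):
        with open(path, "w") as fh:
            for i, r in enumerate(self.reads):
                fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")

    def write_txt(self, path):
        with open(path, "w") as fh:
            fh.write("\n".join(self.reads) + "\n")


def expected_error_rates(params: ChannelParams, ref_len: int = 60):
    """Per-base (p_del, p_sub, p_ins) implied by the Poisson means."""
    return (
        params.lambda_del / ref_len,
        params.lambda_sub / ref_len,
        params.lambda_ins / ref_len,
    )


def corrupt_read(oligo: str, params: ChannelParams, rng: np.random.Generator) -> str:
    """Draw one noisy read of ``oligo`` through the channel."""
    seq = list(oligo)
    ndel, nsub, nins = rng.poisson(
        (params.lambda_del, params.lambda_sub, params.lambda_ins)
    )
    if ndel:
        for p in sorted(
            rng.choice(len(seq), size=min(int(ndel), len(seq)), replace=False),
            reverse=True,
        ):
            del seq[p]
    if nsub and seq:
        for p in rng.choice(len(seq), size=min(int(nsub), len(seq)), replace=False):
            old = _BASES.index(seq[p])
            seq[p] = _BASES[(old + rng.integers(1, 4)) % 4]
    for _ in range(int(nins)):
        p = int(rng.integers(0, len(seq) + 1))
        seq.insert(p, _BASES[rng.integers(0, 4)])
    if params.append_t:
        seq.append("T")
    w = params.window_nt
    if w is not None:
        if params.tail and len(seq) < w:
            p_c = params.tail_ct_ratio / (params.tail_ct_ratio + 1.0)
            fill = rng.random(w - len(seq)) < p_c
            seq.extend("C" if c else "T" for c in fill)
        if len(seq) > w:
            seq = seq[:w]
    return "".join(seq)


def sample_reads(
    oligos,
    params: ChannelParams | None = None,
    coverage: float | None = 30.0,
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Simulate a read pool over an oligo set.

    Per-oligo read counts are negative binomial with the given mean coverage
    and ``params.coverage_dispersion`` (coverage is strongly inhomogeneous on
    a real array; zero-count oligos are a normal outcome).  Alternatively a
    total ``n_reads`` can be requested, with sources drawn uniformly.
    """
    params = params or ChannelParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seqs = getattr(oligos, "sequences", oligos)
    n = len(seqs)
    if n == 0:
        return ReadSet([], np.empty(0, dtype=np.int64))
    if n_reads is not None:
        sources = rng.integers(0, n, size=int(n_reads))
        counts = np.bincount(sources, minlength=n)
    else:
        if coverage is None or coverage <= 0:
            return ReadSet([], np.empty(0, dtype=np.int64))
        size = params.coverage_dispersion
        p = size / (size + coverage)
        counts = rng.negative_binomial(size, p, size=n)
    reads: list[str] = []
    provenance: list[int] = []
    for i in range(n):
        for _ in range(int(counts[i])):
            reads.append(corrupt_read(seqs[i], params, rng))
            provenance.append(i)
    return ReadSet(reads, np.asarray(provenance, dtype=np.int64))
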