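"""Candidate extraction from read clusters: subsampling, multiple alignment
and weighted-majority voting.

Clusters below five reads are discarded (too little signal at synthesis
error levels), clusters of 5-15 reads are aligned whole, and larger
clusters contribute five random subsets of 15 reads, each aligned and voted
separately.  The multiple alignment is a center-star progressive alignment
("once a gap, always a gap" relative to the center read), and the vote
weights A/C/G/T counts with 1.0 against 0.4 per gap — deletions are by far
the most common error, so a gap must outnumber a base 2.5:1 to win a
column.  Gap-win columns are dropped (they correspond to read insertions).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from ._align import decode_codes, encode_seq, nw_align_codes

__all__ = [
    "AlignmentMatrix",
    "CandidateSequence",
    "pairwise_align",
    "subsample_cluster",
    "center_star_msa",
    "weighted_majority",
    "consensus_call",
    "consensus_candidates",
]


@dataclass
class AlignmentMatrix:
    """Aligned reads over {A,C,G,T,-}; degapping row i recovers read i."""

    rows: list[str]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def codes(self) -> np.ndarray:
        lut = np.full(128, 255, dtype=np.uint8)
        for i, c in enumerate(b"ACGT-"):
            lut[c] = i
        return lut[
            np.frombuffer("".join(self.rows).encode("ascii"), np.uint8)
        ].reshape(len(self.rows), -1)


@dataclass
class CandidateSequence:
    sequence: str            # exactly target_len nt (trimmed)
    cluster_id: int = -1
    subsample_id: int = 0
    raw: str = ""            # untrimmed consensus, kept for frameshift repair


def pairwise_align(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -1):
    """Global alignment with linear gap cost and deterministic tie-breaking
    (diagonal, then gap in b, then gap in a).  Returns (a_aln, b_aln, score)."""
    ca, cb, score = nw_align_codes(
        encode_seq(a), encode_seq(b), np.int32(match), np.int32(mismatch), np.int32(gap)
    )
    return decode_codes(ca), decode_codes(cb), int(score)


def subsample_cluster(
    members,
    rng: np.random.Generator,
    min_reads: int = 5,
    max_reads: int = 15,
    n_subsets: int = 5,
) -> list[list]:
    """Read-id sets to align: [] below min_reads, everything up to max_reads,
    and n_subsets random subsets of max_reads for larger clusters."""
    members = list(members)
    if len(members) < min_reads:
        return []
    if len(members) <= max_reads:
        return [members]
    return [
        [members[i] for i in rng.choice(len(members), size=max_reads, replace=False)]
        for _ in range(n_subsets)
    ]


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def center_star_msa(reads: list[str], center: str | None = None) -> AlignmentMatrix:
    """Center-star multiple alignment.

    The center is the read minimizing total edit distance to all others
    (ties to the lowest index); every other read is pairwise-aligned to the
    center and the alignments are merged on center coordinates, so center
    gaps introduced by one read persist for all ("once a gap, always a gap").

    An explicit ``center`` string (e.g. a previous-round consensus) may be
    supplied instead; it then only provides the coordinate system and does
    not appear as an alignment row.
    """
    if not 2 <= len(reads) <= 64:
        raise ValueError("center-star MSA expects 2-64 reads")
    n = len(reads)
    c = -1
    if center is None:
        totals = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                d = _edit_distance(reads[i], reads[j])
                totals[i] += d
                totals[j] += d
        c = int(np.argmin(totals))
        center = reads[c]
    L = len(center)

    # per read: aligned char per center position, plus insertions before
    # each center position (index L = after the last base)
    per_read_chars: list[list[str]] = []
    per_read_ins: list[list[str]] = []
    for i, read in enumerate(reads):
        if i == c:
            per_read_chars.append(list(center))
            per_read_ins.append([""] * (L + 1))
            continue
        ca, ra, _ = pairwise_align(center, read)
        chars = [""] * L
        ins = [""] * (L + 1)
        p = 0
        for x, y in zip(ca, ra):
            if x == "-":
                ins[p] += y
            else:
                chars[p] = y
                p += 1
        per_read_chars.append(chars)
        per_read_ins.append(ins)

    ins_len = [max(len(per_read_ins[i][p]) for i in range(n)) for p in range(L + 1)]
    rows = []
    for i in range(n):
        parts = []
        for p in range(L + 1):
            g = ins_len[p]
            s = per_read_ins[i][p]
            parts.append(s + "-" * (g - len(s)))
            if p < L:
                parts.append(per_read_chars[i][p])
        rows.append("".join(parts))
    return AlignmentMatrix(rows)


_VOTE_ORDER = b"ACGT-"  # argmax tie-break: A < C < G < T, and a base beats a gap


def weighted_majority(
    alignment: AlignmentMatrix,
    base_weight: float = 1.0,
    gap_weight: float = 0.4,
    target_len: int | None = 60,
):
    """Column-wise weighted vote over an alignment.

    score(x) = base_weight * count(x) for x in {A,C,G,T} and
    gap_weight * count(-) for the gap; the winner is emitted, gap-win
    columns are dropped.  Results longer than ``target_len`` keep the first
    ``target_len`` nt; shorter results are rejected (None) since the inner
    code needs exactly 120 bits.
    """
    if not alignment.rows:
        return None
    codes = alignment.codes()
    counts = np.stack([(codes == v).sum(axis=0) for v in range(5)])
    scores = counts.astype(np.float64)
    scores[:4] *= base_weight
    scores[4] *= gap_weight
    winners = np.argmax(scores, axis=0)  # first max wins: A<C<G<T<gap
    cons = bytes(_VOTE_ORDER[w] for w in winners if w < 4).decode("ascii")
    if target_len is None:
        return cons
    if len(cons) < target_len:
        return None
    return cons[:target_len]


def consensus_call(reads: list[str], target_len: int | None = 60, n_refine: int = 2):
    """MSA + weighted vote with iterative refinement.

    After the first vote the consensus replaces the (noisy) center read as
    the alignment coordinate system and the vote is repeated; this corrects
    registration errors inherited from the initial center.  Stops early on
    a fixed point.
    """
    msa = center_star_msa(reads)
    cons = weighted_majority(msa, target_len=None)
    for _ in range(n_refine):
        if not cons:
            break
        msa = center_star_msa(reads, center=cons)
        new = weighted_majority(msa, target_len=None)
        if new == cons:
            break
        cons = new
    if cons is None or target_len is None:
        return cons
    if len(cons) < target_len:
        return None
    return cons[:target_len]


def consensus_candidates(
    cluster_reads: dict[int, list[str]],
    rng: np.random.Generator,
    min_reads: int = 5,
    max_reads: int = 15,
    n_subsets: int = 5,
    target_len: int = 60,
    n_refine: int = 2,
) -> list[CandidateSequence]:
    """Run subsample -> MSA -> vote over a {cluster_id: reads} mapping.

    For clusters that contributed several subset candidates, one extra
    meta-candidate (the consensus of the candidates themselves) is emitted;
    sparse independent errors in the subset candidates cancel there.
    """
    out: list[CandidateSequence] = []
    for cid in sorted(cluster_reads):
        reads = cluster_reads[cid]
        cands: list[str] = []
        for sid, subset in enumerate(
            subsample_cluster(range(len(reads)), rng, min_reads, max_reads, n_subsets)
        ):
            cons = consensus_call(
                [reads[i] for i in subset], target_len=None, n_refine=n_refine
            )
            if cons is not None and len(cons) >= target_len:
                out.append(CandidateSequence(cons[:target_len], cid, sid, raw=cons))
                cands.append(cons[:target_len])
        if len(cands) >= 2:
            meta = consensus_call(cands, target_len=None, n_refine=1)
            if meta is not None and len(meta) >= target_len:
                out.append(CandidateSequence(meta[:target_len], cid, n_subsets, raw=meta))
    return out
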