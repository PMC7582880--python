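"""End-to-end reconstruction: reads -> clusters -> candidates -> file.

Stages mirror the storage channel in reverse: trim reads to the 60-nt
window, cluster them, extract consensus candidates per cluster, inner-decode
the candidates (collating rows by index with a plurality vote), and
outer-decode the collated table with missing indices as erasures.  The
:class:`DecodeReport` carries counts from every stage; on outer-decode
failure no partial file is emitted.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .channel import ReadSet
from .clustering import cluster_by_prefix, cluster_lsh
from .codec import CodeParams, OligoSet, inner_decode_batch, outer_decode
from .consensus import CandidateSequence, consensus_candidates
from .rs import RSDecodeError

__all__ = [
    "DecodeReport",
    "trim_reads",
    "collate_candidates",
    "reconstruct",
    "read_reads",
]


@dataclass
class DecodeReport:
    """Stagewise statistics of one reconstruction run."""

    n_reads: int = 0
    n_trimmed: int = 0
    n_clusters: int = 0
    n_clusters_ge5: int = 0
    n_candidates: int = 0
    frac_candidates_error_free: float | None = None
    n_indices_recovered: int = 0
    n_erasures: int = 0
    n_outer_errors_corrected: int = 0
    success: bool = False
    failure_reason: str | None = None

    def to_json(self, **extra) -> str:
        d = dataclasses.asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2, sort_keys=True)


def trim_reads(reads: ReadSet | list, window: int = 60) -> ReadSet:
    """Truncate reads longer than the window at the 3' end; count conserved."""
    seqs = getattr(reads, "reads", reads)
    prov = getattr(reads, "provenance", None)
    return ReadSet([r[:window] for r in seqs], prov)


def _repair_variants(cand: CandidateSequence, window: int) -> list[str]:
    """Single-indel repair hypotheses for a frameshifted candidate.

    Consensus errors at synthesis error rates are dominated by single-base
    deletions (usually in homopolymer runs), which shift every downstream
    symbol and make the inner decode fail.  Re-inserting one base at every
    position (and, when the untrimmed consensus is longer than the window,
    deleting one base and pulling in the next) enumerates all single-indel
    repairs; duplicates collapse because indels within a run are equivalent.
    """
    c = cand.sequence
    variants: set[str] = set()
    ext = cand.raw[: window + 1] if len(cand.raw) > window else None
    for pos in range(window):
        for b in "ACGT":
            variants.add((c[:pos] + b + c[pos:])[:window])
        if ext:
            variants.add((ext[:pos] + ext[pos + 1 :])[:window])
    variants.discard(c)
    return sorted(variants)


def collate_candidates(
    candidates: list[CandidateSequence], params: CodeParams, repair: bool = True
):
    """Inner-decode candidates and reduce to one 84-bit row per index.

    Candidates failing the inner decode (or decoding to an out-of-range
    index) are dropped, unless ``repair`` finds a single-indel variant that
    is an exact inner codeword; repaired rows vote with half weight.  For an
    index with several surviving rows the highest-weight identical row wins;
    ties prefer the row backed by more zero-correction decodes, then the
    lexicographically smallest row.

    Returns (rows table, stats dict).
    """
    seqs = [c.sequence for c in candidates]
    if seqs:
        idx, rows, ncorr, ok = inner_decode_batch(seqs, params)
    else:
        idx = np.empty(0, np.int64)
        rows = np.empty((0, params.payload_bits_per_seq), np.uint8)
        ncorr = np.empty(0, np.int64)
        ok = np.empty(0, bool)
    # per index: row bytes -> [vote weight, zero-correction count]
    groups: dict[int, dict[bytes, list[float]]] = defaultdict(
        lambda: defaultdict(lambda: [0.0, 0])
    )
    for t in np.nonzero(ok)[0]:
        rec = groups[int(idx[t])][rows[t].tobytes()]
        rec[0] += 1.0
        rec[1] += int(ncorr[t] == 0)
    n_repaired = 0
    repair_contributors: set[int] = set()
    if repair:
        failed = np.nonzero(~ok)[0]
        variants: list[str] = []
        owner: list[int] = []
        for t in failed:
            vs = _repair_variants(candidates[t], params.oligo_len_nt)
            variants.extend(vs)
            owner.extend([int(t)] * len(vs))
        if variants:
            vi, vr, vn, vok = inner_decode_batch(variants, params)
            # only exact codewords count: a repair plus an RS correction is
            # too likely to be a miscorrection
            vok = vok & (vn == 0)
            seen: set[tuple[int, int, bytes]] = set()
            for u in np.nonzero(vok)[0]:
                key = (owner[u], int(vi[u]), vr[u].tobytes())
                if key in seen:
                    continue
                seen.add(key)
                groups[int(vi[u])][vr[u].tobytes()][0] += 0.5
                n_repaired += 1
                repair_contributors.add(owner[u])
    table: dict[int, np.ndarray] = {}
    for index, variants_ in groups.items():
        best = max(
            variants_.items(),
            key=lambda kv: (kv[1][0], kv[1][1], _neg_bytes(kv[0])),
        )
        table[index] = np.frombuffer(best[0], dtype=np.uint8).copy()
    contributed = {candidates[t].cluster_id for t in np.nonzero(ok)[0]}
    contributed |= {candidates[o].cluster_id for o in repair_contributors}
    stats = {
        "n_candidates": len(candidates),
        "n_inner_ok": int(ok.sum()) if len(seqs) else 0,
        "n_repaired_votes": n_repaired,
        "n_indices": len(table),
        "contributing_clusters": contributed,
    }
    return table, stats


def _second_chance_candidates(cluster_reads, rng, params):
    """Retry candidates for clusters whose first-round candidates all failed."""
    import edlib

    from .consensus import consensus_call

    out = []
    for cid in sorted(cluster_reads):
        reads = cluster_reads[cid]
        if len(reads) > 15:
            out.extend(
                c
                for c in consensus_candidates(
                    {cid: reads}, rng, target_len=params.oligo_len_nt
                )
            )
            continue
        if len(reads) < 6:
            continue
        # rank members by total edit distance to the rest; drop the worst,
        # one at a time, for up to five leave-one-out alignments
        totals = np.zeros(len(reads))
        for i in range(len(reads)):
            for j in range(i + 1, len(reads)):
                d = edlib.align(reads[i], reads[j])["editDistance"]
                totals[i] += d
                totals[j] += d
        order = np.argsort(-totals)
        for sid, drop in enumerate(order[:5]):
            subset = [r for t, r in enumerate(reads) if t != drop]
            cons = consensus_call(subset, target_len=None)
            if cons is not None and len(cons) >= params.oligo_len_nt:
                out.append(
                    CandidateSequence(
                        cons[: params.oligo_len_nt], cid, 10 + sid, raw=cons
                    )
                )
    return out


def _neg_bytes(b: bytes):
    # sort helper: higher tuple wins in max(); invert bytes so that the
    # lexicographically smallest row is preferred on full ties
    return tuple(255 - x for x in b)


def reconstruct(
    reads: ReadSet | list,
    params: CodeParams | None = None,
    cluster_method: str = "lsh",
    seed: int = 0,
    truth: OligoSet | None = None,
    cluster_kwargs: dict | None = None,
):
    """Full pipeline; returns (file_bytes | None, DecodeReport).

    ``truth`` (the designed oligo set) is only used to fill the
    candidate-error-free fraction in the report.
    """
    params = params or CodeParams()
    report = DecodeReport()
    rs_in = reads if isinstance(reads, ReadSet) else ReadSet(list(reads))
    report.n_reads = len(rs_in)
    trimmed = trim_reads(rs_in, params.oligo_len_nt)
    report.n_trimmed = sum(
        1 for a, b in zip(rs_in.reads, trimmed.reads) if len(a) != len(b)
    )

    kw = dict(cluster_kwargs or {})
    if cluster_method == "lsh":
        clusters, _ = cluster_lsh(trimmed, seed=seed, **kw)
    elif cluster_method == "prefix":
        clusters, _ = cluster_by_prefix(trimmed, **kw)
    else:
        raise ValueError(f"unknown cluster method {cluster_method!r}")
    report.n_clusters = len(clusters)
    report.n_clusters_ge5 = sum(1 for c in clusters if len(c.members) >= 5)

    rng = np.random.default_rng(seed)
    cluster_reads = {
        cid: [trimmed.reads[i] for i in cl.members] for cid, cl in enumerate(clusters)
    }
    candidates = consensus_candidates(cluster_reads, rng, target_len=params.oligo_len_nt)
    table, stats = collate_candidates(candidates, params)

    # second-chance pass: clusters large enough to vote whose candidates all
    # failed the inner decode get one more try.  Large clusters draw fresh
    # random subsets; 6-15-read clusters align leave-one-out subsets instead
    # (dropping one likely-junk read at a time), since their single full-MSA
    # candidate has no sampling randomness to vary.
    retry_ids = [
        cid
        for cid, reads in cluster_reads.items()
        if len(reads) >= 5 and cid not in stats["contributing_clusters"]
    ]
    if retry_ids:
        extra = _second_chance_candidates(
            {cid: cluster_reads[cid] for cid in retry_ids}, rng, params
        )
        if extra:
            candidates = candidates + extra
            table, stats = collate_candidates(candidates, params)

    report.n_candidates = len(candidates)
    if truth is not None and candidates:
        good = set(truth.sequences)
        report.frac_candidates_error_free = sum(
            1 for c in candidates if c.sequence in good
        ) / len(candidates)
    report.n_indices_recovered = len(table)
    report.n_erasures = params.total_n - len(table)
    try:
        data, stats = outer_decode(table, params)
    except RSDecodeError as e:
        report.failure_reason = str(e)
        return None, report
    report.n_outer_errors_corrected = sum(s[0] for s in stats if s[0] > 0)
    report.success = True
    return data, report


def read_reads(path) -> ReadSet:
    """Load reads from FASTQ/FASTA (by extension) or plain one-per-line text."""
    path = str(path)
    if path.endswith((".fastq", ".fq", ".fasta", ".fa")):
        from Bio import SeqIO

        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
        return ReadSet([str(r.seq) for r in SeqIO.parse(path, fmt)])
    with open(path) as fh:
        return ReadSet([line.strip() for line in fh if line.strip()])
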