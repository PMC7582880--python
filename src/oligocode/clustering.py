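"""Grouping noisy reads by their (unknown) source oligo.

Two methods:

* :func:`cluster_by_prefix` — hash reads on their first 16 nt.  Linear time
  and adequate at high coverage: reads whose prefix survived error-free land
  together, everything else forms tiny clusters that the consensus stage
  discards.
* :func:`cluster_lsh` — MinHash/LSH clustering.  Reads are summarized by H
  min-hashes over their k-mer sets, banded signatures propose candidate
  clusters, and every assignment is verified by edit distance against the
  cluster representative, so bucket collisions cannot chain unrelated reads
  together.  Far more complete than the prefix method at synthesis error
  rates, at a modest cost.

At a per-base error rate around 20% the probability that a k-mer survives
intact is (1-p)^k, so k must stay small for recall; k = 8 (with 64 bands of
2 rows over 128 min-hashes) balances enough intact k-mers per read against
the flood of chance collisions that shorter k-mers produce, and the
edit-distance verification supplies the precision the k-mers cannot.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

__all__ = [
    "Cluster",
    "cluster_by_prefix",
    "minhash_signature",
    "minhash_signatures",
    "cluster_lsh",
    "cluster_metrics",
]

_MERSENNE = (1 << 31) - 1


@dataclass
class Cluster:
    members: list[int]
    key: object = None


def cluster_by_prefix(reads, prefix_len: int = 16):
    """Exact-match hash on the first ``prefix_len`` nt.

    Returns (clusters, discarded) where ``discarded`` holds ids of reads
    shorter than the prefix.
    """
    seqs = getattr(reads, "reads", reads)
    buckets: dict[str, list[int]] = defaultdict(list)
    discarded: list[int] = []
    for i, r in enumerate(seqs):
        if len(r) < prefix_len:
            discarded.append(i)
        else:
            buckets[r[:prefix_len]].append(i)
    clusters = [Cluster(v, k) for k, v in buckets.items()]
    return clusters, discarded


def _kmer_codes(read: str, k: int) -> np.ndarray:
    """2-bit packed k-mers of a read (empty for reads shorter than k)."""
    lut = np.full(128, 255, dtype=np.int64)
    for i, c in enumerate(b"ACGT"):
        lut[c] = i
    codes = lut[np.frombuffer(read.encode("ascii"), np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(codes.size - k + 1, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | codes[j : codes.size - k + 1 + j]
    return out


def _hash_params(n_hashes: int, seed: int):
    rng = np.random.default_rng(seed)
    a = rng.integers(1, _MERSENNE, size=n_hashes, dtype=np.int64)
    b = rng.integers(0, _MERSENNE, size=n_hashes, dtype=np.int64)
    return a, b


def minhash_signature(read: str, k: int = 8, n_hashes: int = 128, seed: int = 0):
    """H minima of seeded universal hashes over the read's k-mer set.

    Identical reads give identical signatures, and the expected fraction of
    matching components between two signatures equals the Jaccard similarity
    of the k-mer sets.  Reads shorter than k return None (routed to the
    discard bin by the clustering driver).
    """
    kmers = _kmer_codes(read, k)
    if kmers.size == 0:
        return None
    a, b = _hash_params(n_hashes, seed)
    return ((a[:, None] * kmers[None, :] + b[:, None]) % _MERSENNE).min(axis=1)


def minhash_signatures(seqs: list[str], k: int, n_hashes: int, seed: int):
    """Batch signatures; rows for too-short reads are -1."""
    a, b = _hash_params(n_hashes, seed)
    sigs = np.full((len(seqs), n_hashes), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        kmers = _kmer_codes(s, k)
        if kmers.size:
            sigs[i] = ((a[:, None] * kmers[None, :] + b[:, None]) % _MERSENNE).min(axis=1)
    return sigs


def _edit_distance(a: str, b: str, limit: int = -1) -> int:
    d = edlib.align(a, b, k=limit)["editDistance"]
    return d if d >= 0 else 1 << 30


def cluster_lsh(
    reads,
    k: int = 8,
    n_hashes: int = 128,
    bands: int = 64,
    rows: int = 2,
    seed: int = 0,
    max_dist: int = 24,
    max_candidates: int = 8,
    refine: bool = True,
    reassign_dist: int | None = None,
):
    """MinHash-banded clustering with edit-distance verification.

    Reads are processed in order; each read's banded signature keys are
    looked up in per-band hash tables to propose existing clusters (ranked
    by number of band collisions), the read joins the closest representative
    within ``max_dist`` edits, and otherwise founds a new cluster.  Every
    member's band keys are registered, so clusters become easier to hit as
    they grow.  A merge pass then unions clusters whose representatives
    share a band bucket and verify within ``max_dist``.

    With ``refine`` (default), each merged cluster elects a medoid from a
    member sample, clusters are merged again on medoid distances, and all
    reads are re-assigned to the nearest medoid proposed by their own band
    keys.  This repairs the two artifacts of single-pass clustering: early
    reads founding duplicate clusters before their oligo's cluster existed,
    and noisy founder reads acting as poor representatives.

    Returns (clusters, discarded).
    """
    if bands * rows != n_hashes:
        raise ValueError("bands * rows must equal n_hashes")
    seqs = getattr(reads, "reads", reads)
    sigs = minhash_signatures(seqs, k, n_hashes, seed)
    band_tables: list[dict[tuple, list[int]]] = [defaultdict(list) for _ in range(bands)]
    members: list[list[int]] = []
    reps: list[str] = []
    discarded: list[int] = []

    def band_keys(sig):
        return [tuple(sig[b * rows : (b + 1) * rows]) for b in range(bands)]

    for rid, read in enumerate(seqs):
        if sigs[rid, 0] < 0:
            discarded.append(rid)
            continue
        keys = band_keys(sigs[rid])
        hits: dict[int, int] = defaultdict(int)
        for b, key in enumerate(keys):
            for cid in band_tables[b].get(key, ()):
                hits[cid] += 1
        best_cid = -1
        best_d = max_dist + 1
        ranked = sorted(hits, key=lambda c: (-hits[c], c))[:max_candidates]
        for cid in ranked:
            d = _edit_distance(read, reps[cid], limit=best_d - 1)
            if d < best_d:
                best_d = d
                best_cid = cid
        if best_cid >= 0:
            members[best_cid].append(rid)
            cid = best_cid
        else:
            cid = len(members)
            members.append([rid])
            reps.append(read)
        for b, key in enumerate(keys):
            bucket = band_tables[b][key]
            if not bucket or bucket[-1] != cid:
                bucket.append(cid)

    # merge pass: representatives sharing a bucket and verifying
    parent = list(range(len(members)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for table in band_tables:
        for bucket in table.values():
            cids = sorted({find(c) for c in bucket})
            for i in range(1, len(cids)):
                a_, b_ = cids[0], cids[i]
                if find(a_) == find(b_):
                    continue
                if _edit_distance(reps[a_], reps[b_], limit=max_dist) <= max_dist:
                    parent[find(b_)] = find(a_)
    merged: dict[int, list[int]] = defaultdict(list)
    for cid, mem in enumerate(members):
        merged[find(cid)].extend(mem)
    groups = [sorted(v) for _, v in sorted(merged.items())]

    if refine and groups:
        groups = _refine_clusters(
            seqs, sigs, groups, bands, rows, max_dist, max_candidates,
            max_dist if reassign_dist is None else reassign_dist,
        )
    clusters = [Cluster(mem, key=i) for i, mem in enumerate(groups)]
    return clusters, discarded


def _medoid(seqs, member_ids, sample: int = 9) -> int:
    """Member minimizing total edit distance to a member sample."""
    ids = member_ids[:sample]
    if len(ids) == 1:
        return ids[0]
    best, best_tot = ids[0], float("inf")
    for i in ids:
        tot = 0
        for j in ids:
            if i != j:
                tot += _edit_distance(seqs[i], seqs[j])
        if tot < best_tot:
            best, best_tot = i, tot
    return best


def _refine_clusters(seqs, sigs, groups, bands, rows, max_dist, max_candidates, reassign_dist):
    """Medoid election, medoid-level merge, and global re-assignment."""
    medoids = [_medoid(seqs, mem) for mem in groups]

    # merge clusters whose medoids share a band bucket and verify
    bucket_map: dict[tuple, list[int]] = defaultdict(list)
    for cid, mid in enumerate(medoids):
        for b in range(bands):
            bucket_map[(b, tuple(sigs[mid, b * rows : (b + 1) * rows]))].append(cid)
    parent = list(range(len(groups)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for bucket in bucket_map.values():
        roots = sorted({find(c) for c in bucket})
        for i in range(1, len(roots)):
            a_, b_ = roots[0], roots[i]
            if find(a_) != find(b_) and (
                _edit_distance(seqs[medoids[a_]], seqs[medoids[b_]], limit=max_dist)
                <= max_dist
            ):
                parent[find(b_)] = find(a_)
    rep_of_root: dict[int, list[int]] = defaultdict(list)
    for cid in range(len(groups)):
        rep_of_root[find(cid)].append(medoids[cid])

    final_meds = []  # one medoid (largest source cluster first) per merged cluster
    fid_of_root: dict[int, int] = {}
    for root, meds in sorted(rep_of_root.items()):
        fid_of_root[root] = len(final_meds)
        final_meds.append(meds[0])
    # register every member's band keys under its merged cluster id, so the
    # re-assignment pass proposes clusters as richly as the build pass did
    med_table: dict[tuple, list[int]] = defaultdict(list)
    for cid, mem in enumerate(groups):
        fid = fid_of_root[find(cid)]
        for rid in mem:
            for b in range(bands):
                key = (b, tuple(sigs[rid, b * rows : (b + 1) * rows]))
                if not med_table[key] or med_table[key][-1] != fid:
                    med_table[key].append(fid)

    # re-assign every read to the closest final medoid its bands propose
    new_groups: list[list[int]] = [[] for _ in final_meds]
    leftovers: list[list[int]] = []
    all_read_ids = sorted(i for mem in groups for i in mem)
    for rid in all_read_ids:
        hits: dict[int, int] = defaultdict(int)
        for b in range(bands):
            for fid in med_table.get((b, tuple(sigs[rid, b * rows : (b + 1) * rows])), ()):
                hits[fid] += 1
        best_fid, best_d = -1, reassign_dist + 1
        for fid in sorted(hits, key=lambda c: (-hits[c], c))[:max_candidates]:
            d = _edit_distance(seqs[rid], seqs[final_meds[fid]], limit=best_d - 1)
            if d < best_d:
                best_d, best_fid = d, fid
        if best_fid >= 0:
            new_groups[best_fid].append(rid)
        else:
            leftovers.append([rid])
    return [g for g in new_groups if g] + leftovers


def cluster_metrics(clusters, provenance, min_size: int = 5):
    """Purity / completeness / recovered-oligo fraction on labeled reads.

    purity: read-weighted majority-provenance fraction over clusters;
    completeness: mean over source oligos of the largest fraction of their
    reads kept together; recovered_fraction: fraction of oligos owning at
    least one >= min_size cluster in which they are the majority source.
    """
    provenance = np.asarray(provenance)
    n_oligos = int(provenance.max()) + 1 if provenance.size else 0
    pure_w = 0
    total = 0
    best_per_oligo = np.zeros(n_oligos)
    recovered = np.zeros(n_oligos, dtype=bool)
    reads_per_oligo = np.bincount(provenance, minlength=n_oligos)
    for cl in clusters:
        src = provenance[cl.members]
        counts = np.bincount(src, minlength=n_oligos)
        maj = int(counts.argmax())
        pure_w += counts[maj]
        total += len(cl.members)
        frac = counts / np.maximum(reads_per_oligo, 1)
        best_per_oligo = np.maximum(best_per_oligo, frac)
        if len(cl.members) >= min_size and counts[maj] * 2 > len(cl.members):
            recovered[maj] = True
    return {
        "purity": pure_w / total if total else float("nan"),
        "completeness": float(best_per_oligo[reads_per_oligo > 0].mean())
        if n_oligos
        else float("nan"),
        "recovered_fraction": float(recovered.mean()) if n_oligos else float("nan"),
    }
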