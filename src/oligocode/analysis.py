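"""Read-characterization analytics: per-position error profiles, base
composition, read lengths and GC content.

These reproduce the diagnostics used to characterize photolithographic
synthesis: aligned against the designed references, reads show a roughly
flat deletion rate with an apparent 3' rise in substitution/insertion
rates — an artifact of deletions pulling the C-rich library-prep tail into
the fixed 60-nt window, not of position-dependent synthesis chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import classify_edits, encode_seq

__all__ = [
    "ErrorProfile",
    "classify_errors",
    "error_profile",
    "base_composition",
    "read_length_hist",
    "gc_content",
]

_TYPES = ("sub", "del", "ins")


@dataclass
class ErrorProfile:
    """Positional and overall error probabilities over the read window."""

    sub: np.ndarray            # per reference position, P(substitution)
    dele: np.ndarray           # per reference position, P(deletion)
    ins: np.ndarray            # per reference position, P(insertion before)
    overall: dict              # type -> mean rate over the window
    n_reads_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(len(self.sub)), "sub": self.sub,
             "del": self.dele, "ins": self.ins}
        )


def _resolve_shift_runs(ref_codes, read_codes, pos, typ, rdp):
    """Reclassify substitution runs that are really a shifted block.

    A deletion followed (a few bases later) by an insertion shifts the
    intervening block by one; a minimum-edit alignment renders that as a run
    of substitutions (cost L < 2 + mismatches), systematically converting
    del+ins pairs into subs.  Runs of length >= 2 whose read segment equals
    the reference shifted by one base carry an unambiguous signature and are
    reclassified back into one deletion and one insertion.  Chance matches
    from genuine adjacent double substitutions are ~25%/4^(L-1) and rare.
    """
    events = list(zip(pos.tolist(), typ.tolist(), rdp.tolist()))
    out: list[tuple[int, int]] = []
    i = 0
    while i < len(events):
        p, t, r = events[i]
        if t != 0:
            out.append((p, t))
            i += 1
            continue
        j = i
        while (
            j + 1 < len(events)
            and events[j + 1][1] == 0
            and events[j + 1][0] == events[j][0] + 1
            and events[j + 1][2] == events[j][2] + 1
        ):
            j += 1
        L = j - i + 1
        if L >= 2 and np.array_equal(
            read_codes[r : r + L - 1], ref_codes[p + 1 : p + L]
        ):
            out.append((p, 1))          # deletion of ref[p]
            out.append((p + L, 2))      # insertion before ref[p+L]
        elif L >= 2 and np.array_equal(
            read_codes[r + 1 : r + L], ref_codes[p : p + L - 1]
        ):
            out.append((p, 2))          # insertion before ref[p]
            out.append((p + L - 1, 1))  # deletion of ref[p+L-1]
        else:
            out.extend((events[t_][0], 0) for t_ in range(i, j + 1))
        i = j + 1
    return out


def classify_errors(read: str, reference: str, resolve_shifts: bool = True):
    """List of (reference_position, type) for one read.

    Types are 'sub', 'del' (reference base missing from the read) and 'ins'
    (extra read base, reported at the reference position it precedes).  The
    alignment is a unit-cost edit alignment with a canonical traceback that
    prefers substitutions over indel pairs; ``resolve_shifts`` additionally
    re-attributes substitution runs bearing a one-base-shift signature to
    the del+ins pair that produced them.  Near the 3' end, where the C-rich
    tail intrudes, insertion/substitution attribution remains inherently
    ambiguous and should not be over-interpreted.
    """
    rc, dc = encode_seq(reference), encode_seq(read)
    pos, typ, rdp, _ = classify_edits(rc, dc)
    if resolve_shifts:
        return [(int(p), _TYPES[t]) for p, t in _resolve_shift_runs(rc, dc, pos, typ, rdp)]
    return [(int(p), _TYPES[t]) for p, t in zip(pos, typ)]


def error_profile(reads, references, assignment) -> ErrorProfile | None:
    """Aggregate positional error rates of ``reads`` against assigned
    references.

    ``assignment`` maps each read to a reference index (simulator
    provenance, or a best-match assignment for real data).  Returns None
    when no reads are assigned.
    """
    ref_seqs = getattr(references, "sequences", references)
    seqs = getattr(reads, "reads", reads)
    assignment = np.asarray(assignment, dtype=np.int64)
    if len(seqs) == 0 or assignment.size == 0:
        return None
    window = max(len(r) for r in ref_seqs)
    counts = np.zeros((3, window + 1), dtype=np.int64)
    n = 0
    enc_refs = {i: encode_seq(ref_seqs[i]) for i in set(assignment.tolist())}
    for read, ri in zip(seqs, assignment):
        rc = enc_refs[int(ri)]
        dc = encode_seq(read)
        pos, typ, rdp, _ = classify_edits(rc, dc)
        for p, t in _resolve_shift_runs(rc, dc, pos, typ, rdp):
            counts[t, min(p, window)] += 1
        n += 1
    per_pos = counts[:, :window] / n
    # mean of the positional rates; insertions past the last reference
    # position (column `window`) are excluded from both views.  Note that in
    # a fixed equal-length window total deletions and insertions compensate
    # by construction of a global alignment.
    overall = {t: float(per_pos[i].mean()) for i, t in enumerate(_TYPES)}
    return ErrorProfile(
        sub=per_pos[0], dele=per_pos[1], ins=per_pos[2], overall=overall, n_reads_used=n
    )


def base_composition(reads, window: int = 60) -> pd.DataFrame:
    """Per-position A/C/G/T frequencies over the first ``window`` positions.

    Shorter reads contribute to the positions they cover; each covered
    position's four frequencies sum to 1.
    """
    seqs = getattr(reads, "reads", reads)
    counts = np.zeros((window, 4), dtype=np.int64)
    cover = np.zeros(window, dtype=np.int64)
    for r in seqs:
        arr = encode_seq(r[:window])
        np.add.at(counts, (np.arange(arr.size), arr), 1)
        cover[: arr.size] += 1
    freq = counts / np.maximum(cover, 1)[:, None]
    df = pd.DataFrame(freq, columns=list("ACGT"))
    df.insert(0, "position", np.arange(window))
    df["coverage"] = cover
    return df


def read_length_hist(reads) -> pd.Series:
    """Read-length histogram (index = length, value = count)."""
    seqs = getattr(reads, "reads", reads)
    lengths = pd.Series([len(r) for r in seqs], dtype=int)
    return lengths.value_counts().sort_index()


def gc_content(reads) -> np.ndarray:
    """Per-read GC fraction."""
    seqs = getattr(reads, "reads", reads)
    return np.array(
        [(r.count("G") + r.count("C")) / len(r) if r else np.nan for r in seqs]
    )
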