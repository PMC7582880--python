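# Methods

`oligocode` implements a complete DNA data-storage channel for short,
primer-free oligonucleotides produced by photolithographic (maskless array)
synthesis: a concatenated Reed–Solomon code mapping files to 60-nt
sequences, a Monte-Carlo model of the deletion-dominated synthesis and
sequencing channel, and a reconstruction pipeline that recovers the file
from noisy, unordered reads.

## The coding scheme

A file is framed into K = 10,977 rows of 84 payload bits (row 0 starts with
a 64-bit big-endian length header; trailing bits are zero-padded).  Each
row is XORed with a per-row keystream (SHA-256 in counter mode over
`(seed, row)`), which serves three purposes: near-uniform GC content,
short homopolymers, and pairwise near-orthogonal oligos — the clustering
stage depends on the last property.  No explicit run-length or GC
constraint coding is applied; randomization alone keeps the median maximum
homopolymer below 8 nt.

Each 84-bit row is read as six 14-bit symbols.  Symbol j of row r is
message symbol r of outer codeword j: six interleaved, systematic
RS(N = 16,383, K = 10,977) codewords over GF(2^14) extend the K payload
rows to N rows.  Any code with K/N ≈ 0.67 tolerates the loss of
1 − K/N = 33% of its oligos.  A 24-bit index (XOR-masked with a fixed
constant) is inserted into each row as four 6-bit symbols placed so that
the index occupies nt 40–51 — mid-sequence, where synthesis error rates
are lowest.  Since only indices below 2^14 are used per block, the top ten
masked bits are constant and the first five index nucleotides read ACAAC.
The 18 six-bit symbols get two parity symbols from a systematic RS(20, 18)
code over GF(2^6), and the 120 bits map to 60 nt via 00→A, 01→C, 10→G,
11→T.  Net density: K·84 / (N·60) = 0.94 bits/nt.  Files larger than one
block are split into independent (N, K) blocks with block-offset indices.

Field and code parameters are free choices where the scheme itself is
agnostic: GF(2^6) uses x⁶+x+1, GF(2^14) uses x¹⁴+x¹⁰+x⁶+x+1, generator
roots start at α¹ (narrow sense), parity is appended after the message.
Encode and decode only need to agree on these; no cross-compatibility with
any external bitstream is claimed.

The decoder is errors-and-erasures Berlekamp–Massey: erasure locator
pre-multiplication of the syndrome polynomial, BM on the shifted modified
syndromes, Chien root search, and Forney magnitudes from Ω/Ψ′.  A decode
succeeds whenever 2e + ε ≤ N − K per codeword; the corrected word is
re-checked against all syndromes and any inconsistency raises an explicit
failure — the decoder never silently emits a corrupted message.  All field
arithmetic is table-driven (exp/log) and numpy-vectorized; the full-scale
N = 16,383 encode plus decode of a 99,103-byte file runs in well under a
minute on one CPU, and a 33%-erasure decode in under half a minute.

## The channel model

Synthesis and sequencing errors are modeled per read: Poisson counts of
deletions, substitutions and insertions with means λ = (7, 2, 3) per 60-nt
oligo (per-base rates 11.7%, 3.3%, 5.0%), positions uniform, applied in the
order del → sub → ins with positions re-drawn on the current sequence.
After synthesis one T is appended (3′ linker), and a C:T = 5:1 tail is
appended until the read fills the fixed 60-nt window; reads longer than the
window are truncated.  Error rates are deliberately flat in position: the
apparent 3′ rise in substitution/insertion rates seen in per-position
profiles *emerges* from deletions pulling the tail into the fixed window,
and the analytics are expected to reproduce it rather than have it
injected.  Per-oligo coverage is negative binomial (default mean 30,
dispersion 10), reflecting the strong coverage inhomogeneity of array
synthesis; zero-coverage oligos are a normal outcome.  What the simulator
does not model: PCR amplification bias, quality scores, spatial
(micromirror-position) error structure, paired-end reads.  Tests passing
on simulated reads therefore validate the pipeline against this error
structure, not against every artifact of a real instrument run.

## Reconstruction

1. **Trim** reads to the 60-nt window.
2. **Cluster.**  Two methods.  The naive method hashes the first 16 nt
   and only works when coverage is high enough that each oligo has several
   reads with error-free prefixes.  The MinHash/LSH method summarizes each
   read by 128 min-hashes over its 8-mer set (64 bands × 2 rows); bands
   propose candidate clusters and every join is verified by edit distance
   (≤ 24 over 60 nt) to the cluster representative.  k = 8 balances the
   probability that a k-mer survives the ~20% per-base error rate,
   (1−p)^k ≈ 0.27, against the chance collisions that flood shorter
   k-mers; verification supplies precision, banding supplies recall.
   After the streaming pass, clusters elect a medoid from a member sample,
   clusters whose medoids verify within the threshold are merged, and all
   reads are re-assigned to the nearest proposed medoid — this repairs
   duplicate clusters founded before their oligo's cluster existed and
   demotes noisy founder reads.  Same-oligo read pairs sit at edit
   distance ≈ 19 ± 4 while different-oligo pairs sit at ≈ 33 (scrambled
   oligos are near-orthogonal), so the 24-edit verification threshold
   separates the two populations.
3. **Consensus.**  Clusters under 5 reads are discarded; 5–15 reads are
   aligned whole; larger clusters contribute five random 15-read subsets.
   The multiple alignment is center-star (center = medoid by edit
   distance, "once a gap, always a gap" on center coordinates), followed
   by a weighted per-column vote: bases weigh 1.0, gaps 0.4, so a gap must
   outnumber a base 2.5:1 to win, reflecting that deletions are far more
   likely than the alternatives.  Gap-win columns are dropped; candidates
   shorter than 60 nt are rejected, longer ones keep their first 60 nt.
   Three refinements raise candidate quality, which matters at desk-scale
   coverage (~30×, versus ~1800× in a full sequencing run): (i) after the
   first vote the consensus replaces the noisy center read as the
   coordinate system and the vote repeats (2 rounds), correcting
   registration errors inherited from the center; (ii) each cluster also
   emits a meta-candidate — the consensus of its subset candidates — in
   which sparse independent errors cancel; (iii) clusters whose candidates
   all fail the inner decode get a second chance: large clusters redraw
   subsets, 6–15-read clusters align leave-one-out subsets (dropping the
   most distant member first), because their single full-cluster alignment
   has no sampling randomness to vary.
4. **Inner decode and collation.**  Candidates map back to 20 six-bit
   symbols; RS(20, 18) corrects one symbol error, and anything worse —
   typically a frameshift from an uncorrected indel — is rejected.
   Because the dominant consensus failure is a single lost base in a
   homopolymer run, rejected candidates go through a frameshift-repair
   enumeration: every single-base re-insertion (and, using the untrimmed
   consensus, every single-base removal) is inner-decoded, and a repair is
   accepted only if it forms an *exact* inner codeword (zero corrections);
   repaired rows vote at half weight.  Requiring exactness keeps the
   miscorrection rate negligible — a wrong repair would additionally need
   an RS correction, and its decoded index must also fall inside the used
   index range (probability ≈ N/2^24).  Rows are collated per index by
   weighted plurality (ties: more zero-correction support, then smallest
   row).
5. **Outer decode.**  Missing indices are erasures in all six codewords of
   their block; wrong surviving rows are symbol errors.  Decoding succeeds
   whenever 2e + ε ≤ N − K per codeword, after which rows are
   unscrambled and unframed.  Failure raises with per-codeword
   diagnostics; no partial file is emitted.

## Analytics

`classify_errors` aligns a read to its reference at unit cost with a
canonical traceback (substitutions preferred over indel pairs at equal
cost).  Minimum-edit alignment systematically converts a deletion followed
closely by an insertion into a run of substitutions (the shifted block is
the cheaper explanation); runs of length ≥ 2 whose read segment equals the
reference shifted by one base carry an unambiguous signature and are
re-attributed to the del+ins pair.  With this resolution the estimated
(p_del, p_sub) on the 5′ half of the window land within ±2 percentage
points of the simulator truth; adjacent del+ins pairs (distance 1) are
information-theoretically indistinguishable from substitutions and remain
the residual bias.  At the 3′ end, tail intrusion makes
insertion/substitution attribution inherently ambiguous, and absolute
rates there should not be over-interpreted.  `base_composition`,
`read_length_hist` and `gc_content` provide the standard per-position and
per-read summaries; on simulated reads the composition reproduces the
characteristic signatures (attenuated, left-shifted index peak; C rising
toward the 3′ end) without position-dependent error rates.

## Problem sizes and determinism

The test suite runs the codec full-scale only where it is fast (noiseless
roundtrip, erasure-bound decode) and otherwise uses shortened codes
(N = 255 and N = 1023) with unchanged rate K/N ≈ 0.67, simulator defaults
unchanged; the scaled end-to-end reconstruction stores 10 kB on two
N = 1023/K = 685 blocks at coverage 30 and recovers it byte-exactly in
about two minutes.  Every stochastic component (channel, subsampling,
hashing) is driven by an explicit seed, and repeated runs produce
byte-identical reports.

## Known limitations

- Bit-level compatibility with any externally produced oligo set is out of
  scope: primitive polynomials, root offsets, the index mask, the
  keystream and the framing are internal conventions.
- The LSH stage targets tens of thousands of reads in memory; streaming
  operation at the 30-million-read scale of a production sequencing run
  would need an out-of-core driver around the same primitives.
- Center-star alignment with majority voting recovers a 15-read cluster's
  oligo exactly in roughly a third of clusters at the default error rates;
  the pipeline compensates with multiple candidates per cluster and
  frameshift repair rather than with a heavier MSA engine (an external
  aligner can be substituted upstream of the vote, but nothing in the
  package depends on one).
- Candidate plurality, repair weighting (0.5) and the second-chance pass
  are reconstruction-side engineering choices; they only affect how many
  erasures/errors reach the outer code, never the code itself.
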