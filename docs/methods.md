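# Methods

## The code

The index alphabet {A,C,G,T} is identified with Z4 = {0,1,2,3}. The design
code is a quaternary (8,4) code: 256 length-8 words, 4 data and 4 parity
characters, minimum pairwise Hamming distance 4 (distance is counted per
position over the 4-letter alphabet, never per bit). Distance 4 is the
exact requirement for single-error correction plus double-error detection:
radius-1 spheres around code words are disjoint, and a weight-2 corruption
is at distance ≥ 2 from every word.

Two constructions are registered:

* **bitplane** (default). Each pair (u, v) of extended binary Hamming
  [8,4,4] words is merged position-wise as q_i = 2·u_i + v_i. Two distinct
  quaternary words differ wherever either bit-plane differs, and every
  nonzero extended-Hamming word has weight ≥ 4, so the minimum quaternary
  distance is 4. Parity layout is (d1,d2,d3,d4,p1,p2,p3,p4) with
  p1=d1⊕d2⊕d4, p2=d1⊕d3⊕d4, p3=d2⊕d3⊕d4 and p4 the overall parity; an
  optional position permutation (`layout=`) re-orders the word, which
  matters downstream because the filters are position-sensitive.
* **z4**. The same parity equations read modulo 4. Exhaustive computation
  shows this Z4-linear code also attains minimum distance 4, but its offset
  cosets survive the filters differently (108 rather than 120 indices for
  the reference offset), so it is not the default.

The registry (`register_construction`) accepts further variants.

## Offset, mapping and filters

The raw code read as DNA is rich in 3-base homopolymers, which inflate
sequencing error rates. A fixed offset word W ∈ Z4^8 is added modulo 4 at
every position — a translation of the symbol space, so all pairwise
distances are preserved exactly — and the result is mapped to DNA through a
bijection {0,1,2,3}→{A,C,G,T} (default 0→A, 1→C, 2→G, 3→T; all 24
bijections are accepted). Two filter rules then apply:

* **triplet**: no run of ≥3 identical consecutive bases anywhere;
* **end_duplet**: the first two bases differ and the last two bases differ.

Both rules depend only on base-*equality* patterns, which are invariant
under the choice of nucleotide map; the surviving count is therefore the
same for all 24 maps. For the reference offset W = (1,2,2,3,3,0,0,0) the
default construction leaves exactly 120 indices, perfectly balanced: every
base appears exactly 30 times at every position.

`search_offsets` evaluates all 4^8 = 65,536 offsets exhaustively
(vectorised, ~3 s on one CPU) and ranks by surviving count (descending),
imbalance (ascending), then lexicographic W, so results are bit-for-bit
reproducible. Balance is quantified as the sum over the 8×4 position×base
cells of squared deviations from the uniform expectation n/4; zero iff
usage is perfectly uniform. The best achievable count over all offsets is
136; the reference offset is one of the offsets combining a high count
with imbalance 0.

## Subset selection

A working set of k indices (k = 96 for a full plate) is chosen by a greedy
swap heuristic: start from the first k in codebook order, repeatedly apply
the single in/out swap that most reduces the imbalance, stop when no swap
improves. The result is deterministic; the seed only orders exact ties in
swap gains. Greedy selection never does worse than the first-k subset, and
any subset inherits the full set's minimum distance. For the shipped design
the 96-subset reaches imbalance 8 (every cell within 1 of the uniform 24).
No claim of global optimality is made — balanced subset selection is a
combinatorial problem the greedy only approximates.

## Decoding

Decoding is exhaustive nearest-neighbour over the index set (96–120
vectorised comparisons), not syndrome decoding: after offsetting and
filtering the set is no longer linear. Outcomes:

* distance 0 → `exact`;
* unique index within `max_mismatch` (0 or 1) → `corrected`;
* otherwise `detected` if the nearest index is at distance 2–3 (an error
  was noticed), `unassigned` at distance ≥ 4.

`N` bases mismatch every index base; a read with more than one `N` is
unassigned outright. The quality policy (`decode_with_quality`) downgrades
a *corrected* result to unassigned when any base of the index read has
Phred quality below `q_min` (default 20, i.e. error probability 1%): a
correction resting on a likely-erroneous base is not trustworthy. Exact
matches are accepted at any quality, since no correction was needed.

### Error audits

`audit_errors(set, w)` enumerates, for every index, all C(8,w)·3^w
substitution patterns of weight w ∈ {1,2,3} and decodes each corrupted word
with radius-1 correction. At minimum distance 4 the outcome structure is
forced for w ≤ 2 (all weight-1 corrected to truth, no weight-2
miscorrected) and combinatorial for w = 3: a triple error is miscorrected
iff it rewrites exactly 3 of the 4 differing positions of a distance-4
neighbour, so

    miscorrected(w=3) = 4 × #{ordered index pairs at distance exactly 4}.

For the 120-index design: 1256 unordered distance-4 pairs, hence
4 × 2512 = 10,048 miscorrected events out of 181,440 (5.54%). The identity
is asserted in the test suite against both the pairwise-distance histogram
and an independent brute-force decode.

## Demultiplexing

Both 8-base index reads of each record are decoded independently; a read is
assigned iff both decode (under the policy) and the decoded (i7, i5) pair
is present in the sample sheet. Undetermined reads are counted under the
first applicable reason, in the fixed precedence low_quality → index1_fail
→ index2_fail → pair_not_in_sheet. Read counts are conserved exactly and
the statistics are independent of input order. Index reads come from
separate I1/I2 FASTQ files synchronised by record order (read-id checked)
or from the `1:N:0:IDX1+IDX2` header dialect; an option reverse-complements
index 2 before decoding for instruments that emit i5 in the opposite
orientation (off by default). Outputs are one FASTQ per sample plus an
undetermined file, gzip-compressed by default, in input order.

## The synthetic-run generator

`simdata` emulates the substitution-error regime the design targets: each
index base is substituted independently with a per-position probability
(default 0.001, a typical per-base index error level; scalar or 8-vector),
the substitute drawn uniformly from the 3 alternative bases. Quality
strings reflect the simulation's knowledge — error-free bases get Phred
q_good = 37, substituted bases q_bad = 10, optional integer jitter, clipped
to [2, 41] — so the quality-rejection policy is exercisable with a truth
table to check against. Insert sequences are i.i.d. uniform bases (default
length 50); they are irrelevant to index decoding and exist only to keep
the FASTQ format-realistic. Everything is deterministic given the profile
seed, down to output bytes.

What the generator does **not** model: insertions/deletions, quality-
correlated or context-dependent substitution rates, index hopping between
libraries, PCR duplicates, or coverage/GC structure of the insert. Passing
tests therefore demonstrate the decoder's combinatorial guarantees under
substitution errors, not performance on every real-run artefact; the
exhaustive audits, however, are model-free and cover *all* substitution
patterns of weight ≤ 3.

## Problem sizes and numerical choices

All headline computations are exhaustive and fast: 32,640 pairwise
distances (< 0.1 s), 65,536-offset search (~3 s), 181,440-event triple
audit (~1 s vectorised). The end-to-end synthetic check uses 10,000 reads
over 96 samples at 1% per-position index error. Greedy swap gains are
compared with an absolute tolerance of 1e-12 to avoid floating-point ties;
counts themselves are integers throughout. Degenerate inputs (empty sets,
k larger than the set, non-ACGT characters, truncated or desynchronised
FASTQ triples, duplicate sample-sheet pairs) raise explicit errors rather
than propagating silently.

## Known limitations

* Substitution errors only; an indel in an index read shifts every
  downstream base and will typically be `detected`/`unassigned`, not
  corrected.
* The greedy 96-subset is a heuristic; the particular historical choice of
  96 from the 120 is not recoverable and is not claimed.
* Quality-aware rejection uses a single min-quality threshold per index
  read, not a posterior over candidate indices.
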