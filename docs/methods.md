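# Methods

This note documents the models, conventions, and numerical choices behind
`minidx`, and what the synthetic experiments do and do not establish.

## Digestion

A minimizer scheme is `(k, w, hash_seed)` with `w > k`. Within each of the
`|s| - w + 1` length-`w` windows of a sequence, the constituent `k`-mer
with the minimal 64-bit hash is selected; ties break to the leftmost
offset, the common convention and the one that keeps selection
deterministic. Consecutive equal selections collapse to one symbol. The
collapse is by *value*: two distinct but adjacent occurrences of the same
`k`-mer also merge, which matches concatenating minimizers and collapsing
equal-minimizer runs, at the cost of losing tandem-repeat length (a known
property of this compression; see Limitations).

The hash is a splitmix64 finalizer applied to the 2-bit-packed `k`-mer
code XORed with a mixed seed: a pure function of `(k-mer, seed)`, well
mixed (all 256 4-mers receive distinct values under the default seed,
asserted in the tests). The default seed is a fixed constant so that
digests, and therefore indexes, are byte-reproducible; `minidx build
--seed` overrides it. Bit-compatibility with any other tool's digests is
not a goal — only the stated contract (deterministic, well mixed) is.

Non-ACGT characters split a sequence into ACGT-only segments; each segment
is digested independently and the digests concatenated, so no undefined
`k`-mer is ever hashed. Sequences shorter than `w` digest to the empty
sequence, which downstream code treats as "no data" rather than an error.

Defaults: `k = 4`, `w = 11`. `k = 4` makes the minimizer alphabet exactly
256 symbols (one byte per symbol); `w = 11` is the accuracy/size sweet
spot for this family of methods, giving roughly a 4-fold reduction of
random DNA (a digest keeps ~2/(w−k+1) of the windows' worth of symbols
after collapsing).

## Text and index construction

Documents (optionally with their reverse complements added as documents of
the same class — the default, so reads can be queried in their given
orientation) are concatenated, each followed by its own sentinel. Sentinel
of document `d` is internal code `d`; data symbol `s` becomes `s + n_docs`.
Distinct, document-ordered sentinels make the suffix order total and the
build fully deterministic; the cost (each sentinel is its own BWT run) is
negligible at the collection sizes indexed here.

The suffix array is built by prefix doubling (Manber–Myers) with numpy
sorts — O(n log n) passes, exact for arbitrary integer alphabets — the BWT
by `BWT[i] = T[sa[i]-1]` with wraparound, and the LCP array by Kasai's
algorithm. O(r)-space construction (prefix-free parsing) is out of scope;
everything here is desk-scale by design.

**Thresholds.** For each pair of consecutive runs of the same symbol `c`
(last row `e` of the earlier run, first row `s` of the later), the
threshold is the row of the *leftmost minimum* of the LCP array in
`(e, s]`. A query at row `q` strictly above the threshold jumps up to `e`,
at or below jumps down to `s`. This convention is fixed not by fiat but by
the property it must satisfy — the chosen boundary's suffix always shares
at least as long a prefix with the current row's suffix as the rejected
boundary's — which the tests verify exhaustively on random texts. Symbols
occurring in a single run need no threshold (the direction is forced), and
a queried symbol with no run at all is a universal mismatch: PML 0, row
unchanged.

**Sampled document array.** 2r class labels: for every run, the class of
the document containing the suffix at its first and at its last row. Only
these rows can be jump targets, so the labels cover every case-2 event.
Entries need `ceil(log2 c)` bits; serialization uses the smallest unsigned
integer dtype that holds `c`.

**Serialization** is a directory: a `key=value` text header (magic,
version, scheme, alphabet, `n`, `r`, flags, null threshold) plus one
little-endian `.npy` array per component. Derived structures (run starts,
rank scaffolding, per-character run lists) are rebuilt on load rather than
stored. Loading verifies magic, version, and the header's `n`/`r` against
the arrays, and reports truncated components by name.

## Queries

The PML walk starts at row 0 with length 0. Initialization is arbitrary in
principle — the first mismatch resets the state — and row 0 is fixed for
determinism. On case 1 the emitted PML is the incremented length; on case
2 the emitted PML is 0 (the reset itself is emitted at the jump position,
and the matched character at the jumped-to boundary contributes to the
*next* position's increment). One consequence worth knowing: a read that
is an exact interior substring of the reference can still show resets,
because the single-row walk may sit on a row whose *preceding* character
belongs to a different occurrence of the current match. That is precisely
the approximation that makes PML ≤ MS a bound rather than an equality, and
it is why classification uses window maxima rather than per-position
values.

Exact MS uses the standard two passes: the first pass runs the same walk
but carries the suffix-array value of the current row (decremented on LF
steps, reloaded from the run-boundary SA samples on jumps), recording per
position a text offset where a longest-match candidate begins; the second
pass resolves every `MS[i]` by direct comparison of `read[i..]` against
`T[offset..]`. This requires the index to retain SA samples and the text
(`ms_support`), which the PML-only index deliberately omits — PML mode is
the small, fast default.

Pause/resume: the walk state is `(row, length, last_label, consumed)` and
is JSON-serializable. Because processing is right-to-left, the resumable
direction is leftward extension: process a later chunk first, resume with
the chunk to its left; output equals the single-shot computation exactly
(asserted over random multi-way splits). The adaptive-sampling driver,
whose batches arrive on the *left-to-right* front, therefore recomputes
the accumulated prefix at each batch — correctness first; at 4 × 180 bp
per read the cost is trivial.

## Classification

**Null threshold.** 500 substrings of 2,000 bases are drawn from the raw
(pre-digest) reference documents, start positions uniform over pooled
bases; each is character-reversed (not reverse-complemented, so base
composition is preserved while homology is destroyed), digested, and
queried like any read. The threshold is the largest pooled null PML
occurring at least 5 times (0 if none qualifies); the occurrence floor is
configurable. 500 × 2,000 is chosen to give a stable pooled distribution
(~a quarter-million null values at the default scheme) at negligible build
cost; both knobs are exposed.

**Binary rule.** Windows of 150 symbols from the left end of the processed
read (digested symbols for minimizer indexes, bases for DNA indexes — the
same window size works across alphabets); a trailing window shorter than
150 merges into the previous one; a read shorter than 150 symbols is one
window. A window is *above* iff its maximum PML is strictly greater than
the threshold; the read is *present* iff strictly more than half its
windows are above (ties → absent). All three strictness choices follow the
literal rule; the boundary cases are pinned in tests.

**Multi-class.** Case-2 events record the boundary label; case-1 positions
inherit the most recent case-2 label; positions before the first case-2
event carry a "no label" sentinel and are excluded from aggregation. The
call is the plurality class of the remaining labels (ties break to the
smallest class id and are flagged). Aggregation is unweighted — the
simplest reading; a PML-weighted variant was considered and not adopted as
default.

**Contamination scan.** Each contig is digested and queried whole; the
contig is *suspicious* iff the 25th percentile of its PMLs is ≥ 2
(inclusive). Percentile interpolation is numpy's default linear rule; the
separation on real use is far from the boundary (planted contaminants sit
at p25 ≫ 2, clean contigs at 0–1), so the interpolation convention is
immaterial.

**Adaptive sampling.** Prefixes of b × 180 bases, b = 1..4; first
*present* verdict ejects at batch b, otherwise retain.

## Synthetic data

The generator produces: a random ancestor per experiment; one class base
genome per class (ancestor mutated at the inter-class rate, default 10%);
strains per class (class base mutated at the intra-class rate, default
1%); reads as uniform substrings of a uniform strain, either strand with
probability 1/2, with i.i.d. substitutions (default 5%, i.e. 95%
identity, ONT-like). Defaults for the classification experiments: 5
strains of 5 kb for the binary setting, 3 classes × 2 strains for
multi-class, 1 kb reads, 200 reads per arm (100 per class in
multi-class), 2 kb contigs with 2 planted 1%-mutated contaminant copies
among 20 clean ones.

What this emulates: the repetitive strain structure that run-length
compression exploits (near-identical strains, both strands), and the
match-breaking effect of sequencing errors. What it does not: indels and
homopolymer artifacts, read-length distributions, composition bias, or
real inter-species similarity structure. Passing the synthetic recovery
tests therefore demonstrates the machinery is correct and the decision
rules separate signal from noise under substitution-type divergence; it
does not forecast accuracy on any particular real dataset.

All generators, the null sampler, and every experiment are seeded;
identical seeds give byte-identical FASTA/FASTQ and identical index files.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full suite finishes in well under a minute on one core: references up to
2,000 symbols for the exact-MS oracle comparisons (1,000 pairs in the
suite, 300 in the script), texts up to 200 symbols for the exhaustive
brute-force SA/BWT/threshold checks (100 texts), 50 kb of indexed sequence
(before digestion) for the classification experiments. All algorithms are
pure-Python/numpy over the run-length structures; rank within the BWT is a
binary search over run starts (O(log r) per step), which is the right
trade-off at these sizes.

## Limitations

- Value-level run collapsing erases tandem-repeat copy number.
- PML-only indexes cannot produce exact MS (by design; rebuild with
  `--ms-support`).
- The sampled document array records one class per run boundary; when a
  match occurs in many classes, the emitted label is just one of them, and
  short reads aggregate few labels — the known uncertainty of this
  sampling, compensated by read-level aggregation.
- Construction is not O(r)-space; collections are limited by the
  suffix-array build (fine for the multi-megabase desk scale this package
  targets).
- Canonical (strand-min) minimizers, syncmers, locate queries, and raw
  nanopore signal processing are out of scope.
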