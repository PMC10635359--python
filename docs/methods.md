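# Methods

## Model and conventions

The index answers count queries over a single terminated text
`S[0..n-1]`, `S[n-1] = $`, where `$` occurs exactly once and sorts below
every alphabet symbol. Because the terminator is unique and smallest, the
lexicographic order of suffixes equals the order of cyclic rotations; the
package relies on this equivalence in both levels (the suffix array of
`S`, and the suffix array of the parse rotated so its unique 0 — the
terminator phrase's ID — is last). Conventions fixed package-wide:
0-based indexing, inclusive BWT intervals, `rank(c, i)` counts
occurrences strictly before `i`, `select` is 1-indexed.

## Prefix-free parsing

The text is scanned cyclically; a length-`w` window is a trigger if its
Karp–Rabin fingerprint is ≡ 0 mod `p` (hashed mode) or if it belongs to a
given set (explicit mode, provided so that worked examples with a stated
trigger set are reproducible bit-exactly). The window starting at the
terminator (`$` followed by the first `w-1` characters) is always a
trigger; no other window containing `$`, `#`, or a configured record
separator is ever one. Trigger occurrences may overlap, so phrases can be
as short as `w+1` characters.

The Karp–Rabin hash is a polynomial rolling hash modulo the Mersenne
prime 2^61 − 1, with the base derived deterministically from a recorded
seed; seed and constants are stored in the index header so index-time and
query-time parsing always agree. The phrase-fingerprint map uses the same
hash family with an independent base; if two dictionary phrases ever
collide, the base is re-derived and the map rebuilt, and every query-time
lookup is verified character by character against the stored phrase, so
"phrase absent" answers are exact rather than high-probability.

A degenerate note: with `p = 1` every window is a trigger and almost
every phrase has length `w+1`, but the one phrase crossing the terminator
seam has length `2w` (the `w-1` windows overlapping `$` cannot be
triggers), so the mean phrase length is `(w+1) + (w-1)/|P|`, not exactly
`w+1`.

## Query decomposition

A pattern is scanned with the same policy, non-cyclically and without a
terminator. With no trigger the pattern is searched entirely at character
level. With at least two trigger occurrences the decomposition is the
standard one: prefix `α` ending at the end of the first trigger (empty if
the pattern starts with one), complete phrases between consecutive
triggers, suffix `β` from the start of the last trigger (empty if the
pattern ends with one). With exactly one trigger occurrence at position
`t` there is no complete phrase; we set `α = pattern[:t+w]` and
`β = pattern[t:]`, both containing the trigger, search `β`, and continue
the character-level search with `α` minus its last `w` characters — the
char→phrase→char round trip is the identity on `β`'s interval (all its
rows are marked), so this shortcut is provably equivalent.

Whether `β` "falls inside a trigger's interval" is never tested against
the BWT: `β` starts with a trigger by construction whenever the pattern
contains one, which is the parse-based equivalent of that test (the
bridging tests assert that every row of `β`'s interval is marked, so the
equivalence is checked, not assumed). Patterns containing `$` or symbols
outside the indexed alphabet count 0 rather than raising.

## Data structures and numerics

- Suffix arrays are built by prefix doubling (Manber–Myers) on numpy
  lexsorts: O(n log n), exact for any integer alphabet, used unchanged
  for both the character text and the parse. At the package's intended
  scale (up to a few hundred thousand characters) this builds in well
  under a second.
- Rank support stores, per symbol, the sorted positions of its BWT
  occurrences (one stable argsort); `rank(c, i)` is a binary search. The
  contract is exactness; no compressed or sampled structure is attempted.
- The mark bitvector keeps a prefix-sum array for `rank` and the set-bit
  positions for `select`; its 1s form at most one run per distinct
  trigger string (asserted in tests, counting the terminator window's
  trigger).
- Backward steps are counted per FM-index. For a pattern with `k ≥ 2`
  complete phrases, character-level steps are at most `|α| + |β|` (in
  fact `|α| + |β| − w`) and phrase-level steps equal `k`; this operation
  count is the portable proxy for the hardware-dependent wall-clock
  speedups of two-level search, reported by the sweep but never
  thresholded.

## Serialization

The on-disk container is little-endian and sectioned: magic `PFPFM1`, a
format version, a JSON header (policy, alphabet, dictionary phrases,
fingerprint seed, lengths, array dtype) and three raw sections — BWT(S)
and BWT(P) as `<u4`, the bitvector packed to bits. Rank structures are
rebuilt on load; the round-trip contract is behavioral (every query
answer equal), and magic/version mismatch or truncation raise a
corruption error.

## Synthetic data

The generator emulates a pangenome: one random ancestor and `M − 1`
copies with i.i.d. substitutions (rate μ per base, substituted bases
always change) and rare indels (rate split evenly between deletions and
single-base insertions). Defaults — ancestor 5,000 bp, 50 copies,
μ = 0.002, indels 0.0002 — model a small collection of near-identical
viral genomes: divergence in the per-mille range keeps phrases shared
across copies, which is the regime where phrase-level search pays off.
What it does not model: structural variation, uneven relatedness
(phylogeny), IUPAC ambiguity codes, or real base composition; passing
tests therefore demonstrate correctness of counting and the operation
count structure, not performance on real data. Test and acceptance runs
use scaled-down collections (total text a few kilobytes for the
randomized oracle sweep; the full 250 kb default for the operation-count
check), sizes chosen so the whole suite runs in seconds while still
exercising every parameter cell.

## Known limitations

- count only: no locate, no suffix-array sampling, no run-length
  compressed BWT, no compressed-space guarantees.
- The parser is in-memory and single-threaded; no external-memory or
  parallel construction.
- Multi-record FASTA input is concatenated without separators by default
  (patterns sampled across a junction can match the concatenation);
  `--record-separator` inserts a sentinel that is excluded from trigger
  windows, at the cost of one extra alphabet symbol.
- IUPAC/N characters are indexed as ordinary symbols.
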