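# Methods

## Problem and model

For a word `y` of length `n` over an ordered alphabet `Σ` of size `σ`, a
*minimal absent word* (MAW) is a word `x` of length `m ≥ 2` that does not
occur in `y` while every proper factor of `x` does. Writing `x = a·w` with
`a` a letter and `w = x[1..m−1]`, minimality is equivalent to a membership
test on two letter sets attached to `w`:

- `B1(w)` — letters immediately preceding occurrences of `w` in `y`;
- `B2(w)` — letters immediately preceding occurrences of the longest
  proper prefix of `w`.

`x = a·w` is a MAW exactly when `a ∈ B2(w) \ B1(w)`: `a` extends the
prefix of `w` somewhere in `y` (so `x`'s own longest proper prefix
occurs) but never extends `w` itself (so `x` is absent). Every proper
factor of `x` then occurs because `w` and `x[0..m−2]` do.

Only `2n` candidate tails `w` need to be examined. With `sa` the suffix
array, `lcp` the longest-common-prefix array (`lcp[r]` = LCP of the
suffixes ranked `r−1` and `r`, `lcp[0] = 0`, boundary `lcp[n] = 0`), the
factors

    S_2i   = y[sa[i] .. sa[i] + lcp[i]]        (length lcp[i] + 1)
    S_2i+1 = y[sa[i] .. sa[i] + lcp[i+1]]      (length lcp[i+1] + 1)

for `i ∈ [0, n)` cover every possible MAW tail: for any MAW, the ranks of
an occurrence of its tail and of its longest proper prefix (shifted by
one) bracket a rank where the tail is spelled by exactly one of these two
formulas. So filling `B1[j]`, `B2[j]` for `j ∈ [0, 2n)` and differencing
yields the complete MAW set, at most `σ·(n+1)` words.

## The two sweeps

`B1`/`B2` are bit vectors of `σ` bits per factor id. They are filled by
two sweeps over suffix ranks sharing one working structure, the
*interval table*: one letter set per prefix length of the suffix under
the cursor, of which only the lengths held in a monotone stack of LCP
values are live. The invariant at rank `i` is: for each stacked value
`v`, entry `v` holds the letters preceding the already-visited ranks
whose suffix shares a prefix of length ≥ `v` with the current suffix.
Entries are nested — smaller live lengths hold supersets.

The top-down sweep visits ranks `0 … n−1` and accumulates contributions
from occurrences at ranks ≤ `i`; the bottom-up sweep visits `n−1 … 0`
and completes them with ranks ≥ `i`. Per rank each sweep:

1. retires stacked values greater than the connecting LCP value (those
   prefix lengths are no longer shared); a value pushed in their place
   inherits their letters — nestedness makes the deepest retired entry
   their union — plus the neighbouring rank's preceding letter;
2. propagates the current rank's preceding letter `y[sa[i]−1]` down the
   stack until it meets an entry that already holds it (nested entries
   below then hold it too);
3. records the four sets of the rank's factor pair by reading the entry
   at the smallest live length ≥ the queried prefix length (a binary
   search on the stack), OR-ing in the current rank's own preceding
   letter.

In the bottom-up sweep, retired values are parked on a second stack and
their entries cleared only after the rank's recordings, since a rank may
share more than `lcp[i]` symbols with the ranks below it. Each sweep
pushes at most one value per rank (≤ `n` pushes, asserted by tests via
counters) and inserts at most `σ` letters per rank into the table, so
both sweeps do `O(nσ)` work. The inherit-on-push rule (step 1) is this
package's resolution of a gap in the usual prose description of the
sweeps, where retired entries are simply zeroed: without it, recordings
at freshly pushed LCP values verifiably lose letters (word `ABAB`, rank
1 of the top-down sweep is a two-line counterexample). The resolution is
validated exhaustively against the definitional `B1`/`B2` sets.

## Conventions at the boundaries

- **No predecessor at position 0.** An occurrence starting at position 0
  contributes no letter to any B set.
- **Length-1 tails.** The longest proper prefix of a single letter is
  the empty word, which occurs at every position; `B2` is then the set
  of all letters occurring in `y`. This is the unique convention under
  which the emission rule reproduces the length-2 MAWs demanded by the
  definition (e.g. `y = AB` has MAWs `{AA, BA, BB}`, including `BB`
  although `B`'s only occurrence is final).
- **Overrun skip.** A candidate `S_2i+1` with `lcp[i+1] + 1 > n − sa[i]`
  would run past the end of `y`; it is skipped, and the same factor is
  covered as `S_2(i+1)` at the next rank. `S_2i` can never overrun
  (a suffix is lexicographically larger than its proper prefixes).
- **Deduplication.** The same tail can appear under several ids (e.g.
  `A` in `ABAB`); emission deduplicates on (first letter, tail string)
  and keeps the witness interval from the smallest id. Tail strings of a
  sequence are short in practice (near `2·log_σ n` for random text), so
  the string key does not threaten the linear behaviour; pathological
  inputs (unary words) have O(1) MAWs.
- **MAW length.** `m ≥ 2` by definition; absent single letters are never
  reported. `min_len ≥ 2`; `max_len` defaults to `n + 1`, the largest
  possible MAW length (attained only by unary words).

## Construction choices

Suffix arrays are built by prefix doubling over `numpy.lexsort` —
`O(n log n)` with small vectorised constants — because the package's
contract is the output arrays, not the construction route; LCP arrays
use Kasai's `O(n)` algorithm. No sentinel appears in exposed arrays. All
positions are 0-based, intervals inclusive. Letter sets are Python
integer bitmasks (arbitrary `σ`), so set union/difference/membership are
single integer operations for realistic alphabets.

## Input handling

FASTA records are parsed with Biopython after a pre-scan that rejects
empty input and sequence data before the first header. Residues are
uppercased (soft-masking case is meaningless here). Every distinct
symbol, including `N` and other ambiguity codes, is a first-class
alphabet letter; the CLI's `--dna-only` flag suppresses reported MAWs
containing non-ACGT letters for DNA-only output. Multi-FASTA records are
processed independently — concatenation would manufacture factors
spanning record boundaries. With `--reverse-complement`, each record's
reverse complement is analysed as a separate block (suffix `_revcomp`),
mirroring per-strand reporting; MAW sets of the two strands are exact
reverse complements of each other, which the tests assert.

## Verification strategy and its limits

The independent reference is a brute-force oracle that applies the
definition directly: candidates `a·f` over all factors `f`, kept when
absent with their longest proper prefix present (quadratic, no shared
code with the sweeps). Agreement is checked exactly on every binary word
of length ≤ 12 and on 1,000 seeded random words (`σ ∈ {1,2,3,4}`,
lengths 1–200), alongside property tests for soundness, the `σ·(n+1)`
bound, strand symmetry, determinism, and the work counters. The random
generator draws letters i.i.d. uniform; it deliberately covers the
degenerate corners (`σ = 1`, length 1) but does not emulate genome-scale
composition biases, repeats, or ambiguity-code runs — passing tests
certify the combinatorics of the algorithm, not biological
interpretation. The acceptance script adds a 100 kb uniform-random DNA
census as a scale demonstration; its MAW count is seed-dependent by
design, while the agreement percentages and worked-example counts are
invariant. Problem sizes throughout (words ≤ 300 for oracle comparisons,
100 kb for the scale demo) were chosen so the whole verification runs in
well under a minute on one core; the implementation itself handles
multi-megabase bacterial genomes in seconds to minutes in pure
Python + numpy.

## Known limitations

- Suffix-array construction is `O(n log n)`, not strictly linear; for
  the package's target scales this is never the bottleneck.
- The sweeps are pure Python; constants are far higher than a C
  implementation's, though asymptotics match.
- No streaming: a record is held in memory with ~5 machine words per
  position.
- Generalised (multi-record) suffix structures, suffix automata and
  BWT-based routes are out of scope.
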