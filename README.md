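# mawkit

Minimal absent words of a sequence, computed in linear time from its
suffix array.

A word `x` is an *absent word* of a sequence `y` if it does not occur in
`y`; it is a **minimal absent word** (MAW) if additionally every proper
factor of `x` occurs in `y`. Equivalently, `x = a·w·b` where `a·w` and
`w·b` occur but `a·w·b` does not. MAW sets are a compact negative
fingerprint of a sequence — at most `σ·(n+1)` words over an alphabet of
size `σ` — and are used for alignment-free genome comparison, phylogeny
reconstruction, and studies of sequence hypermutability.

`mawkit` computes the complete MAW set of each record in a (multi-)FASTA
file, or of any string through the library API. The algorithm builds the
suffix array `SA` and LCP array of `y`, then fills, for the `2n`
candidate tails `S_2i = y[SA[i] .. SA[i]+LCP[i]]` and
`S_2i+1 = y[SA[i] .. SA[i]+LCP[i+1]]`, the sets `B1(S_j)` / `B2(S_j)` of
letters immediately preceding occurrences of `S_j` / of its longest
proper prefix, in two stack-driven sweeps over suffix ranks (O(nσ) work,
at most one stack push per rank). Every letter `a ∈ B2(S_j) \ B1(S_j)`
starts exactly one MAW `a·S_j`, reported as a constant-size tuple
`⟨a,(i,j)⟩`. A deliberately naive brute-force oracle ships with the
package and backs an exhaustive + randomized verification suite. See
`docs/methods.md` for the full account.

## Worked example

The word `y = AABABABB` has exactly seven minimal absent words.

```sh
$ printf '>y\nAABABABB\n' > y.fa
$ mawkit -i y.fa -o y.maw -v
mawkit: y: n=8 sigma=2 maws=7
$ cat y.maw
>y
AAA
AABABB
AABB
BAA
BABABA
BBA
BBB
```

`AABB` is the classic case: `AAB` and `ABB` both occur in `y`, `AABB`
does not, so it is absent and minimal. Restricting the length window
keeps only the four length-3 MAWs:

```sh
$ mawkit -i y.fa -o y3.maw -k 3 -K 3
$ cat y3.maw
>y
AAA
BAA
BBA
BBB
```

Other flags: `-r/--reverse-complement` adds a separate `_revcomp` block
per record with the MAWs of the other strand, `--tuples` emits
`a<TAB>i<TAB>j` tuples instead of decoded words, `--dna-only` suppresses
MAWs containing non-ACGT letters.

From Python:

```python
>>> from mawkit import compute_maw_strings, compute_maws
>>> compute_maw_strings("AABABABB")
['AAA', 'AABABB', 'AABB', 'BAA', 'BABABA', 'BBA', 'BBB']
>>> compute_maws("AB")   # tuple encoding <a, (i, j)>: a + y[i..j]
[MawTuple(a='A', i=0, j=0), MawTuple(a='B', i=0, j=0), MawTuple(a='B', i=1, j=1)]
```

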