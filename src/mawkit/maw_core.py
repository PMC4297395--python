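"""Minimal absent words from the suffix and LCP arrays in two linear sweeps.

A word ``x = a · w`` (``a`` a letter, ``w`` non-empty) is a minimal absent
word (MAW) of ``y`` exactly when ``a`` precedes some occurrence of the
longest proper prefix of ``w`` but no occurrence of ``w`` itself.  Writing
``B1(w)`` for the letters immediately preceding occurrences of ``w`` and
``B2(w)`` for those preceding occurrences of its longest proper prefix,
the first letters of MAWs with tail ``w`` are ``B2(w) \\ B1(w)``.

Only ``2n`` candidate tails need inspecting: for every suffix rank ``i``,
the factors ``S_2i = y[sa[i] .. sa[i] + lcp[i]]`` and ``S_2i+1 =
y[sa[i] .. sa[i] + lcp[i+1]]`` (with the boundary convention
``lcp[n] = 0``).  Every MAW tail appears among them, so filling the arrays
``B1[j]``, ``B2[j]`` for ``j in [0, 2n)`` and differencing yields the
complete MAW set.

The B arrays are filled by two sweeps over suffix ranks.  Each sweep keeps
an :class:`IntervalTable` — one letter set per live prefix length of the
current suffix — controlled by a monotone stack of LCP values
(:class:`LcpStack`): at rank ``i``, the set at stacked value ``v`` holds
the letters preceding already-visited ranks whose suffix shares a prefix
of length at least ``v`` with the current one.  The top-down sweep covers
occurrences at ranks ``<= i``, the bottom-up sweep ranks ``>= i``; their
union is the full set.  Each sweep pushes at most one value per rank and
inserts O(sigma) letters per rank, giving O(n sigma) total work.

Conventions where the definitions are silent:

* an occurrence starting at position 0 has no preceding letter and
  contributes nothing to any B set;
* a length-1 tail has the empty word as longest proper prefix; the empty
  word occurs everywhere, so ``B2`` is then the set of all letters that
  occur in ``y`` (this makes length-2 MAWs come out right, e.g.
  ``y = "AB"`` has MAWs ``{AA, BA, BB}``);
* a candidate ``S_2i+1`` whose length ``lcp[i+1] + 1`` would overrun the
  suffix end is skipped — the same factor is a valid ``S_2(i+1)`` at the
  next rank;
* the same tail may arise at several ids ``j``; emission deduplicates and
  keeps the witness interval from the smallest ``j``.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

from mawkit.sequence_io import Alphabet
from mawkit.suffix_structures import IndexedWord

__all__ = [
    "LetterSet",
    "PrecedingSets",
    "IntervalTable",
    "LcpStack",
    "MawTuple",
    "enumerate_factor_pairs",
    "top_down_pass",
    "bottom_up_pass",
    "emit_maws",
    "compute_maws",
    "compute_maw_strings",
    "decode_tuple",
]


class LetterSet:
    """A set of alphabet letters as a bit vector (one bit per letter)."""

    __slots__ = ("size", "mask")

    def __init__(self, size: int, mask: int = 0):
        self.size = size
        self.mask = mask

    def add(self, letter: int) -> None:
        self.mask |= 1 << letter

    def discard(self, letter: int) -> None:
        self.mask &= ~(1 << letter)

    def clear(self) -> None:
        self.mask = 0

    def difference(self, other: "LetterSet") -> "LetterSet":
        return LetterSet(self.size, self.mask & ~other.mask)

    def __contains__(self, letter: int) -> bool:
        return bool(self.mask >> letter & 1)

    def __iter__(self) -> Iterator[int]:
        m, k = self.mask, 0
        while m:
            if m & 1:
                yield k
            m >>= 1
            k += 1

    def __len__(self) -> int:
        return self.mask.bit_count()

    def __eq__(self, other: object) -> bool:
        if isinstance(other, LetterSet):
            return self.mask == other.mask
        return NotImplemented

    def __repr__(self) -> str:
        return f"LetterSet(size={self.size}, letters={sorted(self)})"


class PrecedingSets:
    """The paired B arrays: ``b1[j]`` / ``b2[j]`` for factor ids ``j in [0, 2n)``.

    Stored as plain int bitmasks for speed; :meth:`b1_set` / :meth:`b2_set`
    give :class:`LetterSet` views.  ``all_letters`` is the bitmask of the
    letters that occur in the word (the B2 value for length-1 tails).
    """

    __slots__ = ("n", "sigma", "b1", "b2", "all_letters")

    def __init__(self, n: int, sigma: int, all_letters: int):
        self.n = n
        self.sigma = sigma
        self.b1 = [0] * (2 * n)
        self.b2 = [0] * (2 * n)
        self.all_letters = all_letters

    def b1_set(self, j: int) -> LetterSet:
        return LetterSet(self.sigma, self.b1[j])

    def b2_set(self, j: int) -> LetterSet:
        return LetterSet(self.sigma, self.b2[j])


class IntervalTable:
    """Letter sets indexed by prefix length, for the live lengths of a sweep.

    Capacity is ``max(lcp) + 2`` so every reachable prefix length has a
    slot.  ``insertions`` counts individual letter additions (the O(n sigma)
    work term).
    """

    __slots__ = ("entries", "insertions")

    def __init__(self, capacity: int):
        self.entries = [0] * capacity
        self.insertions = 0

    def reset(self) -> None:
        self.entries = [0] * len(self.entries)


class LcpStack:
    """Monotone stack of LCP values (bottom-up sweeps also use ``rem``).

    ``main`` is non-decreasing bottom-to-top and receives at most one push
    per rank (``pushes`` counts them).  During the bottom-up sweep, values
    about to expire are parked on ``rem`` so their interval entries can be
    cleared after the rank's bookkeeping is complete.
    """

    __slots__ = ("main", "rem", "pushes")

    def __init__(self):
        self.main: list[int] = []
        self.rem: list[int] = []
        self.pushes = 0

    def push(self, value: int) -> None:
        self.main.append(value)
        self.pushes += 1


class MawTuple(NamedTuple):
    """A MAW encoded as first letter ``a`` plus the tail interval ``y[i..j]``."""

    a: str
    i: int
    j: int


def enumerate_factor_pairs(ix: IndexedWord) -> Iterator[tuple[int, int, int]]:
    """Yield ``(id, start, length)`` for every candidate tail ``S_2i``, ``S_2i+1``.

    ``S_2i`` starts at ``sa[i]`` with length ``lcp[i] + 1``; ``S_2i+1``
    with length ``lcp[i+1] + 1`` (``lcp[n] = 0``).  A pair whose length
    exceeds the suffix length ``n - sa[i]`` is skipped.
    """
    n = len(ix)
    sa = ix.sa.tolist()
    lcp = ix.lcp.tolist()
    lcp.append(0)
    for i in range(n):
        start = sa[i]
        suffix_len = n - start
        yield 2 * i, start, lcp[i] + 1
        if lcp[i + 1] + 1 <= suffix_len:
            yield 2 * i + 1, start, lcp[i + 1] + 1


def _query(main: list[int], entries: list[int], t: int, a_bit: int, suffix_len: int) -> int:
    """Letters preceding visited occurrences of the current suffix's prefix of
    length ``t``, including the current rank's own preceding letter."""
    out = a_bit if t <= suffix_len else 0
    if main and t <= main[-1]:
        out |= entries[main[bisect_left(main, t)]]
    return out


def top_down_pass(
    ix: IndexedWord, sets: PrecedingSets, interval: IntervalTable, stack: LcpStack
) -> PrecedingSets:
    """Sweep ranks upward, filling B contributions from occurrences at ranks
    ``<= i``.

    Per rank: retire interval entries for prefix lengths greater than
    ``lcp[i]`` (their letters fold into the entry that replaces them), push
    ``lcp[i]`` if new, propagate the letter preceding ``sa[i]`` down the
    stack until a set that already holds it, then record the four B sets of
    the rank's factor pair.
    """
    word = ix.word.tolist()
    sa = ix.sa.tolist()
    lcp = ix.lcp.tolist()
    lcp.append(0)
    n = len(sa)
    main = stack.main
    ent = interval.entries
    b1, b2 = sets.b1, sets.b2
    all_mask = sets.all_letters
    prev_bit = 0
    for i in range(n):
        li = lcp[i]
        li1 = lcp[i + 1]
        # retire prefix lengths no longer shared with the current suffix;
        # the last (smallest) retired entry is the union of all of them
        carry = 0
        while main and main[-1] > li:
            v = main.pop()
            carry = ent[v]
            ent[v] = 0
        if not main or main[-1] < li:
            stack.push(li)
            # a fresh length inherits the retired letters plus the previous
            # rank's preceding letter (that suffix shares >= lcp[i] with us)
            ent[li] = carry | prev_bit
        p = sa[i]
        suffix_len = n - p
        a_bit = (1 << word[p - 1]) if p > 0 else 0
        if a_bit:
            for v in reversed(main):
                if ent[v] & a_bit:
                    break
                ent[v] |= a_bit
                interval.insertions += 1
        j0 = 2 * i
        b1[j0] |= _query(main, ent, li + 1, a_bit, suffix_len)
        b2[j0] |= all_mask if li == 0 else _query(main, ent, li, a_bit, suffix_len)
        if li1 + 1 <= suffix_len:
            j1 = j0 + 1
            b1[j1] |= _query(main, ent, li1 + 1, a_bit, suffix_len)
            b2[j1] |= all_mask if li1 == 0 else _query(main, ent, li1, a_bit, suffix_len)
        prev_bit = a_bit
    return sets


def bottom_up_pass(
    ix: IndexedWord, sets: PrecedingSets, interval: IntervalTable, stack: LcpStack
) -> PrecedingSets:
    """Sweep ranks downward, completing the B sets with occurrences at ranks
    ``>= i``.

    The interval table must be re-zeroed and the stack empty on entry.  Per
    rank the four B sets are recorded first (entries still cover lengths up
    to ``lcp[i+1]``), the rank's preceding letter is propagated, and only
    then are lengths greater than ``lcp[i]`` parked on ``rem`` and their
    entries cleared — the length ``lcp[i]`` slot that survives into the
    next rank inherits their letters.
    """
    word = ix.word.tolist()
    sa = ix.sa.tolist()
    lcp = ix.lcp.tolist()
    lcp.append(0)
    n = len(sa)
    main = stack.main
    rem = stack.rem
    ent = interval.entries
    b1, b2 = sets.b1, sets.b2
    all_mask = sets.all_letters
    for i in range(n - 1, -1, -1):
        li = lcp[i]
        li1 = lcp[i + 1]
        p = sa[i]
        suffix_len = n - p
        a_bit = (1 << word[p - 1]) if p > 0 else 0
        j0 = 2 * i
        b1[j0] |= _query(main, ent, li + 1, a_bit, suffix_len)
        b2[j0] |= all_mask if li == 0 else _query(main, ent, li, a_bit, suffix_len)
        if li1 + 1 <= suffix_len:
            j1 = j0 + 1
            b1[j1] |= _query(main, ent, li1 + 1, a_bit, suffix_len)
            b2[j1] |= all_mask if li1 == 0 else _query(main, ent, li1, a_bit, suffix_len)
        if a_bit:
            for v in reversed(main):
                if ent[v] & a_bit:
                    break
                ent[v] |= a_bit
                interval.insertions += 1
        # park lengths that exceed lcp[i] on rem, then clear their entries;
        # the deepest parked entry carries the union of their letters
        while main and main[-1] > li:
            rem.append(main.pop())
        carry = 0
        if rem:
            carry = ent[rem[-1]]
            for v in rem:
                ent[v] = 0
            rem.clear()
        if i > 0 and (not main or main[-1] < li):
            stack.push(li)
            ent[li] = carry | a_bit
    return sets


def emit_maws(
    ix: IndexedWord,
    sets: PrecedingSets,
    alphabet: Alphabet,
    residues: str,
    min_len: int = 2,
    max_len: int | None = None,
) -> list[MawTuple]:
    """Difference the completed B sets into MAW tuples.

    For every candidate tail id ``j`` and letter ``a`` in
    ``b2[j] & ~b1[j]``, the word ``a · S_j`` is a MAW.  Duplicates (one
    tail reachable through several ids) are removed on the key
    ``(a, tail string)``; the witness from the smallest id is kept.  Only
    lengths in ``[min_len, max_len]`` are reported.
    """
    n = len(ix)
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    if max_len is None:
        max_len = n + 1
    if max_len < min_len:
        raise ValueError(f"max_len ({max_len}) must be >= min_len ({min_len})")
    letters = alphabet.letters
    b1, b2 = sets.b1, sets.b2
    out: list[MawTuple] = []
    seen: set[tuple[int, str]] = set()
    for j, start, length in enumerate_factor_pairs(ix):
        diff = b2[j] & ~b1[j]
        if not diff or not (min_len <= length + 1 <= max_len):
            continue
        tail = residues[start : start + length]
        a = 0
        while diff:
            if diff & 1:
                key = (a, tail)
                if key not in seen:
                    seen.add(key)
                    out.append(MawTuple(letters[a], start, start + length - 1))
            diff >>= 1
            a += 1
    return out


def compute_maws(
    residues: str,
    alphabet: Alphabet | None = None,
    min_len: int = 2,
    max_len: int | None = None,
    *,
    collect_stats: dict | None = None,
) -> list[MawTuple]:
    """All minimal absent words of ``residues``, as tuples ``<a, (i, j)>``.

    Facade over index construction, the two sweeps, and emission.  When
    ``alphabet`` is ``None`` it is inferred from the residues.  If
    ``collect_stats`` is a dict it receives the sweeps' operation counters
    (stack pushes and interval letter insertions per pass).
    """
    if not residues:
        raise ValueError("cannot compute minimal absent words of an empty word")
    if alphabet is None:
        alphabet = Alphabet.from_text(residues)
    word = alphabet.encode(residues)
    ix = IndexedWord.build(word)
    n = len(ix)
    all_letters = 0
    for c in set(residues):
        all_letters |= 1 << alphabet.index[c]
    sets = PrecedingSets(n, alphabet.size, all_letters)
    interval = IntervalTable(int(ix.lcp.max()) + 2)
    down = LcpStack()
    top_down_pass(ix, sets, interval, down)
    interval_insertions_down = interval.insertions
    interval.reset()
    interval.insertions = 0
    up = LcpStack()
    bottom_up_pass(ix, sets, interval, up)
    if collect_stats is not None:
        collect_stats.update(
            top_down_pushes=down.pushes,
            bottom_up_pushes=up.pushes,
            top_down_insertions=interval_insertions_down,
            bottom_up_insertions=interval.insertions,
        )
    return emit_maws(ix, sets, alphabet, residues, min_len=min_len, max_len=max_len)


def compute_maw_strings(
    residues: str,
    alphabet: Alphabet | None = None,
    min_len: int = 2,
    max_len: int | None = None,
) -> list[str]:
    """Decoded MAWs of ``residues``, sorted lexicographically."""
    tuples = compute_maws(residues, alphabet, min_len, max_len)
    return sorted(decode_tuple(residues, t) for t in tuples)


def decode_tuple(residues: str, t: MawTuple) -> str:
    """Spell out a MAW tuple: ``t.a`` followed by ``residues[t.i .. t.j]``."""
    n = len(residues)
    if not (0 <= t.i <= t.j < n):
        raise IndexError(f"tuple interval ({t.i}, {t.j}) out of bounds for n={n}")
    return t.a + residues[t.i : t.j + 1]
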