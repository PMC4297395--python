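"""Suffix array, inverse suffix array, and LCP array construction.

All positions are 0-based and intervals inclusive.  The arrays cover the
``n`` real suffixes only — no sentinel appears in any exposed array.  The
boundary convention ``lcp[n] = 0`` (the rank just past the last suffix
shares nothing) is applied implicitly by consumers that enumerate factor
pairs; it is not stored.

Suffix arrays are built by prefix doubling over numpy ``lexsort`` — an
O(n log n) construction whose output contract (not its running time) is
what the rest of the package relies on.  LCP arrays use Kasai's O(n)
algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IndexedWord",
    "build_suffix_array",
    "build_inverse",
    "build_lcp",
    "lcp_of_ranks",
]


def build_suffix_array(word: Sequence[int]) -> np.ndarray:
    """Suffix array of ``word`` (a sequence of letter indices).

    Returns the permutation ``sa`` of ``[0, n)`` such that the suffixes
    ``word[sa[0]:] < word[sa[1]:] < ...`` are strictly increasing.
    """
    a = np.asarray(word, dtype=np.int64)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("cannot build a suffix array of an empty word")
    n = a.size
    rank = np.unique(a, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = np.cumsum(
            (rank[order[1:]] != rank[order[:-1]]) | (key2[order[1:]] != key2[order[:-1]])
        )
        if changed[-1] == n - 1:
            return order
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = changed
        rank = new_rank
        k *= 2


def build_inverse(sa: Sequence[int]) -> np.ndarray:
    """Inverse permutation: ``isa[sa[r]] = r``."""
    sa = np.asarray(sa, dtype=np.int64)
    n = sa.size
    if n == 0:
        raise ValueError("empty array is not a permutation")
    isa = np.full(n, -1, dtype=np.int64)
    if sa.min() < 0 or sa.max() >= n:
        raise ValueError("input is not a permutation of [0, n)")
    isa[sa] = np.arange(n, dtype=np.int64)
    if (isa < 0).any():
        raise ValueError("input is not a permutation of [0, n)")
    return isa


def build_lcp(word: Sequence[int], sa: Sequence[int], isa: Sequence[int]) -> np.ndarray:
    """LCP array by Kasai's algorithm: ``lcp[r]`` is the length of the longest
    common prefix of the suffixes at ranks ``r - 1`` and ``r``; ``lcp[0] = 0``.
    """
    w = np.asarray(word, dtype=np.int64)
    sa = np.asarray(sa, dtype=np.int64)
    isa = np.asarray(isa, dtype=np.int64)
    n = w.size
    if sa.size != n or isa.size != n:
        raise ValueError("word, sa and isa must have equal length")
    if n and not (isa[sa] == np.arange(n)).all():
        raise ValueError("isa is not the inverse of sa")
    lcp = np.zeros(n, dtype=np.int64)
    wl = w.tolist()
    sal = sa.tolist()
    isal = isa.tolist()
    k = 0
    for p in range(n):
        r = isal[p]
        if r == 0:
            k = 0
            continue
        q = sal[r - 1]
        while p + k < n and q + k < n and wl[p + k] == wl[q + k]:
            k += 1
        lcp[r] = k
        if k:
            k -= 1
    return lcp


@dataclass(frozen=True)
class IndexedWord:
    """A word together with its suffix array, inverse, and LCP array."""

    word: np.ndarray
    sa: np.ndarray
    isa: np.ndarray
    lcp: np.ndarray

    @classmethod
    def build(cls, word: Sequence[int]) -> "IndexedWord":
        w = np.asarray(word, dtype=np.int64)
        sa = build_suffix_array(w)
        isa = build_inverse(sa)
        lcp = build_lcp(w, sa, isa)
        return cls(word=w, sa=sa, isa=isa, lcp=lcp)

    def __len__(self) -> int:
        return int(self.word.size)


def lcp_of_ranks(ix: IndexedWord, r: int, s: int) -> int:
    """Length of the longest common prefix of the suffixes at ranks ``r``, ``s``.

    ``lcp(r, r)`` is the full suffix length.  Naive range-minimum over the
    LCP array; intended for verification, not for inner loops.
    """
    n = len(ix)
    if not (0 <= r < n and 0 <= s < n):
        raise IndexError(f"ranks ({r}, {s}) out of bounds for n={n}")
    if r == s:
        return int(n - ix.sa[r])
    lo, hi = min(r, s), max(r, s)
    return int(ix.lcp[lo + 1 : hi + 1].min())
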