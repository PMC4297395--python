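"""Brute-force references and random-word generation for verification.

Everything here is deliberately naive — quadratic or worse — and shares no
code with the suffix-array pipeline, so agreement between the two routes
is meaningful evidence of correctness.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator

from mawkit.sequence_io import Alphabet

__all__ = [
    "RandomWordSpec",
    "factor_set",
    "brute_force_maws",
    "preceding_letter_sets",
    "random_words",
]

_LETTER_POOL = "ABCD"


def factor_set(word: str) -> set[str]:
    """All distinct non-empty factors (substrings) of ``word``."""
    if not word:
        raise ValueError("word must be non-empty")
    n = len(word)
    return {word[i:j] for i in range(n) for j in range(i + 1, n + 1)}


def brute_force_maws(word: str, alphabet: Alphabet | None = None) -> set[str]:
    """Minimal absent words of ``word`` straight from the definition.

    A candidate ``x = a + f`` (``f`` a factor) is a MAW when ``x`` is
    absent and its longest proper prefix ``x[:-1]`` occurs; the longest
    proper suffix ``f`` occurs by construction, and then so does every
    proper factor.  Enumerating ``a + f`` over factors rather than all
    words of each length keeps the search polynomial without losing any
    candidate (a MAW's tail is always a factor).
    """
    if alphabet is None:
        alphabet = Alphabet.from_text(word)
    factors = factor_set(word)
    out: set[str] = set()
    for f in factors:
        for a in alphabet.letters:
            x = a + f
            if x in factors:
                continue
            if x[:-1] in factors:
                out.add(x)
    return out


def preceding_letter_sets(word: str, factor: str) -> tuple[set[str], set[str]]:
    """Definitional ``(B1, B2)`` for a factor: the letters immediately
    preceding its occurrences, and those preceding occurrences of its
    longest proper prefix.

    For a length-1 factor the longest proper prefix is the empty word,
    which occurs at every position, so ``B2`` is every letter of ``word``.
    """
    def preceders(f: str) -> set[str]:
        out = set()
        start = word.find(f)
        while start != -1:
            if start > 0:
                out.add(word[start - 1])
            start = word.find(f, start + 1)
        return out

    prefix = factor[:-1]
    b1 = preceders(factor)
    b2 = set(word) if not prefix else preceders(prefix)
    return b1, b2


@dataclass(frozen=True)
class RandomWordSpec:
    """Reproducible random-word stream: alphabet size, length range, seed."""

    sigma: int
    min_len: int
    max_len: int
    seed: int
    count: int

    def __post_init__(self) -> None:
        if not 1 <= self.sigma <= len(_LETTER_POOL):
            raise ValueError(f"sigma must be in [1, {len(_LETTER_POOL)}]")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.count < 0:
            raise ValueError("count must be non-negative")


def random_words(spec: RandomWordSpec) -> Iterator[str]:
    """Yield ``spec.count`` uniform random words; identical for a fixed seed."""
    rng = random.Random(spec.seed)
    letters = _LETTER_POOL[: spec.sigma]
    for _ in range(spec.count):
        n = rng.randint(spec.min_len, spec.max_len)
        yield "".join(rng.choice(letters) for _ in range(n))
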