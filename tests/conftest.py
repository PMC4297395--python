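"""Shared fixtures and naive reference helpers.

The suffix-structure oracles here sort or compare suffixes directly by
string comparison — independent of the package's constructions.
"""

import pytest

WORKED_WORD = "AABABABB"
WORKED_MAWS = {"AAA", "AABABB", "AABB", "BAA", "BABABA", "BBA", "BBB"}


def naive_suffix_array(word):
    """Sort all suffixes lexicographically by direct comparison."""
    return sorted(range(len(word)), key=lambda i: word[i:])


def naive_lcp_array(word, sa):
    """Character-by-character comparison of consecutive sorted suffixes."""
    lcp = [0] * len(word)
    for r in range(1, len(word)):
        a, b = word[sa[r - 1]:], word[sa[r]:]
        k = 0
        while k < min(len(a), len(b)) and a[k] == b[k]:
            k += 1
        lcp[r] = k
    return lcp


@pytest.fixture
def worked_word():
    return WORKED_WORD


@pytest.fixture
def worked_maws():
    return set(WORKED_MAWS)
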