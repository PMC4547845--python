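"""Dynamic-programming edit-distance oracles shared by the test modules."""

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Global alignment edit distance (substitutions, insertions, deletions)."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def dp_infix(read: str, locus: str) -> int:
    """Best edit distance of ``read`` against any substring of ``locus``."""
    prev = np.zeros(len(locus) + 1, dtype=int)  # free leading gap in locus
    for i, ca in enumerate(read, 1):
        cur = np.empty(len(locus) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(locus, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev.min())  # free trailing gap
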