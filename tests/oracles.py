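"""Independent oracles used by the tests.

Deliberately written in a different style from the package (plain-Python
list DP and substring enumeration, no numpy, no shared helpers) so they check
the implementation rather than mirror it.
"""
from functools import lru_cache
from typing import List, Tuple


def _sigma(a: str, b: str, match: int, mismatch: int) -> int:
    return match if (a == b and a in "ACGT") else mismatch


def sw_score_plain(read: str, ref: str, match: int = 1, mismatch: int = -1,
                   gap: int = -1) -> int:
    """Score-only Smith-Waterman, plain row DP over python lists."""
    n = len(ref)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, len(read) + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            cur[j] = max(0,
                         prev[j - 1] + _sigma(read[i - 1], ref[j - 1], match, mismatch),
                         cur[j - 1] + gap,
                         prev[j] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def brute_force_local(read: str, ref: str, match: int = 1, mismatch: int = -1,
                      gap: int = -1) -> int:
    """Best local score via enumeration: max over all substring pairs of the
    recursively-defined global (end-to-end) alignment score."""
    def global_score(a: str, b: str) -> int:
        @lru_cache(maxsize=None)
        def g(i: int, j: int) -> int:
            if i == 0 and j == 0:
                return 0
            cands = []
            if i and j:
                cands.append(g(i - 1, j - 1)
                             + _sigma(a[i - 1], b[j - 1], match, mismatch))
            if i:
                cands.append(g(i - 1, j) + gap)
            if j:
                cands.append(g(i, j - 1) + gap)
            return max(cands)
        return g(len(a), len(b))

    best = 0
    for i1 in range(len(read)):
        for i2 in range(i1 + 1, len(read) + 1):
            for j1 in range(len(ref)):
                for j2 in range(j1 + 1, len(ref) + 1):
                    score = global_score(read[i1:i2], ref[j1:j2])
                    if score > best:
                        best = score
    return best


def concat_pair_scores(read: str, left_seqs: List[str],
                       right_seqs: List[str]) -> List[Tuple[int, int, int]]:
    """Classic SW of the read against every left+right concatenation.

    Returns (score, left_index, right_index) per pair; the fanned aligner's
    global maximum must equal the max over these.
    """
    out = []
    for fl, left in enumerate(left_seqs):
        for fr, right in enumerate(right_seqs):
            out.append((sw_score_plain(read, left + right), fl, fr))
    return out


def concat_best(read: str, left_seqs: List[str], right_seqs: List[str]) -> int:
    return max(s for s, _, _ in concat_pair_scores(read, left_seqs, right_seqs))
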