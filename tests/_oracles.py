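"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively and shares no code with the package:
quadratic-DP edit distance, per-rule sequence filters, an exhaustive
self-priming window enumerator, and a channel-union color-balance check.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def lev_dp(a: str, b: str) -> int:
    """Textbook quadratic dynamic-programming edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def naive_leading_g(s: str) -> bool:
    return not s.startswith("G")


def naive_gc(s: str) -> bool:
    gc = sum(c in "GC" for c in s) / len(s)
    return not (gc <= 0.25 or gc >= 0.75)


def naive_repeats(s: str, max_units: int = 2) -> bool:
    for i in range(len(s)):
        # homopolymer run of max_units + 1 starting at i
        if s[i : i + max_units + 1] == s[i] * (max_units + 1):
            return False
        unit = s[i : i + 2]
        if len(unit) == 2 and s[i : i + 2 * (max_units + 1)] == unit * (max_units + 1):
            return False
    return True


def naive_sequence_filter(s: str) -> bool:
    return naive_leading_g(s) and naive_gc(s) and naive_repeats(s)


def naive_self_priming(
    full: str, i0: int, i1: int, window: int = 8, min_hamming: int = 3
) -> bool:
    """Enumerate every window of the primer, keep those overlapping the
    index span, compare each to the 3'-end reverse-complement probe."""
    probe = revcomp(full[len(full) - window :])
    hit = False
    for s in range(0, len(full) - window + 1):
        span = range(s, s + window)
        if not any(i0 <= p < i1 for p in span):
            continue
        dist = sum(x != y for x, y in zip(probe, full[s : s + window]))
        if dist < min_hamming:
            hit = True
    return hit


_CH = {"A": {"ch1", "ch2"}, "C": {"ch1"}, "T": {"ch2"}, "G": set()}


def naive_balanced(group) -> bool:
    """Channel-union color-balance re-implementation."""
    for pos in range(len(group[0])):
        union = set()
        for s in group:
            union = union | _CH[s[pos]]
        if "ch1" not in union or "ch2" not in union:
            return False
    return True
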