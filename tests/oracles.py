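"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: Levenshtein distance by
the textbook recursion, barcode assignment by exhaustive search over the
whole whitelist x all 16-bp windows, and cosine similarity from raw k-mer
dictionaries.
"""

from __future__ import annotations

import math
from functools import lru_cache
from collections import Counter


def levenshtein_recursive(a: str, b: str) -> int:
    """Textbook recursive definition (memoized); exponential-safe only for
    short strings."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + cost,
        )

    return rec(len(a), len(b))


def cosine_kmer(a: str, b: str, k: int = 8) -> float:
    """Cosine similarity between raw overlapping k-mer count vectors."""
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    dot = sum(ca[t] * cb[t] for t in ca)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def exhaustive_best_barcode(
    seq: str, whitelist, edit_distance, prefilter=None
) -> tuple[int, str | None]:
    """Global minimum edit distance over whitelist x all 16-bp windows.

    Ties resolve to the earliest whitelist entry (then leftmost window),
    which matches the implementation's deterministic tie rules when cosine
    information is absent. ``edit_distance`` is injected so the oracle can
    run on either the package's distance or an independent one;
    ``prefilter(barcode, best_so_far)`` may return a lower bound to skip
    hopeless barcodes (used only to speed up large sweeps; exactness is
    preserved because a true lower bound can never skip the argmin).
    """
    best_d, best_bc = math.inf, None
    for bc in whitelist:
        if prefilter is not None and best_d < math.inf:
            if prefilter(bc, best_d) > best_d:
                continue
        for off in range(len(seq) - 16 + 1):
            d = edit_distance(seq[off : off + 16], bc)
            if d < best_d:
                best_d, best_bc = d, bc
    return best_d, best_bc
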