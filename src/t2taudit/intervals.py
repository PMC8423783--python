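"""Half-open interval arithmetic on plain ``(start, end)`` pairs.

All coordinates are 0-based half-open throughout the package; these helpers
are the single implementation of union/subtract/coverage used by every
analysis module.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Pair = tuple[int, int]


def merge(pairs: Iterable[Pair]) -> list[Pair]:
    """Union of half-open intervals as a sorted list of disjoint pairs.

    Touching intervals (end == next start) are merged.
    """
    pairs = sorted((int(s), int(e)) for s, e in pairs)
    out: list[Pair] = []
    for s, e in pairs:
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union_length(pairs: Iterable[Pair]) -> int:
    return sum(e - s for s, e in merge(pairs))


def subtract(length: int, pairs: Iterable[Pair]) -> list[Pair]:
    """Complement of the union of ``pairs`` within ``[0, length)``."""
    out: list[Pair] = []
    cursor = 0
    for s, e in merge(pairs):
        s = max(0, min(s, length))
        e = max(0, min(e, length))
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out


def overlap_bp(a: Pair, b: Pair) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def clip(pairs: Iterable[Pair], lo: int, hi: int) -> list[Pair]:
    out = []
    for s, e in pairs:
        s, e = max(s, lo), min(e, hi)
        if e > s:
            out.append((s, e))
    return out


def window_coverage(pairs: Sequence[Pair], seq_length: int, window_size: int) -> np.ndarray:
    """Fraction of each fixed window covered by the union of ``pairs``.

    Windows are anchored at 0 and non-overlapping; the last (possibly short)
    window is normalised by its true width.  Intervals beyond ``seq_length``
    are clipped.
    """
    if seq_length <= 0:
        return np.zeros(0)
    n_win = -(-seq_length // window_size)  # ceil
    covered = np.zeros(n_win, dtype=float)
    for s, e in merge(clip(pairs, 0, seq_length)):
        w0, w1 = s // window_size, (e - 1) // window_size
        for w in range(w0, w1 + 1):
            ws, we = w * window_size, min((w + 1) * window_size, seq_length)
            covered[w] += overlap_bp((s, e), (ws, we))
    widths = np.minimum(
        (np.arange(n_win) + 1) * window_size, seq_length
    ) - np.arange(n_win) * window_size
    return covered / widths
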