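"""Half-open integer interval arithmetic on sorted ``(start, end)`` tuples.

All coordinates are 0-based, half-open. Inputs need not be sorted or
disjoint; outputs always are.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Bases of ``a`` not covered by ``b`` (both merged internally)."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def gaps(intervals: list[Interval]) -> list[Interval]:
    """Gaps between consecutive merged intervals (introns of an exon chain)."""
    m = merge(intervals)
    return [(m[i][1], m[i + 1][0]) for i in range(len(m) - 1) if m[i + 1][0] > m[i][1]]
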