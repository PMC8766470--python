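"""Independent reference implementations used only by the test suite.

These are deliberately written without reusing any package internals: a
memoized affine-state recursion for semi-global alignment scores, a naive
three-rule scan for off-target calling, and a string-slicing enumerator for
candidate ZFD sites.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def semiglobal_score(read: str, ref: str, match=2.0, mismatch=-3.0,
                     gap_open=-5.0, gap_extend=-2.0) -> float:
    """Best score over all alignments consuming the whole read, with free
    reference overhangs and affine gaps (length-L gap = open + (L-1)*extend)."""
    n, m = len(read), len(ref)
    neg = float("-inf")

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: str) -> float:
        if i == n:
            return 0.0  # remaining reference suffix is free
        best = neg
        if j < m:
            sub = match if read[i] == ref[j] else mismatch
            best = max(best, sub + go(i + 1, j + 1, "M"))
            dcost = gap_extend if state == "D" else gap_open
            best = max(best, dcost + go(i, j + 1, "D"))
        icost = gap_extend if state == "I" else gap_open
        best = max(best, icost + go(i + 1, j, "I"))
        return best

    result = max(go(0, j0, "S") for j0 in range(m + 1))
    go.cache_clear()
    return result


def naive_offtarget_scan(table_rows, masked, on_start, on_end, min_rate):
    """Apply the three off-target rules independently, row by row."""
    calls = []
    for row in table_rows:
        pos, rate = row["pos"], row["rate"]
        if rate < min_rate:
            continue
        if pos in masked:
            continue
        if on_start <= pos < on_end:
            continue
        calls.append(pos)
    return calls


def naive_site_scan(seq: str, half_len: int, smin: int, smax: int,
                    require_tc: bool, circular: bool):
    """Enumerate (plus_start, strand, left, spacer, right) tuples by brute force."""

    def rc(s):
        return "".join(_COMP[b] for b in reversed(s))

    n = len(seq)
    found = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        doubled = s + s
        for slen in range(smin, smax + 1):
            total = 2 * half_len + slen
            if total > n:
                continue
            starts = range(n) if circular else range(n - total + 1)
            for st in starts:
                w = doubled[st : st + total]
                spacer = w[half_len : half_len + slen]
                if require_tc:
                    # TC-context C on either spacer strand; 5' neighbour may
                    # come from the flanking half-site
                    ok = False
                    for k, b in enumerate(spacer):
                        if b == "C" and w[half_len + k - 1] == "T":
                            ok = True
                        if b == "G" and w[half_len + k + 1] == "A":
                            ok = True
                    if not ok:
                        continue
                plus_start = st if strand == "+" else (n - st - total) % n if circular else n - st - total
                found.append((plus_start, strand, w[:half_len], spacer, w[half_len + slen :]))
    return sorted(found)
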