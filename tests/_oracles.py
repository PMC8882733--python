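"""Independent brute-force oracles used only by the test suite.

These intentionally re-derive results with the simplest possible algorithms
(full dynamic programming, exhaustive enumeration, naive set logic) so the
package implementations are checked against a second route.
"""

from __future__ import annotations

STOP, DIAG, UP, LEFT = 0, 1, 2, 3


def full_local_dp(q: str, r: str):
    """Full (unbanded) Smith-Waterman with unit costs and traceback.

    Tie-break mirrors the package aligner: diagonal > up > left > stop, and
    the best cell is the first maximum in (i, j) scan order.  Returns
    (score, matches, mismatches, ins, dels, ref_start, ref_end,
    query_start, query_end) or None.
    """
    n, m = len(q), len(r)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[STOP] * (m + 1) for _ in range(n + 1)]
    best = (0, -1, -1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1][j - 1] + (1 if q[i - 1] == r[j - 1] else -1)
            up = H[i - 1][j] - 1
            left = H[i][j - 1] - 1
            score, ptr = 0, STOP
            if diag > score:
                score, ptr = diag, DIAG
            if up > score:
                score, ptr = up, UP
            if left > score:
                score, ptr = left, LEFT
            H[i][j] = score
            P[i][j] = ptr
            if score > best[0]:
                best = (score, i, j)
    if best[0] <= 0:
        return None
    score, i, j = best
    ref_end = j
    query_end = i
    matches = mismatches = ins = dels = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        ptr = P[i][j]
        if ptr == DIAG:
            if q[i - 1] == r[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i, j = i - 1, j - 1
        elif ptr == UP:
            ins += 1
            i -= 1
        elif ptr == LEFT:
            dels += 1
            j -= 1
        else:
            break
    return score, matches, mismatches, ins, dels, j, ref_end, i, query_end


def global_match_count(a: str, b: str) -> int:
    """Match count of a match-only-scoring global alignment (recursive defn)."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def circular_identity_oracle(a: str, b: str) -> float:
    """Exhaustive rotation enumeration with the full-DP match count."""
    best = 0
    for r in range(len(b)):
        rot = b[r:] + b[:r]
        best = max(best, global_match_count(a, rot))
    return best / max(len(a), len(b))


def confusion_oracle(assembled: dict, verified: dict) -> dict:
    """Naive per-candidate double loop over strategies and keys."""
    out = {}
    for s, asm in assembled.items():
        tp = fp = fn = 0
        for key in asm:
            if key in verified[s]:
                tp += 1
            else:
                fp += 1
        union_others = set()
        for t, ver in verified.items():
            if t != s:
                for key in ver:
                    union_others.add(key)
        for key in union_others:
            if key not in asm:
                fn += 1
        out[s] = (tp, fp, fn)
    return out


def enumerate_chains(annotation, chrom, start, end, strand):
    """All consecutive-exon runs anchored exactly at (start, end)."""
    chains = []
    for tx in annotation.transcripts.values():
        if tx.chrom != chrom or tx.strand != strand:
            continue
        exons = tx.exons
        for i in range(len(exons)):
            for j in range(i, len(exons)):
                if exons[i].start == start and exons[j].end == end:
                    chains.append(exons[i : j + 1])
    return chains
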