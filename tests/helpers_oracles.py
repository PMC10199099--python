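"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive — per-basepair marking, all-pairs
scans, exhaustive enumeration — and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def merge_oracle_per_bp(intervals: list[tuple[str, int, int]]):
    """Merge by marking covered bases and extracting runs.

    Per-bp marking fuses book-ended intervals, so this is the oracle
    for min_overlap_bp=0 (and for covered-base accounting generally).
    """
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = [(s, e) for c, s, e in intervals if c == chrom]
        hi = max(e for _, e in ivs)
        cov = np.zeros(hi + 2, dtype=bool)
        for s, e in ivs:
            cov[s:e] = True
        runs = []
        in_run = False
        for i in range(len(cov)):
            if cov[i] and not in_run:
                start, in_run = i, True
            elif not cov[i] and in_run:
                runs.append((chrom, start, i))
                in_run = False
        out.extend(runs)
    return out


def merge_oracle_components(intervals: list[tuple[str, int, int]], min_overlap_bp: int = 1):
    """Merge by exhaustive pairwise-overlap connected components.

    Two intervals are linked when they share >= min_overlap_bp bases;
    each component contributes its (min start, max end) span.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and min(ei, ej) - max(si, sj) >= min_overlap_bp:
                parent[find(i)] = find(j)
    spans = {}
    for i, (c, s, e) in enumerate(intervals):
        root = find(i)
        if root in spans:
            cs, ss, es = spans[root]
            spans[root] = (c, min(ss, s), max(es, e))
        else:
            spans[root] = (c, s, e)
    return sorted(spans.values())


def intersect_oracle_all_pairs(a, b, min_overlap_bp: int = 1):
    """All-pairs overlap scan: dict a-id -> sorted list of b-ids."""
    out = {}
    for ca, sa, ea, ida in a:
        hits = []
        for cb, sb, eb, idb in b:
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap_bp:
                hits.append(idb)
        out[ida] = sorted(hits)
    return out


def nearest_oracle(peaks, tss_list):
    """Exhaustive nearest-TSS scan.

    ``peaks``: (chrom, start, end, id); ``tss_list``: (chrom, tss, gene_id).
    Distance 0 when the TSS is inside the peak, else signed bp gap from
    the peak edge; ties by smallest (|distance|, gene_id).
    """
    out = {}
    for chrom, start, end, pid in peaks:
        best = None
        for gc, tss, gid in tss_list:
            if gc != chrom:
                continue
            if start <= tss < end:
                signed = 0
            elif tss < start:
                signed = tss - start
            else:
                signed = tss - end
            key = (abs(signed), gid)
            if best is None or key < best[0]:
                best = (key, (gid, signed))
        out[pid] = None if best is None else best[1]
    return out


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up, evaluated literally.

    q_(i) = min_{j >= i} ( n * p_(j) / j ), capped at 1, mapped back to
    the original order.
    """
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q_sorted = [0.0] * n
    running_min = 1.0
    for rank in range(n - 1, -1, -1):
        val = n * p[order[rank]] / (rank + 1)
        running_min = min(running_min, val)
        q_sorted[rank] = min(1.0, running_min)
    q = [0.0] * n
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def gcr_rule_oracle(traj, theta, mode, min_total_drop=None):
    """Literal evaluation of the GCR membership rule, step by step."""
    steps = [traj[i] - traj[i + 1] for i in range(len(traj) - 1)]
    if mode == "monotone_min_step":
        return all(d >= theta for d in steps)
    if min_total_drop is None:
        min_total_drop = theta
    return (
        all(d >= 0 for d in steps)
        and all(d <= theta for d in steps)
        and (traj[0] - traj[-1]) >= min_total_drop
    )


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def classify_sequence_oracle(states):
    """Label an open/closed sequence by literal switch counting."""
    switches = sum(1 for i in range(len(states) - 1) if states[i] != states[i + 1])
    if switches == 0:
        return "stable_open" if states[0] else "stable_closed"
    if switches >= 2:
        return "complex"
    # single switch: find it
    k = next(i for i in range(len(states) - 1) if states[i] != states[i + 1]) + 1
    return (f"OC{k}" if states[0] else f"CO{k}")
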