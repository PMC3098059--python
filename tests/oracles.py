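"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(n*m) scans, explicit base-set
arithmetic, exhaustive combinatorial sums — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import math


def bases(start: int, end: int) -> set[int]:
    """Explicit set of bases covered by a closed interval."""
    return set(range(start, end + 1))


def brute_gap(a, b) -> float:
    """Gap via explicit base sets (coordinates must be small)."""
    if a.chrom != b.chrom:
        return math.inf
    sa, sb = bases(a.start, a.end), bases(b.start, b.end)
    if sa & sb:
        return 0
    lo, hi = (a, b) if a.end < b.start else (b, a)
    between = set(range(lo.end + 1, hi.start)) - sa - sb
    return len(between)


def brute_nearest(peak, features):
    """Argmin of |signed TSS distance| with the documented tie-break:
    smaller |d|, then upstream (d<0) before downstream, then name."""
    best = None
    best_key = None
    for f in features:
        if f.chrom != peak.chrom:
            continue
        tss = f.start if f.strand == "+" else f.end
        d = (peak.start - tss) if f.strand == "+" else (tss - peak.start)
        key = (abs(d), 0 if d < 0 else 1, f.name)
        if best_key is None or key < best_key:
            best, best_key = (f, d), key
    return best  # (feature, distance) or None


def brute_overlapping(peak, features, maxgap: int):
    """All features with gap <= maxgap, by direct pairwise scan."""
    hits = []
    for f in features:
        if f.chrom != peak.chrom:
            continue
        if f.start > peak.end:
            g = f.start - peak.end - 1
        elif peak.start > f.end:
            g = peak.start - f.end - 1
        else:
            g = 0
        if g <= maxgap:
            hits.append(f)
    return hits


def brute_components(tagged_regions, maxgap: int):
    """Union-find over the full pairwise gap matrix.

    ``tagged_regions`` is a list of (set_index, region); returns a list of
    frozensets of indices into that list.
    """
    n = len(tagged_regions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tagged_regions[i][1], tagged_regions[j][1]
            if a.chrom != b.chrom:
                continue
            if a.start > b.start:
                a, b = b, a
            if b.start - a.end - 1 <= maxgap:
                union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n), by exhaustive summation."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_step_up(pvals):
    """Benjamini-Hochberg adjusted p-values from the step-up definition:
    adj(i) = min_{j >= i} p(j) * m / j on the sorted vector, capped at 1,
    mapped back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted_sorted = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        adjusted_sorted[rank - 1] = min(1.0, running)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = adjusted_sorted[rank]
    return out


def parse_fasta_text(text: str) -> dict[str, str]:
    """Minimal FASTA parser (id = header up to first whitespace)."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks)
    return records
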