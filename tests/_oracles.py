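"""Independent brute-force oracles for the interval algebra and statistics.

These deliberately avoid the package's own data paths: coverage questions are
answered with per-base boolean masks, neighbour questions with all-pairs
scans, and the small-sample rank test with full enumeration.
"""

from itertools import combinations

import numpy as np

from accessmarks.intervals import GenomicInterval


def mask_of(intervals, genome):
    """Per-chromosome boolean coverage mask (only usable on tiny genomes)."""
    masks = {chrom: np.zeros(genome[chrom], dtype=bool) for chrom in genome}
    for iv in intervals:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def intervals_from_mask(masks):
    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def brute_nearest(query, subjects):
    """All-pairs minimum edge-to-edge gap; None if no subject on the chromosome."""
    best = None
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        gap = max(0, s.start - query.end, query.start - s.end)
        if best is None or gap < best:
            best = gap
    return best


def brute_count(query, subjects):
    """Quadratic overlap count (shared base pairs required)."""
    return sum(
        1
        for s in subjects
        if s.chrom == query.chrom and s.start < query.end and query.start < s.end
    )


def random_intervals(rng, genome, n, max_len=500):
    out = []
    chroms = list(genome)
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def track_mean_per_base(segments, start, end):
    """Length-weighted mean over [start, end) from explicit (s, e, v) segments."""
    base = np.zeros(end - start)
    for s, e, v in segments:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            base[lo - start:hi - start] = v
    return float(base.mean())


def mannwhitney_exact_greater(other, reference):
    """P(U >= observed) for 'other greater' by enumerating all rank splits."""
    pooled = list(other) + list(reference)
    n_other = len(other)
    observed = _u_stat(other, reference)
    idx = range(len(pooled))
    total = 0
    at_least = 0
    for combo in combinations(idx, n_other):
        grp = [pooled[i] for i in combo]
        rest = [pooled[i] for i in idx if i not in combo]
        total += 1
        if _u_stat(grp, rest) >= observed:
            at_least += 1
    return at_least / total


def _u_stat(a, b):
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
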