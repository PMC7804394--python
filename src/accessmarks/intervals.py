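"""Interval algebra on 0-based half-open genomic coordinates.

All region sets in the pipeline (Tn5 hypersensitive sites, histone-mark
peaks, TF binding sites, blacklist entries) are collections of
:class:`GenomicInterval` on a :class:`Genome`.  Coordinates follow the BED
convention: ``start`` is 0-based inclusive, ``end`` exclusive.

Two conventions matter downstream and are fixed here:

* *overlap* means sharing at least one base pair; intervals that merely touch
  (``a.end == b.start``) do not overlap;
* *distance* between non-overlapping intervals is the edge-to-edge gap in bp,
  so touching intervals have distance 0 even though they do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Genome",
    "GenomicInterval",
    "PeakSet",
    "CoordinateError",
    "merge",
    "intersect",
    "subtract",
    "nearest_distance",
    "count_overlaps",
    "total_length",
]


class CoordinateError(ValueError):
    """Raised when an interval violates coordinate invariants."""


class Genome:
    """Chromosome name -> length table (a chrom.sizes file in memory)."""

    def __init__(self, sizes: Mapping[str, int]):
        if not sizes:
            raise ValueError("genome must contain at least one chromosome")
        clean: dict[str, int] = {}
        for name, length in sizes.items():
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in clean:
                raise ValueError(f"duplicate chromosome name {name!r}")
            clean[name] = length
        self._sizes = clean

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def validate(self, intervals: Iterable["GenomicInterval"]) -> None:
        """Raise :class:`CoordinateError` for any interval outside the genome."""
        for iv in intervals:
            if iv.chrom not in self._sizes:
                raise CoordinateError(f"unknown chromosome in {iv}")
            if iv.end > self._sizes[iv.chrom]:
                raise CoordinateError(
                    f"{iv} extends past end of {iv.chrom} ({self._sizes[iv.chrom]} bp)"
                )


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."
    qvalue: Optional[float] = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                " (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise CoordinateError(f"q-value {self.qvalue} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """Named, sorted, deduplicated collection of intervals.

    Exact coordinate duplicates collapse on construction (first record wins).
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        seen: set[tuple] = set()
        out: list[GenomicInterval] = []
        for iv in sorted(self.intervals, key=GenomicInterval.sort_key):
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                out.append(iv)
        self.intervals = out

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def filtered(self, predicate) -> "PeakSet":
        return PeakSet(self.label, [iv for iv in self.intervals if predicate(iv)])


# ---------------------------------------------------------------------------
# helpers


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=GenomicInterval.sort_key)
    return out


def _arrays(intervals: Sequence[GenomicInterval]):
    starts = np.fromiter((iv.start for iv in intervals), dtype=np.int64, count=len(intervals))
    ends = np.fromiter((iv.end for iv in intervals), dtype=np.int64, count=len(intervals))
    return starts, ends


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the (merged) union of ``intervals``."""
    return sum(len(iv) for iv in merge(list(intervals)))


# ---------------------------------------------------------------------------
# algebra


def merge(intervals: Sequence[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Union of intervals; runs separated by <= ``gap`` bp are bridged."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: list[GenomicInterval] = []
    grouped = _by_chrom(intervals)
    for chrom in sorted(grouped):
        cur_s = cur_e = None
        for iv in grouped[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-pair intersection of the coverage of ``a`` and ``b``."""
    am = _by_chrom(merge(a))
    bm = _by_chrom(merge(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(
    a: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove blacklisted base pairs from ``a`` (region-level masking)."""
    bl = _by_chrom(merge(blacklist))
    out: list[GenomicInterval] = []
    for iv in sorted(a, key=GenomicInterval.sort_key):
        cuts = bl.get(iv.chrom, [])
        pos = iv.start
        for c in cuts:
            if c.end <= pos:
                continue
            if c.start >= iv.end:
                break
            if c.start > pos:
                out.append(replace(iv, start=pos, end=c.start))
            pos = max(pos, c.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(replace(iv, start=pos, end=iv.end))
    return out


def nearest_distance(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[Optional[int]]:
    """Edge-to-edge gap from each query to its nearest subject interval.

    Overlap gives 0; touching also gives 0 (but is not an overlap).  Queries on
    chromosomes with no subject interval get ``None`` — never a spurious 0.
    """
    subj = {c: _arrays(ivs) for c, ivs in _by_chrom(subject).items()}
    out: list[Optional[int]] = []
    for q in query:
        if q.chrom not in subj:
            out.append(None)
            continue
        starts, ends = subj[q.chrom]
        gaps = np.maximum(0, np.maximum(starts - q.end, q.start - ends))
        out.append(int(gaps.min()))
    return out


def count_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> np.ndarray:
    """Number of subject intervals sharing >= 1 bp with each query."""
    grouped = _by_chrom(subject)
    sorted_starts = {}
    sorted_ends = {}
    for chrom, ivs in grouped.items():
        starts, ends = _arrays(ivs)
        sorted_starts[chrom] = np.sort(starts)
        sorted_ends[chrom] = np.sort(ends)
    counts = np.zeros(len(query), dtype=np.int64)
    for i, q in enumerate(query):
        if q.chrom not in sorted_starts:
            continue
        n_start_before_qend = np.searchsorted(sorted_starts[q.chrom], q.end, side="left")
        n_end_before_qstart = np.searchsorted(sorted_ends[q.chrom], q.start, side="right")
        counts[i] = n_start_before_qend - n_end_before_qstart
    return counts
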