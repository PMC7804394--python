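"""Spatial association between consensus accessible regions and mark peaks.

Distances are edge-to-edge gaps in bp; distance 0 with shared base pairs is an
overlap, distance 0 without shared base pairs is touching.  The binned report
is non-overlapping (each region counted once, in the bin of its nearest mark
peak); a cumulative report ("within d bp") is emitted alongside because the
headline numbers in this kind of analysis are cumulative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, PeakSet, count_overlaps, nearest_distance


@dataclass
class DistanceBinSummary:
    edges: tuple[int, ...]
    table: pd.DataFrame       # per-bin count and percent, plus terminal bin
    cumulative: pd.DataFrame  # percent within each edge (overlap counted in all)
    total: int


def distance_bin_percentages(
    consensus: Sequence[GenomicInterval],
    marks: PeakSet,
    edges: Sequence[int] = (0, 100, 500, 1000, 2000),
) -> DistanceBinSummary:
    """Fraction of regions whose nearest mark peak falls in each distance bin.

    ``edges[0]`` must be 0: the first bin is overlap (shared base pairs).
    Regions beyond the last edge, or on chromosomes without any mark peak,
    fall in the terminal bin.
    """
    edges = tuple(int(e) for e in edges)
    if not consensus:
        raise ValueError("no consensus regions provided")
    if edges[0] != 0 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must start at 0 and be strictly increasing")

    dists = nearest_distance(consensus, marks.intervals)
    overlapping = count_overlaps(consensus, marks.intervals) > 0

    labels = ["overlap"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"({lo},{hi}]")
    terminal = f">{edges[-1]}_or_none"
    labels.append(terminal)

    counts = {label: 0 for label in labels}
    for d, ov in zip(dists, overlapping):
        if ov:
            counts["overlap"] += 1
            continue
        if d is None or d > edges[-1]:
            counts[terminal] += 1
            continue
        for lo, hi in zip(edges, edges[1:]):
            if lo <= d <= hi if lo == 0 else lo < d <= hi:
                counts[f"({lo},{hi}]"] += 1
                break
    total = len(consensus)
    table = pd.DataFrame({"count": [counts[label] for label in labels]}, index=labels)
    table["percent"] = 100.0 * table["count"] / total

    cum_rows = {}
    for edge in edges:
        n = sum(
            1
            for d, ov in zip(dists, overlapping)
            if ov or (d is not None and d <= edge)
        )
        cum_rows[f"within_{edge}bp"] = n
    cumulative = pd.DataFrame({"count": cum_rows})
    cumulative["percent"] = 100.0 * cumulative["count"] / total
    return DistanceBinSummary(edges=edges, table=table, cumulative=cumulative, total=total)


def colocalization_venn(
    consensus: Sequence[GenomicInterval],
    marks_a: PeakSet,
    marks_b: PeakSet,
    d: int = 2000,
) -> pd.DataFrame:
    """Classify regions by having an A and/or B mark peak within ``d`` bp.

    Returns the four cell counts (both, a_only, b_only, neither), their
    percentages, and the share of A-associated regions that are also
    B-associated (both / (both + a_only)).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    near_a = _within(consensus, marks_a, d)
    near_b = _within(consensus, marks_b, d)
    both = sum(1 for x, y in zip(near_a, near_b) if x and y)
    a_only = sum(1 for x, y in zip(near_a, near_b) if x and not y)
    b_only = sum(1 for x, y in zip(near_a, near_b) if y and not x)
    neither = len(consensus) - both - a_only - b_only
    total = len(consensus)
    df = pd.DataFrame(
        {"count": [both, a_only, b_only, neither]},
        index=["both", "a_only", "b_only", "neither"],
    )
    df["percent"] = 100.0 * df["count"] / total if total else 0.0
    df.attrs["share_of_a_also_b"] = both / (both + a_only) if (both + a_only) else float("nan")
    df.attrs["share_of_b_also_a"] = both / (both + b_only) if (both + b_only) else float("nan")
    return df


def _within(regions, marks: PeakSet, d: int) -> list[bool]:
    dists = nearest_distance(regions, marks.intervals)
    overlapping = count_overlaps(regions, marks.intervals) > 0
    return [
        bool(ov or (dist is not None and dist <= d))
        for dist, ov in zip(dists, overlapping)
    ]
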