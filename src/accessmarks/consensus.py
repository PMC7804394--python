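"""Consensus accessible-region (THS) construction and accessibility matrices.

Per-genotype THSs are the base-pair intersection of the two replicate peak
sets; the consensus set is the merged union across genotypes.  A region is
kept as high-confidence when its accessibility exceeds a minimum CPM and it
passes the peak-caller q cutoff in at least one genotype.  The module also
computes the TSS-relative distribution of consensus regions and strand-aware
average signal profiles around the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, count_overlaps, intersect, merge
from .io import GeneModel, SignalTrack
from .stats import moderated_diff

logger = logging.getLogger("accessmarks")


@dataclass(frozen=True)
class ConsensusTHS:
    interval: GenomicInterval
    provenance: tuple[str, ...]  # genotypes whose THSs overlap this region

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def replicate_consensus(rep1: PeakSet, rep2: PeakSet, mode: str = "intersect") -> PeakSet:
    """Genotype THSs from two replicates (base-pair intersection, merged).

    ``mode='union'`` instead keeps the merged union of peaks that overlap a
    peak in the other replicate.
    """
    if mode == "intersect":
        regions = merge(intersect(rep1.intervals, rep2.intervals))
    elif mode == "union":
        keep1 = [iv for iv, c in zip(rep1, count_overlaps(rep1.intervals, rep2.intervals)) if c > 0]
        keep2 = [iv for iv, c in zip(rep2, count_overlaps(rep2.intervals, rep1.intervals)) if c > 0]
        regions = merge(keep1 + keep2)
    else:
        raise ValueError(f"unknown replicate consensus mode {mode!r}")
    return PeakSet(f"{rep1.label}-consensus", regions)


def build_consensus(genotype_ths: Mapping[str, PeakSet]) -> list[ConsensusTHS]:
    """Merged union across genotypes, with per-region genotype provenance."""
    if not genotype_ths:
        raise ValueError("need at least one genotype THS set")
    union = merge([iv for ps in genotype_ths.values() for iv in ps])
    out = []
    overlaps = {
        g: count_overlaps(union, ps.intervals) > 0 for g, ps in genotype_ths.items()
    }
    for i, iv in enumerate(union):
        prov = tuple(g for g in genotype_ths if overlaps[g][i])
        out.append(ConsensusTHS(iv, prov))
    return out


def genotype_qpass(
    consensus: Sequence[ConsensusTHS],
    replicate_peaks: Mapping[str, Sequence[PeakSet]],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-region, per-genotype q-pass flags.

    A genotype passes on a region when *both* of its replicates have an
    overlapping peak called at q < cutoff (peaks are called per replicate).
    Peaks without a q-value never pass.
    """
    regions = [c.interval for c in consensus]
    idx = [c.region_id for c in consensus]
    flags = {}
    for genotype, reps in replicate_peaks.items():
        per_rep = []
        for rep in reps:
            good = [iv for iv in rep if iv.qvalue is not None and iv.qvalue < q_cutoff]
            per_rep.append(count_overlaps(regions, good) > 0)
        flags[genotype] = np.logical_and.reduce(per_rep)
    return pd.DataFrame(flags, index=idx)


def build_matrix(
    consensus: Sequence[ConsensusTHS], tracks: Mapping[str, SignalTrack]
) -> pd.DataFrame:
    """Regions x samples matrix of length-weighted mean CPM."""
    idx = [c.region_id for c in consensus]
    data = {}
    for sample, track in tracks.items():
        data[sample] = [
            track.mean(c.interval.chrom, c.interval.start, c.interval.end, warn_missing=True)
            for c in consensus
        ]
    return pd.DataFrame(data, index=idx)


def filter_matrix(
    matrix: pd.DataFrame,
    percentile: Optional[float] = 5.0,
    fallback_min: float = 3.0,
) -> tuple[pd.DataFrame, float]:
    """Drop rows whose maximum across samples is below the noise threshold.

    The threshold is the given lower percentile of the pooled entry
    distribution (linear interpolation); with ``percentile=None`` the fixed
    ``fallback_min`` CPM floor is used instead.  Returns (filtered, threshold).
    """
    if matrix.empty:
        raise ValueError("matrix is empty")
    if percentile is None:
        threshold = float(fallback_min)
    else:
        threshold = float(np.percentile(matrix.to_numpy(dtype=float).ravel(), percentile))
    keep = matrix.max(axis=1) >= threshold
    logger.info(
        "signal filter threshold %.4g CPM; %d/%d regions retained",
        threshold, int(keep.sum()), len(matrix),
    )
    if not keep.any():
        logger.warning("signal filter removed every row")
    return matrix.loc[keep], threshold


def confidence_filter(
    consensus: Sequence[ConsensusTHS],
    matrix: pd.DataFrame,
    qpass: pd.DataFrame,
    sample_genotypes: Mapping[str, str],
    min_cpm: float = 3.0,
) -> list[ConsensusTHS]:
    """High-confidence consensus: CPM > min_cpm with a q-pass in >= 1 genotype.

    Per-genotype CPM is the mean over that genotype's replicate columns; the
    region is retained when its maximum per-genotype CPM exceeds ``min_cpm``
    and at least one genotype passes the q cutoff.
    """
    by_genotype: dict[str, list[str]] = {}
    for sample, genotype in sample_genotypes.items():
        by_genotype.setdefault(genotype, []).append(sample)
    genotype_means = pd.DataFrame(
        {g: matrix[cols].mean(axis=1) for g, cols in by_genotype.items()}
    )
    keep = []
    for c in consensus:
        rid = c.region_id
        if rid not in matrix.index:
            continue
        if genotype_means.loc[rid].max() > min_cpm and bool(qpass.loc[rid].any()):
            keep.append(c)
    return keep


def differential_accessibility(
    matrix: pd.DataFrame,
    sample_genotypes: Mapping[str, str],
    genotype: str,
    reference: str = "WT",
    alpha: float = 0.05,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-region moderated log2FC mutant vs reference plus a direction call.

    Direction is 'increased'/'decreased' at p < alpha, else 'unchanged'; no
    fold-change floor is applied.
    """
    group_a = [s for s, g in sample_genotypes.items() if g == genotype]
    group_b = [s for s, g in sample_genotypes.items() if g == reference]
    res = moderated_diff(matrix, group_a, group_b, prior_df=prior_df)
    direction = np.where(
        res.p < alpha,
        np.where(res.log2fc > 0, "increased", "decreased"),
        "unchanged",
    )
    return pd.DataFrame(
        {"log2fc": res.log2fc, "t": res.t, "p": res.p, "direction": direction},
        index=matrix.index,
    )


# ---------------------------------------------------------------------------
# TSS geometry


def tss_distribution(
    consensus: Sequence[ConsensusTHS],
    genes: Sequence[GeneModel],
    upstream_edges: Sequence[int] = (1000, 3000),
) -> pd.DataFrame:
    """Percentage of consensus regions per TSS-relative location bin.

    Each region is assigned once, by the signed strand-aware distance from its
    center to the nearest TSS (negative upstream): inside a gene body ->
    'gene_body'; otherwise upstream bins split at ``upstream_edges`` or a
    single 'downstream' bin.
    """
    if not genes:
        raise ValueError("no gene models provided")
    if not consensus:
        raise ValueError("no consensus regions provided")
    edges = sorted(int(e) for e in upstream_edges)
    labels = []
    labels.append(f"upstream_gt_{edges[-1]}")
    for hi, lo in zip(reversed(edges), list(reversed(edges))[1:] + [0]):
        labels.append(f"upstream_{lo}_{hi}")
    labels += ["gene_body", "downstream"]

    bodies = [g.body for g in genes]
    by_chrom_tss: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom_tss.setdefault(g.chrom, []).append((g.tss, g.strand))

    counts = {label: 0 for label in labels}
    centers = [
        GenomicInterval(c.interval.chrom, (c.interval.start + c.interval.end) // 2,
                        (c.interval.start + c.interval.end) // 2 + 1)
        for c in consensus
    ]
    in_body = count_overlaps(centers, bodies) > 0
    for center_iv, inside in zip(centers, in_body):
        if inside:
            counts["gene_body"] += 1
            continue
        tss_list = by_chrom_tss.get(center_iv.chrom)
        if not tss_list:
            counts["downstream"] += 1  # no anchor on this chromosome
            continue
        center = center_iv.start
        best = None
        for tss, strand in tss_list:
            signed = center - tss if strand == "+" else tss - center
            if best is None or abs(signed) < abs(best):
                best = signed
        if best >= 0:
            counts["downstream"] += 1
        else:
            d = -best
            placed = False
            lo = 0
            for hi in edges:
                if d <= hi:
                    counts[f"upstream_{lo}_{hi}"] += 1
                    placed = True
                    break
                lo = hi
            if not placed:
                counts[f"upstream_gt_{edges[-1]}"] += 1
    total = len(consensus)
    df = pd.DataFrame(
        {"count": [counts[label] for label in labels]}, index=labels
    )
    df["percent"] = 100.0 * df["count"] / total
    return df


def tss_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (-2000, 2000),
    binsize: int = 100,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Strand-aware average signal profile around the TSS.

    Returns a frame indexed by the bin's relative start position; each value
    is the mean over genes of the mean CPM in that bin.  Bins that would fall
    off a chromosome edge are excluded from their positional mean.
    """
    w0, w1 = window
    if not (w0 < 0 < w1):
        raise ValueError("window must span the TSS")
    if (w1 - w0) % binsize != 0:
        raise ValueError("binsize must divide the window")
    rel_starts = np.arange(w0, w1, binsize)
    sums = np.zeros(len(rel_starts))
    ns = np.zeros(len(rel_starts), dtype=int)
    for g in genes:
        limit = chrom_sizes[g.chrom] if chrom_sizes is not None and g.chrom in chrom_sizes else None
        t = g.tss
        for i, r0 in enumerate(rel_starts):
            if g.strand == "+":
                s, e = t + r0, t + r0 + binsize
            else:
                s, e = t - r0 - binsize + 1, t - r0 + 1
            if s < 0 or (limit is not None and e > limit):
                continue
            sums[i] += track.mean(g.chrom, s, e)
            ns[i] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return pd.DataFrame({"mean_cpm": means, "n_genes": ns}, index=pd.Index(rel_starts, name="rel_start"))
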