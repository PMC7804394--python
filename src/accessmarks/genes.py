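"""Gene-centric mark quantification and classification.

A gene is associated with a histone-mark peak when the peak overlaps the gene
body or the 750 bp promoter upstream of the TSS (strand-aware).  Per-gene mark
signal is the length-weighted mean CPM over the base-pair union of the gene's
associated peaks; low-signal genes (below ~3 CPM, the lower 5% of the pooled
signal distribution) are filtered out.  Mutant levels are expressed as a
fraction of wild type and binned; <60% of WT corresponds to log2FC <=
log2(0.6) = -0.737, the usual printed cutoff -0.74.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, merge
from .io import GeneModel, SignalTrack
from .stats import moderated_diff

logger = logging.getLogger("accessmarks")

LEVEL_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.2, math.inf)
LEVEL_BIN_LABELS = ("<20%", "20-40%", "40-60%", "60-80%", "80-120%", ">120%")
LT60_LOG2_CUTOFF = math.log2(0.6)


def _peak_trees(peaks: Sequence[GenomicInterval]):
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def assign_peaks_to_genes(
    peaks: PeakSet, genes: Sequence[GeneModel], genome=None
) -> dict[str, list[GenomicInterval]]:
    """Map gene id -> peaks overlapping the gene body or promoter."""
    trees = _peak_trees(list(peaks))
    mapping: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        hits: dict[tuple, GenomicInterval] = {}
        for window in g.regulatory_region(genome):
            for node in tree.overlap(window.start, window.end):
                peak = node.data
                hits[(peak.start, peak.end)] = peak
        if hits:
            mapping[g.gene_id] = sorted(hits.values(), key=GenomicInterval.sort_key)
    return mapping


def gene_mark_table(
    mapping: Mapping[str, Sequence[GenomicInterval]],
    tracks: Mapping[str, SignalTrack],
    percentile: Optional[float] = 5.0,
    fallback_min: float = 3.0,
) -> tuple[pd.DataFrame, float]:
    """Gene x sample mean-CPM table over each gene's peak union, then filtered.

    Signal is averaged over the base-pair union of the gene's associated
    peaks (each base counted once).  Genes whose maximum across samples is
    below the threshold (pooled lower percentile, or ``fallback_min`` when
    ``percentile`` is None) are removed.  Returns (table, threshold).
    """
    if not mapping:
        raise ValueError("empty gene-peak mapping")
    gene_ids = sorted(mapping)
    unions = {gid: merge(list(mapping[gid])) for gid in gene_ids}
    data = {}
    for sample, track in tracks.items():
        col = []
        for gid in gene_ids:
            ivs = unions[gid]
            tot = sum(len(iv) for iv in ivs)
            val = sum(track.mean(iv.chrom, iv.start, iv.end) * len(iv) for iv in ivs) / tot
            col.append(val)
        data[sample] = col
    table = pd.DataFrame(data, index=gene_ids)
    if percentile is None:
        threshold = float(fallback_min)
    else:
        threshold = float(np.percentile(table.to_numpy().ravel(), percentile))
    keep = table.max(axis=1) >= threshold
    logger.info("gene signal filter at %.4g CPM; %d/%d genes kept",
                threshold, int(keep.sum()), len(table))
    return table.loc[keep], threshold


@dataclass
class LevelClass:
    gene: str
    ratio: float
    log2fc: float
    p: float
    bin: str


def classify_levels(
    table: pd.DataFrame,
    mutant_cols: Sequence[str],
    wt_cols: Sequence[str],
    bin_edges: Sequence[float] = LEVEL_BIN_EDGES,
    bin_labels: Sequence[str] = LEVEL_BIN_LABELS,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene mutant/WT level ratio, log2FC, moderated p, and level bin.

    The ratio is computed on linear mean CPM and binned left-closed
    right-open; the default bins are [0,0.2) ... [0.8,1.2) (WT-like) and
    [1.2, inf).  Genes with WT mean 0 are unclassifiable and dropped with a
    log entry.
    """
    if len(bin_edges) != len(bin_labels) + 1:
        raise ValueError("need one more edge than labels")
    mut_mean = table[list(mutant_cols)].mean(axis=1)
    wt_mean = table[list(wt_cols)].mean(axis=1)
    ok = wt_mean > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d genes unclassifiable (WT mean 0); excluded", n_bad)
    ratio = (mut_mean[ok] / wt_mean[ok]).astype(float)
    stats = moderated_diff(table.loc[ok], list(mutant_cols), list(wt_cols), prior_df=prior_df)
    bins = pd.cut(
        ratio, bins=list(bin_edges), labels=list(bin_labels),
        right=False, include_lowest=True,
    ).astype(str)
    out = pd.DataFrame(
        {
            "ratio": ratio,
            "log2fc": stats.log2fc,
            "p": stats.p,
            "bin": bins,
        }
    )
    out.attrs["lt60_log2_cutoff"] = LT60_LOG2_CUTOFF
    return out


def mark_categories(
    h2a_wt: Sequence[PeakSet],
    k27_wt: Sequence[PeakSet],
    genes: Sequence[GeneModel],
    genome=None,
) -> pd.Series:
    """Partition genes into only-H2AK121ub / H2AK121ub+H3K27me3 / only-H3K27me3 / non-PcG.

    A gene carries a mark when the body/promoter window overlaps a peak in ANY
    of the provided wild-type datasets for that mark.
    """
    if not h2a_wt or not k27_wt:
        raise ValueError("need at least one WT dataset per mark")
    has_h2a = _marked_genes(h2a_wt, genes, genome)
    has_k27 = _marked_genes(k27_wt, genes, genome)
    labels = {}
    for g in genes:
        a, b = g.gene_id in has_h2a, g.gene_id in has_k27
        if a and b:
            labels[g.gene_id] = "H2AK121ub/H3K27me3"
        elif a:
            labels[g.gene_id] = "only-H2AK121ub"
        elif b:
            labels[g.gene_id] = "only-H3K27me3"
        else:
            labels[g.gene_id] = "non-PcG"
    return pd.Series(labels, name="category")


def _marked_genes(peaksets, genes, genome) -> set[str]:
    trees = _peak_trees([iv for ps in peaksets for iv in ps])
    marked: set[str] = set()
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        for window in g.regulatory_region(genome):
            if tree.overlaps(window.start, window.end):
                marked.add(g.gene_id)
                break
    return marked


def classify_expression(
    expr: pd.DataFrame,
    mutant_cols: Sequence[str],
    wt_cols: Sequence[str],
    log2fc_cut: float = 1.0,
    p_cut: float = 0.05,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Activated / repressed / unaltered calls from the expression matrix.

    Activated: log2FC >= +cut AND p < p_cut; repressed symmetric; everything
    else (including all-zero rows) unaltered.  The boundary |log2FC| = cut is
    inclusive; the p threshold is strict.
    """
    res = moderated_diff(expr, list(mutant_cols), list(wt_cols), prior_df=prior_df)
    call = np.where(
        (res.log2fc >= log2fc_cut) & (res.p < p_cut),
        "activated",
        np.where((res.log2fc <= -log2fc_cut) & (res.p < p_cut), "repressed", "unaltered"),
    )
    return pd.DataFrame(
        {"log2fc": res.log2fc, "p": res.p, "class": call}, index=expr.index
    )
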