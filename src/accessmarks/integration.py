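"""Integration of mark levels, chromatin accessibility, and expression.

Genes are paired with the consensus accessible regions overlapping their body
or promoter; a gene's accessibility is the mean over its paired regions.
Profile-group comparisons use one-sided Mann-Whitney-Wilcoxon tests between
genes with wild-type-like mark levels (80-120% of WT) and genes in other level
bins.  The integration table restricts to genes of a mark category with less
than 60% of WT mark signal and a significant accessibility change, and
cross-tabulates the accessibility direction against the expression class; the
six percentages sum to 100 of the restricted set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusTHS
from .io import GeneModel
from .stats import rank_sum_one_sided

logger = logging.getLogger("accessmarks")

EXPRESSION_CLASSES = ("activated", "unaltered", "repressed")
ACCESS_DIRECTIONS = ("increased", "decreased")


@dataclass
class GeneTHSPairing:
    mapping: dict[str, list[str]]          # gene id -> paired region ids
    accessibility: pd.DataFrame            # per-gene mean over paired regions
    n_unpaired: int


def gene_ths_pairing(
    genes: Sequence[GeneModel],
    consensus: Sequence[ConsensusTHS],
    matrix: pd.DataFrame,
    genome=None,
    summary: str = "mean",
) -> GeneTHSPairing:
    """Pair each gene with consensus regions overlapping body or promoter.

    Per-gene accessibility is the mean (or max) of the paired rows of the
    accessibility matrix, per sample.  Genes with no paired region are
    excluded and tallied.
    """
    if summary not in ("mean", "max"):
        raise ValueError("summary must be 'mean' or 'max'")
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for c in consensus:
        if c.region_id not in matrix.index:
            continue
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end, c.region_id
        )
    mapping: dict[str, list[str]] = {}
    rows = {}
    n_unpaired = 0
    for g in genes:
        tree = trees.get(g.chrom)
        hits: set[str] = set()
        if tree is not None:
            for window in g.regulatory_region(genome):
                hits.update(node.data for node in tree.overlap(window.start, window.end))
        if not hits:
            n_unpaired += 1
            continue
        rids = sorted(hits)
        mapping[g.gene_id] = rids
        sub = matrix.loc[rids]
        rows[g.gene_id] = sub.mean(axis=0) if summary == "mean" else sub.max(axis=0)
    logger.info("%d genes paired with consensus regions; %d without", len(mapping), n_unpaired)
    accessibility = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=matrix.columns)
    return GeneTHSPairing(mapping=mapping, accessibility=accessibility, n_unpaired=n_unpaired)


def profile_group_test(
    profile_values: pd.Series,
    group_wt_like: Sequence[str],
    group_other: Sequence[str],
    direction: str = "greater",
) -> dict:
    """One-sided rank-sum p for group_other vs the WT-like group.

    ``profile_values`` holds one scalar per gene (mean signal in a TSS
    window).  ``direction='greater'`` tests whether the other group's values
    are stochastically greater than the WT-like group's.  Groups smaller than
    3 are flagged low-power (the p is still computed).
    """
    wt_vals = profile_values.loc[list(group_wt_like)].to_numpy(dtype=float)
    other_vals = profile_values.loc[list(group_other)].to_numpy(dtype=float)
    p = rank_sum_one_sided(other_vals, wt_vals, direction=direction)
    return {
        "p": p,
        "n_wt_like": len(wt_vals),
        "n_other": len(other_vals),
        "low_power": min(len(wt_vals), len(other_vals)) < 3,
    }


def tss_window_means(
    track, genes: Sequence[GeneModel], window: tuple[int, int] = (-500, 500),
    chrom_sizes=None,
) -> pd.Series:
    """Per-gene mean signal in a strand-aware window around the TSS."""
    w0, w1 = window
    vals = {}
    for g in genes:
        t = g.tss
        if g.strand == "+":
            s, e = t + w0, t + w1
        else:
            s, e = t - w1 + 1, t - w0 + 1
        if s < 0:
            s = 0
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            e = min(e, chrom_sizes[g.chrom])
        if s >= e:
            continue
        vals[g.gene_id] = track.mean(g.chrom, s, e)
    return pd.Series(vals, name="tss_window_mean")


def integrate(
    level_classes: pd.DataFrame,
    accessibility_calls: pd.Series,
    expression_classes: pd.Series,
    mark_categories: pd.Series,
    category: str,
    ratio_cut: float = 0.6,
) -> pd.DataFrame:
    """Expression x accessibility cross-tab for mark-depleted genes.

    Restricts to genes of ``category`` with mark ratio < ``ratio_cut`` and a
    significant accessibility change ('increased' or 'decreased'), then
    reports counts and percentages (summing to 100 of the restricted set) for
    each accessibility direction x expression class cell.
    """
    genes_in_cat = set(mark_categories.index[mark_categories == category])
    depleted = set(level_classes.index[level_classes["ratio"] < ratio_cut])
    changed = set(accessibility_calls.index[accessibility_calls.isin(ACCESS_DIRECTIONS)])
    keyed = genes_in_cat & depleted & changed & set(expression_classes.index)
    n_excluded = len(genes_in_cat) - len(keyed)
    logger.info(
        "integration (%s): %d genes restricted, %d of the category excluded",
        category, len(keyed), n_excluded,
    )
    counts = pd.DataFrame(
        0, index=list(ACCESS_DIRECTIONS), columns=list(EXPRESSION_CLASSES), dtype=int
    )
    for gid in keyed:
        counts.loc[accessibility_calls[gid], expression_classes[gid]] += 1
    total = counts.to_numpy().sum()
    if total == 0:
        logger.warning("integration (%s): empty restricted set", category)
        percent = counts.astype(float)
    else:
        percent = 100.0 * counts / total
    out = pd.concat({"count": counts, "percent": percent}, axis=1)
    out.attrs["n_restricted"] = int(total)
    out.attrs["category"] = category
    return out


def scatter_export(
    level_log2fc: pd.Series,
    accessibility_log2fc: pd.Series,
    expression_class: pd.Series,
    mark_categories: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """One row per gene present in every layer: the three values + labels."""
    keys = set(level_log2fc.index) & set(accessibility_log2fc.index) & set(expression_class.index)
    if mark_categories is not None:
        keys &= set(mark_categories.index)
    dropped = (
        len(set(level_log2fc.index) | set(accessibility_log2fc.index) | set(expression_class.index))
        - len(keys)
    )
    if dropped:
        logger.info("scatter export: %d genes missing a layer were excluded", dropped)
    keys = sorted(keys)
    out = pd.DataFrame(
        {
            "mark_log2fc": level_log2fc.loc[keys],
            "accessibility_log2fc": accessibility_log2fc.loc[keys],
            "expression_class": expression_class.loc[keys],
        }
    )
    if mark_categories is not None:
        out["category"] = mark_categories.loc[keys]
    return out
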