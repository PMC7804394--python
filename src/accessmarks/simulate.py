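"""Synthetic study generator with planted, recoverable structure.

Every analysis stage in the package is exercised against data generated here:
accessible regions (THSs) with jittered replicate peak calls, CPM signal
tracks with per-genotype effect multipliers, histone-mark domains planted at
controlled distances from THSs, TF binding sites placed with a known density
enrichment factor inside THSs, gene-level mark matrices at controlled
fractions of wild-type signal, and expression tables with planted
differential-expression classes.  Generators are pure functions of
(spec, seed); one study seed fans out into independent per-stage streams so a
stage can be regenerated in isolation.

THSs are placed on a slot grid with generous margins so that a mark domain
planted at a given distance from one THS can never stray into the distance
bins of a neighbouring THS; planted distance-bin fractions are therefore
recovered up to binomial noise only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval, PeakSet, merge
from .io import GeneModel, SignalTrack

H2A = "H2AK121ub"
K27 = "H3K27me3"

_STAGES = {
    "ths": 1,
    "replicates": 2,
    "tracks": 3,
    "marks": 4,
    "tfbs": 5,
    "genes": 6,
    "gene_marks": 7,
    "expression": 8,
    "categories": 9,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


@dataclass
class SimSpec:
    """Study-condition parameters for the synthetic generator."""

    # genome and accessible regions
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {f"Chr{i}": 8_000_000 for i in range(1, 6)}
    )
    n_ths: int = 2000
    ths_len_meanlog: float = math.log(400.0)
    ths_len_sdlog: float = 0.4
    ths_len_range: tuple[int, int] = (100, 2000)
    slot_margin: int = 7000

    # replicate peak calls (two per genotype)
    replicate_jitter_sd: float = 20.0
    replicate_dropout: float = 0.05
    n_noise_peaks: int = 200
    peak_qvalue: float = 1e-3

    # genotypes and accessibility signal
    genotypes: tuple[str, ...] = ("WT", "bmi1abc", "clf28swn7", "emf1", "ring1ab", "lhp1")
    accessibility_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "WT": 1.0, "bmi1abc": 2.0, "clf28swn7": 1.6,
            "emf1": 1.5, "ring1ab": 1.0, "lhp1": 1.0,
        }
    )
    n_atac_replicates: int = 2
    base_cpm: float = 10.0
    background_cpm: float = 0.5
    track_noise_sd: float = 0.5

    # mark domains near THSs (fractions per nearest-distance bin; the
    # remainder of THSs get no nearby domain)
    mark_bin_fractions: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            H2A: {0: 0.30, 100: 0.20, 500: 0.15, 1000: 0.075, 2000: 0.075},
            K27: {0: 0.15, 100: 0.10, 500: 0.06, 1000: 0.05, 2000: 0.04},
        }
    )
    coloc_share: float = 0.96  # share of K27-associated THSs drawn from H2A-associated ones
    mark_len_mean: Mapping[str, float] = field(
        default_factory=lambda: {H2A: 500.0, K27: 2000.0}
    )
    mark_len_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {H2A: (100, 2000), K27: (200, 6000)}
    )

    # TF binding sites
    n_tfbs: int = 50_000
    tfbs_width: int = 200
    tfbs_factor: float = 7.5

    # genes
    promoter_bp: int = 750
    gene_body_len: int = 2000
    ths_gene_fraction: float = 0.8  # fraction of THSs that anchor a gene promoter
    n_extra_genes: int = 300

    # gene-level mark matrix
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "H2AK121ub/H3K27me3": 0.35, "only-H2AK121ub": 0.25,
            "only-H3K27me3": 0.20, "non-PcG": 0.20,
        }
    )
    level_bin_centers: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 1.0, 1.5)
    level_bin_fractions: tuple[float, ...] = (0.15, 0.15, 0.15, 0.10, 0.35, 0.10)
    wt_mark_meanlog: float = math.log(10.0)
    wt_mark_sdlog: float = 0.3
    mark_noise_sd: float = 0.1  # sd of multiplicative log-normal replicate noise
    n_chip_replicates: int = 2

    # expression
    expr_base_log2_mean: float = 5.0
    expr_base_log2_sd: float = 1.0
    expr_noise_sd: float = 0.1  # sd on log2 replicate values
    n_rna_replicates: int = 3
    de_effect: float = 2.0      # |log2FC| of planted DE genes
    background_de_fraction: float = 0.05

    # integration coupling
    focal_mutants: tuple[str, ...] = ("bmi1abc", "clf28swn7", "emf1")
    access_boost: float = 2.0   # extra accessibility at THSs of mark-depleted genes
    activated_fraction_among_loss: float = 0.4

    def __post_init__(self):
        for frac in (self.replicate_dropout, self.ths_gene_fraction, self.coloc_share,
                     self.activated_fraction_among_loss, self.background_de_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"probability {frac} outside [0, 1]")
        if self.tfbs_factor < 0:
            raise ValueError("tfbs_factor must be >= 0")
        for mark, fracs in self.mark_bin_fractions.items():
            if sum(fracs.values()) > 1.0 + 1e-9:
                raise ValueError(f"{mark} distance-bin fractions sum above 1")


# ---------------------------------------------------------------------------
# genome and THSs


def simulate_genome(spec: SimSpec) -> Genome:
    return Genome(dict(spec.chrom_sizes))


def simulate_ths(spec: SimSpec, genome: Genome, seed: int) -> list[GenomicInterval]:
    """Place true THSs on a slot grid (one region per slot, margins kept)."""
    rng = stage_rng(seed, "ths")
    chroms = list(genome)
    lens = np.array([genome[c] for c in chroms], dtype=float)
    n_per = np.floor(spec.n_ths * lens / lens.sum()).astype(int)
    for i in range(spec.n_ths - n_per.sum()):
        n_per[i % len(chroms)] += 1
    out = []
    k = 0
    for chrom, n_c in zip(chroms, n_per):
        if n_c == 0:
            continue
        slot = genome[chrom] // n_c
        lo_len, hi_len = spec.ths_len_range
        if slot <= 2 * spec.slot_margin + hi_len:
            raise ValueError(
                f"genome too small: slot {slot} bp on {chrom} cannot hold a THS "
                f"with {spec.slot_margin} bp margins"
            )
        lengths = np.clip(
            rng.lognormal(spec.ths_len_meanlog, spec.ths_len_sdlog, n_c),
            lo_len, hi_len,
        ).astype(int)
        for j in range(n_c):
            lo = j * slot + spec.slot_margin
            hi = (j + 1) * slot - spec.slot_margin - lengths[j]
            start = int(rng.integers(lo, hi + 1))
            out.append(GenomicInterval(chrom, start, start + int(lengths[j]),
                                       name=f"THS{k:05d}"))
            k += 1
    return out


def simulate_ths_replicates(
    spec: SimSpec, genome: Genome, seed: int,
    truth: Optional[Sequence[GenomicInterval]] = None,
) -> tuple[list[GenomicInterval], dict[str, list[PeakSet]]]:
    """Per-genotype replicate peak sets: truth with edge jitter + drop-outs.

    Each replicate also receives uniformly placed noise peaks that, being
    replicate-specific, are removed by the replicate intersection.
    """
    if truth is None:
        truth = simulate_ths(spec, genome, seed)
    rng = stage_rng(seed, "replicates")
    replicates: dict[str, list[PeakSet]] = {}
    for genotype in spec.genotypes:
        reps = []
        for r in range(spec.n_atac_replicates):
            ivs = []
            for iv in truth:
                if rng.random() < spec.replicate_dropout:
                    continue
                s = iv.start + int(round(rng.normal(0, spec.replicate_jitter_sd)))
                e = iv.end + int(round(rng.normal(0, spec.replicate_jitter_sd)))
                s = max(0, s)
                e = min(genome[iv.chrom], max(e, s + 50))
                ivs.append(GenomicInterval(iv.chrom, s, e, name=iv.name,
                                           qvalue=spec.peak_qvalue))
            for _ in range(spec.n_noise_peaks):
                chrom = str(rng.choice(list(genome)))
                length = int(rng.integers(150, 600))
                start = int(rng.integers(0, genome[chrom] - length))
                ivs.append(GenomicInterval(chrom, start, start + length,
                                           qvalue=spec.peak_qvalue))
            reps.append(PeakSet(f"{genotype}_rep{r + 1}", ivs))
        replicates[genotype] = reps
    return list(truth), replicates


# ---------------------------------------------------------------------------
# signal tracks


def simulate_signal_tracks(
    spec: SimSpec,
    true_ths: Sequence[GenomicInterval],
    genome: Genome,
    seed: int,
    boosted: Optional[Mapping[str, set]] = None,
) -> dict[str, SignalTrack]:
    """Per-sample CPM tracks: genotype-scaled signal at THSs over background.

    ``boosted`` optionally maps genotype -> set of THS names whose signal is
    additionally multiplied by ``spec.access_boost`` in that genotype (the
    mark-loss/accessibility coupling used by the integrated scenario).
    """
    rng = stage_rng(seed, "tracks")
    tracks: dict[str, SignalTrack] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sorted(true_ths, key=GenomicInterval.sort_key):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for genotype in spec.genotypes:
        mult = spec.accessibility_multipliers[genotype]
        boost_names = (boosted or {}).get(genotype, set())
        for r in range(spec.n_atac_replicates):
            records = []
            for chrom in genome:
                pos = 0
                for iv in by_chrom.get(chrom, []):
                    if iv.start > pos:
                        records.append((chrom, pos, iv.start, spec.background_cpm))
                    level = spec.base_cpm * mult
                    if iv.name in boost_names:
                        level *= spec.access_boost
                    level += rng.normal(0, spec.track_noise_sd)
                    records.append((chrom, iv.start, iv.end, max(level, 0.0)))
                    pos = iv.end
                if pos < genome[chrom]:
                    records.append((chrom, pos, genome[chrom], spec.background_cpm))
            tracks[f"{genotype}_rep{r + 1}"] = SignalTrack.from_records(records)
    return tracks


# ---------------------------------------------------------------------------
# mark domains at controlled distances


def simulate_mark_peaks(
    spec: SimSpec,
    true_ths: Sequence[GenomicInterval],
    genome: Genome,
    seed: int,
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Mark domains planted per THS in nearest-distance bins.

    Returns one PeakSet per mark and a truth table with the planted bin
    ('overlap', the bin's upper edge, or 'none') for every THS and mark.
    K27-associated THSs are drawn preferentially (``coloc_share``) from the
    H2A-associated ones, planting the co-localization structure.
    """
    rng = stage_rng(seed, "marks")
    n = len(true_ths)
    truth = pd.DataFrame(index=[iv.name for iv in true_ths])

    # H2A: independent multinomial assignment per THS
    h2a_bins = _assign_bins(rng, n, spec.mark_bin_fractions[H2A])
    # K27: choose the associated subset with the co-localization constraint
    k27_fracs = spec.mark_bin_fractions[K27]
    n_k27 = int(round(sum(k27_fracs.values()) * n))
    h2a_assoc = np.flatnonzero(h2a_bins >= 0)
    h2a_not = np.flatnonzero(h2a_bins < 0)
    n_from_h2a = min(int(round(spec.coloc_share * n_k27)), len(h2a_assoc))
    n_from_rest = min(n_k27 - n_from_h2a, len(h2a_not))
    chosen = np.concatenate([
        rng.choice(h2a_assoc, size=n_from_h2a, replace=False),
        rng.choice(h2a_not, size=n_from_rest, replace=False),
    ]).astype(int)
    k27_bins = np.full(n, -1, dtype=int)
    edges = sorted(k27_fracs)
    if len(chosen) and edges:
        probs = np.array([k27_fracs[e] for e in edges], dtype=float)
        probs = probs / probs.sum()
        k27_bins[chosen] = rng.choice(len(edges), size=len(chosen), p=probs)

    peaksets = {}
    for mark, bins in ((H2A, h2a_bins), (K27, k27_bins)):
        edges_m = sorted(spec.mark_bin_fractions[mark])
        ivs, labels = [], []
        lo_len, hi_len = spec.mark_len_range[mark]
        for idx, iv in enumerate(true_ths):
            b = bins[idx]
            if b < 0:
                labels.append("none")
                continue
            edge = edges_m[b]
            length = int(np.clip(rng.exponential(spec.mark_len_mean[mark]), lo_len, hi_len))
            ivs.append(_place_domain(rng, iv, edge, edges_m, length, genome))
            labels.append("overlap" if edge == 0 else str(edge))
        truth[mark] = labels
        peaksets[mark] = PeakSet(f"{mark}_domains", ivs)
    return peaksets, truth


def _assign_bins(rng, n: int, fractions: Mapping[int, float]) -> np.ndarray:
    """Per-THS bin index into sorted(fractions) keys, or -1 for none."""
    edges = sorted(fractions)
    probs = [fractions[e] for e in edges]
    probs.append(1.0 - sum(probs))
    draws = rng.choice(len(edges) + 1, size=n, p=np.array(probs) / sum(probs))
    return np.where(draws == len(edges), -1, draws)


def _place_domain(rng, ths: GenomicInterval, edge: int, edges: list[int],
                  length: int, genome: Genome) -> GenomicInterval:
    limit = genome[ths.chrom]
    if edge == 0:  # overlap: domain centred on the THS centre
        center = (ths.start + ths.end) // 2
        s = max(0, center - length // 2)
        return GenomicInterval(ths.chrom, s, min(s + length, limit))
    lo = edges[edges.index(edge) - 1]
    gap = int(rng.integers(lo + 1, edge + 1))
    if rng.random() < 0.5 and ths.start - gap - length >= 0:
        e = ths.start - gap
        return GenomicInterval(ths.chrom, e - length, e)
    s = ths.end + gap
    return GenomicInterval(ths.chrom, s, min(s + length, limit))


# ---------------------------------------------------------------------------
# TF binding sites with a planted density factor


def simulate_tfbs(
    spec: SimSpec,
    true_ths: Sequence[GenomicInterval],
    genome: Genome,
    seed: int,
    n_tfbs: Optional[int] = None,
    factor: Optional[float] = None,
    width: Optional[int] = None,
) -> PeakSet:
    """TFBS placed so that centre density inside THSs is ``factor`` x outside.

    Mixture sampling: with probability f*T / (f*T + (G - T)) the centre lands
    uniformly inside the THS mass T, otherwise uniformly outside.  ``factor=1``
    is exactly uniform placement; ``factor=0`` puts no site inside a THS.
    """
    rng = stage_rng(seed, "tfbs")
    n = spec.n_tfbs if n_tfbs is None else n_tfbs
    f = spec.tfbs_factor if factor is None else factor
    w = spec.tfbs_width if width is None else width
    merged = merge(list(true_ths))
    t_bases = sum(len(iv) for iv in merged)
    g_bases = genome.total_length
    if f > 0 and t_bases == 0:
        raise ValueError("positive factor with zero THS mass")
    p_in = f * t_bases / (f * t_bases + (g_bases - t_bases)) if t_bases else 0.0

    ths_lens = np.array([len(iv) for iv in merged], dtype=float)
    ths_cum = ths_lens.cumsum() / ths_lens.sum() if t_bases else None
    chroms = list(genome)
    chrom_lens = np.array([genome[c] for c in chroms], dtype=float)
    chrom_cum = chrom_lens.cumsum() / chrom_lens.sum()
    cover = _coverage_arrays(merged)

    ivs = []
    inside = rng.random(n) < p_in
    for i in range(n):
        if inside[i]:
            j = int(np.searchsorted(ths_cum, rng.random()))
            iv = merged[j]
            center = int(rng.integers(iv.start, iv.end))
            chrom = iv.chrom
        else:
            while True:
                ci = int(np.searchsorted(chrom_cum, rng.random()))
                chrom = chroms[ci]
                center = int(rng.integers(0, genome[chrom]))
                if not _covered(cover, chrom, center, center + 1):
                    break
        s = max(0, center - w // 2)
        e = min(genome[chrom], s + max(w, 1))
        ivs.append(GenomicInterval(chrom, s, e, name=f"TFBS{i:06d}"))
    return PeakSet("TFBS", ivs)


def _coverage_arrays(merged: Sequence[GenomicInterval]):
    """Per-chromosome (starts, ends) arrays of merged, disjoint intervals."""
    cover: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=GenomicInterval.sort_key)
        cover[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return cover


def _covered(cover, chrom: str, start: int, end: int) -> bool:
    """True when [start, end) overlaps any covered base on chrom."""
    if chrom not in cover:
        return False
    starts, ends = cover[chrom]
    j = int(np.searchsorted(starts, end, side="left"))
    return j > 0 and ends[j - 1] > start


# ---------------------------------------------------------------------------
# genes


def simulate_gene_models(
    spec: SimSpec,
    true_ths: Sequence[GenomicInterval],
    genome: Genome,
    seed: int,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Gene models, most anchored so a THS sits in their promoter.

    Returns the genes and the truth map gene id -> anchoring THS name.  Extra
    genes without an anchoring THS are placed at least 3 kb from any THS.
    """
    rng = stage_rng(seed, "genes")
    genes: list[GeneModel] = []
    anchor: dict[str, str] = {}
    k = 0
    for iv in true_ths:
        if rng.random() >= spec.ths_gene_fraction:
            continue
        gid = f"GENE{k:05d}"
        offset = int(rng.integers(50, 301))
        if rng.random() < 0.5:
            start = iv.end + offset
            end = start + spec.gene_body_len
            strand = "+"
        else:
            end = iv.start - offset
            start = end - spec.gene_body_len
            strand = "-"
        if start < 0 or end > genome[iv.chrom]:
            continue
        genes.append(GeneModel(gid, iv.chrom, start, end, strand, spec.promoter_bp))
        anchor[gid] = iv.name
        k += 1
    cover = _coverage_arrays(merge(list(true_ths)))
    for _ in range(spec.n_extra_genes):
        for _attempt in range(200):
            chrom = str(rng.choice(list(genome)))
            start = int(rng.integers(0, genome[chrom] - spec.gene_body_len))
            if not _covered(cover, chrom, max(0, start - 3000),
                            start + spec.gene_body_len + 3000):
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(f"GENE{k:05d}", chrom, start,
                                       start + spec.gene_body_len, strand,
                                       spec.promoter_bp))
                k += 1
                break
    return genes, anchor


def simulate_categories(spec: SimSpec, genes: Sequence[GeneModel], seed: int) -> pd.Series:
    """Planted PcG category per gene."""
    rng = stage_rng(seed, "categories")
    cats = list(spec.category_fractions)
    probs = np.array([spec.category_fractions[c] for c in cats], dtype=float)
    draws = rng.choice(len(cats), size=len(genes), p=probs / probs.sum())
    return pd.Series({g.gene_id: cats[d] for g, d in zip(genes, draws)}, name="category")


def category_wt_mark_peaks(
    genes: Sequence[GeneModel], categories: pd.Series
) -> dict[str, list[PeakSet]]:
    """WT mark peak sets consistent with the planted categories.

    Each gene carrying a mark gets one domain inside its body; two nominal WT
    datasets are emitted per mark (identical here — the category rule ORs
    them, so recovery is exact).
    """
    per_mark: dict[str, list[GenomicInterval]] = {H2A: [], K27: []}
    for g in genes:
        cat = categories[g.gene_id]
        carried = []
        if cat in ("H2AK121ub/H3K27me3", "only-H2AK121ub"):
            carried.append(H2A)
        if cat in ("H2AK121ub/H3K27me3", "only-H3K27me3"):
            carried.append(K27)
        for mark in carried:
            mid = (g.start + g.end) // 2
            per_mark[mark].append(GenomicInterval(g.chrom, g.start, mid, name=g.gene_id))
    return {
        mark: [PeakSet(f"WT_{mark}_ds1", ivs), PeakSet(f"WT_{mark}_ds2", list(ivs))]
        for mark, ivs in per_mark.items()
    }


# ---------------------------------------------------------------------------
# gene-level mark matrix


def simulate_gene_mark_matrix(
    spec: SimSpec,
    gene_ids: Sequence[str],
    seed: int,
    mutants: Optional[Sequence[str]] = None,
    noise_sd: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample mean-CPM table with planted per-mutant level multipliers.

    WT means are log-normal; each mutant's mean is WT x a multiplier drawn
    from the planted level-bin centres; replicates get multiplicative
    log-normal noise.  Returns (table, truth) where truth holds the multiplier
    and the implied level bin per (gene, mutant).
    """
    rng = stage_rng(seed, "gene_marks")
    sd = spec.mark_noise_sd if noise_sd is None else noise_sd
    mutants = [g for g in spec.genotypes if g != "WT"] if mutants is None else list(mutants)
    n = len(gene_ids)
    wt_mean = rng.lognormal(spec.wt_mark_meanlog, spec.wt_mark_sdlog, n)
    centers = np.array(spec.level_bin_centers)
    probs = np.array(spec.level_bin_fractions, dtype=float)
    probs = probs / probs.sum()

    cols = {}
    truth_rows = []
    for r in range(spec.n_chip_replicates):
        cols[f"WT_rep{r + 1}"] = wt_mean * _repnoise(rng, sd, n)
    for mutant in mutants:
        mult = centers[rng.choice(len(centers), size=n, p=probs)]
        for r in range(spec.n_chip_replicates):
            cols[f"{mutant}_rep{r + 1}"] = wt_mean * mult * _repnoise(rng, sd, n)
        for gid, m in zip(gene_ids, mult):
            truth_rows.append({"gene": gid, "mutant": mutant, "multiplier": float(m),
                               "bin": _level_bin(m)})
    table = pd.DataFrame(cols, index=list(gene_ids))
    truth = pd.DataFrame(truth_rows)
    return table, truth


def _repnoise(rng, sd: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, sd, n)) if sd > 0 else np.ones(n)


def _level_bin(ratio: float) -> str:
    from .genes import LEVEL_BIN_EDGES, LEVEL_BIN_LABELS

    for lo, hi, label in zip(LEVEL_BIN_EDGES, LEVEL_BIN_EDGES[1:], LEVEL_BIN_LABELS):
        if lo <= ratio < hi:
            return label
    return LEVEL_BIN_LABELS[-1]


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    spec: SimSpec,
    gene_ids: Sequence[str],
    seed: int,
    planted: Optional[Mapping[tuple[str, str], str]] = None,
    mutants: Optional[Sequence[str]] = None,
    noise_sd: Optional[float] = None,
    de_fraction: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like expression matrix with planted DE classes per mutant.

    ``planted`` optionally forces (gene, mutant) -> class; remaining genes are
    activated/repressed with probability ``de_fraction``/2 each.  Effects are
    +/- ``spec.de_effect`` on the log2 scale; replicates get Gaussian log2
    noise.  Returns (matrix, truth).
    """
    rng = stage_rng(seed, "expression")
    sd = spec.expr_noise_sd if noise_sd is None else noise_sd
    de_frac = spec.background_de_fraction if de_fraction is None else de_fraction
    mutants = [g for g in spec.genotypes if g != "WT"] if mutants is None else list(mutants)
    n = len(gene_ids)
    base = rng.normal(spec.expr_base_log2_mean, spec.expr_base_log2_sd, n)

    cols = {}
    for r in range(spec.n_rna_replicates):
        cols[f"WT_rep{r + 1}"] = _expr_values(rng, base, sd)
    truth_rows = []
    for mutant in mutants:
        log2_mean = base.copy()
        classes = []
        for i, gid in enumerate(gene_ids):
            cls = (planted or {}).get((gid, mutant))
            if cls is None:
                u = rng.random()
                if u < de_frac / 2:
                    cls = "activated"
                elif u < de_frac:
                    cls = "repressed"
                else:
                    cls = "unaltered"
            if cls == "activated":
                log2_mean[i] = base[i] + spec.de_effect
            elif cls == "repressed":
                log2_mean[i] = base[i] - spec.de_effect
            classes.append(cls)
            truth_rows.append({"gene": gid, "mutant": mutant, "class": cls})
        for r in range(spec.n_rna_replicates):
            cols[f"{mutant}_rep{r + 1}"] = _expr_values(rng, log2_mean, sd)
    matrix = pd.DataFrame(cols, index=list(gene_ids))
    truth = pd.DataFrame(truth_rows)
    return matrix, truth


def _expr_values(rng, log2_mean: np.ndarray, sd: float) -> np.ndarray:
    noise = rng.normal(0.0, sd, len(log2_mean)) if sd > 0 else 0.0
    return np.exp2(log2_mean + noise)


# ---------------------------------------------------------------------------
# the integrated scenario


@dataclass
class SyntheticStudy:
    spec: SimSpec
    seed: int
    genome: Genome
    true_ths: list[GenomicInterval]
    replicate_peaks: dict[str, list[PeakSet]]
    tracks: dict[str, SignalTrack]
    mark_peaks: dict[str, PeakSet]
    mark_distance_truth: pd.DataFrame
    tfbs: PeakSet
    genes: list[GeneModel]
    gene_anchor: dict[str, str]
    categories: pd.Series
    wt_mark_peaks: dict[str, list[PeakSet]]
    mark_tables: dict[str, pd.DataFrame]
    mark_truth: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    expression_truth: pd.DataFrame
    boosted: dict[str, set]

    @property
    def sample_genotypes(self) -> dict[str, str]:
        return {
            f"{g}_rep{r + 1}": g
            for g in self.spec.genotypes
            for r in range(self.spec.n_atac_replicates)
        }


def simulate_study(spec: SimSpec, seed: int) -> SyntheticStudy:
    """Generate one fully coupled synthetic study.

    The coupling plants the headline structure: genes whose primary mark drops
    below 60% of WT in a focal mutant have their anchoring THS boosted in
    accessibility in that mutant, and only a minority
    (``activated_fraction_among_loss``) of them are transcriptionally
    activated — the rest stay unaltered.
    """
    genome = simulate_genome(spec)
    true_ths, replicate_peaks = simulate_ths_replicates(spec, genome, seed)
    mark_peaks, mark_distance_truth = simulate_mark_peaks(spec, true_ths, genome, seed)
    tfbs = simulate_tfbs(spec, true_ths, genome, seed)
    genes, gene_anchor = simulate_gene_models(spec, true_ths, genome, seed)
    categories = simulate_categories(spec, genes, seed)
    wt_mark_peaks = category_wt_mark_peaks(genes, categories)

    carriers = {
        H2A: [gid for gid in (g.gene_id for g in genes)
              if categories[gid] in ("H2AK121ub/H3K27me3", "only-H2AK121ub")],
        K27: [gid for gid in (g.gene_id for g in genes)
              if categories[gid] in ("H2AK121ub/H3K27me3", "only-H3K27me3")],
    }
    mark_tables, mark_truth = {}, {}
    for offset, mark in enumerate((H2A, K27)):
        table, truth = simulate_gene_mark_matrix(spec, carriers[mark], seed + offset + 1)
        mark_tables[mark], mark_truth[mark] = table, truth

    # primary mark per gene: H2A when carried, else K27
    primary = {}
    for g in genes:
        cat = categories[g.gene_id]
        if cat in ("H2AK121ub/H3K27me3", "only-H2AK121ub"):
            primary[g.gene_id] = H2A
        elif cat == "only-H3K27me3":
            primary[g.gene_id] = K27

    loss: dict[str, set] = {m: set() for m in spec.focal_mutants}
    for mark in (H2A, K27):
        t = mark_truth[mark]
        for mutant in spec.focal_mutants:
            sub = t[(t["mutant"] == mutant) & (t["multiplier"] < 0.6)]
            for gid in sub["gene"]:
                if primary.get(gid) == mark:
                    loss[mutant].add(gid)

    boosted = {
        mutant: {gene_anchor[gid] for gid in genes_lost if gid in gene_anchor}
        for mutant, genes_lost in loss.items()
    }
    tracks = simulate_signal_tracks(spec, true_ths, genome, seed, boosted=boosted)

    rng = stage_rng(seed, "expression")  # class draws below use their own stream
    planted: dict[tuple[str, str], str] = {}
    for mutant in spec.focal_mutants:
        for gid in sorted(loss[mutant]):
            if gid in gene_anchor:
                cls = "activated" if rng.random() < spec.activated_fraction_among_loss \
                    else "unaltered"
                planted[(gid, mutant)] = cls
    expression, expression_truth = simulate_expression(
        spec, [g.gene_id for g in genes], seed + 11, planted=planted
    )

    return SyntheticStudy(
        spec=spec, seed=seed, genome=genome, true_ths=true_ths,
        replicate_peaks=replicate_peaks, tracks=tracks, mark_peaks=mark_peaks,
        mark_distance_truth=mark_distance_truth, tfbs=tfbs, genes=genes,
        gene_anchor=gene_anchor, categories=categories,
        wt_mark_peaks=wt_mark_peaks, mark_tables=mark_tables,
        mark_truth=mark_truth, expression=expression,
        expression_truth=expression_truth, boosted=boosted,
    )
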