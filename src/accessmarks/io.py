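"""Readers and writers for the plain-text formats the pipeline touches.

Supported dialects: two-column chrom.sizes, BED3/BED6, narrowPeak (BED6+4),
bedGraph, a GTF-lite gene table, and TSV matrices (through pandas).  Readers
reject malformed records with the offending line number instead of silently
repairing them; every writer round-trips through its reader.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import CoordinateError, Genome, GenomicInterval, PeakSet

logger = logging.getLogger("accessmarks")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------------------
# genome / BED


def read_chrom_sizes(path: PathLike) -> Genome:
    sizes: dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: PathLike, label: Optional[str] = None) -> PeakSet:
    """Read BED3/BED6 into a PeakSet (extra columns ignored)."""
    ivs = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            iv = GenomicInterval(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                name=fields[3] if len(fields) > 3 and fields[3] != "." else None,
                score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else None,
                strand=fields[5] if len(fields) > 5 else ".",
            )
        except (ValueError, CoordinateError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        ivs.append(iv)
    return PeakSet(label or Path(path).stem, ivs)


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{_fmt(iv.score)}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path: PathLike, label: Optional[str] = None) -> PeakSet:
    """Read MACS2 narrowPeak (BED6+4); field 9 is -log10 q, converted to linear."""
    ivs = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 10:
            raise FormatError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}")
        try:
            neglog_q = float(fields[8])
            q = 10.0 ** (-neglog_q) if neglog_q >= 0 else None
            iv = GenomicInterval(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                name=fields[3] if fields[3] != "." else None,
                score=float(fields[4]) if fields[4] != "." else None,
                strand=fields[5],
                qvalue=q,
            )
        except (ValueError, CoordinateError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        ivs.append(iv)
    return PeakSet(label or Path(path).stem, ivs)


def write_narrowpeak(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            if iv.qvalue is not None and iv.qvalue > 0:
                neglog_q = -math.log10(iv.qvalue)
            else:
                neglog_q = -1.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{_fmt(iv.score, 0)}\t{iv.strand}\t0\t-1\t{neglog_q:.8g}\t-1\n"
            )


# ---------------------------------------------------------------------------
# signal tracks (bedGraph)


class SignalTrack:
    """Piecewise-constant CPM signal; uncovered bases read as 0."""

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chromosome: (starts, ends, values), sorted, non-overlapping
        self._segs = segments

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in records:
            by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        segs = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(starts >= ends):
                raise FormatError(f"empty or inverted segment on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping bedGraph segments on {chrom}")
            segs[chrom] = (starts, ends, vals)
        return cls(segs)

    def chroms(self):
        return self._segs.keys()

    def mean(self, chrom: str, start: int, end: int, warn_missing: bool = False) -> float:
        """Length-weighted mean over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._segs:
            if warn_missing:
                logger.warning("track has no data for chromosome %s; treated as 0", chrom)
            return 0.0
        starts, ends, vals = self._segs[chrom]
        i0 = np.searchsorted(ends, start, side="right")
        i1 = np.searchsorted(starts, end, side="left")
        if i0 >= i1:
            return 0.0
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        return float(np.dot(np.clip(ov, 0, None), vals[i0:i1]) / (end - start))

    def means(self, intervals) -> np.ndarray:
        return np.array([self.mean(iv.chrom, iv.start, iv.end) for iv in intervals])


def read_bedgraph(path: PathLike, genome: Optional[Genome] = None) -> SignalTrack:
    records = []
    for lineno, line in _lines(path):
        if line.startswith("track"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        try:
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        track = SignalTrack.from_records(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if genome is not None:
        for chrom in track.chroms():
            if chrom not in genome:
                raise FormatError(f"{path}: unknown chromosome {chrom}")
    return track


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms()):
            starts, ends, vals = track._segs[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# gene models (GTF-lite)


@dataclass(frozen=True)
class GeneModel:
    """Gene body span plus the strand-aware 750 bp promoter upstream of the TSS."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open body span
    end: int
    strand: str
    promoter_bp: int = 750

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise CoordinateError(f"gene {self.gene_id}: bad span {self.start}-{self.end}")

    @property
    def tss(self) -> int:
        """0-based coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id,
                               strand=self.strand)

    def promoter(self, genome: Optional[Genome] = None) -> Optional[GenomicInterval]:
        """Promoter interval abutting the TSS; truncated at chromosome edges."""
        if self.strand == "+":
            s, e = max(0, self.start - self.promoter_bp), self.start
        else:
            limit = genome[self.chrom] if genome is not None else None
            s = self.end
            e = self.end + self.promoter_bp
            if limit is not None:
                e = min(e, limit)
        if s >= e:
            return None
        return GenomicInterval(self.chrom, s, e, name=self.gene_id, strand=self.strand)

    def regulatory_region(self, genome: Optional[Genome] = None) -> list[GenomicInterval]:
        """Body plus promoter — the peak-to-gene assignment window."""
        prom = self.promoter(genome)
        return [self.body] if prom is None else [self.body, prom]


def read_gene_models(path: PathLike, promoter_bp: int = 750) -> list[GeneModel]:
    """Read gene records from a GTF-lite file (feature == 'gene' lines).

    GTF coordinates are 1-based inclusive and converted to 0-based half-open.
    """
    genes = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
        if fields[2] != "gene":
            continue
        strand = fields[6]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
        gene_id = _gtf_attr(fields[8], "gene_id")
        if gene_id is None:
            raise FormatError(f"{path}:{lineno}: no gene_id attribute")
        try:
            start = int(fields[3]) - 1
            end = int(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        genes.append(GeneModel(gene_id, fields[0], start, end, strand, promoter_bp))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            value = part[len(key):].strip()
            return value.strip('"')
    return None


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run; seeds appear in every output."""

    genome: str = ""
    blacklist: Optional[str] = None
    replicate_peaks: dict[str, list[str]] = dc_field(default_factory=dict)
    tracks: dict[str, str] = dc_field(default_factory=dict)
    mark_peaks: dict[str, dict[str, str]] = dc_field(default_factory=dict)
    tfbs: Optional[str] = None
    genes: Optional[str] = None
    expression: Optional[str] = None
    min_cpm: float = 3.0
    signal_percentile: float = 5.0
    q_cutoff: float = 0.05
    promoter_bp: int = 750
    de_log2fc: float = 1.0
    de_p: float = 0.05
    mc_sets: int = 10000
    distance_edges: tuple = (0, 100, 500, 1000, 2000)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: PathLike) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise FormatError(f"{path}: unknown config key {key!r}")
            if key == "distance_edges":
                value = tuple(value)
            setattr(cfg, key, value)
        for name in ("min_cpm", "de_log2fc", "de_p"):
            if getattr(cfg, name) <= 0:
                raise FormatError(f"{path}: {name} must be positive")
        return cfg


def write_manifest(path: PathLike, **entries) -> None:
    """Record seed/thresholds/tool versions for a run (one key per line)."""
    import json

    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------


def _lines(path: PathLike):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with open(p) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _fmt(x: Optional[float], ndigits: int = 6) -> str:
    if x is None:
        return "."
    if ndigits == 0:
        return str(int(round(x)))
    return f"{x:.{ndigits}g}"
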