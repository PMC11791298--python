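"""Coordinate conventions, interval algebra, coverage tracks, and file I/O.

Every coordinate in this package is 0-based, half-open ``[start, end)`` —
the BED/narrowPeak/bedGraph convention. The single exception is the ROSE
GFF dialect, which is 1-based inclusive; conversion happens only at that
boundary and is inverted exactly on read.

Chromosome ordering is lexicographic with natural numeric ordering of
digit runs (``chr2`` < ``chr10``), so outputs are deterministic across
platforms and locales.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "GeneModel",
    "chrom_sort_key",
    "overlap_bp",
    "merge_intervals",
    "filter_excluded",
    "read_narrowpeak",
    "write_narrowpeak",
    "write_rose_gff",
    "read_rose_gff",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_library_sizes",
    "write_library_sizes",
]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


_DIGIT_RUN = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key: digit runs compare numerically (chr2 < chr10)."""
    parts = _DIGIT_RUN.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.start, self.end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record: an interval plus summit offset and scores."""

    interval: GenomicInterval
    summit_offset: int | None = None
    signal_value: float = 0.0
    p_score: float = -1.0
    q_score: float = -1.0

    def __post_init__(self):
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak {self.interval}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when no summit was called."""
        if self.summit_offset is None:
            return self.interval.start + self.interval.length // 2
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    is_oncogene: bool = False

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two half-open intervals (0 if none,
    0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap (next.start - prev.end) is <= ``max_gap``.

    Touching intervals (gap 0) merge at ``max_gap=0``, matching
    ``bedtools merge``. Output is sorted; each merged interval's ``score``
    carries the count of inputs merged into it.
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    cur_chrom = None
    cur_start = cur_end = 0
    cur_n = 0

    def _flush():
        if cur_n:
            out.append(
                GenomicInterval(cur_chrom, cur_start, cur_end, score=float(cur_n))
            )

    for iv in ivs:
        if iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
            cur_n += 1
        else:
            _flush()
            cur_chrom, cur_start, cur_end, cur_n = iv.chrom, iv.start, iv.end, 1
    _flush()
    return out


def filter_excluded(
    peaks: Sequence[Peak], exclusion: Sequence[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping any exclusion-list interval by >= 1 bp."""
    if not exclusion:
        return list(peaks)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {e.chrom for e in exclusion}:
        ivs = [e for e in exclusion if e.chrom == chrom]
        by_chrom[chrom] = (
            np.array([e.start for e in ivs]),
            np.array([e.end for e in ivs]),
        )
    kept = []
    for p in peaks:
        arr = by_chrom.get(p.interval.chrom)
        if arr is not None and bool(
            np.any((arr[0] < p.interval.end) & (arr[1] > p.interval.start))
        ):
            continue
        kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

class SignalTrack:
    """Binned, non-negative coverage with a stated library size.

    Values are reads (or read-equivalents) per fixed-size bin; the bin grid
    starts at position 0 on every chromosome. ``library_size`` is the total
    mapped reads of the library the track came from — it need not equal the
    in-track sum, since a real library includes reads outside the covered
    region.
    """

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        bin_size: int,
        library_size: float,
        name: str = "track",
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not library_size > 0:
            raise ValueError(f"library_size must be > 0 (track {name!r})")
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for c, v in self.values.items():
            if v.ndim != 1 or (v.size and v.min() < 0):
                raise ValueError(f"track {name!r}, chrom {c}: values must be 1-D, >= 0")
        self.bin_size = int(bin_size)
        self.library_size = float(library_size)
        self.name = name

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        library_size: float,
        bin_size: int | None = None,
        name: str | None = None,
    ) -> "SignalTrack":
        """Read a fixed-step bedGraph. Every line must start on the bin grid
        and span at most one bin (a final short bin is allowed)."""
        path = Path(path)
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        if df.empty:
            raise ParseError(f"{path}: empty bedGraph")
        widths = (df["end"] - df["start"]).to_numpy()
        if bin_size is None:
            bin_size = int(widths.max())
        bad = df.index[(df["start"].to_numpy() % bin_size != 0) | (widths > bin_size)]
        if len(bad):
            raise ParseError(
                f"{path}: line {bad[0] + 1} not on a fixed {bin_size} bp bin grid"
            )
        values: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            n_bins = int(math.ceil(sub["end"].max() / bin_size))
            arr = np.zeros(n_bins)
            arr[sub["start"].to_numpy() // bin_size] = sub["value"].to_numpy()
            values[str(chrom)] = arr
        return cls(values, bin_size, library_size, name=name or path.stem)

    def to_bedgraph(self, path: str | Path, write_zero: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values, key=chrom_sort_key):
                arr = self.values[chrom]
                for i, v in enumerate(arr):
                    if v == 0 and not write_zero:
                        continue
                    fh.write(
                        f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}"
                        f"\t{v:.6g}\n"
                    )

    def extent(self, chrom: str) -> int:
        return len(self.values.get(chrom, ())) * self.bin_size

    def interval_signal(self, region: GenomicInterval) -> float:
        """Sum of bin values overlapping ``region``, pro-rated for partial
        bins. Raises if the region is outside the covered extent."""
        arr = self.values.get(region.chrom)
        if arr is None or region.end > len(arr) * self.bin_size:
            raise ValueError(
                f"region {region} outside covered extent of track {self.name!r}"
            )
        b = self.bin_size
        first, last = region.start // b, (region.end - 1) // b
        if first == last:
            return float(arr[first]) * (region.end - region.start) / b
        total = float(arr[first]) * ((first + 1) * b - region.start) / b
        total += float(arr[last]) * (region.end - last * b) / b
        total += float(arr[first + 1 : last].sum())
        return total

    def per_million(self, region: GenomicInterval) -> float:
        """Signal in ``region`` per million mapped reads of the library."""
        return self.interval_signal(region) * 1e6 / self.library_size


# ---------------------------------------------------------------------------
# narrowPeak / BED / GFF I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Parse a BED6+4 narrowPeak file into :class:`Peak` records, order
    preserved. Malformed lines raise :class:`ParseError` naming the line."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: expected 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if fields[3] != "." else None
                score = float(fields[4])
                strand = fields[5]
                signal, p_sc, q_sc = (float(x) for x in fields[6:9])
                summit = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            try:
                iv = GenomicInterval(chrom, start, end, name, score, strand)
                peaks.append(
                    Peak(iv, None if summit < 0 else summit, signal, p_sc, q_sc)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or f"peak_{i + 1}",
                        str(int(iv.score) if iv.score is not None else 0),
                        iv.strand or ".",
                        f"{p.signal_value:g}",
                        f"{p.p_score:g}",
                        f"{p.q_score:g}",
                        str(-1 if p.summit_offset is None else p.summit_offset),
                    ]
                )
                + "\n"
            )


def write_rose_gff(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write the ROSE GFF dialect: 1-based inclusive coordinates, region ID
    in columns 2 and 9. Duplicate names are disambiguated with an index."""
    seen: dict[str, int] = {}
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            base = iv.name or f"peak_{i + 1}"
            if base in seen:
                seen[base] += 1
                uid = f"{base}_{seen[base]}"
            else:
                seen[base] = 0
                uid = base
            fh.write(
                "\t".join(
                    [iv.chrom, uid, "", str(iv.start + 1), str(iv.end), "",
                     iv.strand or ".", "", uid]
                )
                + "\n"
            )


def read_rose_gff(path: str | Path) -> list[GenomicInterval]:
    """Invert :func:`write_rose_gff` exactly (1-based inclusive -> half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 GFF columns")
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            out.append(
                GenomicInterval(
                    f[0], start1 - 1, end1, name=f[1] or None,
                    strand=f[6] if f[6] in "+-." else None,
                )
            )
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                name = f[3] if len(f) > 3 and f[3] != "." else None
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                strand = f[5] if len(f) > 5 and f[5] in "+-." else None
                out.append(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), name, score, strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or f"region_{i + 1}",
                        f"{iv.score:g}" if iv.score is not None else "0",
                        iv.strand or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene tables and library sizes
# ---------------------------------------------------------------------------

_GENE_COLS = ("gene_id", "chrom", "strand", "tss")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene/TSS annotation. Required columns: gene_id, chrom,
    strand, tss; optional: symbol (defaults to gene_id), is_oncogene."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=str(getattr(row, "symbol", row.gene_id)),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                is_oncogene=bool(getattr(row, "is_oncogene", False)),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "is_oncogene": g.is_oncogene,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def tss_positions(genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    """Sorted TSS positions per chromosome, the form the callers consume."""
    out: dict[str, list[int]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g.tss)
    return {c: np.array(sorted(v)) for c, v in out.items()}


def read_library_sizes(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, names=["track", "library_size"])
    sizes = dict(zip(df["track"].astype(str), df["library_size"].astype(float)))
    for k, v in sizes.items():
        if not v > 0:
            raise ParseError(f"{path}: non-positive library size for {k!r}")
    return sizes


def write_library_sizes(sizes: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k in sorted(sizes):
            fh.write(f"{k}\t{sizes[k]:g}\n")
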