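"""Cross-sample SE consensus classes, SE->gene association, oncogene flags.

Sharing between samples uses asymmetric fractional overlap (bedtools
``-f`` semantics, default 0.2): region A of sample X is shared with sample
Y iff some region of Y covers at least ``min_fraction`` of A's length.
Intersection patterns are assembled from those pairwise flags, one sample
at a time, matching Intervene's pairwise behaviour.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, overlap_bp

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusRegion",
    "SEGeneLink",
    "shared_by_fraction",
    "membership_classes",
    "associate_genes",
    "flag_oncogenes",
    "links_table",
]


@dataclass
class ConsensusRegion:
    """One sample's SE region with per-sample presence flags."""

    interval: GenomicInterval
    sample_id: str
    membership: dict[str, bool]

    @property
    def n_samples(self) -> int:
        return sum(self.membership.values())

    @property
    def pattern(self) -> str:
        return "&".join(sorted(s for s, f in self.membership.items() if f))


@dataclass
class SEGeneLink:
    se_region: GenomicInterval
    gene: GeneModel
    distance: int
    is_oncogene: bool = False


def shared_by_fraction(
    a_regions: Sequence[GenomicInterval],
    b_regions: Sequence[GenomicInterval],
    min_fraction: float = 0.2,
) -> list[bool]:
    """Per-region flags: A is shared with set B iff some single B region
    overlaps >= ``min_fraction`` x length(A) (inclusive)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in b_regions:
        by_chrom.setdefault(b.chrom, []).append(b)
    flags = []
    for a in a_regions:
        need = min_fraction * a.length
        flags.append(
            any(overlap_bp(a, b) >= need and overlap_bp(a, b) > 0
                for b in by_chrom.get(a.chrom, ()))
        )
    return flags


def membership_classes(
    sample_regions: Mapping[str, Sequence[GenomicInterval]],
    min_fraction: float = 0.2,
) -> tuple[list[ConsensusRegion], pd.DataFrame, pd.DataFrame]:
    """Label every sample's regions with the samples sharing them.

    Returns ``(regions, class_counts, per_sample_pct)`` where
    ``class_counts`` counts regions per intersection pattern and
    ``per_sample_pct`` gives, per sample, the percentage of its regions
    classed unique / shared-in-k / common (rows sum to 100).
    """
    samples = list(sample_regions)
    if len(samples) < 2:
        logger.warning("membership_classes with <2 samples: everything is unique")
    regions: list[ConsensusRegion] = []
    for s in samples:
        own = list(sample_regions[s])
        flags_by_other = {
            o: shared_by_fraction(own, sample_regions[o], min_fraction)
            for o in samples
            if o != s
        }
        for i, iv in enumerate(own):
            membership = {s: True}
            for o in samples:
                if o != s:
                    membership[o] = flags_by_other[o][i]
            regions.append(ConsensusRegion(iv, s, membership))

    counts = (
        pd.Series([r.pattern for r in regions]).value_counts().rename("n_regions")
    )
    class_counts = counts.rename_axis("pattern").reset_index()

    n_total = len(samples)

    def _class(n: int) -> str:
        if n == 1:
            return "unique"
        if n == n_total:
            return "common"
        return f"shared_in_{n}"

    rows = {}
    classes = ["unique"] + [f"shared_in_{k}" for k in range(2, n_total)] + (
        ["common"] if n_total > 1 else []
    )
    for s in samples:
        mine = [r for r in regions if r.sample_id == s]
        row = {c: 0.0 for c in classes}
        for r in mine:
            row[_class(r.n_samples)] += 1
        total = max(1, len(mine))
        rows[s] = {c: 100.0 * v / total for c, v in row.items()}
    per_sample_pct = pd.DataFrame.from_dict(rows, orient="index")[classes]
    per_sample_pct.index.name = "sample"
    return regions, class_counts, per_sample_pct


def _boundary_distance(iv: GenomicInterval, pos: int) -> int:
    """Distance from a point to the nearest interval boundary: 0 inside,
    ``start - pos`` to the left, ``pos - end`` to the right."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end
    return 0


def associate_genes(
    se_regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_dist: int = 50_000,
    mode: str = "window",
) -> tuple[list[SEGeneLink], list[GeneModel]]:
    """Link genes whose TSS lies within ``max_dist`` bp (inclusive) of an
    SE boundary; distance 0 when the TSS falls inside the SE.

    ``mode='window'`` is the default convention; ``mode='overlap'`` links
    only TSS-inside genes, and ``mode='nearest'`` links each SE to its
    single nearest gene regardless of distance. A gene may link to several
    SEs and vice versa; the deduplicated gene list is returned alongside.
    """
    if mode not in ("window", "overlap", "nearest"):
        raise ValueError(f"unknown association mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links: list[SEGeneLink] = []
    for se in se_regions:
        cands = by_chrom.get(se.chrom, ())
        if mode == "nearest":
            if cands:
                g = min(cands, key=lambda g: (_boundary_distance(se, g.tss), g.gene_id))
                links.append(SEGeneLink(se, g, _boundary_distance(se, g.tss)))
            continue
        for g in cands:
            d = _boundary_distance(se, g.tss)
            if (mode == "overlap" and d == 0) or (mode == "window" and d <= max_dist):
                links.append(SEGeneLink(se, g, d))
    seen: dict[str, GeneModel] = {}
    for ln in links:
        seen.setdefault(ln.gene.gene_id, ln.gene)
    return links, list(seen.values())


def flag_oncogenes(
    links: Sequence[SEGeneLink], oncogene_list: Iterable[str]
) -> tuple[list[SEGeneLink], dict]:
    """Set ``is_oncogene`` by case-normalized exact symbol match; returns
    the links plus a summary with the distinct oncogene count."""
    symbols = {s.strip().upper() for s in oncogene_list if s.strip()}
    if not symbols:
        logger.warning("empty oncogene list: no links flagged")
    flagged = set()
    for ln in links:
        ln.is_oncogene = ln.gene.symbol.upper() in symbols
        if ln.is_oncogene:
            flagged.add(ln.gene.symbol.upper())
    return list(links), {
        "n_oncogenes": len(flagged),
        "oncogenes": sorted(flagged),
    }


def links_table(links: Sequence[SEGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "se_id": ln.se_region.name or str(ln.se_region),
                "se_chrom": ln.se_region.chrom,
                "se_start": ln.se_region.start,
                "se_end": ln.se_region.end,
                "gene_id": ln.gene.gene_id,
                "symbol": ln.gene.symbol,
                "distance": ln.distance,
                "is_oncogene": ln.is_oncogene,
            }
            for ln in links
        ],
        columns=[
            "se_id", "se_chrom", "se_start", "se_end",
            "gene_id", "symbol", "distance", "is_oncogene",
        ],
    )
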