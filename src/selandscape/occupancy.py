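"""SWI/SNF occupancy sites: construction, enrichment, partition, quadrants.

Sites are built from subunit peak intersections — the core subunit SMARCC1
co-occupied by DPF2 marks BAF, by ARID2 marks PBAF — separately per
condition, then unioned and merged into the full site set. Enrichment per
assay and condition is a pseudocount-stabilized per-million IP/input
ratio; per-assay log2 fold-changes (re-expression vs control) feed the
weighted histograms, the +/-1.5-fold concordance quadrants, and the
strong-decrease (>2-fold) partition ratio.

Partition classes: ``proximal`` (a TSS inside the site), ``distal_in_SE``
and ``distal_out_SE`` (nearest TSS > 2,000 bp, split by >=1 bp SE
overlap), and ``unclassified`` (1-2,000 bp from a TSS but not proximal;
counted, excluded from partition statistics).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, Peak, SignalTrack, merge_intervals, overlap_bp

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancySite",
    "QuadrantSummary",
    "define_sites",
    "normalized_enrichment",
    "compute_enrichments",
    "log2_fold_changes",
    "partition_sites",
    "weighted_histogram",
    "quadrant_fractions",
    "quadrant_summary",
    "strong_decrease_ratio",
    "export_signal_matrix",
    "sites_table",
]

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_DISTAL_MIN_DIST = 2_000
PARTITIONS = ("proximal", "distal_in_SE", "distal_out_SE", "unclassified")


@dataclass
class OccupancySite:
    """One SWI/SNF binding site with its classes and measurements."""

    interval: GenomicInterval
    center: int
    complex_class: str  # BAF | PBAF | both
    condition_origin: str  # control | reexpression | both
    partition: str | None = None
    enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    source_peaks: tuple[str, ...] = ()


@dataclass
class QuadrantSummary:
    """Concordance quadrant fractions for one partition group."""

    group: str
    n_sites: int
    fold_threshold: float
    both_down: float
    both_up: float
    discordant: float
    inside_gray: float
    strong_fold: float
    n_strong_decrease: int
    degenerate: bool = False


def _overlaps_any(peak: Peak, others: Sequence[Peak]) -> bool:
    return any(overlap_bp(peak.interval, o.interval) > 0 for o in others)


def define_sites(
    subunit_peaks: Mapping[str, Mapping[str, Sequence[Peak]]],
    site_interval: str = "smarcc1",
) -> list[OccupancySite]:
    """Construct the full SWI/SNF site set.

    ``subunit_peaks`` maps condition -> subunit -> peaks, with conditions
    ``control`` / ``reexpression`` and subunits ``SMARCC1``, ``DPF2``,
    ``ARID2``. Per condition, a SMARCC1 peak overlapping (>=1 bp) any DPF2
    peak is a BAF site and likewise ARID2 for PBAF; the site interval and
    summit are the SMARCC1 peak's. Contributions from both complexes and
    conditions are merged (gap 0) into the final site set with class and
    condition provenance.

    ``site_interval='intersection'`` instead uses the literal overlap
    segment(s) between SMARCC1 and the partner subunit.
    """
    if site_interval not in ("smarcc1", "intersection"):
        raise ValueError(f"unknown site_interval mode {site_interval!r}")
    contributors: list[tuple[GenomicInterval, int, str, str, str, float]] = []
    # (interval, summit, complex, condition, peak_id, smarcc1 signal)
    any_smarcc1 = False
    for cond, by_subunit in subunit_peaks.items():
        smarcc1 = list(by_subunit.get("SMARCC1", ()))
        dpf2 = list(by_subunit.get("DPF2", ()))
        arid2 = list(by_subunit.get("ARID2", ()))
        any_smarcc1 = any_smarcc1 or bool(smarcc1)
        by_chrom_d: dict[str, list[Peak]] = {}
        for p in dpf2:
            by_chrom_d.setdefault(p.interval.chrom, []).append(p)
        by_chrom_a: dict[str, list[Peak]] = {}
        for p in arid2:
            by_chrom_a.setdefault(p.interval.chrom, []).append(p)
        for i, p in enumerate(smarcc1):
            classes = []
            if _overlaps_any(p, by_chrom_d.get(p.interval.chrom, ())):
                classes.append(("BAF", by_chrom_d))
            if _overlaps_any(p, by_chrom_a.get(p.interval.chrom, ())):
                classes.append(("PBAF", by_chrom_a))
            pid = p.interval.name or f"{cond}_SMARCC1_{i + 1}"
            for cls, partner_map in classes:
                if site_interval == "smarcc1":
                    contributors.append(
                        (p.interval, p.summit, cls, cond, pid, p.signal_value)
                    )
                else:
                    for o in partner_map.get(p.interval.chrom, ()):
                        ov = overlap_bp(p.interval, o.interval)
                        if ov > 0:
                            seg = GenomicInterval(
                                p.interval.chrom,
                                max(p.interval.start, o.interval.start),
                                min(p.interval.end, o.interval.end),
                            )
                            contributors.append(
                                (seg, p.summit, cls, cond, pid, p.signal_value)
                            )
    if not any_smarcc1:
        logger.warning("define_sites: no SMARCC1 peaks; empty site set")
    if not contributors:
        return []

    merged = merge_intervals([c[0] for c in contributors], max_gap=0)
    sites: list[OccupancySite] = []
    for i, iv in enumerate(merged):
        members = [
            c
            for c in contributors
            if c[0].chrom == iv.chrom and c[0].start < iv.end and c[0].end > iv.start
        ]
        classes = {c[2] for c in members}
        conds = {c[3] for c in members}
        best = max(members, key=lambda c: (c[5], -c[0].start))
        sites.append(
            OccupancySite(
                interval=GenomicInterval(
                    iv.chrom, iv.start, iv.end, name=f"site_{i + 1}"
                ),
                center=best[1],
                complex_class="both" if len(classes) > 1 else classes.pop(),
                condition_origin="both" if len(conds) > 1 else conds.pop(),
                source_peaks=tuple(sorted({c[4] for c in members})),
            )
        )
    return sites


def normalized_enrichment(
    region: GenomicInterval | OccupancySite,
    ip: SignalTrack,
    input_ctrl: SignalTrack | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Pseudocount-stabilized per-million enrichment ratio.

    ``(IP per-million + pc) / (input per-million + pc)``; with no input
    track (e.g. ATAC) the IP per-million plus pseudocount is returned.
    Always strictly positive; equals 1 on all-zero data with an input.
    """
    iv = region.interval if isinstance(region, OccupancySite) else region
    num = ip.per_million(iv) + pseudocount
    if input_ctrl is None:
        return num
    return num / (input_ctrl.per_million(iv) + pseudocount)


def compute_enrichments(
    sites: Sequence[OccupancySite],
    tracks: Mapping[tuple[str, str], tuple[SignalTrack, SignalTrack | None]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[OccupancySite]:
    """Fill ``site.enrichment`` for every (assay, condition) track pair."""
    for site in sites:
        for (assay, cond), (ip, inp) in tracks.items():
            site.enrichment[(assay, cond)] = normalized_enrichment(
                site, ip, inp, pseudocount
            )
    return list(sites)


def log2_fold_changes(
    sites: Sequence[OccupancySite],
    assays: Sequence[str] | None = None,
    control: str = "control",
    reexpression: str = "reexpression",
) -> list[OccupancySite]:
    """``log2(enrichment_reexpression / enrichment_control)`` per assay;
    finite always, since enrichments are strictly positive."""
    for site in sites:
        todo = assays or sorted({a for a, _ in site.enrichment})
        for assay in todo:
            e_c = site.enrichment.get((assay, control))
            e_r = site.enrichment.get((assay, reexpression))
            if e_c is None or e_r is None:
                raise ValueError(
                    f"site {site.interval}: enrichment missing for {assay!r} "
                    "in one condition"
                )
            site.log2fc[assay] = math.log2(e_r / e_c)
    return list(sites)


def partition_sites(
    sites: Sequence[OccupancySite],
    tss_positions: Mapping[str, np.ndarray],
    se_regions: Sequence[GenomicInterval],
    distal_min_dist: int = DEFAULT_DISTAL_MIN_DIST,
) -> list[OccupancySite]:
    """Assign the TSS/SE partition class to every site.

    ``se_regions`` should be the merged (control u re-expression) H3K27ac
    SE set. An empty TSS annotation is an error.
    """
    if not any(len(v) for v in tss_positions.values()):
        raise ValueError("partition_sites: empty TSS list")
    se_by_chrom: dict[str, list[GenomicInterval]] = {}
    for se in se_regions:
        se_by_chrom.setdefault(se.chrom, []).append(se)
    n_unclassified = 0
    for site in sites:
        tss = tss_positions.get(site.interval.chrom)
        if tss is None or len(tss) == 0:
            dist = np.inf
        else:
            j = int(np.searchsorted(tss, site.interval.start))
            inside = np.any(
                (tss >= site.interval.start) & (tss < site.interval.end)
            )
            if inside:
                site.partition = "proximal"
                continue
            cands = []
            if j > 0:
                cands.append(site.interval.start - tss[j - 1])
            if j < len(tss):
                cands.append(tss[j] - site.interval.end)
            dist = min(cands) if cands else np.inf
        if dist > distal_min_dist:
            in_se = any(
                overlap_bp(site.interval, se) > 0
                for se in se_by_chrom.get(site.interval.chrom, ())
            )
            site.partition = "distal_in_SE" if in_se else "distal_out_SE"
        else:
            site.partition = "unclassified"
            n_unclassified += 1
    if n_unclassified:
        logger.info(
            "partition_sites: %d sites within 1-%d bp of a TSS excluded "
            "from partition statistics",
            n_unclassified,
            distal_min_dist,
        )
    return list(sites)


def weighted_histogram(
    values_by_group: Mapping[str, Sequence[float]],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-group frequencies weighted by group size: bar heights are
    count/group_size so every group sums to 1 regardless of its size."""
    edges = np.asarray(bin_edges, dtype=float)
    cols = {}
    for group, values in values_by_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            logger.warning("weighted_histogram: empty group %r omitted", group)
            continue
        counts, _ = np.histogram(v, bins=edges)
        cols[group] = counts / v.size
    idx = pd.IntervalIndex.from_breaks(edges, closed="left")
    return pd.DataFrame(cols, index=idx).rename_axis("bin")


def quadrant_fractions(
    x: Sequence[float], y: Sequence[float], fold_threshold: float = 1.5
) -> dict[str, float]:
    """Fractions of points in the four +/-``fold_threshold`` concordance
    classes of the (x, y) log2 fold-change plane."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    t = math.log2(fold_threshold)
    both_down = (x <= -t) & (y <= -t)
    both_up = (x >= t) & (y >= t)
    discordant = ((x <= -t) & (y >= t)) | ((x >= t) & (y <= -t))
    gray = ~(both_down | both_up | discordant)
    n = x.size
    return {
        "both_down": both_down.sum() / n,
        "both_up": both_up.sum() / n,
        "discordant": discordant.sum() / n,
        "inside_gray": gray.sum() / n,
    }


def quadrant_summary(
    sites: Sequence[OccupancySite],
    assay_x: str = "SMARCC1",
    assay_y: str = "H3K27ac",
    fold_threshold: float = 1.5,
    strong_fold: float = 2.0,
    groups: Sequence[str] = ("proximal", "distal_in_SE", "distal_out_SE"),
) -> dict[str, QuadrantSummary]:
    """Per-partition-group concordance quadrant summary plus the count of
    sites with an ``assay_y`` decrease stronger than ``strong_fold``."""
    out: dict[str, QuadrantSummary] = {}
    for group in groups:
        members = [s for s in sites if s.partition == group]
        if not members:
            logger.warning("quadrant_summary: empty group %r", group)
            out[group] = QuadrantSummary(
                group, 0, fold_threshold,
                math.nan, math.nan, math.nan, math.nan,
                strong_fold, 0, degenerate=True,
            )
            continue
        x = [s.log2fc[assay_x] for s in members]
        y = [s.log2fc[assay_y] for s in members]
        fr = quadrant_fractions(x, y, fold_threshold)
        n_strong = int(np.sum(np.asarray(y) <= -math.log2(strong_fold)))
        out[group] = QuadrantSummary(
            group, len(members), fold_threshold,
            fr["both_down"], fr["both_up"], fr["discordant"], fr["inside_gray"],
            strong_fold, n_strong,
        )
    return out


def strong_decrease_ratio(
    sites: Sequence[OccupancySite],
    assay: str = "H3K27ac",
    fold: float = 2.0,
) -> dict:
    """Per-partition counts and fractions of sites with an ``assay``
    decrease stronger than ``fold``; ratios of the in-SE fraction over
    each other partition's fraction (inf where a denominator is zero)."""
    t = math.log2(fold)
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for group in ("proximal", "distal_in_SE", "distal_out_SE"):
        members = [s for s in sites if s.partition == group]
        totals[group] = len(members)
        counts[group] = sum(1 for s in members if s.log2fc[assay] <= -t)
    fractions = {
        g: (counts[g] / totals[g]) if totals[g] else math.nan for g in counts
    }
    ratios = {}
    for g in ("proximal", "distal_out_SE"):
        denom = fractions[g]
        if not denom or math.isnan(denom):
            ratios[g] = math.inf
        else:
            ratios[g] = fractions["distal_in_SE"] / denom
    flagged = any(math.isinf(r) for r in ratios.values())
    if flagged:
        logger.warning("strong_decrease_ratio: zero denominator; ratio infinite")
    return {
        "counts": counts,
        "totals": totals,
        "fractions": fractions,
        "ratio_in_se_over": ratios,
        "degenerate": flagged,
    }


def export_signal_matrix(
    sites: Sequence[OccupancySite],
    track: SignalTrack,
    flank: int = 1_500,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Site x position matrix of coverage around site centers (+/-flank),
    for external heatmap plotting. Out-of-extent bins are zero."""
    n_bins = 2 * flank // bin_size
    offsets = np.arange(n_bins) * bin_size - flank
    rows = []
    for site in sites:
        row = np.zeros(n_bins)
        for j, off in enumerate(offsets):
            start = site.center + int(off)
            end = start + bin_size
            if start < 0 or end > track.extent(site.interval.chrom):
                continue
            row[j] = track.interval_signal(
                GenomicInterval(site.interval.chrom, start, end)
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        index=[s.interval.name or str(s.interval) for s in sites],
        columns=offsets,
    )


def sites_table(sites: Sequence[OccupancySite]) -> pd.DataFrame:
    records = []
    for s in sites:
        rec = {
            "site": s.interval.name or str(s.interval),
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "center": s.center,
            "complex_class": s.complex_class,
            "condition_origin": s.condition_origin,
            "partition": s.partition,
        }
        for (assay, cond), v in sorted(s.enrichment.items()):
            rec[f"enrichment_{assay}_{cond}"] = v
        for assay, v in sorted(s.log2fc.items()):
            rec[f"log2fc_{assay}"] = v
        records.append(rec)
    return pd.DataFrame(records)
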