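"""Shared fixtures: demo synthetic datasets and brute-force oracle helpers.

The oracles here are deliberately naive O(n^2) re-implementations used as
independent references; they must never share code with the package paths
they check.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import selandscape as sl
from selandscape.core import (
    SignalTrack,
    read_bed,
    read_gene_table,
    read_library_sizes,
    read_narrowpeak,
    tss_positions,
)
from selandscape.simulate import demo_landscape_config


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def rose_cutoff_exhaustive(signals):
    """Independent exhaustive tangent-cutoff: per candidate index, count
    points on or below the slope-m line through it; min count wins,
    ties -> smallest index."""
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    m = (s[-1] - s[0]) / n
    best = None
    for x in range(n):
        count = 0
        for i in range(n):
            if s[i] - s[x] <= m * (float(i) - float(x)):
                count += 1
        if best is None or count < best[0]:
            best = (count, x)
    return float(s[best[1]]), best[1] + 1


def merge_bruteforce(triples, max_gap=0):
    """Repeated pairwise merging to a fixed point; input/output as
    (chrom, start, end) triples, output sorted."""
    items = [list(t) for t in triples]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= max_gap:
                    merged = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    items = [items[k] for k in range(len(items)) if k not in (i, j)]
                    items.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e in items)


def overlap_bruteforce(a, b):
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def reciprocal_overlap(a, b, fraction=0.5):
    ov = overlap_bruteforce(a, b)
    return ov >= fraction * (a[2] - a[1]) and ov >= fraction * (b[2] - b[1])


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=5_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append((chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# demo datasets (module-scoped: generated once per test session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def demo_landscape(tmp_path_factory):
    """The demo landscape (seed 1) plus everything loaded for calling."""
    outdir = tmp_path_factory.mktemp("landscape")
    config = demo_landscape_config(seed=1)
    truth = sl.simulate_landscape(config, outdir)
    sizes = read_library_sizes(outdir / "library_sizes.tsv")
    genes = read_gene_table(outdir / "genes.tsv")
    peaks = sl.filter_excluded(
        read_narrowpeak(outdir / "demo.h3k27ac.narrowPeak"),
        read_bed(outdir / "exclusion.bed"),
    )
    return {
        "outdir": outdir,
        "config": config,
        "truth": truth,
        "peaks": peaks,
        "genes": genes,
        "tss": tss_positions(genes),
        "ip": SignalTrack.from_bedgraph(
            outdir / "demo.h3k27ac.bedGraph", sizes["demo.h3k27ac"]
        ),
        "input": SignalTrack.from_bedgraph(outdir / "input.bedGraph", sizes["input"]),
    }


@pytest.fixture(scope="session")
def demo_occupancy(tmp_path_factory):
    """The demo occupancy design (seed 7), run through the full site
    measurement chain."""
    import yaml

    from selandscape import occupancy as occ

    outdir = tmp_path_factory.mktemp("occupancy")
    config = sl.SyntheticConfig(seed=7)
    truth = sl.simulate_occupancy(config, outdir)
    spec = yaml.safe_load(open(outdir / "inputs.yaml"))
    subunit_peaks = {
        cond: {sub: read_narrowpeak(outdir / p) for sub, p in by_sub.items()}
        for cond, by_sub in spec["peaks"].items()
    }
    tracks = {}
    for assay, by_cond in spec["tracks"].items():
        for cond, t in by_cond.items():
            tracks[(assay, cond)] = (
                SignalTrack.from_bedgraph(outdir / t["ip"], t["ip_library_size"]),
                SignalTrack.from_bedgraph(
                    outdir / t["input"], t["input_library_size"]
                ),
            )
    sites = occ.define_sites(subunit_peaks)
    occ.compute_enrichments(sites, tracks)
    occ.log2_fold_changes(sites)
    occ.partition_sites(
        sites,
        tss_positions(read_gene_table(outdir / spec["tss"])),
        read_bed(outdir / spec["se_regions"]),
    )
    return {
        "outdir": outdir,
        "config": config,
        "truth": truth,
        "sites": sites,
        "tracks": tracks,
    }
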