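"""Seed-reproducible synthetic data with planted, recoverable structure.

Three generators emulate the statistical structure of the study designs
the pipeline serves, so every stage is testable without any sequencing
download:

* :func:`simulate_landscape` — an H3K27ac-like enhancer landscape per
  sample: Poisson background coverage, isolated enhancer peaks spaced
  beyond the stitch window, and planted super-enhancers (dense clusters
  of high-amplitude peaks) with a configurable cross-sample sharing
  design. Emits narrowPeak, bedGraph, TSS/gene TSV, an exclusion BED with
  decoy peaks inside it, an oncogene list, and the planted truth.
* :func:`simulate_occupancy` — SWI/SNF subunit peaks in three strata
  (TSS-proximal, distal-in-SE, distal-out), DPF2/ARID2 co-peaks drawn per
  co-occupancy rate, and two-condition coverage realizing planted
  per-site log2 fold-change quadrants exactly (noise-free tracks, labels
  assigned in exact planted proportions).
* :func:`simulate_de` — a DESeq2-style DE table whose significant genes'
  down/up direction is a true Bernoulli draw with log-odds shifted by a
  planted odds ratio for SE-linked genes, plus non-significant filler.

Determinism contract: identical config + seed give byte-identical output
files. Every output file gets its own labeled random substream derived
from the master seed, so adding one file never perturbs another.

Coverage bumps are triangular (summit-centered); the pipeline consumes
binned coverage, so read-level simulation would add cost without
exercising more code. Each track declares a nominal library size of 1e6
mapped reads (a real library includes reads outside the simulated
region), which makes per-million signal equal raw track sums exactly.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    GeneModel,
    GenomicInterval,
    Peak,
    write_bed,
    write_gene_table,
    write_library_sizes,
    write_narrowpeak,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SimulationError",
    "simulate_landscape",
    "simulate_occupancy",
    "simulate_de",
    "simulate_all",
]

LIBRARY_SIZE = 1_000_000.0


class SimulationError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    """All knobs of the three generators; the defaults are the demo study
    conditions every recovery test runs under."""

    seed: int
    # --- landscape ---
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    samples: tuple = ("sampleA", "sampleB", "sampleC")
    n_isolated_peaks: int = 200
    n_planted_se: int = 10
    n_se_common: int = 4        # present in all samples
    n_se_shared2: int = 3       # present in exactly two samples
    n_se_unique: int = 3        # private to one sample
    n_peaks_per_se: int = 6
    se_gap_range: tuple = (500, 1500)
    peak_width: int = 600
    base_amplitude: float = 60.0      # reads per isolated peak bump
    amplitude_multiplier: float = 5.0  # SE constituents vs isolated
    background_rate: float = 0.5       # Poisson reads per bin
    bin_size: int = 50
    min_spacing: int = 13_000          # between elements; > stitch window
    n_genes: int = 120
    n_oncogenes: int = 8
    n_exclusion_zones: int = 2
    exclusion_zone_length: int = 5_000
    n_decoy_peaks: int = 3
    # --- occupancy ---
    n_sites_per_stratum: int = 500
    occ_unit_span: int = 8_000
    occ_site_width: int = 400
    p_dpf2: float = 0.85
    p_arid2: float = 0.5
    quadrant_fractions_in_se: dict = field(
        default_factory=lambda: {"both_down": 0.6, "both_up": 0.05, "discordant": 0.05}
    )
    quadrant_fractions_out: dict = field(
        default_factory=lambda: {"both_down": 0.2, "both_up": 0.25, "discordant": 0.1}
    )
    strong_decrease_fraction_in_se: float = 0.3
    strong_decrease_fraction_out: float = 0.1
    # --- DE ---
    de_n_significant: int = 400
    de_n_filler: int = 200
    de_se_fraction: float = 0.4
    de_odds_ratio: float = 3.0
    de_baseline_down_odds: float = 0.52

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_se_common + self.n_se_shared2 + self.n_se_unique != self.n_planted_se:
            raise ValueError("SE sharing design must sum to n_planted_se")
        for name in ("n_isolated_peaks", "n_planted_se", "n_peaks_per_se",
                     "n_sites_per_stratum", "de_n_significant", "de_n_filler"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for fr in (self.quadrant_fractions_in_se, self.quadrant_fractions_out):
            vals = list(fr.values())
            if any(not 0 <= v <= 1 for v in vals) or sum(vals) > 1 + 1e-9:
                raise ValueError("quadrant fractions must lie in [0,1] and sum <= 1")
        if not 0 < self.de_baseline_down_odds:
            raise ValueError("de_baseline_down_odds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "samples" in data:
            data["samples"] = tuple(data["samples"])
        if "se_gap_range" in data:
            data["se_gap_range"] = tuple(data["se_gap_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["samples"] = list(data["samples"])
        data["se_gap_range"] = list(data["se_gap_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """The planted structure, sufficient to score every recovery test."""

    planted_se: list = field(default_factory=list)       # dict rows
    isolated_peaks: list = field(default_factory=list)
    occupancy_sites: list = field(default_factory=list)  # dict rows
    occupancy_counts: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Labeled substream: stable across runs and insertion order."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _place_elements(
    chrom_size: int,
    widths: Sequence[int],
    min_spacing: int,
    rng: np.random.Generator,
) -> list[int]:
    """Place elements left-to-right with gaps >= min_spacing (including the
    chromosome ends); slack is spread randomly. Returns start positions."""
    k = len(widths)
    total_min = sum(widths) + (k + 1) * min_spacing
    if total_min > chrom_size:
        raise SimulationError(
            f"infeasible packing: {k} elements need {total_min} bp "
            f"but chromosome is {chrom_size} bp"
        )
    slack = chrom_size - total_min
    extras = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    starts = []
    pos = 0
    for i, w in enumerate(widths):
        pos += min_spacing + int(extras[i])
        starts.append(pos)
        pos += w
    return starts


def _add_bump(arr: np.ndarray, bin_size: int, summit: int, width: int, area: float):
    """Add a triangular bump of total ``area`` centered at ``summit``."""
    lo = max(0, (summit - width // 2) // bin_size)
    hi = min(len(arr), -(-(summit + width // 2) // bin_size))
    if hi <= lo:
        return
    centers = (np.arange(lo, hi) + 0.5) * bin_size
    w = np.maximum(0.0, 1.0 - np.abs(centers - summit) / (width / 2))
    if w.sum() > 0:
        arr[lo:hi] += area * w / w.sum()


def simulate_landscape(config: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Generate the multi-sample enhancer landscape; see module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = sorted(config.chrom_sizes)
    place_rng = _rng(config.seed, "landscape/placement")

    # -- design the element list per chromosome ------------------------------
    se_specs = []  # (se_id, chrom_idx, gaps, samples)
    patterns = (
        [tuple(config.samples)] * config.n_se_common
        + [
            tuple(sorted({config.samples[i % len(config.samples)],
                          config.samples[(i + 1) % len(config.samples)]}))
            for i in range(config.n_se_shared2)
        ]
        + [
            (config.samples[i % len(config.samples)],)
            for i in range(config.n_se_unique)
        ]
    )
    for i in range(config.n_planted_se):
        gaps = place_rng.integers(
            config.se_gap_range[0], config.se_gap_range[1] + 1,
            size=max(0, config.n_peaks_per_se - 1),
        )
        se_specs.append((f"planted_se_{i + 1}", i % len(chroms), gaps, patterns[i]))

    elements: dict[str, list[dict]] = {c: [] for c in chroms}
    for se_id, ci, gaps, samps in se_specs:
        span = config.n_peaks_per_se * config.peak_width + int(gaps.sum())
        elements[chroms[ci]].append(
            {"type": "se", "width": span, "se_id": se_id, "gaps": gaps,
             "samples": samps}
        )
    for i in range(config.n_isolated_peaks):
        elements[chroms[i % len(chroms)]].append(
            {"type": "isolated", "width": config.peak_width, "idx": i}
        )
    for i in range(config.n_exclusion_zones):
        elements[chroms[i % len(chroms)]].append(
            {"type": "exclusion", "width": config.exclusion_zone_length, "idx": i}
        )

    truth = SyntheticTruth()
    peaks_by_sample: dict[str, list[Peak]] = {s: [] for s in config.samples}
    bumps_by_sample: dict[str, list[tuple[str, int, float]]] = {
        s: [] for s in config.samples
    }
    exclusion: list[GenomicInterval] = []

    amp_rng = _rng(config.seed, "landscape/amplitudes")
    for chrom in chroms:
        elems = elements[chrom]
        order = place_rng.permutation(len(elems))
        elems = [elems[int(j)] for j in order]
        starts = _place_elements(
            config.chrom_sizes[chrom],
            [e["width"] for e in elems],
            config.min_spacing,
            place_rng,
        )
        for e, start in zip(elems, starts):
            if e["type"] == "isolated":
                iv = GenomicInterval(
                    chrom, start, start + config.peak_width,
                    name=f"iso_{e['idx'] + 1}",
                )
                summit_off = config.peak_width // 2
                truth.isolated_peaks.append(
                    {"chrom": chrom, "start": iv.start, "end": iv.end, "name": iv.name}
                )
                for s in config.samples:
                    amp = config.base_amplitude * amp_rng.uniform(0.7, 1.3)
                    peaks_by_sample[s].append(
                        Peak(iv, summit_off, signal_value=round(amp, 3))
                    )
                    bumps_by_sample[s].append((chrom, iv.start + summit_off, amp))
            elif e["type"] == "se":
                pos = start
                constituent_rows = []
                for j in range(config.n_peaks_per_se):
                    iv = GenomicInterval(
                        chrom, pos, pos + config.peak_width,
                        name=f"{e['se_id']}_p{j + 1}",
                    )
                    constituent_rows.append(iv)
                    if j < config.n_peaks_per_se - 1:
                        pos += config.peak_width + int(e["gaps"][j])
                se_end = constituent_rows[-1].end
                truth.planted_se.append(
                    {
                        "se_id": e["se_id"],
                        "chrom": chrom,
                        "start": start,
                        "end": se_end,
                        "samples": list(e["samples"]),
                    }
                )
                for s in e["samples"]:
                    for iv in constituent_rows:
                        amp = (
                            config.base_amplitude
                            * config.amplitude_multiplier
                            * amp_rng.uniform(0.8, 1.2)
                        )
                        peaks_by_sample[s].append(
                            Peak(iv, config.peak_width // 2, signal_value=round(amp, 3))
                        )
                        bumps_by_sample[s].append(
                            (chrom, iv.start + config.peak_width // 2, amp)
                        )
            else:  # exclusion zone, with decoy peaks inside
                zone = GenomicInterval(
                    chrom, start, start + e["width"], name=f"excl_{e['idx'] + 1}"
                )
                exclusion.append(zone)

    # decoy peaks inside exclusion zones (should be filtered out upstream)
    decoy_rng = _rng(config.seed, "landscape/decoys")
    for i in range(config.n_decoy_peaks):
        zone = exclusion[i % len(exclusion)] if exclusion else None
        if zone is None or zone.length <= config.peak_width:
            break
        off = int(decoy_rng.integers(0, zone.length - config.peak_width))
        iv = GenomicInterval(
            zone.chrom, zone.start + off, zone.start + off + config.peak_width,
            name=f"decoy_{i + 1}",
        )
        for s in config.samples:
            peaks_by_sample[s].append(
                Peak(iv, config.peak_width // 2, signal_value=999.0)
            )

    # -- genes/TSS: guaranteed SE-adjacent genes, then uniform filler --------
    gene_rng = _rng(config.seed, "landscape/genes")
    se_spans = {
        c: [(r["start"], r["end"]) for r in truth.planted_se if r["chrom"] == c]
        for c in chroms
    }

    def _near_se(chrom: str, pos: int, pad: int) -> bool:
        return any(s - pad <= pos < e + pad for s, e in se_spans[chrom])

    genes: list[GeneModel] = []
    oncogene_symbols: list[str] = []
    gi = 0
    for r in truth.planted_se:
        tss = r["end"] + int(gene_rng.integers(10_000, 30_000))
        if tss >= config.chrom_sizes[r["chrom"]]:
            tss = max(0, r["start"] - int(gene_rng.integers(10_000, 30_000)))
        gi += 1
        genes.append(
            GeneModel(f"GSYN{gi:04d}", f"SYNG{gi:04d}", r["chrom"],
                      "+" if gi % 2 else "-", int(tss))
        )
    n_se_genes = gi
    attempts = 0
    while gi < config.n_genes and attempts < 50 * config.n_genes:
        attempts += 1
        chrom = chroms[int(gene_rng.integers(0, len(chroms)))]
        pos = int(gene_rng.integers(0, config.chrom_sizes[chrom]))
        if _near_se(chrom, pos, 6_000):  # keep TSS exclusion away from SE peaks
            continue
        gi += 1
        genes.append(
            GeneModel(f"GSYN{gi:04d}", f"SYNG{gi:04d}", chrom,
                      "+" if gi % 2 else "-", pos)
        )
    genes.sort(key=lambda g: (g.chrom, g.tss))
    n_onco_near = min(config.n_oncogenes // 2 + 1, n_se_genes)
    oncogene_symbols = [f"SYNG{i + 1:04d}" for i in range(n_onco_near)]
    far = [g.symbol for g in genes if int(g.symbol[4:]) > n_se_genes]
    oncogene_symbols += far[: config.n_oncogenes - n_onco_near]

    # -- coverage tracks -----------------------------------------------------
    sizes: dict[str, float] = {}
    for s in config.samples:
        track_rng = _rng(config.seed, f"landscape/track/{s}")
        with open(outdir / f"{s}.h3k27ac.bedGraph", "w") as fh:
            for chrom in chroms:
                n_bins = -(-config.chrom_sizes[chrom] // config.bin_size)
                arr = track_rng.poisson(
                    config.background_rate, n_bins
                ).astype(float)
                for bchrom, summit, area in bumps_by_sample[s]:
                    if bchrom == chrom:
                        _add_bump(arr, config.bin_size, summit,
                                  config.peak_width, area)
                for i, v in enumerate(arr):
                    fh.write(
                        f"{chrom}\t{i * config.bin_size}"
                        f"\t{(i + 1) * config.bin_size}\t{v:.6g}\n"
                    )
        sizes[f"{s}.h3k27ac"] = LIBRARY_SIZE
    input_rng = _rng(config.seed, "landscape/track/input")
    with open(outdir / "input.bedGraph", "w") as fh:
        for chrom in chroms:
            n_bins = -(-config.chrom_sizes[chrom] // config.bin_size)
            arr = input_rng.poisson(config.background_rate, n_bins).astype(float)
            for i, v in enumerate(arr):
                fh.write(
                    f"{chrom}\t{i * config.bin_size}"
                    f"\t{(i + 1) * config.bin_size}\t{v:.6g}\n"
                )
    sizes["input"] = LIBRARY_SIZE

    # -- write the remaining files ------------------------------------------
    for s in config.samples:
        peaks = sorted(peaks_by_sample[s], key=lambda p: p.interval.sort_key())
        write_narrowpeak(peaks, outdir / f"{s}.h3k27ac.narrowPeak")
    write_bed(exclusion, outdir / "exclusion.bed")
    write_gene_table(genes, outdir / "genes.tsv")
    with open(outdir / "oncogenes.txt", "w") as fh:
        fh.write("\n".join(oncogene_symbols) + "\n")
    write_library_sizes(sizes, outdir / "library_sizes.tsv")
    se_df = pd.DataFrame(
        truth.planted_se, columns=["se_id", "chrom", "start", "end", "samples"]
    )
    se_df["samples"] = se_df["samples"].map(",".join)
    se_df.to_csv(outdir / "truth_planted_se.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    config.to_yaml(outdir / "config.yaml")
    return truth


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

_LABEL_RANGES = {
    # (x_lo, x_hi, y_lo, y_hi); margins keep draws clear of the +/-log2(1.5)
    # and +/-1 boundaries even after pseudocount distortion (<0.02 log2 units)
    "both_down_strong": (-2.2, -0.65, -2.4, -1.05),
    "both_down_mild": (-2.2, -0.65, -0.96, -0.65),
    "both_up": (0.65, 2.0, 0.65, 2.0),
    "discordant_xdown": (-2.2, -0.65, 0.65, 2.0),
    # y stays above -1 so the strong-decrease count is exactly the
    # both_down_strong contingent
    "discordant_xup": (0.65, 2.0, -0.96, -0.65),
    "gray": (-0.5, 0.5, -0.5, 0.5),
}


def _stratum_labels(n: int, fr: Mapping[str, float], f_strong: float,
                    rng: np.random.Generator) -> list[str]:
    """Quadrant labels in exact planted proportions, order shuffled."""
    n_bd = round(n * fr["both_down"])
    n_strong = min(round(n * f_strong), n_bd)
    n_bu = round(n * fr["both_up"])
    n_dc = round(n * fr["discordant"])
    labels = (
        ["both_down_strong"] * n_strong
        + ["both_down_mild"] * (n_bd - n_strong)
        + ["both_up"] * n_bu
        + ["discordant_xdown"] * ((n_dc + 1) // 2)
        + ["discordant_xup"] * (n_dc // 2)
    )
    labels += ["gray"] * (n - len(labels))
    return [labels[int(i)] for i in rng.permutation(len(labels))]


def simulate_occupancy(config: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Generate the SWI/SNF occupancy design; see module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, "occupancy/design")
    n = config.n_sites_per_stratum
    unit, width = config.occ_unit_span, config.occ_site_width
    if width >= unit - 2 * DEFAULT_SE_PAD - 200:
        raise SimulationError("occ_site_width too large for occ_unit_span")
    chrom = "chrO"
    strata = ["proximal"] * n + ["distal_in_SE"] * n + ["distal_out_SE"] * n
    strata = [strata[int(i)] for i in rng.permutation(len(strata))]
    chrom_size = (len(strata) + 2) * unit

    peaks = {"SMARCC1": [], "DPF2": [], "ARID2": []}
    tss_list: list[int] = []
    se_regions: list[GenomicInterval] = []
    site_rows = []
    labels_by_stratum = {
        "proximal": _stratum_labels(
            n, config.quadrant_fractions_out,
            config.strong_decrease_fraction_out, _rng(config.seed, "occupancy/q/prox"),
        ),
        "distal_in_SE": _stratum_labels(
            n, config.quadrant_fractions_in_se,
            config.strong_decrease_fraction_in_se, _rng(config.seed, "occupancy/q/inse"),
        ),
        "distal_out_SE": _stratum_labels(
            n, config.quadrant_fractions_out,
            config.strong_decrease_fraction_out, _rng(config.seed, "occupancy/q/out"),
        ),
    }
    counters = {k: 0 for k in labels_by_stratum}
    draw_rng = _rng(config.seed, "occupancy/draws")

    for i, stratum in enumerate(strata):
        base = (i + 1) * unit
        iv = GenomicInterval(chrom, base, base + width, name=f"occ_{i + 1}")
        has_dpf2 = bool(draw_rng.random() < config.p_dpf2)
        has_arid2 = bool(draw_rng.random() < config.p_arid2)
        peaks["SMARCC1"].append(Peak(iv, width // 2, signal_value=1.0))
        shift = int(draw_rng.integers(-100, 101))
        partner_iv = GenomicInterval(
            chrom, max(0, base + shift), max(0, base + shift) + width,
            name=f"{iv.name}_co",
        )
        if has_dpf2:
            peaks["DPF2"].append(Peak(partner_iv, width // 2))
        if has_arid2:
            peaks["ARID2"].append(Peak(partner_iv, width // 2))
        if stratum == "proximal":
            tss_list.append(base + width // 2)
        elif stratum == "distal_in_SE":
            se_regions.append(
                GenomicInterval(chrom, base - DEFAULT_SE_PAD,
                                base + width + DEFAULT_SE_PAD)
            )
        is_site = has_dpf2 or has_arid2
        if is_site:
            label = labels_by_stratum[stratum][counters[stratum]]
            counters[stratum] += 1
            x_lo, x_hi, y_lo, y_hi = _LABEL_RANGES[label]
            x = float(draw_rng.uniform(x_lo, x_hi))
            y = float(draw_rng.uniform(y_lo, y_hi))
        else:
            label, x, y = "not_a_site", 0.0, 0.0
        site_rows.append(
            {
                "name": iv.name,
                "chrom": chrom,
                "start": iv.start,
                "end": iv.end,
                "stratum": stratum,
                "is_site": is_site,
                "complex": ("both" if has_dpf2 and has_arid2
                            else "BAF" if has_dpf2
                            else "PBAF" if has_arid2 else "none"),
                "label": label,
                "log2fc_smarcc1": round(x, 6),
                "log2fc_h3k27ac": round(y, 6),
            }
        )

    # -- tracks: flat background + rectangular site coverage, noise-free ----
    bin_size = config.bin_size
    n_bins = chrom_size // bin_size
    bg_ip, bg_input = 0.1, 0.1  # reads (== per-million) per bin
    base_rpm_rng = _rng(config.seed, "occupancy/base_rpm")
    base_rpm = {
        r["name"]: (float(base_rpm_rng.uniform(30, 60)),
                    float(base_rpm_rng.uniform(30, 60)))
        for r in site_rows
    }

    def _site_bins(start: int) -> slice:
        return slice(start // bin_size, (start + width) // bin_size)

    tracks: dict[str, np.ndarray] = {}
    for assay, fc_key in (("smarcc1", "log2fc_smarcc1"),
                          ("h3k27ac", "log2fc_h3k27ac")):
        for cond in ("control", "reexpression"):
            arr = np.full(n_bins, bg_ip)
            for j, r in enumerate(site_rows):
                a_c = base_rpm[r["name"]][0 if assay == "smarcc1" else 1]
                if cond == "control":
                    target = a_c
                else:
                    target = (a_c + DEFAULT_PSEUDOCOUNT) * 2.0 ** r[fc_key] \
                        - DEFAULT_PSEUDOCOUNT
                sl = _site_bins(r["start"])
                nb = sl.stop - sl.start
                bump = max(0.0, target - bg_ip * nb)
                arr[sl] += bump / nb
            tracks[f"{assay}_{cond}"] = arr
    for cond in ("control", "reexpression"):
        tracks[f"input_{cond}"] = np.full(n_bins, bg_input)

    sizes = {}
    for name, arr in tracks.items():
        with open(outdir / f"{name}.bedGraph", "w") as fh:
            for i, v in enumerate(arr):
                fh.write(
                    f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.8g}\n"
                )
        sizes[name] = LIBRARY_SIZE
    write_library_sizes(sizes, outdir / "library_sizes.tsv")

    for cond in ("control", "reexpression"):
        for subunit, plist in peaks.items():
            write_narrowpeak(plist, outdir / f"{subunit.lower()}_{cond}.narrowPeak")
    write_gene_table(
        [
            GeneModel(f"OCCG{i + 1:04d}", f"OCCG{i + 1:04d}", chrom, "+", t)
            for i, t in enumerate(sorted(tss_list))
        ],
        outdir / "tss.tsv",
    )
    write_bed(se_regions, outdir / "se_regions.bed")

    manifest = {
        "peaks": {
            cond: {sub: f"{sub.lower()}_{cond}.narrowPeak"
                   for sub in ("SMARCC1", "DPF2", "ARID2")}
            for cond in ("control", "reexpression")
        },
        "tracks": {
            assay: {
                cond: {
                    "ip": f"{assay.lower()}_{cond}.bedGraph",
                    "ip_library_size": LIBRARY_SIZE,
                    "input": f"input_{cond}.bedGraph",
                    "input_library_size": LIBRARY_SIZE,
                }
                for cond in ("control", "reexpression")
            }
            for assay in ("SMARCC1", "H3K27ac")
        },
        "tss": "tss.tsv",
        "se_regions": "se_regions.bed",
    }
    with open(outdir / "inputs.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    truth = SyntheticTruth(
        occupancy_sites=site_rows,
        occupancy_counts={
            s: {
                "n_peaks": strata.count(s),
                "n_sites": counters[s],
            }
            for s in counters
        },
    )
    pd.DataFrame(site_rows).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return truth


DEFAULT_SE_PAD = 800
DEFAULT_PSEUDOCOUNT = 0.1


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def simulate_de(
    config: SyntheticConfig,
    outdir: str | Path,
    se_gene_ids: Sequence[str] | None = None,
) -> SyntheticTruth:
    """Generate a DE table with a planted direction/SE-proximity odds ratio.

    Directions are true Bernoulli draws: P(down) has odds
    ``de_baseline_down_odds`` for non-SE genes, multiplied by
    ``de_odds_ratio`` for SE-linked genes. Non-significant filler genes
    exercise the significance filter. If ``se_gene_ids`` is given, those
    ids define SE linkage; otherwise a synthetic universe is built.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, "de/table")
    n_sig, n_fill = config.de_n_significant, config.de_n_filler
    n_total = n_sig + n_fill

    if se_gene_ids is None:
        gene_ids = [f"DEG{i + 1:05d}" for i in range(n_total)]
        n_se = round(n_total * config.de_se_fraction)
        se_flags = np.zeros(n_total, dtype=bool)
        se_flags[rng.choice(n_total, size=n_se, replace=False)] = True
        se_ids = {gene_ids[i] for i in np.flatnonzero(se_flags)}
    else:
        se_ids = set(map(str, se_gene_ids))
        gene_ids = [f"DEG{i + 1:05d}" for i in range(n_total)]
        n_from_links = min(len(se_ids), round(n_total * config.de_se_fraction))
        linked = sorted(se_ids)[:n_from_links]
        for i, gid in enumerate(linked):
            gene_ids[i] = gid
        gene_ids = list(dict.fromkeys(gene_ids))
        se_ids = set(linked)

    odds0 = config.de_baseline_down_odds
    odds1 = odds0 * config.de_odds_ratio
    p_down = {False: odds0 / (1 + odds0), True: odds1 / (1 + odds1)}

    rows = []
    for i, gid in enumerate(gene_ids):
        is_se = gid in se_ids
        if i < n_sig:
            down = bool(rng.random() < p_down[is_se])
            mag = 1.5 + float(rng.exponential(0.8))
            lfc = -mag if down else mag
            padj = float(rng.uniform(1e-8, 0.0499))
        else:
            # filler: small fold-change or non-significant padj
            if rng.random() < 0.5:
                lfc = float(rng.uniform(-1.49, 1.49))
                padj = float(rng.uniform(0.0, 1.0))
            else:
                lfc = float(rng.normal(0, 2.5))
                padj = float(rng.uniform(0.05, 1.0))
        rows.append(
            {"gene_id": gid, "symbol": gid, "log2fc": round(lfc, 5),
             "padj": padj, "_se": is_se}
        )
    order = rng.permutation(len(rows))
    rows = [rows[int(i)] for i in order]
    df = pd.DataFrame(rows)
    df.drop(columns="_se").to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    links = df[df["_se"]][["gene_id"]].copy()
    links["se_id"] = [f"SE{(i % 40) + 1:03d}" for i in range(len(links))]
    links.to_csv(outdir / "se_links.tsv", sep="\t", index=False)

    truth = SyntheticTruth(
        de={
            "odds_ratio": config.de_odds_ratio,
            "baseline_down_odds": odds0,
            "p_down_non_se": p_down[False],
            "p_down_se": p_down[True],
            "n_significant": n_sig,
            "n_filler": n_fill,
            "n_se_linked": int(df["_se"].sum()),
        }
    )
    truth.to_json(outdir / "truth.json")
    return truth


def demo_landscape_config(seed: int = 1) -> SyntheticConfig:
    """The single-sample demo landscape: 2 Mb chromosomes, 200 isolated
    peaks, 10 planted SEs at 5x amplitude, all present in one sample."""
    return SyntheticConfig(
        seed=seed,
        samples=("demo",),
        n_se_common=10,
        n_se_shared2=0,
        n_se_unique=0,
    )


def simulate_all(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Run all three generators under ``outdir``/{landscape,occupancy,de}."""
    outdir = Path(outdir)
    return {
        "landscape": simulate_landscape(config, outdir / "landscape"),
        "occupancy": simulate_occupancy(config, outdir / "occupancy"),
        "de": simulate_de(config, outdir / "de"),
    }
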