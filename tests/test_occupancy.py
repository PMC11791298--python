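"""Site construction, enrichment normalization, partition, quadrants."""
import math

import numpy as np
import pytest

from selandscape.core import GenomicInterval, Peak, SignalTrack
from selandscape.occupancy import (
    OccupancySite,
    define_sites,
    log2_fold_changes,
    normalized_enrichment,
    partition_sites,
    quadrant_fractions,
    quadrant_summary,
    strong_decrease_ratio,
    weighted_histogram,
)
from conftest import overlap_bruteforce, random_intervals


def _peak(chrom, start, end, name=None, summit=None, signal=1.0):
    iv = GenomicInterval(chrom, start, end, name=name)
    return Peak(iv, summit, signal_value=signal)


class TestDefineSites:
    def test_smarcc1_overlapping_dpf2_is_baf_site(self):
        sites = define_sites(
            {
                "control": {
                    "SMARCC1": [_peak("chr1", 100, 600, summit=250)],
                    "DPF2": [_peak("chr1", 550, 800)],
                    "ARID2": [],
                }
            }
        )
        assert len(sites) == 1
        s = sites[0]
        assert (s.interval.start, s.interval.end) == (100, 600)
        assert s.complex_class == "BAF"
        assert s.center == 350

    def test_both_partners_give_class_both(self):
        sites = define_sites(
            {
                "control": {
                    "SMARCC1": [_peak("chr1", 100, 600, summit=250)],
                    "DPF2": [_peak("chr1", 550, 800)],
                    "ARID2": [_peak("chr1", 50, 150)],
                }
            }
        )
        assert sites[0].complex_class == "both"

    def test_no_partner_no_site(self):
        sites = define_sites(
            {
                "control": {
                    "SMARCC1": [_peak("chr1", 100, 600, summit=250)],
                    "DPF2": [_peak("chr1", 600, 800)],  # half-open touch
                    "ARID2": [],
                }
            }
        )
        assert sites == []

    def test_conditions_merge_with_origin_flags(self):
        sites = define_sites(
            {
                "control": {
                    "SMARCC1": [_peak("chr1", 100, 600, summit=250)],
                    "DPF2": [_peak("chr1", 400, 800)],
                },
                "reexpression": {
                    "SMARCC1": [_peak("chr1", 300, 900, summit=300)],
                    "DPF2": [_peak("chr1", 400, 800)],
                },
            }
        )
        assert len(sites) == 1
        assert sites[0].condition_origin == "both"
        assert (sites[0].interval.start, sites[0].interval.end) == (100, 900)

    def test_intersection_mode_uses_overlap_segment(self):
        sites = define_sites(
            {
                "control": {
                    "SMARCC1": [_peak("chr1", 100, 600, summit=250)],
                    "DPF2": [_peak("chr1", 550, 800)],
                }
            },
            site_interval="intersection",
        )
        assert (sites[0].interval.start, sites[0].interval.end) == (550, 600)

    @pytest.mark.parametrize("seed", range(10))
    def test_site_count_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(900 + seed)
        smarcc1 = [
            _peak(*t, summit=(t[2] - t[1]) // 2) for t in random_intervals(rng, 60)
        ]
        dpf2 = [_peak(*t) for t in random_intervals(rng, 40)]
        arid2 = [_peak(*t) for t in random_intervals(rng, 40)]
        sites = define_sites(
            {"control": {"SMARCC1": smarcc1, "DPF2": dpf2, "ARID2": arid2}}
        )
        contributing = [
            (p.interval.chrom, p.interval.start, p.interval.end)
            for p in smarcc1
            if any(
                overlap_bruteforce(
                    (p.interval.chrom, p.interval.start, p.interval.end),
                    (o.interval.chrom, o.interval.start, o.interval.end),
                )
                > 0
                for o in dpf2 + arid2
            )
        ]
        from conftest import merge_bruteforce

        assert sorted(
            (s.interval.chrom, s.interval.start, s.interval.end) for s in sites
        ) == merge_bruteforce(contributing, 0)


class TestNormalizedEnrichment:
    def _track(self, reads, m, length=1000, bins=10):
        return SignalTrack({"chr1": np.full(bins, reads / bins)}, length // bins, m)

    def test_all_zero_data_gives_one(self):
        region = GenomicInterval("chr1", 0, 1000)
        zero = self._track(0, 1e6)
        assert normalized_enrichment(region, zero, zero) == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        region = GenomicInterval("chr1", 0, 1000)
        ip = self._track(200, 2e6)
        inp = self._track(50, 1e6)
        # (100 + 0.1) / (50 + 0.1)
        assert normalized_enrichment(region, ip, inp) == pytest.approx(100.1 / 50.1)

    def test_missing_input_returns_per_million_plus_pseudocount(self):
        region = GenomicInterval("chr1", 0, 1000)
        assert normalized_enrichment(region, self._track(200, 2e6)) == pytest.approx(
            100.1
        )

    def test_joint_rescaling_invariance_many_cases(self):
        """Strict positivity and per-million invariance over 1000 random
        read/library configurations."""
        rng = np.random.default_rng(12345)
        region = GenomicInterval("chr1", 0, 1000)
        for _ in range(1000):
            reads_ip = float(rng.uniform(0, 500))
            reads_in = float(rng.uniform(0, 500))
            m_ip = float(rng.uniform(1e5, 5e7))
            m_in = float(rng.uniform(1e5, 5e7))
            c = float(rng.uniform(0.1, 100))
            e1 = normalized_enrichment(
                region, self._track(reads_ip, m_ip), self._track(reads_in, m_in)
            )
            e2 = normalized_enrichment(
                region,
                self._track(reads_ip * c, m_ip * c),
                self._track(reads_in * c, m_in * c),
            )
            assert e1 > 0
            assert e2 == pytest.approx(e1, rel=1e-9)


class TestPartitionSites:
    def _site(self, start, end):
        return OccupancySite(
            GenomicInterval("chr1", start, end), (start + end) // 2, "BAF", "control"
        )

    def test_tss_inside_is_proximal(self):
        sites = partition_sites(
            [self._site(100, 600)], {"chr1": np.array([300])}, []
        )
        assert sites[0].partition == "proximal"

    def test_distance_boundary_2000(self):
        # nearest TSS at 2601: distance from last covered base 599 is 2001 bp
        distal = partition_sites(
            [self._site(100, 600)], {"chr1": np.array([2601])}, []
        )
        assert distal[0].partition == "distal_out_SE"
        near = partition_sites(
            [self._site(100, 600)], {"chr1": np.array([2600])}, []
        )
        assert near[0].partition == "unclassified"

    def test_one_bp_se_overlap_is_in_se(self):
        se = [GenomicInterval("chr1", 599, 5000)]
        sites = partition_sites(
            [self._site(100, 600)], {"chr1": np.array([100_000])}, se
        )
        assert sites[0].partition == "distal_in_SE"

    def test_empty_tss_list_is_error(self):
        with pytest.raises(ValueError):
            partition_sites([self._site(0, 100)], {}, [])

    def test_classes_exhaustive_and_exclusive(self, demo_occupancy):
        parts = [s.partition for s in demo_occupancy["sites"]]
        assert set(parts) <= {
            "proximal", "distal_in_SE", "distal_out_SE", "unclassified"
        }
        assert all(p is not None for p in parts)


class TestFoldChangesAndQuadrants:
    def test_log2fc_worked_values(self):
        site = OccupancySite(
            GenomicInterval("chr1", 0, 100), 50, "BAF", "control",
            enrichment={
                ("SMARCC1", "control"): 1.0,
                ("SMARCC1", "reexpression"): 4.0,
                ("H3K27ac", "control"): 2.0,
                ("H3K27ac", "reexpression"): 2.0,
            },
        )
        log2_fold_changes([site])
        assert site.log2fc["SMARCC1"] == pytest.approx(2.0)
        assert site.log2fc["H3K27ac"] == pytest.approx(0.0)

    def test_quadrant_worked_example(self):
        # 4 both-down, 2 both-up, 1 discordant, 3 at the origin
        x = [-1] * 4 + [1] * 2 + [-1] + [0] * 3
        y = [-1] * 4 + [1] * 2 + [+1] + [0] * 3
        fr = quadrant_fractions(x, y)
        assert fr["both_down"] == pytest.approx(0.4)
        assert fr["both_up"] == pytest.approx(0.2)
        assert fr["discordant"] == pytest.approx(0.1)
        assert fr["inside_gray"] == pytest.approx(0.3)

    def test_threshold_is_inclusive_at_log2_1_5(self):
        t = math.log2(1.5)
        fr = quadrant_fractions([-t], [-t])
        assert fr["both_down"] == 1.0
        fr = quadrant_fractions([-t * 0.999], [-t])
        assert fr["both_down"] == 0.0

    def test_all_origin_is_all_gray(self):
        fr = quadrant_fractions([0] * 7, [0] * 7)
        assert fr["inside_gray"] == 1.0

    def test_fractions_sum_to_one(self, demo_occupancy):
        for q in quadrant_summary(demo_occupancy["sites"]).values():
            assert q.both_down + q.both_up + q.discordant + q.inside_gray == (
                pytest.approx(1.0)
            )

    def test_site_order_invariance(self, demo_occupancy):
        sites = list(demo_occupancy["sites"])
        rng = np.random.default_rng(0)
        shuffled = [sites[i] for i in rng.permutation(len(sites))]
        q1 = quadrant_summary(sites)
        q2 = quadrant_summary(shuffled)
        for g in q1:
            assert q1[g].both_down == q2[g].both_down
            assert q1[g].n_sites == q2[g].n_sites

    def test_empty_group_flagged(self):
        q = quadrant_summary([], groups=("proximal",))
        assert q["proximal"].degenerate and q["proximal"].n_sites == 0


class TestStrongDecreaseRatio:
    def _sites(self, partition, fcs):
        return [
            OccupancySite(
                GenomicInterval("chr1", 100 * i + 1, 100 * i + 50), 100 * i + 10,
                "BAF", "control", partition=partition,
                log2fc={"H3K27ac": fc, "SMARCC1": 0.0},
            )
            for i, fc in enumerate(fcs)
        ]

    def test_worked_ratio_three(self):
        sites = (
            self._sites("distal_in_SE", [-1.5] * 30 + [0.0] * 70)
            + self._sites("distal_out_SE", [-1.5] * 10 + [0.0] * 90)
            + self._sites("proximal", [-1.5] * 10 + [0.0] * 90)
        )
        res = strong_decrease_ratio(sites)
        assert res["ratio_in_se_over"]["distal_out_SE"] == pytest.approx(3.0)
        assert not res["degenerate"]

    def test_threshold_is_two_fold(self):
        sites = self._sites("distal_in_SE", [-1.0, -0.99])
        res = strong_decrease_ratio(sites)
        assert res["counts"]["distal_in_SE"] == 1

    def test_zero_denominator_flagged_infinite(self):
        sites = self._sites("distal_in_SE", [-2.0] * 5) + self._sites(
            "distal_out_SE", [0.0] * 5
        ) + self._sites("proximal", [0.0] * 5)
        res = strong_decrease_ratio(sites)
        assert math.isinf(res["ratio_in_se_over"]["distal_out_SE"])
        assert res["degenerate"]


class TestWeightedHistogram:
    def test_single_bin_group_has_height_one(self):
        df = weighted_histogram({"g": [0.1, 0.2, 0.15, 0.12]}, [0, 0.25, 0.5])
        assert df["g"].iloc[0] == pytest.approx(1.0)
        assert df["g"].sum() == pytest.approx(1.0)

    def test_groups_of_different_size_same_shape_match(self):
        small = [0.1] * 3 + [0.6] * 1
        large = [0.1] * 30 + [0.6] * 10
        df = weighted_histogram({"small": small, "large": large}, [0, 0.5, 1.0])
        np.testing.assert_allclose(df["small"], df["large"])

    def test_heights_equal_count_over_group_size(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, 500)
        edges = np.linspace(-4, 4, 17)
        df = weighted_histogram({"g": values}, edges)
        counts, _ = np.histogram(values, bins=edges)
        np.testing.assert_allclose(df["g"], counts / 500)

    def test_empty_group_omitted(self):
        df = weighted_histogram({"a": [0.1], "b": []}, [0, 1])
        assert list(df.columns) == ["a"]
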