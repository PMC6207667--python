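"""Peak-to-gene assignment rules and auxin-induction enrichment."""

import math

import numpy as np
import pytest

from arfcaliper import targets
from arfcaliper.core import GeneModel, GenomicInterval, Peak, PeakSet
from arfcaliper.overlap import classify_regions
from tests.conftest import make_peakset


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


class TestProximalAssignment:
    def setup_method(self):
        # + gene with TSS 5000 and TTS 8000
        self.g = gene("g1", 5000, 8001)

    def test_upstream_peak_within_window(self):
        ps = make_peakset("A", [(4000, 4100)], clade="A")
        ta = targets.assign_proximal_targets([ps], [self.g])
        assert ta.links["gene_id"].tolist() == ["g1"]

    def test_peak_outside_window(self):
        # proximal window starts at TSS - 1100 = 3900
        ps = make_peakset("A", [(2500, 2600)], clade="A")
        ta = targets.assign_proximal_targets([ps], [self.g])
        assert ta.links.empty

    def test_minus_strand_mirrors_window(self):
        gm = gene("gm", 5000, 8001, strand="-")  # TSS at 8000
        # 1000 bp 3' of the TSS coordinate = upstream of the - gene
        ps = make_peakset("A", [(9000, 9100)], clade="A")
        ta = targets.assign_proximal_targets([ps], [gm])
        assert ta.links["gene_id"].tolist() == ["gm"]
        # the mirrored downstream boundary: TTS - 900 = 4100
        ps2 = make_peakset("A", [(3000, 3100)], clade="A")
        assert targets.assign_proximal_targets([ps2], [gm]).links.empty

    def test_closest_gene_wins_with_id_tiebreak(self):
        g2 = gene("g0", 5400, 8401)  # overlapping competitor
        ps = make_peakset("A", [(5150, 5250)], clade="A")  # summit 5200
        ta = targets.assign_proximal_targets([ps], [self.g, g2])
        # |5200-5000| = 200 beats |5200-5400| = 200 -> tie -> smaller id
        assert ta.links["gene_id"].tolist() == ["g0"]


class TestDistalAssignment:
    def setup_method(self):
        self.g = gene("g1", 50_000, 53_001)

    def test_9kb_upstream_assigned(self):
        ps = make_peakset("A", [(41_000, 41_100)], clade="A")
        assert not targets.assign_distal_targets([ps], [self.g]).links.empty

    def test_11kb_upstream_unassigned(self):
        ps = make_peakset("A", [(38_900, 39_000)], clade="A")
        assert targets.assign_distal_targets([ps], [self.g]).links.empty

    def test_gene_body_peak_assigned(self):
        ps = make_peakset("A", [(51_000, 51_100)], clade="A")
        assert not targets.assign_distal_targets([ps], [self.g]).links.empty

    def test_proximal_subset_of_distal(self, rng):
        genes = [gene(f"g{i}", int(s), int(s) + 2000)
                 for i, s in enumerate(np.arange(20) * 30_000 + 5_000)]
        starts = rng.integers(0, 650_000, size=60)
        ps = make_peakset("A", sorted({(int(s), int(s) + 150) for s in starts}),
                          clade="A")
        prox = targets.assign_proximal_targets([ps], genes)
        dist = targets.assign_distal_targets([ps], genes)
        prox_pairs = set(map(tuple, prox.links[["peak_name", "gene_id"]].values))
        dist_peaks = set(dist.links["peak_name"])
        # every proximally assigned peak is also distally assigned
        assert {p for p, _ in prox_pairs} <= dist_peaks


class TestCoOccupancy:
    def _assignment(self, peaksets, genes):
        return targets.assign_proximal_targets(peaksets, genes)

    def test_independent_peaks_label(self):
        g = gene("g1", 5000, 8001)
        a = make_peakset("A1", [(4500, 4600)], clade="A")
        b = make_peakset("B1", [(8200, 8300)], clade="B")
        rc = classify_regions([GenomicInterval("chr1", 4500, 4600)],
                              [GenomicInterval("chr1", 8200, 8300)])
        summary = targets.co_occupancy_summary(self._assignment([a, b], [g]), rc)
        assert summary.loc["both", "fraction"] == 1.0
        assert summary.loc["both_via_independent_peaks", "fraction"] == 1.0

    def test_shared_region_label(self):
        g = gene("g1", 5000, 8001)
        a = make_peakset("A1", [(4500, 4600)], clade="A")
        b = make_peakset("B1", [(4520, 4620)], clade="B")
        rc = classify_regions([GenomicInterval("chr1", 4500, 4600)],
                              [GenomicInterval("chr1", 4520, 4620)])
        summary = targets.co_occupancy_summary(self._assignment([a, b], [g]), rc)
        assert summary.loc["both_via_shared_peak", "fraction"] == 1.0

    def test_a_only(self):
        g = gene("g1", 5000, 8001)
        a = make_peakset("A1", [(4500, 4600)], clade="A")
        summary = targets.co_occupancy_summary(self._assignment([a], [g]))
        assert summary.loc["A_only", "fraction"] == 1.0

    def test_fractions_partition(self, rng):
        genes = [gene(f"g{i}", int(s), int(s) + 2000)
                 for i, s in enumerate(np.arange(30) * 20_000 + 5_000)]
        a = make_peakset("A1", sorted({(int(s), int(s) + 150)
                                       for s in rng.integers(0, 600_000, 50)}),
                         clade="A")
        b = make_peakset("B1", sorted({(int(s), int(s) + 150)
                                       for s in rng.integers(0, 600_000, 50)}),
                         clade="B")
        summary = targets.co_occupancy_summary(self._assignment([a, b], genes))
        total = summary.loc[["A_only", "B_only", "both"], "fraction"].sum()
        assert total == pytest.approx(1.0)

    def test_empty_assignment_errors(self):
        g = gene("g1", 5000, 8001)
        ps = make_peakset("A", [(100_000, 100_100)], clade="A")
        with pytest.raises(ValueError):
            targets.co_occupancy_summary(self._assignment([ps], [g]))


class TestPeaksWithinDistance:
    def test_distance_arithmetic(self):
        g = gene("g1", 10_000, 12_000)
        other = gene("g2", 500_000, 502_000)
        # summits at 5050 (5 kb away) and 25050 (13 kb away), d = 10 kb:
        # brute-force distance check counts only the first
        ps = make_peakset("A", [(5000, 5100), (25_000, 25_100)])
        counts, _ = targets.peaks_within_distance(
            {"focus": [g, g], "other": [other, other]}, [ps], d=10_000)
        assert counts.loc[counts["group"] == "focus", "n_peaks"].tolist() == [1, 1]
        # a peak genuinely within d on the 3' side is counted too
        ps2 = make_peakset("A", [(5000, 5100), (21_000, 21_100)])
        counts2, _ = targets.peaks_within_distance(
            {"focus": [g, g], "other": [other, other]}, [ps2], d=10_000)
        assert counts2.loc[counts2["group"] == "focus", "n_peaks"].tolist() == [2, 2]

    def test_identical_groups_p_one(self):
        gs = [gene("g1", 10_000, 12_000), gene("g2", 40_000, 42_000)]
        # g1 gets two nearby peaks, g2 one, so within-group variance is real
        ps = make_peakset("A", [(11_000, 11_100), (11_500, 11_600),
                                (41_000, 41_100)])
        _, tests_df = targets.peaks_within_distance(
            {"x": gs, "y": list(gs)}, [ps], d=10_000)
        assert tests_df["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_t_matches_closed_form(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        y = np.array([9.0, 2.0, 6.0, 5.0, 3.0])
        genes_x = [gene(f"x{i}", 1_000_000 * (i + 1), 1_000_000 * (i + 1) + 1000)
                   for i in range(5)]
        genes_y = [gene(f"y{i}", 1_000_000 * (i + 10), 1_000_000 * (i + 10) + 1000)
                   for i in range(5)]
        coords = []
        for g_, k in zip(genes_x + genes_y, np.concatenate([x, y]).astype(int)):
            coords += [(g_.interval.start + 10 * j, g_.interval.start + 10 * j + 5)
                       for j in range(k)]
        ps = make_peakset("A", coords)
        _, tests_df = targets.peaks_within_distance(
            {"x": genes_x, "y": genes_y}, [ps], d=10_000)
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(ddof=1) / 5, y.var(ddof=1) / 5
        t_expected = (mx - my) / math.sqrt(vx + vy)
        assert tests_df["t"].iloc[0] == pytest.approx(t_expected)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            targets.peaks_within_distance(
                {"x": [gene("g", 0, 1000)], "y": [gene("h", 0, 1000)] * 2},
                [make_peakset("A", [(0, 50)])])


class TestTssProximalEnrichment:
    def _universe(self, n, with_peak_ids, peak_offset=0):
        genes_, coords = [], []
        for i in range(n):
            g_ = gene(f"g{i:03d}", 10_000 * i + 5_000, 10_000 * i + 7_000)
            genes_.append(g_)
            if i in with_peak_ids:
                coords.append((g_.tss - 100, g_.tss + 100))
        return genes_, make_peakset("A", coords, clade="A")

    def test_odds_ratio_matches_hand_computation(self):
        # 10 focus genes (6 with a TSS peak), 90 others (9 with)
        withs = set(range(6)) | set(range(10, 19))
        genes_, ps = self._universe(100, withs)
        focus = genes_[:10]
        odds, p, table = targets.tss_proximal_enrichment(focus, genes_, [ps])
        assert odds == pytest.approx((6 * 81) / (4 * 9))  # = 13.5
        assert table.tolist() == [[6, 4], [9, 81]]
        # oracle: brute-force hypergeometric enumeration
        from tests.test_motifs import _hypergeom_two_sided
        assert p == pytest.approx(_hypergeom_two_sided(6, 4, 9, 81), rel=1e-9)

    def test_equal_rates_or_near_one(self):
        withs = set(range(0, 100, 2))  # every other gene, focus and rest alike
        genes_, ps = self._universe(100, withs)
        odds, p, _ = targets.tss_proximal_enrichment(genes_[:20], genes_, [ps])
        assert odds == pytest.approx(1.0)

    def test_empty_focus_errors(self):
        genes_, ps = self._universe(10, {0})
        with pytest.raises(ValueError):
            targets.tss_proximal_enrichment([], genes_, [ps])
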