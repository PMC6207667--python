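"""Core-motif scanning, orientation/spacer classification, baselines,
phasing and signal-versus-count statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arfcaliper import motifs
from arfcaliper.core import GenomicInterval, Peak, PeakSet
from arfcaliper import simulate


def _window_peakset(windows, width):
    """One peak per planted window, summit at its centre on a synthetic
    chromosome where windows are laid out end to end."""
    peaks = []
    for i, w in enumerate(windows):
        start = i * width
        peaks.append(Peak(GenomicInterval("chrW", start, start + width),
                          summit_offset=width // 2, name=f"w{i}", signal=1.0))
    return PeakSet("win", peaks=peaks), {"chrW": "".join(windows)}


class TestScan:
    def test_both_strand_hits(self):
        hits = motifs.scan_core_motif("TGTCAAAGACA")
        assert [(h.position, h.orient) for h in hits] == [(0, "F"), (7, "R")]

    def test_no_hits(self):
        assert motifs.scan_core_motif("AAAAAAA") == []

    def test_n_never_matches(self):
        assert motifs.scan_core_motif("TGNC" * 5) == []

    def test_overlapping_occurrences_reported(self):
        # TGTC at 0 and 4 plus GACA revcomp hits are all kept
        assert len(motifs.scan_core_motif("TGTCTGTC")) == 2

    @given(st.text(alphabet="ACGT", min_size=4, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_revcomp_same_count(self, seq):
        assert len(motifs.scan_core_motif(seq)) == len(
            motifs.scan_core_motif(motifs.revcomp(seq)))


class TestSummitWindowCounts:
    def test_manual_window(self):
        win = "A" * 40 + "TGTCTGTC" + "A" * 53  # 101 bp
        ps, genome = _window_peakset([win], 101)
        assert motifs.summit_window_counts(ps, genome, 101).tolist() == [2]

    def test_all_a_window(self):
        ps, genome = _window_peakset(["A" * 101], 101)
        assert motifs.summit_window_counts(ps, genome, 101).tolist() == [0]

    def test_clipped_at_chromosome_start(self):
        genome = {"chr1": "TGTC" + "A" * 200}
        ps = PeakSet("t", peaks=[Peak(GenomicInterval("chr1", 0, 40),
                                      summit_offset=10, name="p")])
        counts = motifs.summit_window_counts(ps, genome, 101)
        assert counts.tolist() == [1]

    def test_missing_chrom_names_peak(self):
        ps = PeakSet("t", peaks=[Peak(GenomicInterval("chrZ", 0, 40),
                                      summit_offset=10, name="lost")])
        with pytest.raises(KeyError, match="lost"):
            motifs.summit_window_counts(ps, {"chr1": "A" * 100}, 101)


class TestCountDistribution:
    def test_binning(self):
        d = motifs.count_distribution([0, 1, 1, 2, 7])
        assert d.fractions.tolist() == [0.2, 0.4, 0.2, 0.0, 0.0, 0.2]

    def test_all_zero(self):
        d = motifs.count_distribution([0, 0, 0])
        assert d.fractions["0"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        d = motifs.count_distribution(rng.integers(0, 10, size=500))
        assert d.fractions.sum() == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            motifs.count_distribution([])


class TestRandomWindowBaseline:
    def test_poisson_closed_form_uniform_composition(self):
        genome = {"chr1": "ACGT" * 25_000}  # exactly uniform composition
        ref = motifs.poisson_reference(genome, window_bp=100)
        assert ref["0"] == pytest.approx(math.exp(-2 * 97 / 256), rel=1e-6)

    def test_empirical_matches_poisson_within_error(self):
        # the genome must be large relative to the windows, otherwise the
        # windows are correlated through the genome's own motif-count
        # fluctuation and the error is no longer window-limited
        genome = simulate.simulate_genome(1_000_000, 0.47, seed=71)
        dist, ref = motifs.random_window_baseline(genome, 20_000, 100, seed=3)
        assert abs(dist.fractions["0"] - ref["0"]) < 0.02
        tv = 0.5 * float((dist.fractions - ref).abs().sum())
        assert tv < 0.02

    def test_seed_determinism(self, small_genome):
        d1, _ = motifs.random_window_baseline(small_genome, 500, 100, seed=9)
        d2, _ = motifs.random_window_baseline(small_genome, 500, 100, seed=9)
        assert (d1.fractions == d2.fractions).all()


def _hypergeom_two_sided(a, b, c, d):
    """Brute-force two-sided Fisher p: sum of all equally-or-less-likely
    tables with the same margins."""
    n1, n2, k = a + b, c + d, a + c
    N = n1 + n2

    def prob(x):
        return (math.comb(n1, x) * math.comb(n2, k - x)) / math.comb(N, k)

    p_obs = prob(a)
    lo, hi = max(0, k - n2), min(k, n1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestEnrichmentTest:
    def test_matches_hypergeometric_oracle(self):
        peak_counts = [2] * 8 + [0] * 2
        random_counts = [2] * 2 + [0] * 8
        odds, p = motifs.multi_motif_enrichment_test(peak_counts, random_counts)
        assert odds == pytest.approx(16.0)
        assert p == pytest.approx(_hypergeom_two_sided(8, 2, 2, 8), rel=1e-9)

    def test_identical_distributions(self):
        counts = [0, 1, 2, 3] * 10
        odds, p = motifs.multi_motif_enrichment_test(counts, counts)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_infinite_odds(self):
        odds, p = motifs.multi_motif_enrichment_test([2] * 5, [0] * 5)
        assert math.isinf(odds)
        assert p == pytest.approx(_hypergeom_two_sided(5, 0, 0, 5), rel=1e-9)


class TestPairClassification:
    def test_er_window(self):
        win = "A" * 45 + "TGTCAAAGACA" + "A" * 45
        ps, genome = _window_peakset([win], 101)
        spec = motifs.pair_spacing_spectrum(ps, genome, 101)
        assert spec.argmax_cell() == ("ER", 3)

    def test_ir_window(self):
        win = "A" * 45 + "GACAAATGTC" + "A" * 46
        ps, genome = _window_peakset([win], 101)
        spec = motifs.pair_spacing_spectrum(ps, genome, 101)
        assert spec.argmax_cell() == ("IR", 2)

    def test_rr_pair_canonicalized_to_dr(self):
        win = "A" * 45 + "GACAAAAGACA" + "A" * 45
        ps, genome = _window_peakset([win], 101)
        spec = motifs.pair_spacing_spectrum(ps, genome, 101)
        assert spec.argmax_cell() == ("DR", 3)

    def test_spectrum_sums_to_100(self, planted):
        genome, truth = planted
        els = truth.elements
        peaks = []
        for _, r in els.iterrows():
            c = (r.start + r.end) // 2
            if c < 50 or c + 51 > len(genome[r.chrom]):
                continue
            peaks.append(Peak(GenomicInterval(r.chrom, c - 50, c + 51),
                              summit_offset=50, name=r.element_id))
        ps = PeakSet("planted", peaks=peaks)
        spec = motifs.pair_spacing_spectrum(ps, genome, 101)
        assert spec.percent.to_numpy().sum() == pytest.approx(100.0)

    def test_zero_qualifying_peaks_errors(self):
        ps, genome = _window_peakset(["A" * 101], 101)
        with pytest.raises(ValueError):
            motifs.pair_spacing_spectrum(ps, genome, 101)

    @given(
        orient=st.sampled_from(["DR", "ER", "IR"]),
        spacer=st.integers(0, 30),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_strand_invariance(self, orient, spacer, data):
        """Orientation class and spacer survive reverse complement."""
        cores = {"DR": ("TGTC", "TGTC"), "ER": ("TGTC", "GACA"),
                 "IR": ("GACA", "TGTC")}
        up, down = cores[orient]
        gap = data.draw(st.text(alphabet="AC", min_size=spacer, max_size=spacer))
        left = data.draw(st.text(alphabet="AC", min_size=0, max_size=20))
        right = data.draw(st.text(alphabet="AC", min_size=0, max_size=20))
        win = left + up + gap + down + right
        inst = motifs.scan_core_motif(win)
        if len(inst) != 2:
            return  # flanks accidentally created extra cores
        cls1 = motifs.classify_pair(inst[0], inst[1])
        inst_rc = motifs.scan_core_motif(motifs.revcomp(win))
        cls2 = motifs.classify_pair(inst_rc[0], inst_rc[1])
        assert cls1 == cls2 == (orient, spacer)


class TestPhasing:
    def test_phased_spikes_score_one(self):
        row = np.zeros(51)
        row[[7, 17, 27, 37, 47]] = 10.0
        assert motifs.phasing_periodogram(row) == pytest.approx(1.0)

    def test_uniform_row_near_zero(self):
        assert motifs.phasing_periodogram(np.ones(51)) < 0.01

    def test_single_spike_closed_form(self):
        # a delta is a pure tone: |x * e^{-2 pi i s/P}|^2 / x^2 = 1
        row = np.zeros(51)
        row[13] = 42.0
        assert motifs.phasing_periodogram(row) == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            motifs.phasing_periodogram(np.zeros(51))


class TestSignalByCount:
    def test_constant_signal(self):
        peaks = [Peak(GenomicInterval("chr1", i * 100, i * 100 + 50),
                      summit_offset=25, signal=5.0, name=f"p{i}")
                 for i in range(8)]
        ps = PeakSet("t", peaks=peaks)
        df = motifs.signal_by_count(ps, [0, 0, 1, 1, 2, 2, 3, 3])
        meds = df["median"].dropna()
        assert (meds == 5.0).all()
        ps_ = df["p_vs_prev"].dropna()
        assert ((ps_ == 1.0) | ps_.isna()).all()

    def test_medians_increase_with_count(self):
        counts = [0, 0, 1, 1, 2, 2, 3, 3, 5, 5]
        peaks = [Peak(GenomicInterval("chr1", i * 100, i * 100 + 50),
                      summit_offset=25, signal=1.0 + c, name=f"p{i}")
                 for i, c in enumerate(counts)]
        ps = PeakSet("t", peaks=peaks)
        df = motifs.signal_by_count(ps, counts)
        meds = df["median"].dropna().to_numpy()
        assert (np.diff(meds) > 0).all()

    def test_welch_t_close_to_permutation_oracle(self, rng):
        x = np.array([4.1, 5.2, 6.3, 5.8, 4.9, 5.5, 6.1, 4.4])
        y = np.array([6.0, 7.1, 6.6, 7.8, 6.9, 7.3, 5.9, 7.0])
        from scipy import stats
        t_obs = abs(stats.ttest_ind(x, y, equal_var=False).statistic)
        pooled = np.concatenate([x, y])
        n_perm, hits = 20_000, 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t = abs(stats.ttest_ind(perm[:8], perm[8:], equal_var=False).statistic)
            if t >= t_obs:
                hits += 1
        p_perm = hits / n_perm
        p_welch = stats.ttest_ind(x, y, equal_var=False).pvalue
        assert abs(p_welch - p_perm) < 0.01

    def test_small_bin_reported_missing(self):
        peaks = [Peak(GenomicInterval("chr1", i * 100, i * 100 + 50),
                      summit_offset=25, signal=float(i), name=f"p{i}")
                 for i in range(3)]
        ps = PeakSet("t", peaks=peaks)
        df = motifs.signal_by_count(ps, [0, 0, 1])  # bin "1" has a single peak
        assert np.isnan(df.loc["1", "p_vs_prev"])
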