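import math

import numpy as np
import pytest

from tadlink.accessibility import (
    AnnotationParams, CoverageTrack, DARSet, Peak, PeakCallParams,
    adjust_reads, annotate_location, call_dars, call_peaks, poisson_tail,
    promoter_direction_table, promoter_window, replicate_correlation,
)
from tadlink.core import Gene, GenomicInterval
from tadlink.stats import fisher_exact_test


def make_peak(chrom, start, end, condition=""):
    mid = (start + end) // 2
    s0 = min(max(start, mid - 75), end - 150) if end - start >= 150 else start
    summit = GenomicInterval(chrom, s0, s0 + min(150, end - start))
    return Peak(GenomicInterval(chrom, start, end), summit, 1, 1e-5, condition)


class TestAdjustReads:
    def test_zero_offsets_are_identity(self):
        reads = [GenomicInterval("chr1", 100, 150, "+"), GenomicInterval("chr1", 30, 80, "-")]
        track = adjust_reads(reads, plus_offset=0, minus_offset=0)
        assert list(track.positions["chr1"]) == [30 + 50 - 1, 100]

    def test_tn5_offsets(self):
        plus = adjust_reads([GenomicInterval("chr1", 100, 151, "+")])
        minus = adjust_reads([GenomicInterval("chr1", 100, 151, "-")])
        assert list(plus.positions["chr1"]) == [104]
        assert list(minus.positions["chr1"]) == [150 - 5]

    def test_negative_positions_clamped(self):
        track = adjust_reads([GenomicInterval("chr1", 0, 3, "-")])
        assert list(track.positions["chr1"]) == [0]

    def test_output_sorted_matches_resort_oracle(self, rng):
        reads = []
        for _ in range(10_000):
            start = int(rng.integers(0, 1_000_000))
            reads.append(
                GenomicInterval(
                    f"chr{rng.integers(1, 3)}", start, start + 51,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        track = adjust_reads(reads)
        for chrom, pos in track.positions.items():
            assert list(pos) == sorted(pos)
        assert track.total == len(reads)


class TestPoissonTail:
    def test_k_zero_is_certain(self):
        assert poisson_tail(0, 0.5) == 1.0
        assert poisson_tail(0, 100.0) == 1.0

    def test_closed_form_k1(self):
        assert poisson_tail(1, 2.0) == pytest.approx(1 - math.exp(-2), rel=1e-12)

    def test_matches_summation_oracle(self):
        # direct upper-tail summation in extended precision
        from decimal import Decimal, getcontext

        getcontext().prec = 60
        for k, lam in [(20, 2.0), (50, 5.0), (200, 20.0), (5, 0.1)]:
            term = Decimal(lam) ** k * Decimal(-lam).exp() / Decimal(math.factorial(k))
            total = Decimal(0)
            t = term
            j = k
            while t > Decimal(1e-50) * max(total, term):
                total += t
                j += 1
                t = t * Decimal(lam) / j
            assert poisson_tail(k, lam) == pytest.approx(float(total), rel=1e-9)

    def test_monotone_in_k_and_lam(self):
        ks = np.arange(0, 50)
        p = poisson_tail(ks, np.full_like(ks, 5.0, dtype=float))
        assert np.all(np.diff(p) <= 1e-15)
        lams = np.linspace(0.5, 20, 40)
        p2 = poisson_tail(np.full(40, 10), lams)
        assert np.all(np.diff(p2) >= -1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_tail(1, 0.0)
        with pytest.raises(ValueError):
            poisson_tail(-1, 1.0)


def planted_track(rng, chrom_len=1_000_000, rate=0.02, region=(500_000, 502_000), fold=8.0):
    return multi_region_track(rng, chrom_len, rate, [region], fold)


def multi_region_track(rng, chrom_len, rate, regions, fold=8.0):
    n_bg = rng.poisson(rate * chrom_len)
    parts = [rng.integers(0, chrom_len, size=n_bg)]
    for start, end in regions:
        n_extra = rng.poisson((fold - 1) * rate * (end - start))
        parts.append(rng.integers(start, end, size=n_extra))
    return CoverageTrack({"chr1": np.concatenate(parts)})


class TestCallPeaks:
    def test_empty_track_gives_no_peaks(self):
        track = CoverageTrack({})
        assert call_peaks(track, {"chr1": 100_000}) == []

    def test_planted_region_yields_one_overlapping_peak(self, rng):
        track = planted_track(rng)
        peaks = call_peaks(track, {"chr1": 1_000_000})
        region = GenomicInterval("chr1", 500_000, 502_000)
        hits = [p for p in peaks if p.interval.overlap_bp(region) >= 1]
        assert len(hits) == 1
        assert len(peaks) <= 2  # at most stray noise besides the planted site

    def test_summits_equal_exhaustive_argmax(self, rng):
        track = planted_track(rng)
        peaks = call_peaks(track, {"chr1": 1_000_000})
        pos = track.positions["chr1"]
        for peak in peaks:
            s, e = peak.interval.start, peak.interval.end
            best, best_count = None, -1
            for off in range(s, e - 150 + 1):
                c = int(np.searchsorted(pos, off + 150) - np.searchsorted(pos, off))
                if c > best_count:
                    best, best_count = off, c
            if e - s <= 150:
                best = s
            assert peak.summit.start == best

    def test_translation_equivariance(self, rng):
        track = planted_track(rng, chrom_len=500_000, region=(200_000, 202_000))
        shift = 150  # a multiple of the window step
        shifted = CoverageTrack({"chr1": track.positions["chr1"] + shift})
        p1 = call_peaks(track, {"chr1": 500_000})
        p2 = call_peaks(shifted, {"chr1": 500_000 + shift})
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            assert b.interval.start - a.interval.start == shift
            assert b.summit.start - a.summit.start == shift


class TestCallDars:
    def test_identical_tracks_give_no_dars(self, rng):
        track = planted_track(rng)
        sizes = {"chr1": 1_000_000}
        peaks = call_peaks(track, sizes)
        dars = call_dars(peaks, peaks, track, track, sizes)
        assert dars.gained == [] and dars.lost == []
        assert len(dars.shared) == len(peaks)

    def test_planted_gain_is_gained_not_lost(self, rng):
        sizes = {"chr1": 1_000_000}
        rate = 0.02
        bg_a = CoverageTrack({"chr1": rng.integers(0, 1_000_000, size=rng.poisson(rate * 1e6))})
        track_b = planted_track(rng, fold=10.0)
        peaks_a = call_peaks(bg_a, sizes)
        peaks_b = call_peaks(track_b, sizes)
        dars = call_dars(peaks_a, peaks_b, bg_a, track_b, sizes)
        region = GenomicInterval("chr1", 500_000, 502_000)
        assert any(p.interval.overlap_bp(region) >= 1 for p in dars.gained)
        assert not any(p.interval.overlap_bp(region) >= 1 for p in dars.lost)

    def test_swapping_conditions_swaps_gained_and_lost(self, rng):
        sizes = {"chr1": 1_000_000}
        track_a = planted_track(rng, region=(100_000, 102_000))
        track_b = planted_track(rng, region=(700_000, 702_000))
        pa, pb = call_peaks(track_a, sizes), call_peaks(track_b, sizes)
        d1 = call_dars(pa, pb, track_a, track_b, sizes)
        d2 = call_dars(pb, pa, track_b, track_a, sizes)
        key = lambda ps: sorted((p.interval.start, p.interval.end) for p in ps)
        assert key(d1.gained) == key(d2.lost)
        assert key(d1.lost) == key(d2.gained)

    def test_dar_classes_disjoint(self, bundle):
        from tadlink.simulate import PARENTAL, TRANSFORMED

        tp, tt = bundle.combined_track(PARENTAL), bundle.combined_track(TRANSFORMED)
        pa = call_peaks(tp, bundle.genome_sizes)
        pb = call_peaks(tt, bundle.genome_sizes)
        dars = call_dars(pa, pb, tp, tt, bundle.genome_sizes)
        key = lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        g, l, s = map(lambda ps: {key(p) for p in ps}, (dars.gained, dars.lost, dars.shared))
        assert not (g & l) and not (g & s) and not (l & s)


class TestAnnotateLocation:
    gene = Gene("g", GenomicInterval("chr1", 50_000, 80_000, "+"))

    def test_promoter_window_definition(self):
        w = promoter_window(self.gene)
        assert (w.start, w.end) == (49_000, 50_500)

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (48_900, 49_100, "promoter"),  # 100 bp into the promoter window
            (120_000, 120_200, "midrange"),  # 70 kb from the TSS
            (400_000, 400_200, "far"),
        ],
    )
    def test_labels(self, start, end, expected):
        peaks = [make_peak("chr1", start, end)]
        labels, props = annotate_location(peaks, [self.gene])
        assert labels[0] == expected
        assert sum(props.values()) == pytest.approx(1.0)

    def test_minus_strand_promoter_mirrored(self):
        gene = Gene("g", GenomicInterval("chr1", 50_000, 80_000, "-"))
        w = promoter_window(gene)
        # TSS at 79_999; 1000 bp upstream lies to the right
        assert (w.start, w.end) == (79_999 - 500 + 1, 79_999 + 1000 + 1)

    def test_unstranded_gene_rejected(self):
        with pytest.raises(ValueError):
            Gene("g", GenomicInterval("chr1", 0, 10, "."))


class TestPromoterDirectionTable:
    def _setup(self):
        up = Gene("up1", GenomicInterval("chr1", 100_000, 120_000, "+"))
        down = Gene("dn1", GenomicInterval("chr1", 500_000, 520_000, "+"))
        de = {"up1": "up", "dn1": "down"}
        return up, down, de

    def test_perfect_association(self):
        up, down, de = self._setup()
        dars = DARSet(
            gained=[make_peak("chr1", 99_500, 100_200)],
            lost=[make_peak("chr1", 499_500, 500_200)],
        )
        res = promoter_direction_table(dars, [up, down], de)
        assert (res.gained_up, res.gained_down) == (1, 0)
        assert (res.lost_up, res.lost_down) == (0, 1)
        assert res.gained_up_fraction == 1.0 and res.lost_up_fraction == 0.0

    def test_identical_placement_gives_p_one(self):
        up, down, de = self._setup()
        peaks_up = [make_peak("chr1", 99_500, 100_200)]
        peaks_dn = [make_peak("chr1", 499_500, 500_200)]
        dars = DARSet(gained=peaks_up + peaks_dn, lost=peaks_up + peaks_dn)
        res = promoter_direction_table(dars, [up, down], de)
        assert res.test.p == 1.0

    def test_empty_class_flagged_without_test(self):
        up, down, de = self._setup()
        dars = DARSet(gained=[make_peak("chr1", 99_500, 100_200)], lost=[])
        res = promoter_direction_table(dars, [up, down], de)
        assert res.flagged and res.test is None

    def test_random_placement_agrees_with_fisher_oracle(self, rng):
        genes = []
        de = {}
        for i in range(40):
            start = 100_000 + i * 50_000
            genes.append(Gene(f"g{i}", GenomicInterval("chr1", start, start + 10_000, "+")))
            de[f"g{i}"] = "up" if i % 2 == 0 else "down"
        gained = [make_peak("chr1", 100_000 + int(i) * 50_000 - 500, 100_000 + int(i) * 50_000 + 200)
                  for i in rng.integers(0, 40, size=15)]
        lost = [make_peak("chr1", 100_000 + int(i) * 50_000 - 500, 100_000 + int(i) * 50_000 + 200)
                for i in rng.integers(0, 40, size=15)]
        res = promoter_direction_table(DARSet(gained=gained, lost=lost), genes, de)
        n_g = res.gained_up + res.gained_down
        n_l = res.lost_up + res.lost_down
        fisher = fisher_exact_test(res.gained_up, n_g, res.lost_up, n_l)
        # both tests must agree on significance at a loose threshold
        assert (res.test.p < 0.01) == (fisher < 0.01) or abs(res.test.p - fisher) < 0.1


REGIONS = [(i * 100_000 + 50_000, i * 100_000 + 52_000) for i in range(9)]


class TestReplicateCorrelation:
    def test_identical_replicates_give_r_one(self, rng):
        track = multi_region_track(rng, 1_000_000, 0.02, REGIONS)
        r = replicate_correlation(track, track, {"chr1": 1_000_000})
        assert r == pytest.approx(1.0)

    def test_fewer_than_two_merged_peaks_flagged(self):
        empty = CoverageTrack({"chr1": np.arange(0, 1_000_000, 50)})
        assert replicate_correlation(empty, empty, {"chr1": 1_000_000}) is None

    def test_subsampling_reduces_totals(self, rng):
        from tadlink.accessibility import subsample_track

        track = planted_track(rng)
        sub = subsample_track(track, 1000, rng)
        assert sub.total == 1000
        assert set(sub.positions["chr1"]) <= set(track.positions["chr1"])

    def test_noisy_replicates_highly_correlated(self, rng):
        sizes = {"chr1": 1_000_000}
        folds = [3 + (i % 7) for i in range(9)]  # varying peak strengths
        def rep():
            parts = [rng.integers(0, 1_000_000, size=rng.poisson(0.01 * 1e6))]
            for (s, e), f in zip(REGIONS, folds):
                parts.append(rng.integers(s, e, size=rng.poisson((f - 1) * 0.01 * (e - s))))
            return CoverageTrack({"chr1": np.concatenate(parts)})

        r = replicate_correlation(rep(), rep(), sizes, seed=3)
        assert r is not None and r > 0.8
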