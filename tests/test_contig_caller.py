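import numpy as np
import pytest

from itss.contig_caller import (
    TES_LIKE,
    TSS_CANDIDATE,
    CandidatePeak,
    ThresholdSet,
    TranscriptContig,
    build_contig,
    classify_tes,
    compute_thresholds,
    filter_candidates,
    find_peaks,
    merge_contigs,
    score_and_rank,
    surviving,
)
from itss.naive import naive_contig, naive_local_maxima, naive_percentile
from itss.shape_signal import ShapeDiffTrack, SmoothedTrack
from itss.tracks_io import Gene, GeneAnnotation, GenomeLayout


def _difftrack(values, window=10, step=5, n=None):
    values = np.asarray(values, dtype=float)
    n = n or (len(values) - 1) * step + window
    layout = GenomeLayout({"c": n})
    return ShapeDiffTrack(
        layout=layout,
        values={"c": values},
        window=window,
        step=step,
        zero_flag={"c": np.zeros(len(values), dtype=bool)},
        mask_flag={"c": np.zeros(len(values), dtype=bool)},
    )


def _smoothed(values):
    arr = np.asarray(values, dtype=float)
    return SmoothedTrack(layout=GenomeLayout({"c": len(arr)}), values={"c": arr})


class TestFindPeaks:
    def test_single_peak(self):
        peaks = find_peaks(_difftrack([0, 1, 3, 1, 0]))
        assert len(peaks) == 1
        assert peaks[0].value == 3
        assert peaks[0].position == 2 * 5 + 10 // 2  # center-anchored

    def test_monotone_series_has_no_peak(self):
        assert find_peaks(_difftrack([0, 1, 2, 3, 4])) == []

    def test_plateau_collapses_to_middle(self):
        peaks = find_peaks(_difftrack([0, 2, 2, 2, 0]))
        assert len(peaks) == 1
        assert peaks[0].position == 2 * 5 + 5

    def test_boundary_windows_never_peak(self):
        # maxima sitting on the series ends carry one-sided evidence only
        assert find_peaks(_difftrack([5, 1, 0, 1, 4])) == []
        assert find_peaks(_difftrack([4, 1, 2])) == []

    def test_masked_windows_excluded(self):
        d = _difftrack([0, 1, 3, 1, 0])
        d.mask_flag["c"][2] = True
        assert find_peaks(d) == []

    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            v = rng.integers(0, 5, int(rng.integers(5, 60))).astype(float)
            d = _difftrack(v)
            got = sorted(p.position for p in find_peaks(d))
            want = sorted(i * 5 + 5 for i in naive_local_maxima(v))
            assert got == want


class TestClassifyTES:
    def _setup(self, left, right, strand="+"):
        v = np.concatenate([np.full(100, float(left)), np.full(101, float(right))])
        sm = _smoothed(v)
        annot = GeneAnnotation([Gene("g", "c", 0, 201, strand)])
        peak = CandidatePeak(seq="c", position=100, value=1.0)
        return classify_tes(peak, sm, annot, flank=100)

    def test_plus_strand_coverage_dropoff_is_tes(self):
        # 5' flank mean 10 vs 3' flank mean 2, transcription left-to-right
        assert self._setup(10, 2, "+").classification == TES_LIKE

    def test_plus_strand_coverage_rise_is_tss(self):
        assert self._setup(2, 10, "+").classification == TSS_CANDIDATE

    def test_minus_strand_flips_orientation(self):
        out = self._setup(10, 2, "-")
        assert out.classification == TSS_CANDIDATE
        assert out.strand == "-"

    def test_unannotated_peak_keeps_viable_orientation(self):
        v = np.concatenate([np.full(100, 2.0), np.full(101, 10.0)])
        peak = CandidatePeak(seq="c", position=100, value=1.0)
        out = classify_tes(peak, _smoothed(v), None, flank=100)
        assert out.classification == TSS_CANDIDATE
        assert out.strand == "+"
        assert "strand-ambiguous" in out.flags

    def test_strand_context_reaches_half_window(self):
        """A gene within half a window of the peak resolves orientation."""
        v = np.concatenate([np.full(100, 10.0), np.full(101, 2.0)])
        annot = GeneAnnotation([Gene("g", "c", 0, 60, "+")])  # ends before peak
        peak = CandidatePeak(seq="c", position=100, value=1.0)
        out = classify_tes(peak, _smoothed(v), annot, flank=100)
        assert out.strand == "+"
        assert out.classification == TES_LIKE


class TestThresholds:
    def test_percentile_definition(self):
        """Linear interpolation between order statistics on pool 1..100."""
        pool = list(range(1, 101))
        assert naive_percentile(pool, 50) == pytest.approx(50.5)
        assert naive_percentile(pool, 95) == pytest.approx(95.05)
        # the optimized path uses the same definition
        assert np.percentile(pool, 50) == pytest.approx(50.5)
        assert np.percentile(pool, 95) == pytest.approx(95.05)

    def test_pools_against_naive(self):
        rng = np.random.default_rng(7)
        a = rng.random(300)
        b = rng.random(300)
        ctrl, test = _smoothed(a), _smoothed(b)
        diff = _difftrack(rng.random(20), window=10, step=5, n=300)
        thr = compute_thresholds(ctrl, test, diff)
        assert thr.rmsd_median == pytest.approx(
            naive_percentile(diff.values["c"], 50), abs=1e-12
        )
        assert thr.sum_median == pytest.approx(naive_percentile(a + b, 50), abs=1e-12)
        assert thr.sum_p95 == pytest.approx(naive_percentile(a + b, 95), abs=1e-12)
        assert thr.diff_p90 == pytest.approx(naive_percentile(b - a, 90), abs=1e-12)

    def test_all_equal_pool(self):
        ctrl, test = _smoothed(np.full(100, 2.0)), _smoothed(np.full(100, 3.0))
        diff = _difftrack(np.full(10, 0.5), window=10, step=5, n=100)
        thr = compute_thresholds(ctrl, test, diff)
        assert thr.rmsd_median == 0.5
        assert thr.sum_median == thr.sum_p95 == 5.0
        assert thr.diff_p90 == 1.0

    def test_translation_equivariance_of_diff_pool(self):
        rng = np.random.default_rng(8)
        a = rng.random(200)
        b = rng.random(200)
        diff = _difftrack(rng.random(10), window=10, step=5, n=200)
        t1 = compute_thresholds(_smoothed(a), _smoothed(b), diff)
        t2 = compute_thresholds(_smoothed(a), _smoothed(b + 0.25), diff)
        assert t2.diff_p90 == pytest.approx(t1.diff_p90 + 0.25, abs=1e-12)

    def test_masked_everything_is_error(self):
        ctrl, test = _smoothed(np.ones(40)), _smoothed(np.ones(40))
        ctrl.mask["c"][:] = True
        test.mask["c"][:] = True
        diff = _difftrack(np.ones(5), window=10, step=5, n=40)
        diff.mask_flag["c"][:] = True
        with pytest.raises(ValueError, match="empty"):
            compute_thresholds(ctrl, test, diff)


class TestFilterCandidates:
    THR = ThresholdSet(rmsd_median=1.0, sum_median=10.0, sum_p95=20.0, diff_p90=3.0)

    def _run(self, rmsd, ctrl_val, test_val):
        ctrl = _smoothed(np.full(10, float(ctrl_val)))
        test = _smoothed(np.full(10, float(test_val)))
        peak = CandidatePeak(seq="c", position=5, value=float(rmsd))
        return filter_candidates([peak], self.THR, ctrl, test)[0]

    def test_rmsd_exactly_at_median_rejected(self):
        assert "rmsd>median" in self._run(1.0, 6.0, 12.0).failed

    def test_sum_at_median_rejected_and_above_p95_rejected(self):
        assert "sum-in-band" in self._run(2.0, 5.0, 5.0).failed  # sum == median
        assert "sum-in-band" in self._run(2.0, 5.0, 16.0).failed  # sum 21 > p95
        assert "sum-in-band" in self._run(2.0, 5.0, 15.0).failed  # sum == p95

    def test_diff_exactly_at_p90_rejected(self):
        assert "diff>p90" in self._run(2.0, 6.0, 9.0).failed  # diff == 3.0

    def test_passing_peak(self):
        out = self._run(2.0, 6.0, 10.0)  # sum 16 in band, diff 4 > 3
        assert out.failed == ()

    def test_tes_never_survives(self):
        ctrl = _smoothed(np.full(10, 6.0))
        test = _smoothed(np.full(10, 10.0))
        peak = CandidatePeak(
            seq="c", position=5, value=2.0, classification=TES_LIKE
        )
        out = filter_candidates([peak], self.THR, ctrl, test)
        assert out[0].failed == ("tes",)
        assert surviving(out) == []


class TestBuildContig:
    def _peak(self, pos):
        return CandidatePeak(seq="c", position=pos, value=9.0)

    def test_exact_boundaries_from_profile(self):
        d = np.array([0, 0, 5, 5, 5, 0, 0], dtype=float)
        ctrl = _smoothed(np.zeros(7))
        test = _smoothed(d)
        thr = ThresholdSet(rmsd_median=0, sum_median=-1, sum_p95=99, diff_p90=1.0)
        c = build_contig(self._peak(3), ctrl, test, thr)
        assert (c.start, c.end, c.size) == (2, 5, 3)
        assert c.avg_diff == pytest.approx(5.0)
        assert c.score == pytest.approx(15.0)
        # independent naive scan oracle
        assert naive_contig(d, 3, 1.0) == (2, 4)

    def test_clamped_at_sequence_start(self):
        test = _smoothed(np.array([5, 5, 5, 0, 0], dtype=float))
        ctrl = _smoothed(np.zeros(5))
        thr = ThresholdSet(rmsd_median=0, sum_median=-1, sum_p95=99, diff_p90=1.0)
        c = build_contig(self._peak(1), ctrl, test, thr)
        assert c.start == 0
        assert "clamped-5p" in c.flags

    def test_constant_profile_average(self):
        test = _smoothed(np.full(9, 4.0))
        ctrl = _smoothed(np.zeros(9))
        thr = ThresholdSet(rmsd_median=0, sum_median=-1, sum_p95=99, diff_p90=2.0)
        c = build_contig(self._peak(4), ctrl, test, thr)
        assert c.avg_diff == pytest.approx(4.0)
        assert {"clamped-5p", "clamped-3p"} <= set(c.flags)

    def test_interior_above_threshold_flanks_below(self):
        rng = np.random.default_rng(9)
        thr_v = 0.6
        thr = ThresholdSet(rmsd_median=0, sum_median=-1, sum_p95=99, diff_p90=thr_v)
        for _ in range(20):
            d = rng.random(80)
            ctrl = _smoothed(np.zeros(80))
            test = _smoothed(d)
            peaks = np.flatnonzero(d >= thr_v)
            if len(peaks) == 0:
                continue
            p = int(peaks[len(peaks) // 2])
            c = build_contig(self._peak(p), ctrl, test, thr)
            assert np.all(d[c.start : c.end] >= thr_v)
            if c.start > 0:
                assert d[c.start - 1] < thr_v
            if c.end < 80:
                assert d[c.end] < thr_v

    def test_raising_threshold_never_lengthens(self):
        rng = np.random.default_rng(10)
        d = rng.random(120)
        ctrl, test = _smoothed(np.zeros(120)), _smoothed(d)
        p = int(np.argmax(d))
        lo = ThresholdSet(rmsd_median=0, sum_median=-1, sum_p95=99, diff_p90=0.2)
        hi = ThresholdSet(rmsd_median=0, sum_median=-1, sum_p95=99, diff_p90=0.5)
        c_lo = build_contig(self._peak(p), ctrl, test, lo)
        c_hi = build_contig(self._peak(p), ctrl, test, hi)
        assert c_hi.size <= c_lo.size
        assert c_lo.start <= c_hi.start <= c_hi.end <= c_lo.end


def _contig(start, end, avg, strand="+", sample="s1", seq="c"):
    return TranscriptContig(
        seq=seq, start=start, end=end, strand=strand, avg_diff=avg, sample=sample
    )


class TestMerge:
    def _tracks(self, n=3000, diff_value=2.0):
        test = _smoothed(np.full(n, diff_value))
        ctrl = _smoothed(np.zeros(n))
        return ctrl, test

    def test_close_and_similar_merge(self):
        ctrl, test = self._tracks()
        out = merge_contigs(
            [_contig(100, 300, 2.0), _contig(900, 1200, 5.0)], ctrl, test
        )
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 1200)
        # averaged difference recomputed over the union span
        assert out[0].avg_diff == pytest.approx(2.0)

    def test_dissimilar_expression_blocks_merge(self):
        ctrl, test = self._tracks()
        out = merge_contigs(
            [_contig(100, 300, 2.0), _contig(900, 1200, 7.0)], ctrl, test
        )
        assert len(out) == 2

    def test_exactly_1kb_apart_blocks_merge(self):
        ctrl, test = self._tracks()
        out = merge_contigs(
            [_contig(100, 300, 2.0), _contig(1100, 1300, 2.0)], ctrl, test
        )
        assert len(out) == 2  # "less than 1 kb" is strict

    def test_incompatible_strands_block_merge(self):
        ctrl, test = self._tracks()
        out = merge_contigs(
            [_contig(100, 300, 2.0, "+"), _contig(400, 600, 2.0, "-")], ctrl, test
        )
        assert len(out) == 2

    def test_fixed_point_is_order_independent(self):
        rng = np.random.default_rng(11)
        ctrl, test = self._tracks(5000, 1.5)
        contigs = [
            _contig(int(s), int(s) + int(rng.integers(50, 400)),
                    float(rng.uniform(1, 6)))
            for s in rng.integers(0, 4500, 12)
        ]
        ref = merge_contigs(list(contigs), ctrl, test)
        key = lambda c: (c.seq, c.start, c.end)
        for _ in range(5):
            perm = list(contigs)
            rng.shuffle(perm)
            got = merge_contigs(perm, ctrl, test)
            assert sorted(map(key, got)) == sorted(map(key, ref))


class TestScoreAndRank:
    def test_score_is_avgdiff_times_size(self):
        c = _contig(0, 500, 2.0)
        assert c.score == pytest.approx(1000.0)

    def test_rank_order(self):
        contigs = [
            _contig(0, 10, 1.0),  # score 10
            _contig(20, 30, 3.0),  # score 30
            _contig(40, 50, 2.0),  # score 20
        ]
        ranked = score_and_rank(contigs)
        by_start = {c.start: c.rank for c in ranked}
        assert by_start == {0: 3, 20: 1, 40: 2}

    def test_ties_break_by_coordinate_then_sequence(self):
        contigs = [
            _contig(500, 510, 1.0, seq="b"),
            _contig(100, 110, 1.0, seq="b"),
            _contig(100, 110, 1.0, seq="a"),
        ]
        ranked = score_and_rank(contigs)
        assert [(c.start, c.seq) for c in sorted(ranked, key=lambda c: c.rank)] == [
            (100, "a"),
            (100, "b"),
            (500, "b"),
        ]
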