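import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgpipe import (
    AnalysisConfig,
    RRSeries,
    SynthSpec,
    build_rr,
    classify_af,
    detect_pauses,
    detect_rhythm_alterations,
    disorganization_index,
    fence_outliers,
    generate,
    hrv_indices,
    poincare_grid,
    rr_af_sample,
)
from ecgpipe.qrs import BeatAnnotations
from ecgpipe.rhythm import analyze_rhythm


def rr_series(values):
    return RRSeries(rr=np.asarray(values, dtype=float), fs=250.0)


class TestBuildRR:
    def test_uniform_beats(self):
        ann = BeatAnnotations(r_indices=np.array([0, 250, 500]), fs=250)
        rr = build_rr(ann)
        np.testing.assert_allclose(rr.rr, [1.0, 1.0])
        np.testing.assert_allclose(rr.drr, [0.0])

    def test_varying_beats(self):
        ann = BeatAnnotations(r_indices=np.array([0, 200, 500]), fs=250)
        rr = build_rr(ann)
        np.testing.assert_allclose(rr.rr, [0.8, 1.2])
        np.testing.assert_allclose(rr.drr, [0.4])

    def test_single_beat_errors(self):
        with pytest.raises(ValueError, match="at least 2 beats"):
            build_rr(BeatAnnotations(r_indices=np.array([10]), fs=250))

    def test_interval_over_masked_gap_invalid(self):
        ann = BeatAnnotations(r_indices=np.array([0, 250, 500]), fs=250)
        mask = np.ones(501, dtype=bool)
        mask[300:320] = False
        rr = build_rr(ann, valid_mask=mask)
        assert rr.valid.tolist() == [True, False]


class TestWarnings:
    def test_alteration_flagged_above_30pct(self):
        alts = detect_rhythm_alterations(rr_series([0.8, 0.8, 1.2]))
        assert [a[0] for a in alts] == [2]

    def test_25pct_change_not_flagged(self):
        assert detect_rhythm_alterations(rr_series([0.8, 1.0])) == []

    def test_constant_series_no_alterations(self):
        assert detect_rhythm_alterations(rr_series([0.9] * 10)) == []

    def test_pause_above_3s_flagged(self):
        pauses = detect_pauses(rr_series([0.9, 3.1]))
        assert pauses == [(1, 3.1)]

    def test_pause_threshold_is_strict(self):
        assert detect_pauses(rr_series([0.9, 3.0])) == []

    def test_constant_series_no_pauses(self):
        assert detect_pauses(rr_series([1.0] * 20)) == []

    def test_exhaustive_small_rule_enumeration(self):
        """The flag decisions match the printed rules on a lattice of
        two-interval series."""
        cfg = AnalysisConfig()
        for prev in np.arange(0.4, 3.6, 0.1):
            for cur in np.arange(0.4, 3.6, 0.1):
                s = rr_series([prev, cur])
                alt = [a[0] for a in detect_rhythm_alterations(s, cfg.alteration_frac)]
                pause = [p[0] for p in detect_pauses(s, cfg.pause_s)]
                assert (1 in alt) == (abs(cur - prev) / prev > cfg.alteration_frac)
                assert (1 in pause) == (cur > cfg.pause_s)
                assert (0 in pause) == (prev > cfg.pause_s)


class TestFenceOutliers:
    def test_tight_uniform_series_no_outliers(self):
        rng = np.random.default_rng(0)
        rr = fence_outliers(rr_series(rng.uniform(0.7, 0.9, size=100)))
        assert not rr.outlier_mask.any()

    def test_gross_pause_flagged(self):
        vals = 0.8 + 0.02 * np.random.default_rng(1).standard_normal(50)
        vals[25] = 5.0
        rr = fence_outliers(rr_series(vals))
        assert rr.outlier_mask[25]
        assert rr.outlier_mask.sum() <= 3  # neighbours may flag on the dRR axis

    def test_identical_series_degenerate_iqr(self):
        rr = fence_outliers(rr_series([0.8] * 20))
        assert not rr.outlier_mask.any()

    def test_too_few_intervals_skipped(self):
        rr = fence_outliers(rr_series([0.8, 0.9, 5.0]))
        assert not rr.outlier_mask.any()

    def test_literal_printed_rule_is_upper_fence_only(self):
        vals = np.concatenate([np.full(30, 0.8), [0.05], [5.0]])
        two_sided = fence_outliers(rr_series(vals))
        literal = fence_outliers(rr_series(vals), literal_rule=True)
        assert two_sided.outlier_mask[30] and two_sided.outlier_mask[31]
        assert literal.outlier_mask[31]
        # the short interval escapes the literal rule on the RR axis but its
        # dRR swing can still catch interval 30's derivative
        assert not (
            vals[30] > literal.fences.p75_rr + 3 * literal.fences.iqr_rr
        )

    def test_time_reversal_invariant_on_rr_axis(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 1.5, size=60)
        fwd = fence_outliers(rr_series(vals), fence_multiplier=3.0)
        f = fwd.fences
        rev = fence_outliers(rr_series(vals[::-1].copy()))
        g = rev.fences
        assert f.p25_rr == g.p25_rr and f.p75_rr == g.p75_rr

    def test_narrower_fence_flags_superset(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(-0.2, 0.3, size=80)
        wide = fence_outliers(rr_series(vals), fence_multiplier=3.0).outlier_mask.copy()
        narrow = fence_outliers(rr_series(vals), fence_multiplier=1.0).outlier_mask
        assert np.all(wide <= narrow)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_mask_matches_brute_force_oracle(self, seed):
        """Element-wise fence decisions agree with an independent
        per-interval re-derivation using manually interpolated quartiles."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        vals = rng.lognormal(-0.2, 0.4, size=n)
        rr = fence_outliers(rr_series(vals))

        def quartiles(x):
            xs = np.sort(x)
            out = []
            for q in (0.25, 0.75):
                h = (len(xs) - 1) * q
                lo, hi = int(np.floor(h)), int(np.ceil(h))
                out.append(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))
            return out

        p25, p75 = quartiles(vals)
        iqr = p75 - p25
        drr = np.diff(vals)
        d25, d75 = quartiles(drr)
        diqr = d75 - d25
        for i, v in enumerate(vals):
            o1 = v < p25 - 3 * iqr or v > p75 + 3 * iqr
            o2 = i >= 1 and (
                drr[i - 1] < d25 - 3 * diqr or drr[i - 1] > d75 + 3 * diqr
            )
            assert rr.outlier_mask[i] == (o1 or o2)


class TestPoincare:
    def test_constant_rhythm_single_bin(self):
        rr = fence_outliers(rr_series([0.8] * 50))
        grid = poincare_grid(rr)
        assert (grid.counts > 0).sum() == 1
        assert disorganization_index(grid) == 1 / 30**2

    def test_point_count_conservation(self):
        rng = np.random.default_rng(8)
        rr = fence_outliers(rr_series(rng.uniform(0.4, 1.0, size=120)))
        grid = poincare_grid(rr)
        n_expected = np.count_nonzero(~rr.outlier_mask[1:] & ~rr.outlier_mask[:-1])
        assert grid.counts.sum() == n_expected == grid.n_points

    def test_bigeminy_occupies_two_bins(self):
        rr = fence_outliers(rr_series([0.6, 1.0] * 30))
        grid = poincare_grid(rr)
        assert (grid.counts > 0).sum() == 2

    def test_out_of_range_points_clipped_into_edge_bins(self):
        rr = RRSeries(rr=np.array([0.1, 3.0, 0.1, 3.0, 0.1]), fs=250)
        grid = poincare_grid(rr)
        assert grid.counts.sum() == 4


class TestDisorganization:
    def test_bounds_and_full_grid(self):
        counts = np.ones((30, 30), dtype=int)
        from ecgpipe.rhythm import PoincareGrid

        grid = PoincareGrid(counts=counts, rr_range_s=(0.24, 2.0), drr_range_s=(-0.88, 0.88))
        assert disorganization_index(grid) == 1.0

    def test_monotone_in_occupied_bins(self):
        from ecgpipe.rhythm import PoincareGrid

        rng = np.random.default_rng(11)
        counts = (rng.random((30, 30)) < 0.1).astype(int)
        grid = PoincareGrid(counts=counts, rr_range_s=(0.24, 2.0), drr_range_s=(-0.88, 0.88))
        base = disorganization_index(grid)
        counts2 = counts.copy()
        counts2[0, 0] = max(1, counts2[0, 0])
        grid2 = PoincareGrid(counts=counts2, rr_range_s=(0.24, 2.0), drr_range_s=(-0.88, 0.88))
        assert disorganization_index(grid2) >= base
        assert 0.0 <= base <= 1.0

    def test_af_index_exceeds_sinus_in_paired_simulations(self):
        cfg = AnalysisConfig()
        rng = np.random.default_rng(101)
        wins = 0
        n_pairs = 200
        for _ in range(n_pairs):
            spec = SynthSpec(mean_hr_bpm=float(rng.uniform(50, 110)))
            n_s = int(np.ceil(75.0 * spec.mean_hr_bpm / 60.0))
            sinus = np.maximum(rng.normal(60 / spec.mean_hr_bpm, spec.hrv_sd_s, n_s), 0.3)
            af = rng.uniform(0.4, 1.0, size=int(np.ceil(75.0 / 0.7)))

            def idx(vals):
                rr = fence_outliers(RRSeries(rr=vals, fs=250.0))
                return disorganization_index(poincare_grid(rr, cfg.af_bins_per_axis,
                                                           cfg.rr_axis_range_s,
                                                           cfg.drr_axis_range_s))

            wins += idx(af) > idx(sinus)
        assert wins / n_pairs >= 0.95


class TestClassifyAF:
    def test_sinus_record_two_clean_segments(self):
        rec, _ = generate(SynthSpec(duration_s=160, mean_hr_bpm=70, seed=41))
        from ecgpipe import detect_beats

        ann = detect_beats(rec)
        segs = classify_af(build_rr(ann))
        assert len(segs) == 2
        assert not any(s["af"] for s in segs)

    def test_af_record_two_flagged_segments(self):
        rec, _ = generate(SynthSpec(duration_s=160, rhythm="af", seed=43))
        from ecgpipe import detect_beats

        ann = detect_beats(rec)
        segs = classify_af(build_rr(ann))
        assert len(segs) == 2
        assert all(s["af"] for s in segs)

    def test_threshold_one_never_flags(self):
        rng = np.random.default_rng(44)
        rr = RRSeries(rr=rng.uniform(0.4, 1.0, size=300), fs=250.0)
        cfg = AnalysisConfig(af_threshold=1.0)
        assert not any(s["af"] for s in classify_af(rr, cfg))

    def test_short_record_best_effort(self):
        rng = np.random.default_rng(45)
        rr = RRSeries(rr=rng.uniform(0.7, 0.9, size=30), fs=250.0)
        segs = classify_af(rr)
        assert len(segs) == 1 and segs[0]["best_effort"]


class TestHRV:
    def test_constant_series(self):
        h = hrv_indices(rr_series([1.0] * 30))
        assert h["mean_hr_bpm"] == pytest.approx(60.0)
        assert h["sdnn_s"] == 0.0
        assert h["rr_range_s"] == 0.0
        assert h["triangular_index"] == 1.0

    def test_two_interval_arithmetic(self):
        h = hrv_indices(rr_series([0.5, 1.0]))
        assert h["mean_hr_bpm"] == pytest.approx(80.0)
        assert h["rr_range_s"] == pytest.approx(0.5)

    def test_sdnn_matches_brute_force(self):
        rng = np.random.default_rng(46)
        vals = rng.uniform(0.5, 1.2, size=200)
        h = hrv_indices(rr_series(vals))
        brute = float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
        assert h["sdnn_s"] == pytest.approx(brute, rel=1e-12)

    def test_triangular_index_counts_histogram_mode(self):
        # 60 intervals at 0.8 s plus 4 elsewhere: mode bin holds 60
        vals = np.array([0.8] * 60 + [0.5, 0.6, 1.0, 1.1])
        h = hrv_indices(rr_series(vals))
        assert h["triangular_index"] == pytest.approx(64 / 60)


def test_analyze_rhythm_report_fields(sinus_record):
    rec, _ = sinus_record
    from ecgpipe import detect_beats

    ann = detect_beats(rec)
    rep = analyze_rhythm(ann)
    assert rep.n_beats == ann.n_beats
    assert set(rep.hrv) == {"mean_hr_bpm", "sdnn_s", "rr_range_s", "triangular_index"}
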