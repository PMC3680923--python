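import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnclonality import (ArmCall, RegionSet, SampleProfile,
                         SegmentationConfig, SimConfig, classify_arm,
                         estimate_noise, filter_cnv_segment, make_track,
                         segment_arm, segment_profile, simulate_pair)
from cnclonality.segmentation import ArmSegmentation, Segment, whole_arm_z


def brute_force_segment(x, sigma, min_markers):
    """Independent oracle: exhaustive enumeration of all intervals.

    An interval and its complement carry identical |T|, so ties within a
    tiny relative tolerance resolve to the first (i, j) in scan order —
    the same convention as the production scan.
    """
    x = np.asarray(x, float)
    m = len(x)
    sigma = max(sigma, 1e-6)
    all_stats = []
    for i in range(m):
        for j in range(i + min_markers - 1, m):
            L = j - i + 1
            if L == m:
                T = x.mean() / (sigma / np.sqrt(m))
            else:
                mean_in = x[i:j + 1].mean()
                mean_out = (x.sum() - x[i:j + 1].sum()) / (m - L)
                T = (mean_in - mean_out) / (sigma * np.sqrt(1 / L + 1 / (m - L)))
            all_stats.append((i, j, T))
    vmax = max(abs(t) for _, _, t in all_stats)
    tol = 1e-10 * max(vmax, 1.0)
    for i, j, T in all_stats:
        if abs(T) >= vmax - tol:
            return i, j, T
    raise RuntimeError("unreachable")


class TestEstimateNoise:
    def test_recovers_iid_sigma(self, default_layout):
        cfg = SimConfig(noise_sd=0.25)
        track = make_track(cfg)
        rng = np.random.default_rng(42)
        prof = SampleProfile("S1", "P1", "LCIS",
                             rng.normal(0, 0.25, len(track)))
        assert 0.24 <= estimate_noise(prof, track) <= 0.26

    def test_constant_profile_gives_zero(self, small_track):
        prof = SampleProfile("S1", "P1", "LCIS", np.zeros(len(small_track)))
        assert estimate_noise(prof, small_track) == 0.0

    def test_robust_to_single_step(self, small_track):
        # one true change-point adds a single outlying difference; the
        # median-based estimate is unaffected
        vals = np.zeros(len(small_track))
        vals[len(vals) // 2:] = 5.0
        prof = SampleProfile("S1", "P1", "LCIS", vals)
        assert estimate_noise(prof, small_track) == 0.0

    def test_too_few_markers_rejected(self, small_track):
        vals = np.full(len(small_track), np.nan)
        vals[:5] = 1.0
        prof = SampleProfile.__new__(SampleProfile)
        prof.sample_id, prof.patient_id, prof.lesion = "S", "P", "L"
        prof.values = vals
        with pytest.raises(ValueError, match="10 non-missing"):
            estimate_noise(prof, small_track)


class TestSegmentArm:
    def test_finds_planted_interval(self):
        values = np.array([0, 0, 0, 0.8, 0.8, 0.8, 0.8, 0, 0, 0], float)
        i, j, T = segment_arm(values, 0.1, SegmentationConfig())
        assert (i, j) == (3, 6)
        assert T > 0

    def test_all_zeros_gives_zero_statistic(self):
        i, j, T = segment_arm(np.zeros(20), 0.1, SegmentationConfig())
        assert T == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        cfg = SegmentationConfig()
        for _ in range(40):
            m = int(rng.integers(2 * cfg.min_segment_markers, 120))
            x = rng.normal(0, 1, m)
            if rng.random() < 0.5:  # plant a shift half the time
                a = int(rng.integers(0, m - 3))
                b = int(rng.integers(a + 2, m))
                x[a:b + 1] += rng.normal(0, 1.5)
            i, j, T = segment_arm(x, 1.0, cfg)
            oi, oj, oT = brute_force_segment(x, 1.0, cfg.min_segment_markers)
            assert (i, j) == (oi, oj)
            assert T == pytest.approx(oT, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3, allow_nan=False, width=32),
                    min_size=6, max_size=40))
    def test_oracle_equivalence_property(self, values):
        x = np.asarray(values, float)
        cfg = SegmentationConfig()
        i, j, T = segment_arm(x, 0.5, cfg)
        oi, oj, oT = brute_force_segment(x, 0.5, cfg.min_segment_markers)
        assert abs(T) == pytest.approx(abs(oT), abs=1e-9)
        assert (i, j) == (oi, oj)

    def test_scale_equivariance(self, rng):
        x = rng.normal(0, 1, 80)
        cfg = SegmentationConfig()
        i1, j1, T1 = segment_arm(x, 0.7, cfg)
        # powers of two scale exactly in binary floating point
        i2, j2, T2 = segment_arm(4.0 * x, 4.0 * 0.7, cfg)
        assert (i1, j1) == (i2, j2)
        assert T1 == T2

    def test_sigma_zero_floored(self):
        x = np.zeros(12)
        x[4:8] = 1.0
        i, j, T = segment_arm(x, 0.0, SegmentationConfig())
        assert (i, j) == (4, 7)
        assert np.isfinite(T)

    def test_chunked_path_agrees_with_dense(self, rng):
        from cnclonality.segmentation import _segment_arm_chunked
        x = rng.normal(0, 1, 500)
        x[100:200] += 1.0
        cfg = SegmentationConfig()
        i, j, T = segment_arm(x, 1.0, cfg)
        S = np.concatenate(([0.0], np.cumsum(x)))
        ci, cj, cT = _segment_arm_chunked(S, S[-1], len(x), 1.0, cfg)
        assert (i, j) == (ci, cj)
        assert T == pytest.approx(cT, abs=1e-9)


class TestClassifyArm:
    cfg = SegmentationConfig()

    def test_central_gain(self):
        x = np.zeros(30)
        x[10:20] = 0.8
        cand = segment_arm(x, 0.1, self.cfg)
        seg = classify_arm(x, cand, 0.1, self.cfg)
        assert seg.call is ArmCall.GAIN
        assert seg.footprint == (10, 19)
        assert seg.magnitude == pytest.approx(0.8)
        assert seg.breakpoints == (10, 20)

    def test_magnitude_gate_yields_normal(self):
        x = np.zeros(200)
        x[50:150] = 0.05  # significant T but below the call magnitude
        cand = segment_arm(x, 0.01, self.cfg)
        seg = classify_arm(x, cand, 0.01, self.cfg)
        assert abs(cand[2]) >= self.cfg.change_threshold
        assert seg.call is ArmCall.NORMAL
        assert seg.footprint is None and seg.magnitude == 0.0

    def test_one_breakpoint_outstanding_segment(self):
        x = np.concatenate([np.full(15, -0.5), np.full(15, 0.02)])
        cand = segment_arm(x, 0.05, self.cfg)
        seg = classify_arm(x, cand, 0.05, self.cfg)
        assert seg.call is ArmCall.LOSS
        assert seg.footprint == (0, 14)
        assert seg.magnitude == pytest.approx(-0.5)

    def test_whole_arm_shift(self):
        x = np.full(40, 0.4)
        cand = segment_arm(x, 0.1, self.cfg)
        seg = classify_arm(x, cand, 0.1, self.cfg)
        assert seg.call is ArmCall.GAIN
        assert seg.footprint == (0, 39)
        assert seg.is_whole_arm()

    def test_below_threshold_is_normal(self, rng):
        x = rng.normal(0, 1, 50)
        cand = segment_arm(x, 1.0, SegmentationConfig(change_threshold=50.0))
        seg = classify_arm(x, cand, 1.0, SegmentationConfig(change_threshold=50.0))
        assert seg.call is ArmCall.NORMAL
        assert len(seg.segments) == 1

    def test_raising_threshold_never_creates_calls(self, rng):
        lo = SegmentationConfig(change_threshold=3.0)
        hi = SegmentationConfig(change_threshold=6.0)
        for _ in range(30):
            x = rng.normal(0, 1, 60)
            cand = segment_arm(x, 1.0, lo)
            call_lo = classify_arm(x, cand, 1.0, lo).call
            call_hi = classify_arm(x, segment_arm(x, 1.0, hi), 1.0, hi).call
            if call_lo is ArmCall.NORMAL:
                assert call_hi is ArmCall.NORMAL


class TestCnvFilter:
    def make_seg(self, call=ArmCall.GAIN, footprint=(10, 19), n=60):
        segs = [Segment(0, footprint[0] - 1, 0.0),
                Segment(*footprint, 0.8),
                Segment(footprint[1] + 1, n - 1, 0.0)]
        return ArmSegmentation(0, (footprint[0], footprint[1] + 1), segs,
                               call, 0.8, footprint, 10.0)

    def build_track(self, spacing_bp):
        from cnclonality import Arm, GenomeLayout, MarkerTrack
        n = 60
        layout = GenomeLayout([Arm("chr1", "q", 1, spacing_bp * (n + 1))])
        pos = np.arange(1, n + 1) * spacing_bp
        return MarkerTrack(np.full(n, "chr1", dtype=object),
                           pos.astype(np.int64),
                           np.zeros(n, dtype=np.int32), layout)

    def test_short_overlapping_segment_reset(self):
        track = self.build_track(200_000)  # footprint span: 1.8 MB < 2.3 MB
        seg = self.make_seg()
        regions = RegionSet([("chr1", 2_500_000, 2_600_000)])
        out = filter_cnv_segment(seg, track, regions, SegmentationConfig())
        assert out.call is ArmCall.NORMAL
        assert out.breakpoints == () and out.footprint is None
        assert out.magnitude == 0.0 and out.cnv_filtered

    def test_short_non_overlapping_segment_kept(self):
        track = self.build_track(200_000)
        seg = self.make_seg()
        regions = RegionSet([("chr1", 11_000_000, 11_100_000)])
        out = filter_cnv_segment(seg, track, regions, SegmentationConfig())
        assert out.call is ArmCall.GAIN and not out.cnv_filtered

    def test_long_overlapping_segment_kept(self):
        track = self.build_track(300_000)  # footprint span: 2.7 MB >= 2.3 MB
        seg = self.make_seg()
        regions = RegionSet([("chr1", 3_500_000, 3_600_000)])
        out = filter_cnv_segment(seg, track, regions, SegmentationConfig())
        assert out.call is ArmCall.GAIN and not out.cnv_filtered


class TestSegmentProfile:
    def test_all_zero_profile_all_normal(self, small_track):
        prof = SampleProfile("S1", "P1", "LCIS", np.zeros(len(small_track)))
        segs = segment_profile(prof, small_track, sigma=0.1)
        assert all(s.call is ArmCall.NORMAL for s in segs)

    def test_noiseless_recovery_of_event_footprints(self):
        cfg = SimConfig(n_markers=4000, noise_sd=0.0, xi_true=1.0)
        track, profiles, truth = simulate_pair(cfg, clonal=True, seed=3)
        segs = segment_profile(profiles[0], track)
        truth_events = {e.arm_index: e for e in truth.events["T1"]}
        for seg in segs:
            if seg.arm_index in truth_events:
                e = truth_events[seg.arm_index]
                assert seg.call is e.call
                assert seg.footprint == (e.start, e.end)
            else:
                assert seg.call is ArmCall.NORMAL

    def test_pure_noise_false_call_rate_below_one_percent(self):
        cfg = SimConfig(n_markers=15_000, base_event_rate=0.0,
                        rate_1q_gain=0.0, rate_16q_loss=0.0)
        rng = np.random.default_rng(99)
        track = make_track(cfg)
        n_arms = n_called = 0
        for _ in range(20):
            _, profiles, _ = simulate_pair(cfg, clonal=False, seed=rng,
                                           track=track)
            for prof in profiles:
                segs = segment_profile(prof, track)
                n_arms += len(segs)
                n_called += sum(s.call is not ArmCall.NORMAL for s in segs)
        assert n_arms == 20 * 2 * 39
        assert n_called / n_arms < 0.01

    def test_nan_markers_are_tolerated(self, small_track, rng):
        vals = rng.normal(0, 0.1, len(small_track))
        sl = small_track.arm_slice(0)
        vals[sl.start + 5: sl.start + 15] += 2.0
        vals[sl.start + 7] = np.nan
        prof = SampleProfile("S1", "P1", "LCIS", vals)
        segs = segment_profile(prof, small_track)
        assert segs[0].call is ArmCall.GAIN
        # segments still tile the arm despite the missing marker
        assert segs[0].segments[-1].end == sl.stop - sl.start - 1
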