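import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazescan import (
    DataError,
    GazeRecording,
    clip_bound_px,
    clip_dynamics,
    compute_velocity,
    render_segment,
    segment_scanpath,
    speed_to_gray,
)
from gazescan.render import VelocityTrace

from conftest import random_recording


def brute_force_speeds(rec: GazeRecording) -> list[float]:
    """Oracle: per-pair speed via explicit python loop over raw samples."""
    out = []
    samples = list(rec.samples())
    for a, b in zip(samples, samples[1:]):
        if a.valid and b.valid:
            d = ((b.x - a.x) ** 2 + (b.y - a.y) ** 2) ** 0.5
            out.append(d / (b.t - a.t))
    return out


class TestComputeVelocity:
    def test_hand_computed_example(self, tiny_recording):
        # 5 px Euclidean over 4 ms twice -> 1.25 px/ms
        trace = compute_velocity(tiny_recording)
        assert np.allclose(trace.speeds, [1.25, 1.25])

    def test_constant_position_zero_speed(self):
        rec = GazeRecording("p", "s", t=[0, 10, 25], x=[5, 5, 5], y=[7, 7, 7],
                            valid=[True] * 3)
        assert np.allclose(compute_velocity(rec).speeds, 0.0)

    def test_transitions_spanning_invalid_omitted(self):
        rec = GazeRecording("p", "s", t=[0, 4, 8], x=[0, 1, 2], y=[0, 0, 0],
                            valid=[True, False, True])
        with pytest.raises(DataError):
            # only 2 valid samples but no adjacent pair -> empty trace is
            # allowed; fewer than 2 valid samples is the error
            compute_velocity(
                GazeRecording("p", "s", t=[0, 4], x=[0, 1], y=[0, 0],
                              valid=[True, False])
            )
        assert len(compute_velocity(rec)) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for n in (10, 137, 1000):
            rec = random_recording(rng, n, invalid_fraction=0.15)
            got = compute_velocity(rec).speeds
            want = brute_force_speeds(rec)
            assert np.allclose(got, want, rtol=1e-9, atol=0)


class TestClipDynamics:
    def test_quarter_diagonal_bound(self):
        # closed form sqrt(1280^2 + 1024^2) / 4
        assert clip_bound_px((1280, 1024)) == pytest.approx(409.79995, abs=1e-4)

    def test_below_bound_unchanged(self):
        trace = VelocityTrace(speeds=[25.0], dts=[4.0])  # 100 px in 4 ms
        out = clip_dynamics(trace, (1280, 1024))
        assert out.speeds[0] == 25.0

    def test_above_bound_rescaled(self):
        trace = VelocityTrace(speeds=[2500.0], dts=[4.0])  # 10,000 px in 4 ms
        out = clip_dynamics(trace, (1280, 1024))
        assert out.speeds[0] == pytest.approx(409.79995 / 4.0, abs=1e-3)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        trace = VelocityTrace(speeds=rng.uniform(0, 5000, 200),
                              dts=rng.uniform(1, 8, 200))
        once = clip_dynamics(trace, (1280, 1024))
        twice = clip_dynamics(once, (1280, 1024))
        assert np.array_equal(once.speeds, twice.speeds)


class TestSegmentScanpath:
    def _rec(self, n_valid, n_invalid_head=0):
        n = n_valid + n_invalid_head
        valid = np.ones(n, bool)
        valid[:n_invalid_head] = False
        return GazeRecording("p", "s", t=np.arange(n) * 4.0,
                             x=np.zeros(n), y=np.zeros(n), valid=valid)

    @pytest.mark.parametrize(
        "n_valid,expected_sizes",
        [(150, [150]), (400, [200, 200]), (410, [200, 200]), (10, [])],
    )
    def test_partition_rule(self, n_valid, expected_sizes):
        segs = segment_scanpath(self._rec(n_valid))
        assert [len(s) for s in segs] == expected_sizes
        assert [s.segment_index for s in segs] == list(range(len(segs)))

    def test_trailing_run_at_least_min_points_kept(self):
        segs = segment_scanpath(self._rec(230), min_points=20)
        assert [len(s) for s in segs] == [200, 30]


class TestSpeedToGray:
    def test_endpoints(self):
        assert speed_to_gray(0.0, 400.0, 4.0) == 1.0
        assert speed_to_gray(100.0, 400.0, 4.0) == pytest.approx(0.1)
        assert speed_to_gray(999.0, 400.0, 4.0) == pytest.approx(0.1)

    def test_midpoint_linear(self):
        # s = 0.5 -> 1 - 0.9 * 0.5 = 0.55
        assert speed_to_gray(50.0, 400.0, 4.0) == pytest.approx(0.55)

    def test_negative_speed_rejected(self):
        with pytest.raises(DataError):
            speed_to_gray(-1.0, 400.0, 4.0)

    @settings(deadline=None, max_examples=50)
    @given(
        s1=st.floats(0, 200, allow_nan=False),
        s2=st.floats(0, 200, allow_nan=False),
        invert=st.booleans(),
    )
    def test_monotone(self, s1, s2, invert):
        lo, hi = sorted((s1, s2))
        g_lo = speed_to_gray(lo, 400.0, 4.0, invert=invert)
        g_hi = speed_to_gray(hi, 400.0, 4.0, invert=invert)
        assert (g_lo >= g_hi) != invert or g_lo == g_hi


class TestRenderSegment:
    def _segment(self, rng, n=50):
        rec = random_recording(rng, n)
        return segment_scanpath(rec, max_points=n, min_points=2)[0]

    def test_bit_identical_re_render(self):
        rng = np.random.default_rng(7)
        seg = self._segment(rng)
        a = render_segment(seg)
        b = render_segment(seg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_intensities_are_background_or_stroke(self):
        rng = np.random.default_rng(8)
        img = render_segment(self._segment(rng))
        vals = np.unique(img.pixels)
        assert vals[0] == 0.0
        strokes = vals[vals > 0]
        assert strokes.size > 0
        assert np.all((strokes >= 0.1 - 1e-6) & (strokes <= 1.0))

    def test_vertical_mirroring(self):
        # a transition near data-space y=0 must land in the bottom raster rows
        rec = GazeRecording("p", "s", t=[0.0, 4.0], x=[600.0, 640.0],
                            y=[0.0, 2.0], valid=[True, True])
        seg = segment_scanpath(rec, min_points=2)[0]
        img = render_segment(seg, dims=(640, 480))
        rows = np.nonzero(img.pixels.max(axis=1) > 0)[0]
        assert rows.min() >= 470  # bottom rows of a 480-row raster

    def test_stroke_count_matches_transitions(self):
        # N collinear horizontal samples -> N-1 abutting strokes whose
        # pixel span covers exactly the extent of the x range
        n = 6
        rec = GazeRecording("p", "s", t=np.arange(n) * 4.0,
                            x=np.linspace(0, 1280, n), y=np.full(n, 512.0),
                            valid=np.ones(n, bool))
        seg = segment_scanpath(rec, min_points=2)[0]
        img = render_segment(seg, dims=(640, 480))
        row_px = (img.pixels > 0).sum()
        assert row_px == 640  # contiguous horizontal line across the raster

    def test_gap_breaks_stroke(self):
        t = np.arange(5) * 4.0
        x = np.array([0.0, 10.0, 640.0, 1270.0, 1280.0])
        y = np.full(5, 512.0)
        valid = np.array([True, True, False, True, True])
        rec = GazeRecording("p", "s", t=t, x=x, y=y, valid=valid)
        seg = segment_scanpath(rec, min_points=2)[0]
        img = render_segment(seg, dims=(640, 480))
        filled = np.nonzero(img.pixels[240 - 1 : 240 + 2].max(axis=0) > 0)[0]
        # middle of the screen never drawn: the two strokes are disjoint
        assert filled.size < 20

    def test_too_short_segment_rejected(self):
        rng = np.random.default_rng(9)
        seg = self._segment(rng, n=10)
        seg.t = seg.t[:1]; seg.x = seg.x[:1]; seg.y = seg.y[:1]
        seg.src_index = seg.src_index[:1]
        with pytest.raises(DataError):
            render_segment(seg)
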