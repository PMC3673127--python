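"""Decoder: lift-off rules, smoothing, segmentation, metrics, rendering."""

import numpy as np
import pytest

import mripad as mp
from mripad.decoder import (
    LiftoffConfig,
    detect_liftoff,
    pixel_center_mm,
    render_response,
    smooth_positions,
)
from mripad.sensor import PathSegment, PenUpSegment, TrajectoryScript


class TestDetectLiftoff:
    def test_sixty_percent_drop_in_200ms_flags(self):
        t = np.array([0.0, 0.1, 0.2])
        s = np.array([300.0, 250.0, 120.0])
        assert detect_liftoff(t, s)

    def test_forty_percent_drop_does_not_flag(self):
        t = np.array([0.0, 0.1, 0.2])
        s = np.array([300.0, 240.0, 180.0])
        assert not detect_liftoff(t, s)

    def test_slow_sixty_percent_drop_does_not_flag(self):
        # 300 -> 120 linearly over 1 s: no 250 ms sub-interval contains a
        # >50% change (sliding-window brute force inside detect_liftoff)
        t = np.arange(31) / 30.0
        s = 300.0 - 180.0 * t
        assert not detect_liftoff(t, s)

    def test_offmap_color_flags_when_confirmation_enabled(self):
        t = np.array([0.0, 0.1])
        s = np.array([300.0, 290.0])
        flags = np.array([False, True])
        assert detect_liftoff(t, s, offmap_flags=flags)
        cfg = LiftoffConfig(require_offmap_confirmation=False)
        assert not detect_liftoff(t, s, cfg, offmap_flags=flags)


class TestSmoothing:
    def test_constant_stream_is_fixed_point(self):
        p = np.full((50, 2), 7.0)
        assert np.array_equal(smooth_positions(p, 5), p)

    def test_window_arithmetic(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 5.0])
        assert smooth_positions(x, 5)[-1] == pytest.approx(1.0)

    def test_variance_reduction_one_fifth(self, rng):
        x = rng.normal(size=10_000)
        sm = smooth_positions(x, 5)
        ratio = sm[4:].var() / x.var()
        assert ratio == pytest.approx(0.2, rel=0.2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_positions(np.zeros(5), 4)


def _decode_fixture(name, spec, model, lut, fixture_lib, seed=0, **kw):
    stream = mp.simulate_stream(spec, model, fixture_lib[name].script, seed)
    return mp.decode_stream(stream, lut, **kw)


class TestDecodeStream:
    def test_two_stroke_t_matches_script_order(self, default_spec, zero_model,
                                               zero_pipeline, fixture_lib):
        result = _decode_fixture("T", default_spec, zero_model,
                                 zero_pipeline[2], fixture_lib)
        assert len(result.responses) == 1
        resp = result.responses[0]
        assert len(resp.strokes) == 2
        # script order: the horizontal bar first (x extent), then the stem
        bar, stem = resp.strokes
        assert np.ptp(bar.mm[:, 0]) > np.ptp(bar.mm[:, 1])
        assert np.ptp(stem.mm[:, 1]) > np.ptp(stem.mm[:, 0])

    def test_empty_stream(self, zero_pipeline):
        stream = mp.SampleStream(np.empty(0), np.empty((0, 3)), {})
        result = mp.decode_stream(stream, zero_pipeline[2])
        assert result.responses == []

    def test_short_pen_up_merges_into_one_response(self, default_spec,
                                                   zero_model, zero_pipeline,
                                                   fixture_lib):
        # gaps of 0.4 s < completion dwell 1 s: one response, lift-offs count
        result = _decode_fixture("H", default_spec, zero_model,
                                 zero_pipeline[2], fixture_lib)
        assert len(result.responses) == 1
        assert result.responses[0].metrics.liftoff_count == 2

    def test_long_pen_up_splits_responses(self, default_spec, zero_model,
                                          zero_pipeline):
        seg = ((70.0, 100.0), (130.0, 100.0))
        script = TrajectoryScript((
            PathSegment(seg, 1.0), PenUpSegment(1.5), PathSegment(seg, 1.0)))
        stream = mp.simulate_stream(default_spec, zero_model, script)
        result = mp.decode_stream(stream, zero_pipeline[2])
        assert len(result.responses) == 2
        assert [len(r.strokes) for r in result.responses] == [1, 1]
        assert len(result.events) == 2

    def test_segmentation_conserves_samples(self, default_spec, noisy_model,
                                            zero_pipeline, fixture_lib):
        stream = mp.simulate_stream(default_spec, noisy_model,
                                    fixture_lib["H"].script, seed=4)
        result = mp.decode_stream(stream, zero_pipeline[2])
        down = int((result.sample_table[:, 1] == 1).sum())
        up = int((result.sample_table[:, 1] == 0).sum())
        stroke_samples = sum(len(s.t) for r in result.responses
                             for s in r.strokes)
        assert down + up == len(stream)
        assert down == stroke_samples

    def test_mismatched_spec_hash_is_hard_error(self, default_spec,
                                                zero_model, zero_pipeline):
        script = TrajectoryScript(
            (PathSegment(((70.0, 100.0), (130.0, 100.0)), 1.0),))
        stream = mp.simulate_stream(default_spec, zero_model, script)
        stream.meta["spec_hash"] = "deadbeef0000"
        with pytest.raises(ValueError, match="hash"):
            mp.decode_stream(stream, zero_pipeline[2])

    def test_luminance_invariance_exact(self, default_spec, noisy_model,
                                        zero_pipeline, fixture_lib):
        stream = mp.simulate_stream(default_spec, noisy_model,
                                    fixture_lib["H"].script, seed=11)
        base = mp.decode_stream(stream, zero_pipeline[2])
        for k in (0.25, 0.5, 2.0, 4.0):
            other = mp.decode_stream(stream.scaled(k), zero_pipeline[2])
            assert len(other.responses) == len(base.responses)
            for ra, rb in zip(base.responses, other.responses):
                assert len(ra.strokes) == len(rb.strokes)
                for sa, sb in zip(ra.strokes, rb.strokes):
                    assert np.array_equal(sa.pixels, sb.pixels)

    def test_rmse_nondecreasing_in_noise(self, default_spec, zero_pipeline):
        # decoded-position RMSE against the scripted line, averaged over
        # 20 seeds, is monotone in the relative noise level
        lut = zero_pipeline[2]
        y0 = 30.0 + 16.5 * (140.0 / 32)   # mid-pixel row
        rmses = []
        for sigma in (0.0, 0.01, 0.02, 0.05):
            model = mp.SensorModel(rel_noise_sigma=sigma,
                                   luminance_walk_sigma=0.0)
            errs = []
            for seed in range(20):
                script = TrajectoryScript(
                    (PathSegment(((30.0, y0), (170.0, y0)), 2.0),))
                stream = mp.simulate_stream(default_spec, model, script, seed)
                for t, c in zip(stream.t, stream.counts):
                    px = lut.lookup(c / c.sum())
                    if px is not None:
                        errs.append(pixel_center_mm(lut, *px)[1] - y0)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert all(a <= b + 1e-12 for a, b in zip(rmses, rmses[1:]))


class TestMetrics:
    def test_straight_stroke_mean_speed(self, default_spec, zero_model,
                                        zero_pipeline):
        # 140 mm traversed in 2 s: script speed 70 mm/s.  The measured mean
        # is biased low by two structural effects, quantified by arithmetic:
        # pixel quantization trims half a pitch off each end of the decoded
        # path, and the causal 5-point average lags the stroke end by
        # (window-1)/2 samples' worth of travel.
        pitch = 140.0 / 32
        duration = 59 / 30.0                  # last sample before t = 2 s
        expected = (140.0 - pitch - 2 * (70.0 / 30.0)) / duration
        script = TrajectoryScript(
            (PathSegment(((30.0, 100.0), (170.0, 100.0)), 2.0),))
        stream = mp.simulate_stream(default_spec, zero_model, script)
        result = mp.decode_stream(stream, zero_pipeline[2])
        m = result.responses[0].metrics
        assert m.stroke_count == 1
        assert m.mean_speeds_mm_s[0] == pytest.approx(expected, rel=0.02)
        assert m.mean_speeds_mm_s[0] == pytest.approx(70.0, rel=0.06)

    def test_midstroke_dwell_yields_one_hesitation(self, default_spec,
                                                   zero_model, zero_pipeline,
                                                   fixture_lib):
        result = _decode_fixture("hesitation", default_spec, zero_model,
                                 zero_pipeline[2], fixture_lib)
        m = result.responses[0].metrics
        assert m.stroke_count == 1
        assert len(m.hesitations) == 1
        assert m.hesitations[0].duration_s >= 0.9

    def test_single_stroke_has_no_liftoffs(self, default_spec, zero_model,
                                           zero_pipeline, fixture_lib):
        result = _decode_fixture("c", default_spec, zero_model,
                                 zero_pipeline[2], fixture_lib)
        assert result.responses[0].metrics.liftoff_count == 0


class TestRender:
    def test_single_segment_raster(self, zero_pipeline):
        st = mp.Stroke(np.array([0.0, 0.1]),
                       np.array([[4, 4], [20, 20]]),
                       np.array([[50.0, 50.0], [120.0, 120.0]]))
        resp = mp.ResponseRecord([st], completed_at=0.1)
        img = render_response(resp, zero_pipeline[2], canvas_px=64)
        arr = np.asarray(img)
        assert (arr < 128).any()      # some ink on the canvas

    def test_rendering_is_deterministic(self, default_spec, zero_model,
                                        zero_pipeline, fixture_lib):
        result = _decode_fixture("T", default_spec, zero_model,
                                 zero_pipeline[2], fixture_lib)
        a = render_response(result.responses[0], zero_pipeline[2])
        b = render_response(result.responses[0], zero_pipeline[2])
        assert a.tobytes() == b.tobytes()

    def test_h_has_three_distinguishable_strokes(self, default_spec,
                                                 zero_model, zero_pipeline,
                                                 fixture_lib):
        # image-analysis oracle: per-stroke colors -> connected components
        from skimage.measure import label

        result = _decode_fixture("H", default_spec, zero_model,
                                 zero_pipeline[2], fixture_lib)
        img = render_response(result.responses[0], zero_pipeline[2],
                              canvas_px=256, color_by_stroke=True)
        arr = np.asarray(img)
        colors = {tuple(c) for c in arr.reshape(-1, 3)} - {(255, 255, 255)}
        assert len(colors) == 3
        for c in colors:
            mask = (arr == np.array(c)).all(axis=-1)
            # each stroke is a substantial, near-connected blob (later
            # strokes may overpaint a crossing, splitting an earlier one)
            assert mask.sum() > 20
            assert 1 <= label(mask).max() <= 2


class TestStraightedge:
    def test_zero_noise_centered_line_has_zero_dispersion(
            self, default_spec, zero_model, zero_pipeline):
        lut = zero_pipeline[2]
        pitch = 140.0 / 32
        y0 = 30.0 + 10.5 * pitch      # exactly on a pixel-row center
        script = TrajectoryScript(
            (PathSegment(((30.0, y0), (170.0, y0)), 4.0),))
        stream = mp.simulate_stream(default_spec, zero_model, script)
        ys = []
        for c in stream.counts:
            px = lut.lookup(c / c.sum())
            assert px is not None
            ys.append(pixel_center_mm(lut, *px)[1])
        assert np.std(ys) == 0.0

    def test_zero_noise_quantization_bound(self, default_spec, zero_model,
                                           zero_pipeline, rng):
        # Lines at uniform random offsets within a pixel: the decoded-minus-
        # true error is pure quantization noise.  Two lattices contribute:
        # the pixel grid (uniform width = pitch) and the chromaticity grid
        # (one 1/255 level corresponds to w mm through the channel slope;
        # two channels carry the y information).  Their interaction is
        # bounded by the root-sum of the uniform variances.
        lut = zero_pipeline[2]
        pitch = 140.0 / 32
        dchroma_dy = 0.88 * np.sqrt(3) / 2 / 405    # g/b slope per mm
        w = (1 / 255) / dchroma_dy
        bound = np.sqrt((pitch ** 2 + 2 * w ** 2) / 12)
        errs = []
        for _ in range(40):
            y0 = 30.0 + rng.uniform(5, 27) * pitch
            script = TrajectoryScript(
                (PathSegment(((35.0, y0), (165.0, y0)), 1.0),))
            stream = mp.simulate_stream(default_spec, zero_model, script)
            for c in stream.counts:
                px = lut.lookup(c / c.sum())
                errs.append(pixel_center_mm(lut, *px)[1] - y0)
        assert np.std(errs) <= bound * 1.05
        assert np.std(errs) <= pitch / 2          # never worse than half-pixel s.d.

    def test_default_noise_center_edge_report(self, default_spec, noisy_model,
                                              zero_pipeline):
        rep = mp.straightedge_experiment(default_spec, noisy_model,
                                         zero_pipeline[2], seed=0)
        assert rep["n_traversals"] == 10
        assert 0 < rep["central_sd_mm"] < rep["pixel_pitch_mm"]
        assert 0 < rep["outer_sd_mm"] < 2 * rep["pixel_pitch_mm"]
        for rec in rep["lines"]:
            assert "central_sd_mm" in rec and "outer_sd_mm" in rec
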