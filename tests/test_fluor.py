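"""Ratiometric quantification: ROI selection, medians, baseline, smoothing."""

import math
import statistics

import numpy as np
import pytest

from wormloop.fluor import (
    ROISpec,
    bin2x2,
    compute_trace,
    gfp_threshold,
    exceeds_control,
    locate_roi,
    quantify_frame,
    smooth_trace,
    split_dual_view,
)
from wormloop.synthetic import make_fluor_scene


def brute_force_quantify(green, red, center, spec):
    """Independent per-pixel oracle using plain Python loops."""
    roi_g, roi_r, ann_g, ann_r = [], [], [], []
    for r in range(green.shape[0]):
        for c in range(green.shape[1]):
            d = math.hypot(r - center[0], c - center[1])
            if d <= spec.radius:
                roi_g.append(float(green[r, c]))
                roi_r.append(float(red[r, c]))
            elif spec.bg_inner < d <= spec.bg_outer:
                ann_g.append(float(green[r, c]))
                ann_r.append(float(red[r, c]))
    k = math.ceil(spec.brightest_frac * len(roi_g))
    ig = statistics.median(sorted(roi_g, reverse=True)[:k])
    ir = statistics.median(sorted(roi_r, reverse=True)[:k])
    return ig, ir, statistics.median(ann_g), statistics.median(ann_r)


class TestLocateRoi:
    def test_finds_synthetic_spot(self):
        scene = make_fluor_scene(trace_params=(0.0, 1.0, 2.0, 0.0),
                                 noise_sd=0.0, n_frames=1, seed=0)
        center = locate_roi(scene.red[0], ROISpec())
        assert np.linalg.norm(np.array(center) - scene.neuron_tracks[0]) <= 1.0

    def test_window_limits_search_to_tracked_spot(self):
        img = np.zeros((128, 128))
        rr, cc = np.mgrid[:128, :128]
        img += 1000 * np.exp(-((rr - 30) ** 2 + (cc - 30) ** 2) / 18)  # bright
        img += 400 * np.exp(-((rr - 90) ** 2 + (cc - 96) ** 2) / 18)   # dim
        spec = ROISpec(search_radius=12)
        assert locate_roi(img, spec) == (30, 30)
        near_dim = locate_roi(img, spec, prev_center=(88, 94))
        assert np.linalg.norm(np.array(near_dim) - [90, 96]) <= 1.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (64, 64))
        spec = ROISpec(locator_sigma=2)
        assert locate_roi(img, spec) == locate_roi(img + 123.0, spec)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="no peak"):
            locate_roi(np.full((64, 64), 7.0), ROISpec())


class TestQuantifyFrame:
    def test_uniform_image(self):
        img = np.full((64, 64), 7.0)
        ig, ir, bg, br = quantify_frame(img, img, (32, 32), ROISpec())
        assert (ig, ir, bg, br) == (7.0, 7.0, 7.0, 7.0)

    def test_top_fraction_median_worked_example(self):
        # 5-pixel ROI {10,20,30,40,100}: top-2 = {40,100}, median 70
        img = np.zeros((16, 16))
        img[8, 8], img[7, 8], img[9, 8], img[8, 7], img[8, 9] = \
            100, 10, 20, 30, 40
        spec = ROISpec(radius=1.0, bg_inner=3.0, bg_outer=5.0,
                       brightest_frac=0.4)
        ig, _, bg, _ = quantify_frame(img, img, (8, 8), spec)
        assert ig == 70.0
        assert bg == 0.0

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 500, (64, 64))
        a = quantify_frame(img, img, (32, 32), ROISpec())
        b = quantify_frame(img * 3, img * 3, (32, 32), ROISpec())
        assert np.allclose(np.array(b), 3 * np.array(a))

    def test_edge_clip_rejected(self):
        img = np.zeros((64, 64))
        with pytest.raises(ValueError, match="clipped"):
            quantify_frame(img, img, (5, 32), ROISpec())

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        spec = ROISpec()
        for _ in range(10):
            g = rng.uniform(0, 4096, (64, 64))
            r = rng.uniform(0, 4096, (64, 64))
            center = (rng.uniform(25, 39), rng.uniform(25, 39))
            assert quantify_frame(g, r, center, spec) == \
                pytest.approx(brute_force_quantify(g, r, center, spec))


class TestSmoothTrace:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        assert np.allclose(smooth_trace(x), x)

    def test_impulse_conserved(self):
        x = np.zeros(201)
        x[100] = 1.0
        assert smooth_trace(x).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_convolution_and_noise_shrink(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 4000)
        sigma = 5.0
        half = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        direct = np.convolve(x, k, mode="same")
        smoothed = smooth_trace(x, sigma)
        assert np.allclose(smoothed[half:-half], direct[half:-half])
        shrink = smoothed[half:-half].std() / x.std()
        assert shrink == pytest.approx((4 * np.pi * sigma ** 2) ** -0.25,
                                       rel=0.10)

    def test_gaps_stay_gaps(self):
        x = np.ones(50)
        x[20:23] = np.nan
        out = smooth_trace(x)
        assert np.isnan(out[20:23]).all()
        assert np.allclose(out[~np.isnan(out)], 1.0)


class TestComputeTrace:
    def test_constant_stacks_zero_drr0(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(50, 500, (64, 64))
        frame[30, 32] = 4000  # a peak for the locator
        stack = np.repeat(frame[None], 600, axis=0)
        tr = compute_trace(stack, stack, baseline_window=(0, 15),
                           frame_rate=30.0)
        assert np.allclose(tr.dRR0[tr.valid], 0.0, atol=1e-12)

    def test_noiseless_scene_recovers_truth(self):
        scene = make_fluor_scene(trace_params=(1.0, 3.0, 10.0, 15.0),
                                 noise_sd=0.0, gain_jitter=0.2,
                                 n_frames=900, frame_rate=30.0, seed=5)
        tr = compute_trace(scene.green, scene.red,
                           baseline_window=(0, 15), frame_rate=30.0)
        raw = (tr.R - tr.R0) / tr.R0
        assert np.nanmax(np.abs(raw - scene.truth_trace)) <= 0.02
        assert np.nanmax(np.abs(tr.dRR0 - smooth_trace(scene.truth_trace))) \
            <= 0.02

    def test_common_gain_invariance_exact(self):
        rng = np.random.default_rng(6)
        frame = rng.uniform(50, 500, (64, 64))
        frame[30, 32] = 4000
        stack = np.repeat(frame[None], 500, axis=0)
        gamma = rng.uniform(0.8, 1.2, 500)
        jittered_g = stack * gamma[:, None, None]
        jittered_r = stack * gamma[:, None, None]
        a = compute_trace(stack, stack, baseline_window=(0, 15),
                          frame_rate=30.0)
        b = compute_trace(jittered_g, jittered_r, baseline_window=(0, 15),
                          frame_rate=30.0)
        assert np.allclose(a.R[a.valid], b.R[b.valid], atol=1e-9)

    def test_per_channel_constant_gain_leaves_drr0_unchanged(self):
        scene = make_fluor_scene(n_frames=500, frame_rate=30.0, seed=7)
        g = scene.green.astype(float)
        r = scene.red.astype(float)
        a = compute_trace(g, r, baseline_window=(0, 15), frame_rate=30.0)
        b = compute_trace(g * 2.0, r * 0.5, baseline_window=(0, 15),
                          frame_rate=30.0)
        assert np.allclose(b.R[b.valid], 4.0 * a.R[a.valid])
        assert np.array_equal(np.nan_to_num(a.dRR0), np.nan_to_num(b.dRR0))

    def test_short_baseline_rejected(self):
        stack = np.zeros((100, 64, 64))
        with pytest.raises(ValueError, match="baseline"):
            compute_trace(stack, stack, baseline_window=(0, 10),
                          frame_rate=30.0)

    def test_bin2x2_mean(self):
        stack = np.arange(2 * 4 * 4, dtype=float).reshape(2, 4, 4)
        binned = bin2x2(stack)
        assert binned.shape == (2, 2, 2)
        assert binned[0, 0, 0] == stack[0, :2, :2].mean()

    def test_split_dual_view(self):
        stack = np.zeros((3, 8, 10))
        g, r = split_dual_view(stack, 6)
        assert g.shape == (3, 8, 6) and r.shape == (3, 8, 4)


class TestGfpThreshold:
    def _trace(self, dRR0):
        from wormloop.fluor import RatioTrace

        n = len(dRR0)
        z = np.zeros(n)
        return RatioTrace(time_s=np.arange(n) / 30.0, I_green=z, I_red=z,
                          B_green=z, B_red=z, R=z, R0=1.0,
                          dRR0=np.asarray(dRR0, float),
                          valid=np.ones(n, bool))

    def test_all_zero_controls(self):
        tr = self._trace(np.zeros(300))
        mean, sd, thr = gfp_threshold([tr], [[(0.0, 9.0)]])
        assert (mean, sd, thr) == (0.0, 0.0, 0.0)
        assert exceeds_control(self._trace(np.full(300, 0.1)), (0, 9), thr)

    def test_gaussian_null_threshold(self):
        rng = np.random.default_rng(8)
        tr = self._trace(rng.normal(0, 0.1, 10_000))
        _, _, thr = gfp_threshold([tr], [[(0.0, 400.0)]])
        assert thr == pytest.approx(0.1, rel=0.05)

    def test_control_does_not_exceed_itself(self):
        rng = np.random.default_rng(9)
        tr = self._trace(rng.normal(0, 0.05, 2000))
        _, _, thr = gfp_threshold([tr], [[(0.0, 60.0)]])
        assert not exceeds_control(tr, (0.0, 60.0), thr)

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError):
            gfp_threshold([self._trace(np.zeros(10))], [[]])
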