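"""Region geometry, mask rasterisation, DMD warping and the latency loop."""

import numpy as np
import pytest

from wormloop.synthetic import (
    SyntheticScene,
    WormPosture,
    make_behavior_scene,
    render_silhouette,
)
from wormloop.targeting import (
    DMD_SHAPE,
    BodyRegion,
    StimulusPlan,
    builtin_regions,
    check_separation,
    fit_affine,
    from_dmd,
    mask_iou,
    region_mask,
    run_closed_loop,
    to_dmd,
)
from wormloop.vision import pixel_to_body


def brute_force_region_mask(posture, region, frame_shape, silhouette):
    """Per-pixel oracle: body-coordinate membership test for every
    silhouette pixel."""
    mask = np.zeros(frame_shape, dtype=bool)
    for r, c in zip(*np.nonzero(silhouette)):
        bc = pixel_to_body(posture, (r, c))
        mask[r, c] = region.contains(bc.s, bc.w)
    return mask


class TestBuiltinRegions:
    def test_interval_geometry(self):
        by_name = {r.name: r for r in builtin_regions()}
        assert by_name["AVA"].s_interval == pytest.approx((0.05, 0.15))
        assert by_name["AVM"].s_interval == pytest.approx((0.29, 0.42))
        assert by_name["AVA"].s_interval[1] < by_name["AVM"].s_interval[0]

    def test_avm_alm_same_size_different_center(self):
        by_name = {r.name: r for r in builtin_regions()}
        avm, alm = by_name["AVM"], by_name["ALM"]
        assert (avm.length_frac, avm.width_frac) == \
            (alm.length_frac, alm.width_frac)
        assert alm.center_s == pytest.approx(0.425)
        assert alm.center_w == pytest.approx(1.0 - avm.center_w)


class TestRegionMask:
    def test_area_matches_analytic_sector(self, straight_posture):
        # AVA on a straight worm: ribbon sector area = width_frac *
        # integral of the full width over the s-interval
        ava = builtin_regions()[0]
        mask = region_mask(straight_posture, ava, (256, 256))
        s = np.linspace(*ava.s_interval, 200)
        from wormloop.synthetic import width_profile

        L = straight_posture.length_px
        analytic = ava.width_frac * np.trapezoid(
            2 * width_profile(s, 10.0), s * L)
        assert mask.sum() == pytest.approx(analytic, rel=0.15)

    def test_full_region_equals_silhouette(self, straight_posture):
        sil = render_silhouette(straight_posture, (256, 256))
        full = BodyRegion("full", 0.5, 0.5, 1.0, 1.0)
        assert np.array_equal(
            region_mask(straight_posture, full, (256, 256), silhouette=sil),
            sil)

    def test_ava_avm_masks_disjoint(self, straight_posture):
        ava, avm, _ = builtin_regions()
        m1 = region_mask(straight_posture, ava, (256, 256))
        m2 = region_mask(straight_posture, avm, (256, 256))
        assert not (m1 & m2).any()

    def test_matches_brute_force_oracle(self, straight_posture):
        sil = render_silhouette(straight_posture, (256, 256))
        for region in builtin_regions():
            mask = region_mask(straight_posture, region, (256, 256),
                               silhouette=sil)
            oracle = brute_force_region_mask(straight_posture, region,
                                             (256, 256), sil)
            # boundary pixels may differ between the two rasterisation rules
            assert mask_iou(mask, oracle) >= 0.85
            assert abs(int(mask.sum()) - int(oracle.sum())) \
                <= 0.15 * oracle.sum()

    def test_invalid_posture_gives_empty_mask(self):
        mask = region_mask(None, builtin_regions()[0], (64, 64))
        assert not mask.any()


class TestDmdWarp:
    def test_identity_affine_is_noop(self):
        mask = np.zeros(DMD_SHAPE, bool)
        mask[100:200, 300:450] = True
        assert np.array_equal(to_dmd(mask, np.eye(3)), mask)

    def test_translation_equivariance(self):
        mask = np.zeros(DMD_SHAPE, bool)
        mask[100:150, 300:350] = True
        aff = np.eye(3)
        aff[0, 2], aff[1, 2] = 5.0, 7.0
        from scipy.ndimage import center_of_mass

        shift = (np.array(center_of_mass(to_dmd(mask, aff)))
                 - np.array(center_of_mass(mask)))
        assert np.allclose(shift, [5.0, 7.0], atol=1e-9)

    def test_disk_round_trip_iou(self):
        mask = np.zeros(DMD_SHAPE, bool)
        rr = np.arange(DMD_SHAPE[0])[:, None]
        cc = np.arange(DMD_SHAPE[1])[None, :]
        mask[(rr - 200) ** 2 + (cc - 300) ** 2 <= 40 ** 2] = True
        aff = np.diag([2.0, 2.0, 1.0])
        back = from_dmd(to_dmd(mask, aff), aff, DMD_SHAPE)
        assert mask_iou(back, mask) >= 0.95

    def test_singular_affine_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            to_dmd(np.zeros(DMD_SHAPE, bool), np.zeros((3, 3)))

    def test_fit_affine_recovers_transform(self):
        true = np.array([[1.1, 0.1, 5.0], [-0.05, 0.9, -3.0], [0, 0, 1]])
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 500, (5, 2))
        dst = (true[:2, :2] @ src.T).T + true[:2, 2]
        assert np.allclose(fit_affine(src, dst), true, atol=1e-9)


class TestStimulusPlan:
    def test_onset_before_min_imaging_rejected(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            StimulusPlan(onset_s=10.0, min_pre_imaging_s=15.0)

    def test_stimulus_window_closed_interval(self):
        plan = StimulusPlan(onset_s=15.0, duration_s=2.7)
        assert plan.stimulus_active(15.0)
        assert plan.stimulus_active(17.7)
        assert not plan.stimulus_active(14.99)
        assert not plan.stimulus_active(17.71)


def _plan(**kw):
    ava, avm, alm = builtin_regions()
    defaults = dict(imaging_regions=[ava], stimulus_regions=[avm, alm],
                    onset_s=0.5, duration_s=0.4, min_pre_imaging_s=0.0)
    defaults.update(kw)
    return StimulusPlan(**defaults)


class TestClosedLoop:
    def test_latency_is_noop_for_static_worm(self):
        scene = make_behavior_scene(n_frames=8, frame_rate=30.0,
                                    locomotion_schedule=[(0.0, 1.0)], seed=4)
        m0, _ = run_closed_loop(scene, _plan(), latency_frames=0)
        m3, _ = run_closed_loop(scene, _plan(), latency_frames=3)
        for a, b in zip(m0, m3):
            assert mask_iou(a.camera_mask, b.camera_mask) == 1.0

    def test_stimulus_masks_empty_outside_window(self):
        scene = make_behavior_scene(n_frames=45, frame_rate=30.0,
                                    locomotion_schedule=[(0.3, 2.0)], seed=5)
        _, log = run_closed_loop(scene, _plan(), latency_frames=0)
        stim = log[log.region.isin(["AVM", "ALM"])]
        before = stim[stim.time_s < 0.5]
        after = stim[stim.time_s > 0.9]
        assert (before.area_px == 0).all() and (~before.active).all()
        assert (after.area_px == 0).all() and (~after.active).all()

    def test_masks_within_segmented_silhouette(self):
        scene = make_behavior_scene(n_frames=20, frame_rate=30.0,
                                    locomotion_schedule=[(0.3, 1.0)], seed=6)
        from wormloop.vision import segment_stack
        from conftest import ventral_hint_point

        truth0 = scene.truth_postures[0]
        segs = segment_stack(scene.frames, head_hint=truth0.centerline[0],
                             ventral_hint=ventral_hint_point(truth0))
        k = 2
        masks, _ = run_closed_loop(scene, _plan(), latency_frames=k,
                                   segmentations=segs)
        for t, m in enumerate(masks):
            src = segs[max(0, t - k)]
            if src.ok:
                assert not (m.camera_mask & ~src.mask).any()
            else:
                assert not m.camera_mask.any()

    def test_iou_non_increasing_with_latency_for_translation(self):
        scene = make_behavior_scene(
            n_frames=25, frame_rate=30.0,
            locomotion_schedule=[(0.0, 1.0)], seed=7,
            drift_px_per_frame=(0.8, 0.8))
        means = []
        for k in (0, 2, 4):
            _, log = run_closed_loop(scene, _plan(), latency_frames=k)
            means.append(log[log.active].iou.mean())
        assert means[0] >= means[1] >= means[2]

    def test_negative_latency_rejected(self):
        scene = make_behavior_scene(n_frames=3, seed=0)
        with pytest.raises(ValueError):
            run_closed_loop(scene, _plan(), latency_frames=-1)


class TestCheckSeparation:
    def test_disjoint_regions_no_overlap_positive_gap(self, straight_posture):
        ava, avm, _ = builtin_regions()
        report = check_separation(straight_posture, [ava, avm], (256, 256))
        row = report.iloc[0]
        assert row.overlap_px == 0
        assert row.min_gap_px > 0
        assert row.min_gap_um == pytest.approx(row.min_gap_px * 0.62)

    def test_identical_regions_full_overlap(self, straight_posture):
        ava = builtin_regions()[0]
        twin = BodyRegion("AVA2", ava.center_s, ava.center_w,
                          ava.length_frac, ava.width_frac)
        report = check_separation(straight_posture, [ava, twin], (256, 256))
        mask = region_mask(straight_posture, ava, (256, 256))
        assert report.iloc[0].overlap_px == mask.sum()
        assert report.iloc[0].min_gap_px == 0

    def test_avm_alm_overlap_matches_brute_force(self, straight_posture):
        _, avm, alm = builtin_regions()
        sil = render_silhouette(straight_posture, (256, 256))
        report = check_separation(straight_posture, [avm, alm], (256, 256))
        brute = (brute_force_region_mask(straight_posture, avm, (256, 256), sil)
                 & brute_force_region_mask(straight_posture, alm, (256, 256),
                                           sil))
        # the s-intervals overlap by construction; both rasterisations must
        # agree on the overlap size up to boundary pixels
        assert report.iloc[0].overlap_px == \
            pytest.approx(brute.sum(), abs=0.15 * brute.sum() + 5)
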