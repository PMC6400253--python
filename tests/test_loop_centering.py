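"""Loop search, tip centering, face-angle fitting and raster-area definition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microzoo import loop_centering as lc
from microzoo import virtual_beamline as vb


def noise_free_sample(phi=30.0):
    return vb.make_sample(
        loop=vb.LoopTruth(plane_normal_angle=phi, outer_radius=250.0,
                          inner_radius=190.0),
        noise_level=0.0)


def make_binary(mask, pixel_size=5.0, omega=0.0):
    shape = mask.shape
    bc = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return lc.BinaryImage(mask=mask, pixel_size=pixel_size, beam_center=bc,
                          omega=omega, blur_sigma=0.0, threshold=0.0)


class TestBinarize:
    def test_image_equal_to_background_all_false(self, camera):
        sample = noise_free_sample()
        img = vb.capture_image(sample, 0.0, camera)
        assert not lc.binarize(img, img).mask.any()

    def test_threshold_above_max_all_false(self, camera):
        sample = noise_free_sample()
        img = vb.capture_image(sample, 0.0, camera)
        bg = vb.capture_image(vb.VirtualSample(loop=None, noise_level=0.0),
                              0.0, camera)
        b = lc.binarize(img, bg, threshold=1e9)
        assert not b.mask.any()

    def test_mask_matches_ground_truth_silhouette(self, camera):
        sample = noise_free_sample()
        img = vb.capture_image(sample, 0.0, camera)
        bg = vb.capture_image(vb.VirtualSample(loop=None, noise_level=0.0),
                              0.0, camera)
        got = lc.binarize(img, bg).mask
        truth = vb.silhouette_mask(sample, 0.0, camera)
        jaccard = (got & truth).sum() / (got | truth).sum()
        assert jaccard >= 0.95

    def test_shape_mismatch_rejected(self, camera):
        sample = noise_free_sample()
        img = vb.capture_image(sample, 0.0, camera)
        other = vb.capture_image(sample, 0.0,
                                 vb.Camera(shape=(128, 128), pixel_size=4.0))
        with pytest.raises(ValueError, match="shape"):
            lc.binarize(img, other)


class TestSearchLoop:
    def test_loop_in_view_found_without_translation(self, camera):
        g = vb.VirtualGoniometer(noise_free_sample(), camera, seed=0)
        found, shift = lc.search_loop(g, g.background(0.0))
        assert found and shift == 0.0

    def test_displaced_loop_found_after_one_step(self, camera):
        g = vb.VirtualGoniometer(noise_free_sample(), camera, seed=0)
        width = camera.width_um
        g.offset[2] = 1.2 * width  # pin retracted: loop out of view right
        found, shift = lc.search_loop(g, g.background(0.0))
        assert found
        assert abs(shift) == pytest.approx(1.5 * width)

    def test_empty_holder_not_found_after_two_translations(self, camera):
        g = vb.VirtualGoniometer(vb.VirtualSample(loop=None), camera, seed=0)
        found, shift = lc.search_loop(g, g.background(0.0))
        assert not found
        assert abs(shift) == pytest.approx(2 * 1.5 * camera.width_um)


class TestCenterTip:
    def test_already_centered_zero_translation(self, camera):
        sample = noise_free_sample(phi=0.0)
        g = vb.VirtualGoniometer(sample, camera, seed=0)
        bg = g.background(0.0)
        lc.center_tip(g, bg)               # converge once
        first = g.offset.copy()
        res = lc.center_tip(g, bg)         # fixed point
        assert np.linalg.norm(res.translation) <= 2 * camera.pixel_size
        assert np.allclose(g.offset, first, atol=2 * camera.pixel_size)

    def test_known_offset_recovered(self, camera):
        sample = noise_free_sample(phi=20.0)
        g = vb.VirtualGoniometer(sample, camera, seed=0)
        bg = g.background(0.0)
        lc.center_tip(g, bg)
        g.offset[2] += 30.0   # displace tip horizontally by 30 um
        g.offset[1] += -20.0  # and vertically by -20 um (omega 0)
        lc.center_tip(g, bg)
        tip = g.stage_position(sample.loop.tip_position)
        assert abs(tip[2]) <= camera.pixel_size
        assert abs(tip[1]) <= camera.pixel_size
        assert abs(tip[0]) <= 2 * camera.pixel_size

    def test_deterministic(self, camera):
        offsets = []
        for _ in range(2):
            g = vb.VirtualGoniometer(noise_free_sample(), camera, seed=9)
            lc.center_tip(g, g.background(0.0))
            offsets.append(g.offset.copy())
        assert np.array_equal(offsets[0], offsets[1])

    def test_empty_mask_raises(self, camera):
        g = vb.VirtualGoniometer(vb.VirtualSample(loop=None, noise_level=0.0),
                                 camera, seed=0)
        with pytest.raises(lc.EmptyMaskError):
            lc.center_tip(g, g.background(0.0))


class TestFindFaceAngle:
    def test_closed_form_cosine_inversion(self):
        # A=1000, B=300, maximum at 30 deg -> minimum 120 -> face 30
        angles = (0.0, 45.0, 90.0, 135.0)
        counts = [1000 + 300 * np.cos(2 * np.deg2rad(a - 30.0))
                  for a in angles]
        assert lc.find_face_angle(counts) == pytest.approx(30.0, abs=1e-9)

    def test_symmetric_counts_minimum_at_45(self):
        assert lc.find_face_angle([800, 500, 800, 1100]) == pytest.approx(135.0)

    def test_matches_dense_grid_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        angles = np.array([0.0, 45.0, 90.0, 135.0])
        for _ in range(20):
            a0 = rng.uniform(500, 2000)
            b0 = rng.uniform(50, 400)
            phi0 = rng.uniform(0, 180)
            counts = a0 + b0 * np.cos(2 * np.deg2rad(angles - phi0))
            counts += rng.normal(0, 5, size=4)
            counts = np.clip(counts, 0, None)
            # oracle: dense scan of the fitted model's minimising angle
            th = np.deg2rad(angles)
            design = np.column_stack([np.ones(4), np.cos(2 * th),
                                      np.sin(2 * th)])
            coef, *_ = np.linalg.lstsq(design, counts, rcond=None)
            grid = np.linspace(0, 180, 360001)
            model = coef[0] + coef[1] * np.cos(2 * np.deg2rad(grid)) \
                + coef[2] * np.sin(2 * np.deg2rad(grid))
            oracle = (grid[int(np.argmin(model))] + 90.0) % 180.0
            got = lc.find_face_angle(counts)
            delta = abs(got - oracle) % 180
            assert min(delta, 180 - delta) < 0.01

    def test_recovers_ground_truth_face_angle(self, camera):
        sample = noise_free_sample(phi=107.0)  # truth face = 73 deg
        g = vb.VirtualGoniometer(sample, camera, seed=0)
        bg = g.background(0.0)
        lc.center_tip(g, bg)
        counts = lc.silhouette_counts(g, bg)
        got = lc.find_face_angle(counts)
        delta = abs(got - 73.0) % 180
        assert min(delta, 180 - delta) <= 3.0

    def test_degenerate_counts_rejected(self):
        with pytest.raises(lc.DegenerateSilhouetteError):
            lc.find_face_angle([500, 500, 500, 500])
        with pytest.raises(ValueError):
            lc.find_face_angle([100, -5, 100, 100])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=100.0),
           phi=st.floats(min_value=0.0, max_value=179.0))
    def test_scale_invariance(self, scale, phi):
        angles = np.array([0.0, 45.0, 90.0, 135.0])
        counts = 1000 + 300 * np.cos(2 * np.deg2rad(angles - phi))
        a = lc.find_face_angle(counts)
        b = lc.find_face_angle(scale * counts)
        delta = abs(a - b) % 180
        assert min(delta, 180 - delta) < 1e-6


class TestDefineRasterArea:
    def test_exact_ceil_division(self):
        mask = np.zeros((100, 160), dtype=bool)
        mask[10:70, 20:140] = True   # 60 x 120 px = 300 x 600 um at 5 um/px
        area = lc.define_raster_area(make_binary(mask), beam=(10.0, 15.0))
        assert (area.n_h, area.n_v) == (60, 20)

    def test_ceil_rounds_up_on_remainder(self):
        mask = np.zeros((101, 161), dtype=bool)
        # 605 x 301 um at 5 um/px -> 121 x 61 px (prime-ish remainders)
        mask[10:70, 20:141] = True
        mask[70, 20] = True  # one extra row pixel -> 305 um height
        area = lc.define_raster_area(make_binary(mask), beam=(10.0, 15.0))
        assert area.n_h == 61       # ceil(605 / 10)
        assert area.n_v == 21       # ceil(305 / 15)

    def test_single_pixel_gives_1x1_grid_at_that_pixel(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[40, 70] = True
        b = make_binary(mask)
        area = lc.define_raster_area(b, beam=(10.0, 15.0))
        assert (area.n_h, area.n_v) == (1, 1)
        y, z = area.grid_lab()
        assert z[0, 0] == pytest.approx((70 - b.beam_center[1]) * 5.0, abs=5.0)
        assert y[0, 0] == pytest.approx((b.beam_center[0] - 40) * 5.0, abs=7.5)

    def test_user_loop_size_clips_from_tip(self):
        mask = np.zeros((100, 160), dtype=bool)
        mask[10:70, 20:140] = True
        area = lc.define_raster_area(make_binary(mask), beam=(10.0, 15.0),
                                     user_loop_size=400.0)
        assert area.n_h == 40
        full = lc.define_raster_area(make_binary(mask), beam=(10.0, 15.0))
        assert area.origin_z == full.origin_z  # clip keeps the tip side

    def test_area_covers_every_true_pixel(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mask = np.zeros((80, 120), dtype=bool)
            r0, c0 = rng.integers(0, 40), rng.integers(0, 60)
            mask[r0:r0 + rng.integers(1, 40), c0:c0 + rng.integers(1, 60)] = True
            b = make_binary(mask)
            area = lc.define_raster_area(b, beam=(10.0, 15.0))
            rows, cols = np.nonzero(mask)
            z_lo = (cols.min() - 0.5 - b.beam_center[1]) * b.pixel_size
            z_hi = (cols.max() + 0.5 - b.beam_center[1]) * b.pixel_size
            y_hi = (b.beam_center[0] - rows.min() + 0.5) * b.pixel_size
            y_lo = (b.beam_center[0] - rows.max() - 0.5) * b.pixel_size
            assert area.origin_z - area.step_h / 2 <= z_lo + 1e-9
            assert area.origin_z + (area.n_h - 0.5) * area.step_h >= z_hi - 1e-9
            assert area.origin_y_lab + area.step_v / 2 >= y_hi - 1e-9
            assert area.origin_y_lab - (area.n_v - 0.5) * area.step_v <= y_lo + 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(lc.EmptyMaskError):
            lc.define_raster_area(make_binary(np.zeros((64, 64), bool)),
                                  beam=(10.0, 15.0))


class TestEndToEnd:
    def test_centering_recovers_truth_on_random_samples(self, camera):
        """Five random noise-free loops: tip and face angle recovered."""
        for seed in range(5):
            sample = vb.make_random_sample(seed)
            sample = vb.VirtualSample(loop=sample.loop,
                                      crystals=sample.crystals,
                                      noise_level=0.0)
            g = vb.VirtualGoniometer(sample, camera, seed=seed)
            res, area = lc.center_loop(g, g.background(0.0),
                                       beam=(10.0, 15.0))
            assert res.converged
            tip = g.stage_position(sample.loop.tip_position)
            assert abs(tip[2]) <= 10.0
            assert abs(tip[1]) <= 15.0
            delta = abs(res.face_angle - sample.loop.face_angle) % 180
            assert min(delta, 180 - delta) <= 3.0
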