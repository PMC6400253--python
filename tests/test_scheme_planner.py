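"""Crystal segmentation, mixed-scheme categorisation and scan planning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from microzoo import scheme_planner as sp
from microzoo import virtual_beamline as vb
from microzoo import loop_centering as lc
from microzoo import spot_finding as sf

from conftest import simple_heatmap


def region_from_boxes(boxes, step_h=10.0, step_v=15.0, shape=(30, 70)):
    """Build regions by painting score boxes on a synthetic heat map."""
    scores = np.zeros(shape, dtype=int)
    for (r0, r1, c0, c1), val in boxes:
        scores[r0:r1 + 1, c0:c1 + 1] = val
    hm = simple_heatmap(scores, step_h=step_h, step_v=step_v)
    return sp.segment_crystals(hm, 15.0)


class TestSegmentCrystals:
    def test_two_blobs_match_cc_labeling_oracle(self):
        scores = np.zeros((8, 12), dtype=int)
        scores[1:3, 1:4] = 40
        scores[5:7, 6:10] = 30
        scores[3, 5] = 10  # sub-threshold separator
        hm = simple_heatmap(scores)
        regions = sp.segment_crystals(hm, 15.0)
        labels, n = ndimage.label(scores > 15, structure=np.ones((3, 3)))
        assert len(regions) == n == 2
        oracle_members = {frozenset(zip(*np.nonzero(labels == k)))
                          for k in range(1, n + 1)}
        assert {r.members for r in regions} == oracle_members

    def test_random_maps_equal_cc_labeling(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            scores = rng.integers(0, 40, size=(10, 14))
            hm = simple_heatmap(scores)
            regions = sp.segment_crystals(hm, 15.0)
            labels, n = ndimage.label(scores > 15, structure=np.ones((3, 3)))
            assert len(regions) == n
            oracle = {frozenset(zip(*map(lambda a: a.tolist(),
                                         np.nonzero(labels == k))))
                      for k in range(1, n + 1)}
            assert {r.members for r in regions} == oracle

    def test_uniform_below_threshold_no_regions(self):
        hm = simple_heatmap(np.full((5, 5), 10))
        assert sp.segment_crystals(hm, 15.0) == []

    def test_single_grid_region(self):
        scores = np.zeros((5, 5), dtype=int)
        scores[2, 3] = 99
        regions = sp.segment_crystals(simple_heatmap(scores), 15.0)
        assert len(regions) == 1
        assert regions[0].members == frozenset({(2, 3)})
        assert regions[0].size_along_axis == pytest.approx(10.0)

    def test_ordered_by_descending_peak(self):
        scores = np.zeros((6, 12), dtype=int)
        scores[0, 0] = 20
        scores[3, 5] = 90
        scores[5, 10] = 50
        regions = sp.segment_crystals(simple_heatmap(scores), 15.0)
        assert [r.peak_score for r in regions] == [90, 50, 20]


class TestRegionEdges:
    def test_horizontal_run(self):
        scores = np.zeros((3, 10), dtype=int)
        scores[1, 3:8] = 30
        region = sp.segment_crystals(simple_heatmap(scores), 15.0)[0]
        left, right = sp.region_edges(region)
        assert left == (1, 3) and right == (1, 7)

    def test_l_shape_matches_exhaustive_min_max(self):
        scores = np.zeros((6, 10), dtype=int)
        scores[1:5, 2] = 30
        scores[4, 2:7] = 40
        region = sp.segment_crystals(simple_heatmap(scores), 15.0)[0]
        left, right = sp.region_edges(region)
        cols = [m[1] for m in region.members]
        assert left[1] == min(cols) and right[1] == max(cols)

    def test_single_grid(self):
        scores = np.zeros((3, 3), dtype=int)
        scores[1, 1] = 40
        region = sp.segment_crystals(simple_heatmap(scores), 15.0)[0]
        assert sp.region_edges(region) == ((1, 1), (1, 1))


class TestHelicalScanAngles:
    @pytest.mark.parametrize("total,face,expected", [
        (40.0, 0.0, (-20.0, 20.0)),
        (360.0, 0.0, (-90.0, 90.0)),
        (0.2, 57.0, (56.9, 57.1)),
        (200.0, 30.0, (-60.0, 120.0)),
    ])
    def test_wedge_angles(self, total, face, expected):
        got = sp.helical_scan_angles(total, face)
        assert got == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sp.helical_scan_angles(0.0, 10.0)


class TestLocateEdge3D:
    def test_recovers_depth_offset(self):
        crystal = vb.CrystalTruth((12.0, 0.0, 100.0), (5.0, 10.0, 20.0), 50.0)
        sample = vb.VirtualSample(loop=None, crystals=(crystal,))
        face = 0.0
        omega = face + 90.0
        edge = np.array([0.0, 0.0, 85.0])
        offsets = (np.arange(17) - 8) * 5.0
        pts = edge + offsets[:, None] * np.array([np.sin(np.deg2rad(omega)),
                                                  np.cos(np.deg2rad(omega)),
                                                  0.0])
        scores = vb.raster_response(sample, pts, omega, (2.0, 5.0))
        got = sp.locate_edge_3d(edge, omega, scores, 5.0, offsets=offsets,
                                threshold=1.0)
        assert abs(got[0] - 12.0) <= 5.0

    def test_symmetric_response_takes_lower_index(self):
        got = sp.locate_edge_3d((0.0, 0.0, 0.0), 0.0, [0, 5, 5, 0], 5.0)
        assert got[1] == pytest.approx(-2.5)

    def test_all_zero_response_raises(self):
        with pytest.raises(sp.EdgeNotFoundError):
            sp.locate_edge_3d((0.0, 0.0, 0.0), 0.0, [0, 0, 0], 5.0)


class TestCategorize:
    def test_fig4_style_layout(self):
        # isolated in-range crystal, two separated overlappers, a tight pair,
        # a tiny crystal and an oversized one
        regions = region_from_boxes([
            ((0, 1, 1, 6), 40),     # A: isolated, 60 um -> full
            ((6, 7, 10, 17), 40),   # B: overlaps C, gap 4 rows -> partial
            ((13, 14, 12, 19), 40),  # C: partial
            ((20, 21, 30, 35), 40),  # D: tight pair with E -> clustered
            ((23, 24, 32, 37), 40),  # E: clustered
            ((27, 27, 14, 14), 40),  # F: overlaps B/C? no; isolated 10 um -> small
            ((28, 29, 40, 55), 40),  # G: isolated 160 um -> clustered by size
        ])
        cats = {tuple(sorted(a.region.members))[0]: a.category
                for a in sp.categorize(regions, sp.MixedParams())}
        by_anchor = {k[0:2]: v for k, v in cats.items()}
        assert by_anchor[(0, 1)] == sp.Category.HELICAL_FULL
        assert by_anchor[(6, 10)] == sp.Category.PARTIAL_HELICAL
        assert by_anchor[(13, 12)] == sp.Category.PARTIAL_HELICAL
        assert by_anchor[(20, 30)] == sp.Category.CLUSTERED
        assert by_anchor[(23, 32)] == sp.Category.CLUSTERED
        assert by_anchor[(27, 14)] == sp.Category.SMALL_WEDGE
        assert by_anchor[(28, 40)] == sp.Category.CLUSTERED

    def test_gap_below_multiplier_clusters_both(self):
        # two crystals overlapping along z with 2 rows (= 2 beam heights) gap
        regions = region_from_boxes([
            ((0, 0, 0, 4), 40),
            ((3, 3, 2, 6), 40),
        ])
        cats = [a.category for a in sp.categorize(regions, sp.MixedParams())]
        assert cats == [sp.Category.CLUSTERED, sp.Category.CLUSTERED]

    def test_isolated_in_range_is_full(self):
        regions = region_from_boxes([((2, 3, 5, 9), 40)])
        asg, = sp.categorize(regions, sp.MixedParams())
        assert asg.category == sp.Category.HELICAL_FULL

    def test_every_region_gets_exactly_one_category(self):
        rng = np.random.default_rng(23)
        scores = rng.integers(0, 40, size=(12, 20))
        hm = simple_heatmap(scores)
        regions = sp.segment_crystals(hm, 15.0)
        asgs = sp.categorize(regions, sp.MixedParams())
        assert len(asgs) == len(regions)
        assert all(isinstance(a.category, sp.Category) for a in asgs)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(29)
        scores = rng.integers(0, 40, size=(12, 20))
        regions = sp.segment_crystals(simple_heatmap(scores), 15.0)
        base = {a.region.members: a.category
                for a in sp.categorize(regions, sp.MixedParams())}
        for seed in range(5):
            perm = list(regions)
            np.random.default_rng(seed).shuffle(perm)
            got = {a.region.members: a.category
                   for a in sp.categorize(perm, sp.MixedParams())}
            assert got == base


class TestSplitClustered:
    def test_full_block_anchored_at_corner(self):
        scores = np.zeros((6, 6), dtype=int)
        scores[0:4, 0:4] = 30
        scores[0, 0] = 90  # best grid at the corner
        region = sp.segment_crystals(simple_heatmap(scores), 15.0)[0]
        assert sp.split_clustered(region) == [(0, 0), (0, 2), (2, 0), (2, 2)]

    def test_single_grid(self):
        scores = np.zeros((3, 3), dtype=int)
        scores[1, 2] = 30
        region = sp.segment_crystals(simple_heatmap(scores), 15.0)[0]
        assert sp.split_clustered(region) == [(1, 2)]

    def test_row_anchored_at_best(self):
        scores = np.zeros((3, 6), dtype=int)
        scores[1, 0:5] = 30
        scores[1, 2] = 90
        region = sp.segment_crystals(simple_heatmap(scores), 15.0)[0]
        assert sp.split_clustered(region) == [(1, 0), (1, 2), (1, 4)]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10 ** 6))
    def test_picks_nonadjacent_members(self, seed):
        rng = np.random.default_rng(seed)
        scores = (rng.random((8, 10)) < 0.45).astype(int) * 30
        regions = sp.segment_crystals(simple_heatmap(scores), 15.0)
        for region in regions:
            picks = sp.split_clustered(region)
            assert set(picks) <= region.members
            assert region.best in picks
            for a in picks:
                for b in picks:
                    if a != b:
                        assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1


class TestPlanSSROX:
    @pytest.mark.parametrize("h,step,osc,frames,total", [
        (600.0, 10.0, 1.0, 60, 60.0),
        (10.0, 10.0, 1.0, 1, 1.0),
        (605.0, 10.0, 0.5, 61, 30.5),
    ])
    def test_frames_and_oscillation(self, h, step, osc, frames, total):
        plan = sp.plan_ssrox(h, 300.0, step, osc, 15.0)
        assert plan.frames_per_line == frames
        assert plan.total_osc_per_line == pytest.approx(total)

    def test_lines_tile_vertical_extent(self):
        plan = sp.plan_ssrox(600.0, 310.0, 10.0, 1.0, 15.0)
        assert plan.n_lines == 21
        assert plan.line_positions[0] == pytest.approx(7.5)
        assert plan.n_lines * 15.0 >= 310.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sp.plan_ssrox(0.0, 300.0, 10.0, 1.0, 15.0)


class TestHelicalVectorRecovery:
    def test_endpoints_within_one_grid_step(self, camera):
        for seed in (3, 7, 11):
            sample = vb.make_random_sample(seed, 1)
            gonio = vb.VirtualGoniometer(sample, camera, seed=seed)
            res, area = lc.center_loop(gonio, gonio.background(0.0),
                                       beam=(10.0, 15.0))
            pts = area.grid_centers_stage().reshape(-1, 3)
            scores = gonio.response(pts, res.face_angle, (10.0, 15.0),
                                    noise=False)
            hm = sf.assemble_heatmap(np.rint(scores).astype(int), area)
            region = sp.segment_crystals(hm, 15.0)[0]
            vec = sp.plan_helical_vector(
                region, res.face_angle, 360.0,
                lambda p, om: gonio.response(p, om, (2.0, 5.0), noise=False),
                threshold=1.0)
            crystal = sample.crystals[0]
            lo = np.asarray(crystal.center) - [0, 0, crystal.half_extents[2]]
            hi = np.asarray(crystal.center) + [0, 0, crystal.half_extents[2]]
            t_start = gonio.stage_position(lo)
            t_end = gonio.stage_position(hi)
            for got, want in ((vec.start, t_start), (vec.end, t_end)):
                err = np.abs(np.asarray(got) - want)
                assert err[2] <= 10.0   # along the axis: one horizontal step
                assert err[1] <= 15.0   # vertical: one vertical step
                assert err[0] <= 15.0   # depth: recovered by the edge scan
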