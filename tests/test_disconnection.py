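"""Streamline-lesion intersection and per-tract disconnection indices."""

import numpy as np
import pytest
from conftest import make_grid, random_mask

import lesionmap as lm
from lesionmap.disconnection import (
    TractBundle,
    save_bundle_json,
    save_bundle_tck,
)
from oracles import segment_crosses_slab, streamline_hits_mask_walk


def slab_mask(grid, axis, index):
    """One-voxel-thick lesion slab perpendicular to ``axis``."""
    data = np.zeros(grid.shape, np.uint8)
    sl = [slice(None)] * 3
    sl[axis] = index
    data[tuple(sl)] = 1
    return lm.BinaryLesionMask(grid, data, f"slab_{axis}_{index}")


class TestStreamlineHitsMask:
    def test_streamline_outside_bounding_box_misses(self, grid8):
        mask = slab_mask(grid8, 0, 4)
        s = np.array([[100.0, 100.0, 100.0], [120.0, 100.0, 100.0]])
        assert not lm.streamline_hits_mask(s, mask)

    def test_vertex_at_lesioned_voxel_center_hits(self, grid8):
        data = np.zeros(grid8.shape, np.uint8)
        data[3, 3, 3] = 1
        mask = lm.BinaryLesionMask(grid8, data, "one")
        center = grid8.voxel_to_world(np.array([3, 3, 3]))[0]
        s = np.array([center - [0, 0, 30], center, center + [0, 0, 30]])
        assert lm.streamline_hits_mask(s, mask)

    def test_two_vertex_line_crossing_thin_slab_hits(self):
        # no vertex lies in the slab; only segment subdivision can find it
        grid = make_grid((20, 20, 20), voxel_mm=1.0)
        mask = slab_mask(grid, 0, 10)
        x_lo, x_hi = -9.5, 9.5
        s = np.array([[x_lo, 0.0, 0.0], [x_hi, 0.0, 0.0]])
        slab_x = grid.voxel_to_world(np.array([10, 0, 0]))[0][0]
        assert segment_crosses_slab(s[0], s[1], 0, slab_x - 0.5, slab_x + 0.5)
        assert lm.streamline_hits_mask(s, mask)

    def test_line_parallel_to_slab_misses(self):
        grid = make_grid((20, 20, 20), voxel_mm=1.0)
        mask = slab_mask(grid, 0, 10)
        slab_x = grid.voxel_to_world(np.array([10, 0, 0]))[0][0]
        s = np.array([[slab_x - 3.0, -9.0, 0.0], [slab_x - 3.0, 9.0, 0.0]])
        assert not segment_crosses_slab(s[0], s[1], 0, slab_x - 0.5, slab_x + 0.5)
        assert not lm.streamline_hits_mask(s, mask)

    def test_equivalent_to_dense_walk_on_axis_aligned_lines(self, rng):
        grid = make_grid((10, 10, 10), voxel_mm=2.0)
        mask = random_mask(grid, rng, p=0.08)
        for _ in range(30):
            axis = rng.integers(3)
            lo, hi = np.sort(rng.uniform(-12, 12, 2))
            cross = rng.uniform(-10, 10, 3)
            p0, p1 = cross.copy(), cross.copy()
            p0[axis], p1[axis] = lo, hi
            pts = np.stack([p0, p1])
            ours = lm.streamline_hits_mask(pts, mask)
            ref = streamline_hits_mask_walk(pts, mask.data, grid.affine)
            assert ours == ref

    def test_no_false_positives_on_oblique_streamlines(self, rng):
        # a hit we report must be confirmed by a far denser walk of the line
        grid = make_grid((10, 10, 10), voxel_mm=2.0)
        mask = random_mask(grid, rng, p=0.08)
        for _ in range(15):
            pts = rng.uniform(-12, 12, size=(4, 3))
            if lm.streamline_hits_mask(pts, mask):
                assert streamline_hits_mask_walk(pts, mask.data, grid.affine)

    def test_point_order_reversal_is_irrelevant(self, rng):
        grid = make_grid((10, 10, 10), voxel_mm=2.0)
        mask = random_mask(grid, rng, p=0.1)
        for _ in range(10):
            pts = rng.uniform(-10, 10, size=(5, 3))
            assert lm.streamline_hits_mask(pts, mask) == \
                lm.streamline_hits_mask(pts[::-1], mask)


class TestTractDisconnection:
    def test_full_grid_mask_gives_100(self, grid8, rng):
        mask = lm.BinaryLesionMask(grid8, np.ones(grid8.shape, np.uint8), "full")
        bundle = TractBundle("b", [rng.uniform(-6, 6, (3, 3)) for _ in range(10)])
        assert lm.tract_disconnection(bundle, mask)["disconnection_index"] == 100.0

    def test_empty_mask_gives_0(self, grid8, rng):
        mask = lm.BinaryLesionMask(grid8, np.zeros(grid8.shape, np.uint8), "e")
        bundle = TractBundle("b", [rng.uniform(-6, 6, (3, 3)) for _ in range(10)])
        assert lm.tract_disconnection(bundle, mask)["disconnection_index"] == 0.0

    def test_constructed_20_of_50_crossings_give_40_percent(self):
        # 20 streamlines cross the slab, 30 run parallel on the far side
        grid = make_grid((20, 20, 20), voxel_mm=1.0)
        mask = slab_mask(grid, 0, 10)
        slab_x = grid.voxel_to_world(np.array([10, 0, 0]))[0][0]
        crossing = [np.array([[slab_x - 5, y, 0.0], [slab_x + 5, y, 0.0]])
                    for y in np.linspace(-8, 8, 20)]
        parallel = [np.array([[slab_x - 4, y, 0.0], [slab_x - 4, y + 0.5, 0.0]])
                    for y in np.linspace(-8, 7, 30)]
        for s in crossing:
            assert segment_crosses_slab(s[0], s[1], 0, slab_x - 0.5, slab_x + 0.5)
        for s in parallel:
            assert not segment_crosses_slab(s[0], s[1], 0, slab_x - 0.5, slab_x + 0.5)
        bundle = TractBundle("mixed", crossing + parallel)
        row = lm.tract_disconnection(bundle, mask)
        assert row["total_streamlines"] == 50
        assert row["disconnected_streamlines"] == 20
        assert row["disconnection_index"] == pytest.approx(40.0)

    def test_duplicating_every_streamline_keeps_percentage(self, rng):
        grid = make_grid((10, 10, 10), voxel_mm=2.0)
        mask = random_mask(grid, rng, p=0.1)
        lines = [rng.uniform(-9, 9, (4, 3)) for _ in range(12)]
        one = lm.tract_disconnection(TractBundle("b", lines), mask)
        two = lm.tract_disconnection(TractBundle("b", lines + lines), mask)
        assert one["disconnection_index"] == pytest.approx(two["disconnection_index"])

    def test_growing_mask_never_decreases_index(self, rng):
        grid = make_grid((10, 10, 10), voxel_mm=2.0)
        small = random_mask(grid, rng, p=0.05)
        grown_data = small.data | (rng.random(grid.shape) < 0.15)
        grown = lm.BinaryLesionMask(grid, grown_data.astype(np.uint8), "g")
        lines = [rng.uniform(-9, 9, (4, 3)) for _ in range(15)]
        bundle = TractBundle("b", lines)
        assert lm.tract_disconnection(bundle, grown)["disconnection_index"] >= \
            lm.tract_disconnection(bundle, small)["disconnection_index"]


class TestDisconnectionReport:
    def _bundles_with_fractions(self, grid, fractions, n=10):
        # straight lines either through the slab or parallel beside it
        slab_x = grid.voxel_to_world(np.array([10, 0, 0]))[0][0]
        bundles = []
        for bi, frac in enumerate(fractions):
            n_hit = round(frac * n)
            lines = []
            for si in range(n):
                y = -8 + si
                if si < n_hit:
                    lines.append(np.array([[slab_x - 5, y, 0.0],
                                           [slab_x + 5, y, 0.0]]))
                else:
                    lines.append(np.array([[slab_x - 4, y, 0.0],
                                           [slab_x - 4, y + 0.4, 0.0]]))
            bundles.append(TractBundle(f"bundle_{bi}", lines))
        return bundles

    def test_constructed_fractions_recovered_in_order(self):
        grid = make_grid((20, 20, 20), voxel_mm=1.0)
        mask = slab_mask(grid, 0, 10)
        atlas = self._bundles_with_fractions(grid, [1.0, 0.8, 0.5, 0.2, 0.0])
        table = lm.disconnection_report(atlas, mask)
        assert list(table.disconnection_index) == [100.0, 80.0, 50.0, 20.0, 0.0]
        assert list(table.tract_name) == [f"bundle_{i}" for i in range(5)]

    def test_ties_broken_by_name(self, grid8, rng):
        mask = lm.BinaryLesionMask(grid8, np.ones(grid8.shape, np.uint8), "full")
        atlas = [TractBundle(n, [rng.uniform(-6, 6, (3, 3))])
                 for n in ("zeta", "alpha", "midl")]
        table = lm.disconnection_report(atlas, mask)
        assert list(table.tract_name) == ["alpha", "midl", "zeta"]

    def test_empty_atlas_rejected(self, grid8, rng):
        with pytest.raises(lm.EmptyBundleError):
            lm.disconnection_report([], random_mask(grid8, rng))

    def test_empty_bundle_rejected(self):
        with pytest.raises(lm.EmptyBundleError):
            TractBundle("empty", [])


class TestBundleIO:
    def test_json_round_trip(self, rng, tmp_path):
        bundle = TractBundle("arcuate_fasciculus",
                             [rng.uniform(-20, 20, (5, 3)) for _ in range(4)])
        save_bundle_json(bundle, tmp_path / "af.json")
        back = lm.load_bundle(tmp_path / "af.json")
        assert back.name == "arcuate_fasciculus"
        for a, b in zip(back.streamlines, bundle.streamlines):
            np.testing.assert_allclose(a, b)

    def test_tck_round_trip(self, rng, tmp_path):
        bundle = TractBundle("ifof", [rng.uniform(-20, 20, (6, 3)).astype(float)
                                      for _ in range(3)])
        save_bundle_tck(bundle, tmp_path / "ifof.tck")
        back = lm.load_bundle(tmp_path / "ifof.tck")
        assert back.name == "ifof"
        for a, b in zip(back.streamlines, bundle.streamlines):
            np.testing.assert_allclose(a, b, atol=1e-4)

    def test_atlas_directory_loader(self, rng, tmp_path):
        for name in ("b1", "b2"):
            save_bundle_json(TractBundle(name, [rng.uniform(-5, 5, (3, 3))]),
                             tmp_path / f"{name}.json")
        atlas = lm.load_tract_atlas(tmp_path)
        assert [b.name for b in atlas] == ["b1", "b2"]
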