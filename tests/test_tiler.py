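"""Overlapping tiling: planning, cropping and coordinate mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paniclecount.boxgeom import Box
from paniclecount.tiler import (
    TilePlan,
    TilingError,
    crop_tiles,
    plan_tiles,
    to_global,
    to_local,
)


class TestPlanTiles:
    def test_field_image_geometry_is_8_by_5(self):
        """A 6000x4000 image with 1056 px tiles at stride 756 gives 40 tiles."""
        plan = plan_tiles(6000, 4000, 1056, 1056, 756)
        assert plan.n_tiles == 40
        xs = sorted({x for x, _ in plan.origins})
        ys = sorted({y for _, y in plan.origins})
        assert len(xs) == 8 and len(ys) == 5
        assert xs[-1] == 6000 - 1056  # clamped
        assert ys[-1] == 4000 - 1056

    def test_single_tile_when_tile_equals_image(self):
        plan = plan_tiles(1056, 1056, 1056, 1056, 756)
        assert plan.origins == ((0, 0),)

    def test_clamped_progression(self):
        plan = plan_tiles(2000, 1500, 1000, 1000, 500)
        xs = sorted({x for x, _ in plan.origins})
        ys = sorted({y for _, y in plan.origins})
        assert xs == [0, 500, 1000]
        assert ys == [0, 500]
        assert plan.n_tiles == 6

    def test_row_major_ordering(self):
        plan = plan_tiles(2000, 1500, 1000, 1000, 500)
        assert plan.origins[0] == (0, 0)
        assert plan.origins[1] == (500, 0)
        assert plan.origins[3] == (0, 500)

    def test_geometry_errors(self):
        with pytest.raises(TilingError):
            plan_tiles(500, 500, 1000, 1000, 500)
        with pytest.raises(TilingError):
            plan_tiles(2000, 2000, 1000, 1000, 0)
        with pytest.raises(TilingError):
            plan_tiles(2000, 2000, 1000, 1000, 1001)

    @settings(deadline=None, max_examples=100)
    @given(
        image_w=st.integers(50, 400),
        image_h=st.integers(50, 400),
        tile=st.integers(10, 50),
        stride=st.integers(1, 10),
    )
    def test_count_coverage_and_bounds(self, image_w, image_h, tile, stride):
        """Tile count matches the per-axis closed form; tiles stay in
        bounds and cover every pixel."""
        plan = plan_tiles(image_w, image_h, tile, tile, stride)
        nx = -(-(image_w - tile) // stride) + 1
        ny = -(-(image_h - tile) // stride) + 1
        assert plan.n_tiles == nx * ny
        covered = np.zeros((image_h, image_w), dtype=bool)
        for x, y in plan.origins:
            assert 0 <= x <= image_w - tile
            assert 0 <= y <= image_h - tile
            covered[y : y + tile, x : x + tile] = True
        assert covered.all()

    def test_whole_object_guarantee_exhaustive(self):
        """Any box with both sides <= tile - stride fits whole inside at
        least one tile, for every integer placement on a small grid."""
        image_w, image_h, tile, stride = 40, 30, 12, 8
        plan = plan_tiles(image_w, image_h, tile, tile, stride)
        side = tile - stride
        for w in (1, side):
            for h in (1, side):
                for x in range(image_w - w + 1):
                    for y in range(image_h - h + 1):
                        assert any(
                            ox <= x and oy <= y
                            and x + w <= ox + tile and y + h <= oy + tile
                            for ox, oy in plan.origins
                        ), (x, y, w, h)


class TestCropTiles:
    def test_paper_geometry_crop_count_and_shape(self):
        image = np.zeros((4000, 6000, 3), dtype=np.uint8)
        plan = plan_tiles(6000, 4000, 1056, 1056, 756)
        crops = crop_tiles(image, plan)
        assert len(crops) == 40
        assert all(c.shape == (1056, 1056, 3) for c in crops)

    def test_single_tile_equals_image(self, rng):
        image = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        plan = plan_tiles(64, 64, 64, 64, 32)
        (crop,) = crop_tiles(image, plan)
        assert np.array_equal(crop, image)
        assert not np.shares_memory(crop, image)  # copies, not views

    def test_overlap_band_identical_between_tiles(self, rng):
        image = rng.integers(0, 255, size=(10, 15), dtype=np.uint8)
        plan = plan_tiles(15, 10, 10, 10, 5)
        crops = crop_tiles(image, plan)
        # tiles at x=0 and x=5 share columns 5..9
        assert np.array_equal(crops[0][:, 5:], crops[1][:, :5])

    def test_dimension_mismatch(self):
        plan = plan_tiles(100, 100, 50, 50, 25)
        with pytest.raises(TilingError):
            crop_tiles(np.zeros((50, 50)), plan)


class TestCoordinateMapping:
    def test_translation(self):
        g = to_global(Box(10, 10, 50, 50, score=0.9), (756, 0))
        assert (g.x_min, g.y_min, g.x_max, g.y_max) == (766, 10, 806, 50)
        assert g.score == 0.9

    def test_identity_at_origin(self):
        b = Box(1, 2, 3, 4)
        assert to_global(b, (0, 0)) == b

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.integers(0, 100), y=st.integers(0, 100),
        w=st.integers(1, 50), h=st.integers(1, 50),
        ox=st.integers(0, 500), oy=st.integers(0, 500),
    )
    def test_roundtrip(self, x, y, w, h, ox, oy):
        b = Box(x, y, x + w, y + h)
        assert to_local(to_global(b, (ox, oy)), (ox, oy)) == b


def test_plan_json_roundtrip():
    plan = plan_tiles(2000, 1500, 1000, 1000, 500)
    assert TilePlan.from_json(plan.to_json()) == plan
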