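import numpy as np
import pytest

from wsicoloc.pyramid import Rect
from wsicoloc.refinement import (
    build_grid,
    choose_strategy,
    count_registered_pixels,
    refine_point_strategy2,
    refine_tiles_strategy1,
    refinement_config,
    strategy1_chain_steps,
)
from wsicoloc.synthetic import SlideScenario, derive_moving_slide, generate_tissue_slide
from wsicoloc.transforms import SimilarityTransform


class TestBuildGrid:
    def test_exact_tiling(self):
        tiles = build_grid(Rect(0, 0, 4096, 4096), tile_size=2048)
        assert len(tiles) == 4
        assert tiles[0].rect == Rect(0, 0, 2048, 2048)
        assert tiles[3].rect == Rect(2048, 2048, 2048, 2048)

    def test_single_tile_when_size_equals_roi(self):
        assert len(build_grid(Rect(10, 10, 512, 512), tile_size=512)) == 1

    def test_oversized_tile_warns_single_tile(self):
        with pytest.warns(UserWarning, match="single tile"):
            tiles = build_grid(Rect(0, 0, 100, 100), tile_size=300)
        assert len(tiles) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_coverage_and_count_property(self, seed):
        rng = np.random.default_rng(seed)
        w, h = rng.integers(100, 5000, 2)
        ts = int(rng.integers(50, 2000))
        roi = Rect(float(rng.integers(0, 100)), float(rng.integers(0, 100)), float(w), float(h))
        tiles = build_grid(roi, tile_size=ts)
        assert len(tiles) == int(np.ceil(w / ts)) * int(np.ceil(h / ts))
        # union of tiles covers the ROI
        for _ in range(200):
            p = (rng.uniform(roi.x, roi.x2 - 1e-9), rng.uniform(roi.y, roi.y2 - 1e-9))
            assert any(t.rect.contains_point(*p) for t in tiles)

    def test_annotation_retention_and_boundary_tiebreak(self):
        roi = Rect(0, 0, 200, 200)
        pts = np.array([[10.0, 10.0], [100.0, 50.0], [150.0, 150.0]])
        tiles = build_grid(roi, tile_size=100, annotations=pts)
        assert [t.index for t in tiles] == [0, 1, 3]
        # the boundary point (100, 50) belongs to the half-open tile 1 only
        assert tiles[1].annotation_indices == [1]
        assert tiles[0].annotation_indices == [0]

    def test_n_tiles_argument(self):
        tiles = build_grid(Rect(0, 0, 1000, 1000), n_tiles=4)
        assert len(tiles) == 4

    def test_exactly_one_argument(self):
        with pytest.raises(ValueError):
            build_grid(Rect(0, 0, 10, 10))
        with pytest.raises(ValueError):
            build_grid(Rect(0, 0, 10, 10), tile_size=5, n_tiles=4)


class TestPixelAccounting:
    @pytest.mark.parametrize(
        "n,ts,millions",
        [(4, 4096, 67.11), (10, 4096, 167.77), (10, 2048, 41.94), (19, 1024, 19.92), (8, 2048, 33.55)],
    )
    def test_registered_pixels_in_millions(self, n, ts, millions):
        assert round(count_registered_pixels(n, ts) / 1e6, 2) == millions

    def test_single_pixel(self):
        assert count_registered_pixels(1, 1) == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_registered_pixels(0, 1024)


class TestChooseStrategy:
    def test_dense_limit(self):
        pts = np.random.default_rng(0).uniform(0, 500, (100, 2))
        assert choose_strategy(pts, Rect(0, 0, 10000, 10000), tile_size=2048) == "strategy1"

    def test_sparse_limit(self):
        pts = np.array([[i * 3000.0, i * 3000.0] for i in range(10)])
        assert choose_strategy(pts, Rect(0, 0, 30000, 30000), tile_size=2048) == "strategy2"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_cost(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 8000, (rng.integers(2, 60), 2))
        roi = Rect(0, 0, 8000, 8000)
        ts, ps = 1024, 192
        got = choose_strategy(pts, roi, tile_size=ts, patch_size=ps)
        occupied = {(int(p[0] // ts), int(p[1] // ts)) for p in pts}
        overhead = 41_000.0
        cost1 = len(occupied) * (ts**2 + overhead)
        cost2 = len(pts) * (ps**2 + overhead)
        expect = "strategy1" if cost1 < cost2 else "strategy2"
        assert got == expect


@pytest.fixture(scope="module")
def small_pair():
    slide = generate_tissue_slide(512, 512, 60, seed=17)
    fixed = slide.pyramid()
    moving_id, gt_id = derive_moving_slide(slide, SlideScenario(seed=18))
    return slide, fixed, moving_id, gt_id


class TestStrategy1:
    def test_identity_scenario_corrections_near_identity(self, small_pair):
        slide, fixed, moving, gt = small_pair
        base = SimilarityTransform()
        grid = build_grid(Rect(64, 64, 384, 384), tile_size=192)
        grid = refine_tiles_strategy1(
            grid, base, fixed, moving, config=refinement_config(seed=1, tile=True)
        )
        assert all(t.status == "ok" for t in grid)
        for t in grid:
            c = np.array(t.rect.center)
            assert np.linalg.norm(t.correction.apply(c) - c) < 0.25

    def test_chain_steps_row_major_with_domains(self, small_pair):
        _, fixed, moving, _ = small_pair
        grid = build_grid(Rect(64, 64, 384, 384), tile_size=192)
        grid = refine_tiles_strategy1(
            grid, SimilarityTransform(), fixed, moving,
            config=refinement_config(seed=1, tile=True),
        )
        steps = strategy1_chain_steps(grid, start_order=2)
        assert [s.order for s in steps] == list(range(2, 2 + len(steps)))
        assert all(s.domain is not None for s in steps)

    def test_pixel_sum_matches_accounting(self):
        grid = build_grid(Rect(0, 0, 1000, 1000), tile_size=256)
        total = sum(t.rect.w * t.rect.h for t in grid)
        assert total == count_registered_pixels(len(grid), 256)


class TestStrategy2:
    def test_identity_scenario_point_unchanged(self, small_pair):
        _, fixed, moving, _ = small_pair
        pc = refine_point_strategy2(
            np.array([250.0, 260.0]), SimilarityTransform(), fixed, moving,
            patch_size=128, config=refinement_config(seed=2),
        )
        assert pc.status == "ok"
        assert np.allclose(pc.corrected_point, [250.0, 260.0], atol=0.25)

    def test_injected_local_shift_recovered(self, small_pair):
        """A small uncompensated shift between the slides is recovered by
        the per-annotation affine correction to sub-pixel precision."""
        slide, fixed, _, _ = small_pair
        moving, gt = derive_moving_slide(slide, SlideScenario(translation=(2.0, -1.5), seed=19))
        p = np.array([250.0, 260.0])
        pc = refine_point_strategy2(
            p, SimilarityTransform(), fixed, moving,
            patch_size=128, config=refinement_config(seed=3),
        )
        assert pc.status == "ok"
        assert np.linalg.norm(pc.corrected_point - gt(p)) < 0.5

    def test_edge_point_flagged_uncorrected(self, small_pair):
        _, fixed, moving, _ = small_pair
        p = np.array([20.0, 250.0])  # within patch_size/2 of the left edge
        pc = refine_point_strategy2(
            p, SimilarityTransform(), fixed, moving, patch_size=128,
        )
        assert pc.status == "out-of-bounds"
        assert pc.correction is None
        assert np.allclose(pc.corrected_point, p)  # coarse coordinate kept

    def test_patch_size_range_enforced(self, small_pair):
        _, fixed, moving, _ = small_pair
        with pytest.raises(ValueError):
            refine_point_strategy2(np.array([250.0, 250.0]), SimilarityTransform(), fixed, moving, patch_size=32)
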