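import numpy as np
import pytest
from scipy import ndimage

from wsicoloc import hierarchy
from wsicoloc.hierarchy import (
    ORIENTATION_OPS,
    CoarseResult,
    apply_orientation_pretransform,
    apply_to_image,
    coarse_register,
    compose_ops,
    extract_rotated_region,
    extrapolate_to_base,
    inverse_op,
    map_points,
    transformed_dims,
)
from wsicoloc.pyramid import Rect, build_pyramid, read_region
from wsicoloc.transforms import SimilarityTransform, rotation_matrix
from tests.conftest import smooth_random_image


class TestOrientationOps:
    def test_flip_h_example(self):
        assert np.array_equal(map_points("flip_h", [10.0, 20.0], (100, 50)), [89.0, 20.0])

    def test_rot90_four_times_identity(self):
        pts = np.random.default_rng(0).uniform(0, 40, (20, 2))
        dims = (50, 41)
        out = pts
        for _ in range(4):
            out = map_points("rot90", out, dims)
            dims = transformed_dims("rot90", dims)
        assert np.allclose(out, pts)

    @pytest.mark.parametrize("op", ORIENTATION_OPS)
    def test_op_then_inverse_is_identity(self, op):
        dims = (37, 23)
        pts = np.random.default_rng(1).integers(0, 23, (50, 2)).astype(float)
        fwd = map_points(op, pts, dims)
        back = map_points(inverse_op(op), fwd, transformed_dims(op, dims))
        assert np.allclose(back, pts)

    @pytest.mark.parametrize("op", ORIENTATION_OPS)
    def test_image_follows_point_map(self, op):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, (5, 7)).astype(np.uint8)
        out = apply_to_image(op, img)
        pts = np.array([[x, y] for x in range(7) for y in range(5)], float)
        mapped = map_points(op, pts, (7, 5)).astype(int)
        assert np.array_equal(out[mapped[:, 1], mapped[:, 0]],
                              img[pts[:, 1].astype(int), pts[:, 0].astype(int)])

    def test_composition_table_closed_under_dihedral_group(self):
        """All 64 pairs compose to one of the eight ops, consistently with
        sequential point application."""
        dims = (9, 9)  # square so dims survive any op
        pts = np.array([[x, y] for x in range(9) for y in range(9)], float)
        for inner in ORIENTATION_OPS:
            for outer in ORIENTATION_OPS:
                name = compose_ops(outer, inner)
                assert name in ORIENTATION_OPS
                seq = map_points(outer, map_points(inner, pts, dims), dims)
                assert np.allclose(map_points(name, pts, dims), seq), (outer, inner)

    def test_dispatcher(self):
        img = np.zeros((4, 6, 3), np.uint8)
        assert apply_orientation_pretransform(img, "rot90").shape == (6, 4, 3)
        pts = apply_orientation_pretransform(np.array([[1.0, 2.0]]), "flip_v", dims=(6, 4))
        assert np.allclose(pts, [[1.0, 1.0]])
        with pytest.raises(ValueError):
            map_points("rot45", [0, 0], (4, 4))


class TestExtrapolateToBase:
    def make_cr(self, T, roi_f, roi_m, dsf, dsm):
        return CoarseResult(
            transform=T, roi_fixed=roi_f, roi_moving=roi_m,
            level_fixed=int(np.log2(dsf)), level_moving=int(np.log2(dsm)),
            downsample_fixed=dsf, downsample_moving=dsm,
        )

    def test_level0_unchanged(self):
        T = SimilarityTransform(angle_deg=5, scale=1.1, tx=3, ty=4, cx=10, cy=12)
        roi = Rect(0, 0, 100, 100)
        out = extrapolate_to_base(self.make_cr(T, roi, roi, 1, 1))
        pts = np.random.default_rng(0).uniform(0, 100, (50, 2))
        assert np.allclose(out.apply(pts), T.apply(pts), atol=1e-9)

    def test_pure_translation_level5(self):
        T = SimilarityTransform(tx=3, ty=4)
        roi = Rect(0, 0, 32 * 64, 32 * 64)
        out = extrapolate_to_base(self.make_cr(T, roi, roi, 32, 32))
        assert out.tx == pytest.approx(96)
        assert out.ty == pytest.approx(128)
        assert out.angle_deg == pytest.approx(0) and out.scale == pytest.approx(1)

    def test_commutation_upscale_then_map(self):
        """Mapping in base coords equals crop->downsample->overview map->
        upsample->offset, for random points to 1e-6 px."""
        rng = np.random.default_rng(3)
        T = SimilarityTransform(angle_deg=-8, scale=1.04, tx=2.5, ty=-1.25, cx=20, cy=15)
        roi_f = Rect(320, 480, 640, 480)
        roi_m = Rect(160, 64, 640, 512)
        dsf = dsm = 16
        base_T = extrapolate_to_base(self.make_cr(T, roi_f, roi_m, dsf, dsm))
        pts = rng.uniform(0, 1000, (100, 2))
        manual = T.apply((pts - [roi_f.x, roi_f.y]) / dsf) * dsm + [roi_m.x, roi_m.y]
        assert np.abs(base_T.apply(pts) - manual).max() < 1e-6

    def test_angle_preserved_scale_combines_level_factors(self):
        T = SimilarityTransform(angle_deg=7, scale=1.02, cx=5, cy=5)
        roi = Rect(0, 0, 512, 512)
        out = extrapolate_to_base(self.make_cr(T, roi, roi, 16, 32))
        assert out.angle_deg == pytest.approx(7)
        assert out.scale == pytest.approx(1.02 * 2)


@pytest.fixture(scope="module")
def pattern_pyramid():
    img = np.round(smooth_random_image((256, 256), seed=21, sigma=2)).astype(np.uint8)
    return build_pyramid(img, 3, mpp=0.25, magnification=10)


class TestExtractRotatedRegion:
    def test_zero_angle_equals_read_region(self, pattern_pyramid):
        rect = Rect(40, 56, 64, 48)
        patch, clipped = extract_rotated_region(pattern_pyramid, rect, 0.0)
        ref = read_region(pattern_pyramid, 0, rect).data
        assert patch.shape == ref.shape
        assert np.abs(patch.astype(float) - ref.astype(float)).max() <= 1

    def test_right_angle_equals_array_rotation(self, pattern_pyramid):
        rect = Rect(96, 96, 64, 64)
        patch, _ = extract_rotated_region(pattern_pyramid, rect, 90.0)
        crop = read_region(pattern_pyramid, 0, rect).data.astype(float)
        # output(u) = slide(center + R(90) (u - pc)); R(90)(dx,dy) = (dy,-dx)
        oracle = np.zeros_like(crop)
        c = (64 - 1) / 2.0
        for v in range(64):
            for u in range(64):
                x = int(round(c + (v - c)))
                y = int(round(c - (u - c)))
                oracle[v, u] = crop[y, x]
        interior = (slice(2, -2), slice(2, -2))
        assert np.abs(patch.astype(float)[interior] - oracle[interior]).max() <= 1

    def test_arbitrary_angle_matches_dense_oracle(self, pattern_pyramid):
        rect = Rect(80, 90, 60, 50)
        theta = 23.0
        patch, _ = extract_rotated_region(pattern_pyramid, rect, theta)
        base = pattern_pyramid.levels[0].astype(float)
        R = rotation_matrix(theta)
        cx, cy = rect.x + (60 - 1) / 2.0, rect.y + (50 - 1) / 2.0
        uu, vv = np.meshgrid(np.arange(60, dtype=float), np.arange(50, dtype=float))
        rel = np.column_stack([uu.ravel() - (60 - 1) / 2.0, vv.ravel() - (50 - 1) / 2.0])
        pts = rel @ R.T + [cx, cy]
        oracle = ndimage.map_coordinates(base, [pts[:, 1], pts[:, 0]], order=3).reshape(50, 60)
        interior = (slice(3, -3), slice(3, -3))
        assert np.abs(patch.astype(float)[interior] - oracle[interior]).max() <= 2

    def test_level_scaling(self, pattern_pyramid):
        rect = Rect(64, 64, 64, 64)
        patch, _ = extract_rotated_region(pattern_pyramid, rect, 0.0, level=1)
        assert patch.shape == (32, 32)

    def test_outside_slide_raises(self, pattern_pyramid):
        with pytest.raises(ValueError):
            extract_rotated_region(pattern_pyramid, Rect(1000, 1000, 32, 32), 10.0)

    def test_partial_read_flagged(self, pattern_pyramid):
        _, clipped = extract_rotated_region(pattern_pyramid, Rect(230, 230, 40, 40), 15.0)
        assert clipped


class TestCoarseRegister:
    def test_identity_pair(self, light_config):
        from wsicoloc.synthetic import generate_tissue_slide

        slide = generate_tissue_slide(512, 512, 30, seed=13)
        pyr = slide.pyramid()
        roi = Rect(32, 32, 448, 448)
        cr = coarse_register(pyr, pyr, roi, roi, config=light_config)
        assert cr.status == "ok"
        T = cr.transform
        assert abs(T.angle_deg) < 0.2
        assert abs(T.scale - 1) < 0.01
        assert np.hypot(T.tx, T.ty) < 1.0
        base = extrapolate_to_base(cr)
        c = np.array(roi.center)
        assert np.linalg.norm(base.apply(c) - c) < 2 * cr.downsample_fixed
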