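import numpy as np
import pytest
from scipy.spatial import cKDTree

from wsicoloc.pyramid import Rect
from wsicoloc.synthetic import (
    GroundTruthMap,
    SlideScenario,
    derive_moving_slide,
    detect_nuclei,
    generate_annotations,
    generate_tissue_slide,
)


class TestTissueSlide:
    def test_deterministic(self):
        a = generate_tissue_slide(256, 256, 12, seed=5)
        b = generate_tissue_slide(256, 256, 12, seed=5)
        assert np.array_equal(a.rgb, b.rgb)
        assert np.array_equal(a.nucleus_centers, b.nucleus_centers)

    def test_no_nuclei_background_only(self):
        s = generate_tissue_slide(128, 128, 0, seed=1)
        assert len(s.nucleus_centers) == 0
        assert not (s.nucleus_labels > 0).any()

    def test_blob_detector_recovers_nucleus_count(self, tissue_slide):
        detected = detect_nuclei(tissue_slide.rgb)
        assert len(detected) == len(tissue_slide.nucleus_centers)
        d, _ = cKDTree(tissue_slide.nucleus_centers).query(detected)
        assert d.max() < 1.0

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            generate_tissue_slide(32, 128, 5)
        with pytest.raises(ValueError):
            generate_tissue_slide(128, 128, -1)


class TestScenario:
    def test_scale_range_enforced(self):
        with pytest.raises(ValueError):
            SlideScenario(scale=0.5)

    def test_folding_deformation_rejected(self):
        with pytest.raises(ValueError):
            SlideScenario(deformation_amplitude=30, deformation_smoothness=40)

    def test_unknown_stain_rejected(self):
        with pytest.raises(ValueError):
            SlideScenario(stain_model="masson")


class TestDeriveMovingSlide:
    def test_identity_scenario_is_fixed(self, tissue_slide):
        pyr, gt = derive_moving_slide(tissue_slide, SlideScenario(seed=2))
        assert np.array_equal(pyr.levels[0], tissue_slide.rgb)
        pts = np.array([[10.0, 20.0], [300.5, 123.25]])
        assert np.allclose(gt(pts), pts)

    def test_pure_translation_map(self, tissue_slide):
        sc = SlideScenario(translation=(17.0, -4.5), seed=2)
        _, gt = derive_moving_slide(tissue_slide, sc)
        pts = np.random.default_rng(0).uniform(50, 450, (20, 2))
        assert np.allclose(gt(pts), pts + (17.0, -4.5), atol=1e-9)

    def test_similarity_scenario_centroids_match_map(self, tissue_slide):
        """Centroid-detection oracle: nuclei detected on the derived slide
        coincide with the ground-truth mapping of those detected on the
        fixed slide."""
        sc = SlideScenario(angle_deg=7, scale=1.03, translation=(10, 6), seed=4)
        pyr, gt = derive_moving_slide(tissue_slide, sc)
        det_fixed = detect_nuclei(tissue_slide.rgb)
        det_moving = detect_nuclei(pyr.levels[0])
        mapped = gt(det_fixed)
        inside = gt.domain_mask(det_fixed)
        d, _ = cKDTree(mapped[inside]).query(det_moving)
        assert len(det_moving) >= 0.95 * inside.sum()
        assert np.median(d) < 0.5

    def test_deterministic(self, tissue_slide):
        sc = SlideScenario(angle_deg=3, stain_model="ihc", deformation_amplitude=1.0, seed=8)
        p1, g1 = derive_moving_slide(tissue_slide, sc)
        p2, g2 = derive_moving_slide(tissue_slide, sc)
        assert np.array_equal(p1.levels[0], p2.levels[0])
        pts = np.random.default_rng(1).uniform(0, 500, (50, 2))
        assert np.array_equal(g1(pts), g2(pts))

    def test_mpp_ratio_scales_canvas_and_metadata(self, tissue_slide):
        pyr, gt = derive_moving_slide(tissue_slide, SlideScenario(mpp_ratio=1.1, seed=1))
        assert pyr.mpp_x == pytest.approx(tissue_slide.mpp * 1.1)
        assert pyr.levels[0].shape[0] == pytest.approx(512 / 1.1, abs=1)

    def test_stain_independence_of_geometry(self, tissue_slide):
        kw = dict(angle_deg=-6, scale=1.04, translation=(8, -3),
                  deformation_amplitude=1.5, seed=12)
        _, gt_he = derive_moving_slide(tissue_slide, SlideScenario(stain_model="he", **kw))
        _, gt_ihc = derive_moving_slide(tissue_slide, SlideScenario(stain_model="ihc", **kw))
        pts = np.random.default_rng(2).uniform(0, 500, (100, 2))
        assert np.array_equal(gt_he(pts), gt_ihc(pts))

    def test_ground_truth_inverse_consistency(self, tissue_slide):
        """Applying the map then inverting numerically recovers the input
        to 1e-3 px when the deformation amplitude is zero."""
        sc = SlideScenario(angle_deg=11, scale=1.05, translation=(-14, 9),
                           orientation_op="flip_h", seed=3)
        _, gt = derive_moving_slide(tissue_slide, sc)
        grid = np.column_stack([g.ravel() for g in np.meshgrid(
            np.linspace(50, 450, 9), np.linspace(50, 450, 9))])
        assert np.abs(gt.inverse_points(gt(grid)) - grid).max() < 1e-3

    def test_ground_truth_serialization_roundtrip(self, tissue_slide):
        sc = SlideScenario(angle_deg=5, deformation_amplitude=1.5, seed=6)
        _, gt = derive_moving_slide(tissue_slide, sc)
        back = GroundTruthMap.from_dict(gt.to_dict())
        pts = np.random.default_rng(3).uniform(0, 500, (30, 2))
        assert np.allclose(back(pts), gt(pts), atol=1e-9)


class TestAnnotations:
    def test_clustered_inside_region_exact_count(self):
        region = Rect(100, 100, 3500, 3500)
        pts = generate_annotations(100, "clustered", region, seed=1)
        assert pts.shape == (100, 2)
        assert (pts[:, 0] >= 100).all() and (pts[:, 0] <= 3600).all()
        assert (pts[:, 1] >= 100).all() and (pts[:, 1] <= 3600).all()

    def test_sparse_min_distance_brute_force(self):
        pts = generate_annotations(
            12, "sparse", Rect(0, 0, 5000, 5000), seed=2, min_distance=1024
        )
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 1024

    def test_sparse_infeasible_raises(self):
        with pytest.raises(RuntimeError):
            generate_annotations(
                50, "sparse", Rect(0, 0, 200, 200), seed=3,
                min_distance=150, max_retries=500,
            )

    def test_deterministic(self):
        r = Rect(0, 0, 1000, 1000)
        assert np.array_equal(
            generate_annotations(10, "clustered", r, seed=9),
            generate_annotations(10, "clustered", r, seed=9),
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_annotations(0, "clustered", Rect(0, 0, 10, 10))
        with pytest.raises(ValueError):
            generate_annotations(5, "scattered", Rect(0, 0, 10, 10))
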