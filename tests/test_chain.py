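import numpy as np
import pytest

from wsicoloc.chain import (
    ChainError,
    ChainStep,
    NotReusableError,
    TransformChain,
    apply_chain,
    apply_chain_continuous,
    compose_chain,
    reuse_chain,
)
from wsicoloc.pyramid import Rect
from wsicoloc.transforms import AffineTransform, SimilarityTransform


def translation_step(kind, order, tx, ty, **kw):
    return ChainStep(kind=kind, order=order, transform=SimilarityTransform(tx=tx, ty=ty), **kw)


class TestCompose:
    def test_empty_chain_is_identity(self):
        chain = compose_chain([])
        pts = np.array([[1.0, 2.0], [3.5, 4.5]])
        out, flags = apply_chain(pts, chain)
        assert np.array_equal(out, [[1, 2], [4, 4]])  # half-to-even rounding of 3.5
        assert all(f == "ok" for f in flags)

    def test_two_translations_compose(self):
        chain = compose_chain(
            [translation_step("global", 0, 1, 2), translation_step("global", 1, 3, 4)]
        )
        out, _ = apply_chain(np.array([[0.0, 0.0]]), chain)
        assert np.array_equal(out, [[4, 6]])

    def test_order_must_match_creation_order(self):
        with pytest.raises(ChainError, match="creation order"):
            compose_chain([translation_step("global", 1, 0, 0), translation_step("global", 0, 0, 0)])

    def test_overlapping_tile_domains_rejected(self):
        s1 = translation_step("tile", 0, 1, 0, domain=Rect(0, 0, 100, 100))
        s2 = translation_step("tile", 1, 2, 0, domain=Rect(50, 50, 100, 100))
        with pytest.raises(ChainError, match="overlap"):
            compose_chain([s1, s2])

    def test_duplicate_point_steps_rejected(self):
        s1 = translation_step("point", 0, 1, 0, annotation_id=7)
        s2 = translation_step("point", 1, 2, 0, annotation_id=7)
        with pytest.raises(ChainError, match="duplicate"):
            compose_chain([s1, s2])


class TestApply:
    def test_matches_sequential_oracle(self):
        """Chain application equals manual step-by-step application."""
        rng = np.random.default_rng(4)
        T_glob = SimilarityTransform(angle_deg=5, scale=1.02, tx=10, ty=-3, cx=50, cy=50)
        A = AffineTransform(matrix=[[1.01, 0.01], [-0.02, 0.99]], tx=1.5, ty=-0.5)
        chain = compose_chain(
            [
                ChainStep(kind="orientation", order=0, op="flip_h", dims=(200, 200)),
                ChainStep(kind="global", order=1, transform=T_glob),
                ChainStep(kind="tile", order=2, transform=A, domain=Rect(0, 0, 200, 200)),
            ]
        )
        pts = rng.uniform(0, 199, (1000, 2))
        out, _ = apply_chain_continuous(pts, chain)
        manual = pts.copy()
        manual[:, 0] = 199 - manual[:, 0]
        manual = A.apply(T_glob.apply(manual))
        assert np.allclose(out, manual, atol=1e-9)

    def test_round_half_to_even(self):
        chain = compose_chain([])
        out, _ = apply_chain(np.array([[10.5, 20.5], [11.5, 2.25]]), chain)
        assert np.array_equal(out, [[10, 20], [12, 2]])

    def test_tile_membership_by_original_fixed_coords(self):
        t1 = translation_step("tile", 1, 10, 0, domain=Rect(0, 0, 50, 50))
        t2 = translation_step("tile", 2, 0, 10, domain=Rect(50, 0, 50, 50))
        glob = translation_step("global", 0, 100, 100)
        chain = compose_chain([glob, t1, t2])
        pts = np.array([[10.0, 10.0], [60.0, 10.0]])
        out, flags = apply_chain(pts, chain)
        assert np.array_equal(out, [[120, 110], [160, 120]])
        assert all(f == "ok" for f in flags)

    def test_point_outside_all_tiles_base_only_flag(self):
        t1 = translation_step("tile", 1, 10, 0, domain=Rect(0, 0, 50, 50))
        chain = compose_chain([translation_step("global", 0, 1, 1), t1])
        out, flags = apply_chain(np.array([[80.0, 80.0]]), chain)
        assert np.array_equal(out, [[81, 81]])
        assert flags[0] == "base-only"

    def test_point_steps_match_ids(self):
        p0 = translation_step("point", 1, 5, 0, annotation_id=0)
        p1 = translation_step("point", 2, 0, 5, annotation_id=1)
        chain = compose_chain([translation_step("global", 0, 0, 0), p0, p1])
        out, _ = apply_chain(np.array([[0.0, 0.0], [0.0, 0.0]]), chain, ids=np.array([0, 1]))
        assert np.array_equal(out, [[5, 0], [0, 5]])


class TestSmoothTileField:
    def test_spline_reproduces_displacements_at_tile_centers(self):
        """With a complete 4x4 tile grid, the interpolated correction
        field passes through the per-tile displacement at tile centers."""
        steps = [translation_step("global", 0, 0, 0)]
        order = 1
        rng = np.random.default_rng(8)
        shifts = {}
        for iy in range(4):
            for ix in range(4):
                d = rng.uniform(-2, 2, 2)
                shifts[(ix, iy)] = d
                steps.append(
                    translation_step(
                        "tile", order, d[0], d[1],
                        domain=Rect(ix * 100, iy * 100, 100, 100),
                    )
                )
                order += 1
        chain = compose_chain(steps)
        centers = np.array([[ix * 100 + 50.0, iy * 100 + 50.0] for iy in range(4) for ix in range(4)])
        out, _ = apply_chain_continuous(centers, chain, smooth_tiles=True)
        expected = centers + np.array([shifts[(int(c[0] // 100), int(c[1] // 100))] for c in centers])
        assert np.allclose(out, expected, atol=1e-6)

    def test_incomplete_grid_falls_back_to_per_tile(self):
        steps = [
            translation_step("global", 0, 0, 0),
            translation_step("tile", 1, 3, 0, domain=Rect(0, 0, 100, 100)),
        ]
        chain = compose_chain(steps)
        out, _ = apply_chain_continuous(np.array([[50.0, 50.0]]), chain, smooth_tiles=True)
        assert np.allclose(out, [[53.0, 50.0]])


class TestSerialization:
    def make_chain(self):
        return compose_chain(
            [
                ChainStep(kind="orientation", order=0, op="rot90", dims=(512, 256)),
                ChainStep(
                    kind="global", order=1,
                    transform=SimilarityTransform(angle_deg=7.3, scale=1.013, tx=12.25, ty=-8.5, cx=100, cy=90),
                ),
                ChainStep(
                    kind="tile", order=2,
                    transform=AffineTransform(matrix=[[1.002, 0.003], [-0.001, 0.998]], tx=0.7, ty=-0.2),
                    domain=Rect(0, 0, 256, 256),
                ),
            ],
            provenance={"seed": 3},
        )

    def test_roundtrip_bit_identical_outputs(self, tmp_path):
        chain = self.make_chain()
        path = tmp_path / "chain.json"
        chain.save(path)
        back = TransformChain.load(path)
        pts = np.random.default_rng(5).uniform(0, 250, (200, 2))
        o1, _ = apply_chain(pts, chain)
        o2, _ = apply_chain(pts, back)
        assert np.array_equal(o1, o2)
        # and the serialized form itself is stable
        assert back.to_json() == chain.to_json()

    def test_unsupported_version_rejected(self):
        with pytest.raises(ChainError):
            TransformChain.from_json('{"format_version": 99, "steps": []}')


class TestReuse:
    def test_tile_chain_reusable_for_new_points(self):
        t1 = translation_step("tile", 1, 10, 0, domain=Rect(0, 0, 100, 100))
        chain = compose_chain([translation_step("global", 0, 5, 5), t1])
        out, flags = reuse_chain(np.array([[20.0, 20.0]]), chain)
        assert np.array_equal(out, [[35, 25]])

    def test_point_chain_refuses_new_points(self):
        p0 = translation_step("point", 1, 5, 0, annotation_id=0)
        chain = compose_chain([translation_step("global", 0, 0, 0), p0])
        with pytest.raises(NotReusableError):
            reuse_chain(np.array([[1.0, 1.0]]), chain)
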