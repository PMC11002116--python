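"""Segmentation: Dice, K-means brain extraction, morphology, polygons,
hemispheres, active contours and supervoxels."""

import numpy as np
import pytest
from shapely.geometry import Point
from shapely.geometry import Polygon as ShapelyPolygon

from mrikit import (
    BinaryMask,
    Geometry,
    ImageVolume,
    MaskRole,
    PhantomSpec,
    Polygon,
    StructuringElement,
    active_contour_roi,
    apply_polygon,
    autocomplete_contralateral,
    dice,
    kmeans_segment,
    make_structural_phantom,
    morph_close,
    morph_open,
    segment_hemisphere,
    supervoxel_partition,
)
from mrikit.errors import (
    ConsistencyError,
    DegenerateInputError,
    GeometryError,
    ParameterError,
    PreconditionError,
)
from mrikit.segmentation import rasterize_polygon

G = Geometry(0.1, 0.1, 0.5)


def brute_force_dice(a, b):
    """Independent oracle: Dice from explicit coordinate sets."""
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


class TestDice:
    def test_identical_masks(self):
        m = BinaryMask(np.eye(8, dtype=bool))
        assert dice(m, m).value == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(BinaryMask(a), BinaryMask(b)).value == 0.0

    def test_worked_example(self):
        # |A| = 4, |B| = 6, |A ∩ B| = 3 -> 2*3/10 = 0.6
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:4] = True
        b.flat[1:7] = True
        score = dice(BinaryMask(a), BinaryMask(b))
        assert (score.mask_a_size, score.mask_b_size, score.intersection_size) == (4, 6, 3)
        assert score.value == pytest.approx(0.6)

    def test_both_empty_is_degenerate_one(self):
        e = BinaryMask(np.zeros((3, 3), bool))
        score = dice(e, e)
        assert score.value == 1.0 and score.degenerate

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            dice(BinaryMask(np.ones((3, 3), bool)), BinaryMask(np.ones((4, 4), bool)))

    def test_oracle_equivalence_on_random_pairs(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(3, 12, size=rng.integers(2, 4)))
            a = rng.random(shape) < rng.uniform(0, 0.8)
            b = rng.random(shape) < rng.uniform(0, 0.8)
            assert dice(BinaryMask(a), BinaryMask(b)).value == pytest.approx(
                brute_force_dice(a, b), abs=0
            )


class TestKmeansSegment:
    def test_phantom_recovery(self, phantom_noiseless, dilated_outline):
        vol, masks = phantom_noiseless
        out = kmeans_segment(vol, dilated_outline, seed=0)
        assert dice(out, masks["brain"]).value >= 0.95

    def test_determinism(self, phantom_noiseless, dilated_outline):
        vol, _ = phantom_noiseless
        a = kmeans_segment(vol, dilated_outline, seed=3)
        b = kmeans_segment(vol, dilated_outline, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_outline_selects_overlapping_region(self):
        # two equal-intensity bright squares; the outline covers only one
        img = np.full((40, 40), 10.0)
        img[5:15, 5:15] = 100.0
        img[25:35, 25:35] = 100.0
        outline = np.zeros((40, 40), bool)
        outline[4:16, 4:16] = True
        vol = ImageVolume(img, G)
        out = kmeans_segment(vol, BinaryMask(outline), seed=0)
        assert out.data[8, 8] and not out.data[30, 30]

    def test_empty_outline_rejected(self, phantom_noiseless):
        vol, _ = phantom_noiseless
        with pytest.raises(PreconditionError):
            kmeans_segment(vol, BinaryMask(np.zeros(vol.spatial_shape, bool)), seed=0)

    def test_constant_image_rejected(self):
        vol = ImageVolume(np.full((10, 10), 7.0), G)
        outline = np.zeros((10, 10), bool)
        outline[3:7, 3:7] = True
        with pytest.raises(DegenerateInputError):
            kmeans_segment(vol, BinaryMask(outline), seed=0)

    def test_per_slice_mode(self, phantom_noiseless, dilated_outline):
        vol, masks = phantom_noiseless
        out = kmeans_segment(vol, dilated_outline, mode="per_slice_2d", seed=0)
        assert dice(out, masks["brain"]).value >= 0.95


class TestMorphology:
    def test_opening_removes_isolated_voxel(self):
        m = np.zeros((20, 20), bool)
        m[3:15, 3:15] = True
        m[18, 18] = True
        out = morph_open(BinaryMask(m), StructuringElement(2))
        assert not out.data[18, 18]
        assert out.data[8, 8]

    def test_closing_fills_hole(self):
        m = np.zeros((24, 24), bool)
        m[2:22, 2:22] = True
        m[10, 10] = False
        out = morph_close(BinaryMask(m), StructuringElement(2))
        assert out.data[10, 10]

    def test_monotonicity_and_idempotence_random(self, rng):
        se = StructuringElement(2)
        for _ in range(20):
            m = BinaryMask(rng.random((16, 16, 2)) < 0.5)
            opened = morph_open(m, se)
            closed = morph_close(m, se)
            assert not np.any(opened.data & ~m.data)  # opening never adds
            assert not np.any(m.data & ~closed.data)  # closing never removes
            np.testing.assert_array_equal(
                morph_open(opened, se).data, opened.data
            )
            np.testing.assert_array_equal(
                morph_close(closed, se).data, closed.data
            )

    def test_oversized_radius_rejected(self):
        with pytest.raises(ParameterError):
            morph_open(BinaryMask(np.ones((10, 10), bool)), StructuringElement(6))

    def test_radius_below_one_rejected(self):
        with pytest.raises(ParameterError):
            StructuringElement(0)


class TestPolygons:
    def test_two_vertices_rejected(self):
        with pytest.raises(PreconditionError):
            Polygon(vertices=((0, 0), (1, 1)))

    def test_square_add_matches_point_in_polygon_oracle(self):
        poly = Polygon(vertices=((1.5, 1.5), (5.5, 1.5), (5.5, 5.5), (1.5, 5.5)))
        mask = BinaryMask(np.zeros((10, 10), bool))
        out = apply_polygon(mask, poly, 0)
        assert out.data.sum() == 16  # voxels (2..5, 2..5)
        shp = ShapelyPolygon(poly.vertices)
        for i in range(10):
            for j in range(10):
                assert out.data[i, j] == shp.contains(Point(i, j))

    def test_random_polygons_match_shapely_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            # star-shaped vertices around a random center: a valid simple polygon
            cx, cy = rng.uniform(4, 11, 2)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            radius = rng.uniform(1.5, 3.8, n)
            verts = tuple(
                (cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radius, angles)
            )
            poly = Polygon(vertices=verts)
            out = apply_polygon(BinaryMask(np.zeros((16, 16), bool)), poly, 0)
            shp = ShapelyPolygon(verts)
            expected = np.array(
                [[shp.contains(Point(i, j)) for j in range(16)] for i in range(16)]
            )
            # boundary-grazing centers may differ by floating-point convention
            disagreement = np.sum(out.data != expected)
            assert disagreement == 0

    def test_remove_mode_clears_only_interior(self):
        poly_add = Polygon(vertices=((1.5, 1.5), (5.5, 1.5), (5.5, 5.5), (1.5, 5.5)))
        full = BinaryMask(np.ones((10, 10), bool))
        removed = apply_polygon(full, Polygon(poly_add.vertices, mode="remove"), 0)
        assert removed.data.sum() == 100 - 16

    def test_slice_out_of_range(self):
        poly = Polygon(vertices=((1, 1), (3, 1), (2, 3)))
        with pytest.raises(IndexError):
            apply_polygon(BinaryMask(np.zeros((8, 8, 2), bool)), poly, 5)


class TestHemispheres:
    def _brain(self):
        spec = PhantomSpec(shape=(32, 32, 4))
        _, masks = make_structural_phantom(spec)
        return masks["brain"]

    def test_left_polygons_give_left_half(self):
        brain = self._brain()
        nx, ny, nz = brain.data.shape
        half = Polygon(
            vertices=((-0.49, -0.49), (nx / 2 - 0.51, -0.49),
                      (nx / 2 - 0.51, ny - 0.51), (-0.49, ny - 0.51))
        )
        hemi = segment_hemisphere(brain, {z: half for z in range(nz)})
        expected = brain.data.copy()
        expected[int(nx / 2):, :, :] = False
        np.testing.assert_array_equal(hemi.data, expected)

    def test_polygons_outside_brain_give_empty(self):
        brain = self._brain()
        corner = Polygon(vertices=((-0.4, -0.4), (1.4, -0.4), (1.4, 1.4), (-0.4, 1.4)))
        hemi = segment_hemisphere(brain, {0: corner})
        assert hemi.n_voxels == 0

    def test_cover_all_returns_brain(self):
        brain = self._brain()
        nx, ny, nz = brain.data.shape
        allpoly = Polygon(
            vertices=((-0.49, -0.49), (nx - 0.51, -0.49),
                      (nx - 0.51, ny - 0.51), (-0.49, ny - 0.51))
        )
        hemi = segment_hemisphere(brain, {z: allpoly for z in range(nz)})
        np.testing.assert_array_equal(hemi.data, brain.data)

    def test_autocomplete_partitions_brain(self, rng):
        for _ in range(25):
            brain_data = rng.random((12, 12, 3)) < 0.4
            sub = brain_data & (rng.random((12, 12, 3)) < 0.5)
            brain = BinaryMask(brain_data, role=MaskRole.BRAIN)
            ipsi = BinaryMask(sub, role=MaskRole.HEMISPHERE_IPSI)
            contra = autocomplete_contralateral(brain, ipsi)
            assert not np.any(contra.data & ipsi.data)
            np.testing.assert_array_equal(contra.data | ipsi.data, brain.data)

    def test_autocomplete_edge_cases(self):
        brain = BinaryMask(np.ones((4, 4), bool), role=MaskRole.BRAIN)
        whole = BinaryMask(np.ones((4, 4), bool), role=MaskRole.HEMISPHERE_IPSI)
        empty = BinaryMask(np.zeros((4, 4), bool), role=MaskRole.HEMISPHERE_IPSI)
        assert autocomplete_contralateral(brain, whole).n_voxels == 0
        np.testing.assert_array_equal(
            autocomplete_contralateral(brain, empty).data, brain.data
        )

    def test_autocomplete_rejects_non_subset(self):
        brain = BinaryMask(np.zeros((4, 4), bool), role=MaskRole.BRAIN)
        hemi = BinaryMask(np.ones((4, 4), bool), role=MaskRole.HEMISPHERE_IPSI)
        with pytest.raises(ConsistencyError):
            autocomplete_contralateral(brain, hemi)


class TestActiveContour:
    def test_bright_disk_recovered_from_small_seed(self):
        xx, yy = np.mgrid[:32, :32]
        disk_mask = (xx - 16) ** 2 + (yy - 16) ** 2 <= 10**2
        img = np.where(disk_mask, 200.0, 20.0)
        seed = BinaryMask((xx - 16) ** 2 + (yy - 16) ** 2 <= 4**2)
        out = active_contour_roi(ImageVolume(img, G), seed, iterations=200)
        assert dice(out, BinaryMask(disk_mask)).value >= 0.9

    def test_uniform_image_returns_seed(self):
        seed_data = np.zeros((16, 16), bool)
        seed_data[6:10, 6:10] = True
        out = active_contour_roi(
            ImageVolume(np.full((16, 16), 5.0), G), BinaryMask(seed_data), iterations=50
        )
        np.testing.assert_array_equal(out.data, seed_data)

    def test_zero_iterations_rejected(self):
        seed = BinaryMask(np.ones((8, 8), bool))
        with pytest.raises(PreconditionError):
            active_contour_roi(ImageVolume(np.zeros((8, 8)), G), seed, iterations=0)


class TestSupervoxels:
    def test_two_halves_recovered(self):
        img = np.zeros((40, 20))
        img[20:, :] = 100.0
        labels = supervoxel_partition(ImageVolume(img, G), 2)
        assert labels.min() >= 1
        ids = np.unique(labels)
        assert 2 <= len(ids) <= 4  # within a factor of 2 of the request
        for half in (img == 0, img == 100):
            best = max(
                2 * np.sum((labels == i) & half) / ((labels == i).sum() + half.sum())
                for i in ids
            )
            assert best >= 0.95

    def test_every_voxel_labeled(self, rng):
        img = rng.random((12, 12, 4))
        labels = supervoxel_partition(ImageVolume(img, G), 6)
        assert labels.shape == img.shape
        assert np.all(labels >= 1)

    def test_parameter_errors(self):
        vol = ImageVolume(np.zeros((4, 4)), G)
        with pytest.raises(ParameterError):
            supervoxel_partition(vol, 1)
        with pytest.raises(ParameterError):
            supervoxel_partition(vol, 16)
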