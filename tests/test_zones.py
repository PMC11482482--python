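"""Contour extraction, revolution, rigid registration and overlap metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import ablasim as ab
from ablasim.zones import RigidTransform, ZoneContour, ZoneVolume


def cube_volume(lo, hi, n=12, spacing=1e-3):
    mask = np.zeros((n, n, n), dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return ZoneVolume(mask=mask, spacing=spacing, origin=np.zeros(3))


class TestExtractContour:
    def test_linear_field_isoline_position(self):
        """f(r, z) = 100 - r_mm at level 60 crosses at r = 40 mm."""
        r = np.linspace(0.5e-3, 59.5e-3, 60)
        z = np.linspace(0.5e-3, 29.5e-3, 30)
        field = 100.0 - r[:, None] * 1e3 + 0.0 * z[None, :]
        contour = ab.extract_contour(field, r, z, level=60.0)
        assert not contour.is_empty
        pts = np.vstack(contour.loops)
        # the loop closes along the padded domain edge; keep the isoline part
        interior = pts[(pts[:, 1] > 5e-3) & (pts[:, 1] < 25e-3) & (pts[:, 0] > 5e-3)]
        assert np.allclose(interior[:, 0], 40e-3, atol=0.5e-3)

    def test_full_mask_contour_encloses_domain(self):
        from shapely.geometry import Polygon

        r = np.linspace(0.5e-3, 19.5e-3, 20)
        z = np.linspace(0.5e-3, 19.5e-3, 20)
        contour = ab.extract_contour(np.ones((20, 20)), r, z)
        assert len(contour.loops) == 1
        area = Polygon(contour.loops[0]).area
        assert area >= 0.95 * (20e-3 * 20e-3)

    def test_empty_mask_empty_contour(self):
        r = z = np.linspace(0.5e-3, 9.5e-3, 10)
        assert ab.extract_contour(np.zeros((10, 10)), r, z).is_empty


class TestRevolve:
    def test_rectangle_revolves_to_cylinder(self):
        """r in [0, 10 mm], z in [0, 20 mm] -> pi R^2 H ~ 6283 mm^3."""
        loop = np.array([[0, 0], [10e-3, 0], [10e-3, 20e-3], [0, 20e-3], [0, 0]])
        vol = ab.revolve(ZoneContour(loops=[loop]), voxel_spacing=0.5e-3)
        analytic = np.pi * 10e-3**2 * 20e-3
        assert vol.volume == pytest.approx(analytic, rel=0.02)
        assert vol.volume == vol.voxel_count * vol.spacing**3

    def test_semicircle_revolves_to_sphere(self):
        theta = np.linspace(-np.pi / 2, np.pi / 2, 200)
        loop = np.column_stack([10e-3 * np.cos(theta), 10e-3 * np.sin(theta)])
        loop = np.vstack([loop, loop[0]])
        vol = ab.revolve(ZoneContour(loops=[loop]), voxel_spacing=0.5e-3)
        analytic = 4 / 3 * np.pi * 10e-3**3
        assert vol.volume == pytest.approx(analytic, rel=0.02)

    def test_voxel_volume_converges_with_spacing(self):
        theta = np.linspace(-np.pi / 2, np.pi / 2, 200)
        loop = np.column_stack([8e-3 * np.cos(theta), 8e-3 * np.sin(theta)])
        analytic = 4 / 3 * np.pi * 8e-3**3
        errs = [
            abs(ab.revolve(ZoneContour(loops=[loop]), voxel_spacing=s).volume - analytic) / analytic
            for s in (1.0e-3, 0.5e-3)
        ]
        assert errs[1] < errs[0]

    def test_empty_contour_empty_volume(self):
        vol = ab.revolve(ZoneContour(loops=[]))
        assert vol.voxel_count == 0

    def test_negative_radius_rejected(self):
        loop = np.array([[-1e-3, 0], [5e-3, 0], [5e-3, 5e-3], [-1e-3, 5e-3], [-1e-3, 0]])
        with pytest.raises(ValueError, match="r < 0"):
            ab.revolve(ZoneContour(loops=[loop]))


class TestRegister:
    def test_self_registration_is_identity(self):
        vol = cube_volume((2, 2, 2), (9, 9, 9))
        tf = ab.register(vol, vol)
        assert tf.provenance == "icp"
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-6)
        assert np.all(np.abs(tf.translation) < 0.01 * vol.spacing)

    def test_translation_recovered(self):
        fixed = cube_volume((2, 2, 2), (9, 9, 9))
        moving = ZoneVolume(mask=fixed.mask.copy(), spacing=fixed.spacing,
                            origin=fixed.origin + np.array([5e-3, 0, 0]))
        tf = ab.register(moving, fixed)
        assert np.allclose(tf.translation, [-5e-3, 0, 0], atol=0.2e-3)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-3)

    def test_supplied_transform_returned_unchanged(self):
        vol = cube_volume((2, 2, 2), (9, 9, 9))
        supplied = RigidTransform.identity()
        tf = ab.register(vol, vol, transform=supplied)
        assert tf.provenance == "supplied"
        assert np.allclose(tf.to_matrix(), np.eye(4))

    def test_non_rigid_matrix_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.diag([2.0, 1.0, 1.0]), translation=np.zeros(3))
        with pytest.raises(ValueError):  # reflection: determinant -1
            RigidTransform(rotation=np.diag([-1.0, 1.0, 1.0]), translation=np.zeros(3))

    def test_empty_volume_rejected(self):
        empty = ZoneVolume(mask=np.zeros((4, 4, 4), bool), spacing=1e-3)
        full = cube_volume((0, 0, 0), (4, 4, 4), n=4)
        with pytest.raises(ValueError):
            ab.register(empty, full)


class TestMetrics:
    def test_identical_masks(self):
        vol = cube_volume((2, 2, 2), (9, 9, 9))
        rep = ab.compute_metrics(vol, vol)
        assert rep.dice == 1.0
        assert rep.hausdorff_mm == 0.0
        assert rep.mean_euclidean_mm == 0.0

    def test_half_overlapping_cubes(self):
        """Two 10^3 cubes sharing a 5x10x10 block: Dice = 2*500/2000 = 0.5."""
        a = cube_volume((0, 0, 0), (10, 10, 10), n=15)
        b = cube_volume((5, 0, 0), (15, 10, 10), n=15)
        assert ab.compute_metrics(a, b).dice == pytest.approx(0.5)

    def test_disjoint_masks(self):
        a = cube_volume((0, 0, 0), (4, 4, 4), n=12)
        b = cube_volume((8, 8, 8), (12, 12, 12), n=12)
        rep = ab.compute_metrics(a, b)
        assert rep.dice == 0.0
        assert rep.hausdorff_mm > 0

    def test_both_empty_rejected(self):
        empty = ZoneVolume(mask=np.zeros((4, 4, 4), bool), spacing=1e-3)
        with pytest.raises(ValueError, match="undefined"):
            ab.compute_metrics(empty, empty)

    def test_symmetry(self, rng):
        a = ZoneVolume(mask=rng.random((10, 10, 10)) > 0.6, spacing=1e-3)
        b = ZoneVolume(mask=rng.random((10, 10, 10)) > 0.6, spacing=1e-3)
        ra, rb = ab.compute_metrics(a, b), ab.compute_metrics(b, a)
        assert ra.dice == pytest.approx(rb.dice)
        assert ra.hausdorff_mm == pytest.approx(rb.hausdorff_mm)
        assert ra.mean_euclidean_mm == pytest.approx(rb.mean_euclidean_mm)

    def test_brute_force_all_pairs_oracle(self, rng):
        """KD-tree surface distances equal exhaustive all-pairs computation."""
        for _ in range(3):
            a = ZoneVolume(mask=ndimage_smooth(rng, 12), spacing=1e-3)
            b = ZoneVolume(mask=ndimage_smooth(rng, 12), spacing=1e-3)
            if a.voxel_count == 0 or b.voxel_count == 0:
                continue
            rep = ab.compute_metrics(a, b)
            pa, pb = a.surface_points(), b.surface_points()
            d = cdist(pa, pb)
            da, db = d.min(axis=1), d.min(axis=0)
            assert rep.hausdorff_mm == pytest.approx(max(da.max(), db.max()) * 1e3)
            assert rep.mean_euclidean_mm == pytest.approx(
                (da.sum() + db.sum()) / (len(da) + len(db)) * 1e3
            )
            inter = (a.mask & b.mask).sum()
            assert rep.dice == pytest.approx(2 * inter / (a.mask.sum() + b.mask.sum()))

    def test_metrics_invariant_under_common_shift(self):
        """Shifting both volumes by the same whole-voxel offset changes nothing."""
        a = cube_volume((1, 1, 1), (7, 8, 6), n=14)
        b = cube_volume((3, 2, 1), (9, 9, 8), n=14)
        base = ab.compute_metrics(a, b)
        a2 = ZoneVolume(mask=np.roll(a.mask, (2, 1, 3), axis=(0, 1, 2)), spacing=a.spacing)
        b2 = ZoneVolume(mask=np.roll(b.mask, (2, 1, 3), axis=(0, 1, 2)), spacing=b.spacing)
        shifted = ab.compute_metrics(a2, b2)
        assert shifted.dice == pytest.approx(base.dice)
        assert shifted.hausdorff_mm == pytest.approx(base.hausdorff_mm, abs=1.0)

    def test_resampling_through_translation(self):
        """A supplied transform mapping the moving frame onto the fixed frame
        restores perfect overlap."""
        fixed = cube_volume((2, 2, 2), (9, 9, 9))
        moving = ZoneVolume(mask=fixed.mask.copy(), spacing=fixed.spacing,
                            origin=fixed.origin + np.array([3e-3, 0, 0]))
        tf = RigidTransform(np.eye(3), np.array([-3e-3, 0.0, 0.0]))
        rep = ab.compute_metrics(moving, fixed, tf)
        assert rep.dice == 1.0
        assert rep.hausdorff_mm == 0.0


def ndimage_smooth(rng, n):
    from scipy import ndimage

    blob = ndimage.gaussian_filter(rng.random((n, n, n)), sigma=2.0)
    return blob > np.quantile(blob, 0.7)
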