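"""Transform algebra, rescaling, compositing, and warping contracts."""

import numpy as np
import pytest

from sectionfuse.core import BinaryMask, PointSet2D, Raster2D
from sectionfuse.synthetic import make_deformation
from sectionfuse.transforms import (
    AffineTransform,
    DisplacementField,
    TransformChain,
    rescale_transform,
    warp_image,
    warp_labels,
    warp_mask,
    warp_points,
)


class TestAffine:
    def test_compose_then_apply(self, rng):
        a = AffineTransform.rotation(30.0, (5.0, 5.0))
        b = AffineTransform.translation(3.0, -2.0)
        pts = rng.uniform(0, 10, (20, 2))
        assert np.allclose((a @ b).apply(pts), a.apply(b.apply(pts)))

    def test_inverse_roundtrip(self, rng):
        a = AffineTransform.from_params([4, -1, 17, 0.1, -0.05, 0.2], (10, 20))
        pts = rng.uniform(0, 40, (50, 2))
        assert np.allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-9)

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((2, 2)), np.zeros(2))


class TestRescale:
    def test_identity_stays_identity(self):
        out = rescale_transform(AffineTransform.identity(), (100, 100), (300, 300))
        assert np.allclose(out.matrix, np.eye(2))
        assert np.allclose(out.offset, 0.0)

    def test_uniform_translation_field_scales_linearly(self):
        disp = np.zeros((20, 20, 2))
        disp[..., 0] = 5.0
        fld = DisplacementField(backward=disp)
        out = rescale_transform(fld, (20, 20), (40, 40))
        assert out.backward.shape == (40, 40, 2)
        assert np.allclose(out.backward[..., 0], 10.0)
        assert np.allclose(out.backward[..., 1], 0.0)

    def test_smooth_field_down_up_roundtrip(self):
        fld = make_deformation(3, (80, 80), amplitude_px=5.0, smoothness_px=25.0)
        down = rescale_transform(fld, (80, 80), (40, 40))
        up = rescale_transform(down, (40, 40), (80, 80))
        assert np.abs(up.backward - fld.backward).max() < 0.5

    def test_translation_affine_conjugation(self):
        t = AffineTransform.translation(5.0, 0.0)
        out = rescale_transform(t, (50, 50), (100, 100))
        pts = out.apply([[10.0, 10.0]])
        assert np.allclose(pts, [[20.0, 10.0]])


class TestComposite:
    def test_two_identities(self):
        chain = TransformChain(
            [AffineTransform.identity(), AffineTransform.identity()],
            fixed_shape=(16, 16), moving_shape=(16, 16),
        )
        fld = chain.composite()
        assert np.abs(fld.backward).max() < 1e-9
        assert np.abs(fld.forward).max() < 1e-9

    def test_translations_add(self):
        chain = TransformChain(
            [AffineTransform.translation(3, 0), AffineTransform.translation(0, 4)],
            fixed_shape=(16, 16), moving_shape=(16, 16),
        )
        fld = chain.composite()
        assert np.allclose(fld.forward[..., 0], 3.0)
        assert np.allclose(fld.forward[..., 1], 4.0)

    def test_composite_matches_sequential_application(self, rng):
        shape = (120, 120)
        aff = AffineTransform.from_params([6, -3, 10, 0.05, 0, 0], (60, 60))
        nr = make_deformation(5, shape, amplitude_px=8.0, smoothness_px=40.0)
        chain = TransformChain([aff, nr], fixed_shape=shape, moving_shape=shape)
        pts = rng.uniform(10, 110, (200, 2))
        sequential = nr.forward_points(aff.apply(pts))
        composed = chain.composite()
        via_field = pts + np.stack(
            [
                _interp(composed.forward[..., c], pts) for c in range(2)
            ],
            axis=1,
        )
        assert np.abs(via_field - sequential).max() < 0.5

    def test_forward_backward_roundtrip(self, rng):
        shape = (120, 120)
        nr = make_deformation(9, shape, amplitude_px=10.0, smoothness_px=40.0)
        chain = TransformChain([nr], fixed_shape=shape, moving_shape=shape)
        fld = chain.composite()
        pts = rng.uniform(20, 100, (1000, 2))
        rt = fld.backward_points(fld.forward_points(pts))
        assert np.linalg.norm(rt - pts, axis=1).mean() < 0.5


def _interp(grid, pts):
    from scipy import ndimage

    return ndimage.map_coordinates(
        grid, np.stack([pts[:, 1], pts[:, 0]]), order=1, mode="nearest"
    )


class TestWarpImage:
    def test_identity_field_is_pixel_identity(self, rng):
        img = Raster2D(rng.integers(0, 255, (30, 30), dtype=np.uint8).astype(np.uint8))
        fld = DisplacementField(backward=np.zeros((30, 30, 2)))
        out = warp_image(img, fld)
        assert np.array_equal(out.pixels, img.pixels)

    def test_integer_translation_exact_shift(self, rng):
        img = Raster2D(rng.uniform(0, 1, (20, 20)))
        fld = DisplacementField.from_affine(
            AffineTransform.translation(3, 2), (20, 20)
        )
        out = warp_image(img, fld, fill=0.0)
        assert np.allclose(out.pixels[5, 7], img.pixels[3, 4])
        assert np.allclose(out.pixels[:2, :], 0.0)  # fill border

    def test_warp_then_inverse_recovers_interior(self, scene):
        img = scene.image.to_gray()
        fld = make_deformation(2, img.shape, amplitude_px=8.0, smoothness_px=60.0)
        warped = warp_image(img, fld, fill=250.0)
        inv = DisplacementField(backward=fld.forward, forward=fld.backward)
        back = warp_image(warped, inv, fill=250.0)
        interior = scene.tissue_mask.pixels
        from scipy import ndimage

        interior = ndimage.binary_erosion(interior, iterations=12)
        err = np.abs(back.pixels[interior] - img.pixels[interior]).mean()
        assert err < 0.02 * 255


class TestWarpMaskAndLabels:
    def test_identity(self, rng):
        mask = BinaryMask(rng.uniform(size=(25, 25)) < 0.3)
        fld = DisplacementField(backward=np.zeros((25, 25, 2)))
        assert np.array_equal(warp_mask(mask, fld).pixels, mask.pixels)

    def test_180_rotation_preserves_area(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:40, 5:25] = True
        mask[12:20, 30:55] = True
        rot = AffineTransform.rotation(180.0, (31.5, 31.5))
        fld = DisplacementField.from_affine(rot, (64, 64))
        out = warp_mask(BinaryMask(mask), fld)
        assert abs(out.pixels.sum() - mask.sum()) <= 0.01 * mask.sum()

    def test_labels_never_invented(self, rng):
        labels = rng.choice([0, 3, 7, 11], size=(40, 40)).astype(np.int32)
        fld = make_deformation(4, (40, 40), amplitude_px=3.0, smoothness_px=15.0)
        out = warp_labels(labels, fld)
        assert set(np.unique(out)) <= set(np.unique(labels))


class TestWarpPoints:
    def test_identity(self, rng):
        pts = PointSet2D(rng.uniform(0, 20, (10, 2)))
        fld = DisplacementField(
            backward=np.zeros((25, 25, 2)), forward=np.zeros((25, 25, 2))
        )
        assert np.allclose(warp_points(pts, fld).points, pts.points)

    def test_translation_shifts_all(self, rng):
        pts = PointSet2D(rng.uniform(2, 18, (10, 2)))
        fld = DisplacementField.from_affine(
            AffineTransform.translation(4, -1), (25, 25)
        )
        assert np.allclose(warp_points(pts, fld).points, pts.points + [4, -1])

    def test_point_and_image_pathways_agree(self):
        """A delta spike warped as an image lands where its coordinate warps."""
        fld = make_deformation(8, (60, 60), amplitude_px=5.0, smoothness_px=25.0)
        spike = np.zeros((60, 60))
        spike[30, 24] = 1.0
        warped = warp_image(Raster2D(spike), fld).pixels
        peak = np.unravel_index(np.argmax(warped), warped.shape)
        pt = fld.forward_points([[24.0, 30.0]])[0]
        assert abs(peak[1] - pt[0]) <= 1.0 and abs(peak[0] - pt[1]) <= 1.0

    def test_geojson_topology_preserved(self):
        from sectionfuse.core import LabeledPolygon, PolygonAnnotation
        from sectionfuse.transforms import warp_geojson

        ann = PolygonAnnotation([
            LabeledPolygon([[2, 2], [10, 2], [10, 10], [2, 10]],
                           holes=[[[4, 4], [6, 4], [6, 6]]], label="roi")
        ])
        fld = DisplacementField.from_affine(
            AffineTransform.translation(1, 2), (20, 20)
        )
        out = warp_geojson(ann, fld)
        assert out.shapes[0].label == "roi"
        assert len(out.shapes[0].holes) == 1
        assert np.allclose(out.shapes[0].exterior,
                           ann.shapes[0].exterior + [1, 2])


class TestPointRasterConsistency:
    def test_points_land_on_their_own_warped_label(self, rng):
        labels = np.zeros((80, 80), dtype=np.int32)
        for k, (y, x) in enumerate([(20, 20), (20, 55), (55, 20), (55, 55)], 1):
            labels[y - 8:y + 8, x - 8:x + 8] = k
        fld = make_deformation(6, (80, 80), amplitude_px=4.0, smoothness_px=30.0)
        warped = warp_labels(labels, fld)
        hits = total = 0
        for k, (y, x) in enumerate([(20, 20), (20, 55), (55, 20), (55, 55)], 1):
            pts = np.stack([rng.uniform(x - 5, x + 5, 50),
                            rng.uniform(y - 5, y + 5, 50)], axis=1)
            moved = fld.forward_points(pts)
            for mx, my in moved:
                total += 1
                hits += warped[int(round(my)), int(round(mx))] == k
        assert hits / total >= 0.99


class TestAgainstSimpleITK:
    def test_warp_matches_sitk_displacement_resampler(self):
        """Independent oracle: warping through a displacement field agrees
        with SimpleITK's resampler on the same field."""
        import SimpleITK as sitk

        rng = np.random.default_rng(3)
        img = ndimage_smooth(rng.uniform(0, 1, (64, 64)))
        fld = make_deformation(12, (64, 64), amplitude_px=5.0, smoothness_px=20.0)
        ours = warp_image(Raster2D(img), fld, fill=0.0).pixels

        disp = np.ascontiguousarray(fld.backward[:, :, :2])  # (H, W, [dx, dy])
        sitk_disp = sitk.GetImageFromArray(disp.astype(np.float64), isVector=True)
        tx = sitk.DisplacementFieldTransform(sitk_disp)
        ref = sitk.GetImageFromArray(img)
        warped = sitk.Resample(ref, ref, tx, sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(warped)
        interior = np.s_[8:-8, 8:-8]
        assert np.abs(ours[interior] - theirs[interior]).max() < 1e-6


def ndimage_smooth(a):
    from scipy import ndimage as _ndi

    return _ndi.gaussian_filter(a, 3.0)
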