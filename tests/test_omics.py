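"""Grid projection of spot/pixel geometries and the omics feature image."""

import numpy as np
import pandas as pd
import pytest

from sectionfuse.core import SectionFuseError
from sectionfuse.omics import (
    MeasurementTable,
    PixelGeometry,
    SpotGeometry,
    msi_feature_image,
    project_pixels,
    project_spots,
)


def circle_cell_count(diameter_um, resolution_um=1.0):
    """Brute-force point-in-circle enumeration oracle."""
    r = diameter_um / 2 / resolution_um
    n = int(np.ceil(r)) + 1
    xs = np.arange(-n, n + 1)
    xx, yy = np.meshgrid(xs, xs)
    return int((xx**2 + yy**2 <= r**2).sum())


class TestProjectSpots:
    def test_single_spot_matches_enumeration(self):
        geom = SpotGeometry(["s"], [[100.0, 100.0]], diameter_um=55.0)
        ref = project_spots(geom, (200, 200), 1.0)
        want = circle_cell_count(55.0)
        got = (ref.labels == 1).sum()
        assert want == pytest.approx(2376, rel=0.01)  # sanity on the oracle
        assert abs(got - want) <= 0.01 * want

    def test_spot_fully_off_image(self):
        geom = SpotGeometry(["in", "out"], [[50.0, 50.0], [500.0, 500.0]])
        ref = project_spots(geom, (100, 100), 1.0)
        assert ref.off_image == ["out"]
        assert (ref.labels == 2).sum() == 0
        assert (ref.labels == 1).sum() > 0

    def test_hex_neighbors_do_not_overlap(self):
        geom = SpotGeometry(["a", "b"], [[100.0, 100.0], [200.0, 100.0]],
                            diameter_um=55.0, pitch_um=100.0)
        ref = project_spots(geom, (200, 300), 1.0)
        a = set(zip(*np.nonzero(ref.labels == 1)))
        b = set(zip(*np.nonzero(ref.labels == 2)))
        assert not (a & b)
        assert len(a) == len(b)

    def test_overlap_tie_breaks_to_lower_id(self):
        geom = SpotGeometry(["a", "b"], [[50.0, 50.0], [60.0, 50.0]],
                            diameter_um=30.0, pitch_um=100.0)
        with pytest.warns(UserWarning, match="overlap"):
            ref = project_spots(geom, (100, 100), 1.0)
        # shared cells went to 'a' (lower id processed first)
        mid = ref.labels[50, 52:58]
        assert np.all(mid[mid > 0] == 1)

    def test_diameter_exceeding_pitch_rejected(self):
        with pytest.raises(SectionFuseError, match="pitch"):
            SpotGeometry(["a"], [[0.0, 0.0]], diameter_um=120.0, pitch_um=100.0)


class TestProjectPixels:
    def test_single_pixel_is_900_cells(self):
        geom = PixelGeometry(["p"], [[0, 0]], origin_um=(0.0, 0.0), pitch_um=30.0)
        ref = project_pixels(geom, (60, 60), 1.0)
        assert (ref.labels == 1).sum() == 900

    def test_adjacent_pixels_disjoint_1800(self):
        geom = PixelGeometry(["p", "q"], [[0, 0], [1, 0]], pitch_um=30.0)
        ref = project_pixels(geom, (60, 90), 1.0)
        assert (ref.labels > 0).sum() == 1800
        assert (ref.labels == 1).sum() == 900
        assert (ref.labels == 2).sum() == 900

    def test_edge_clipping_matches_enumeration(self):
        geom = PixelGeometry(["p"], [[0, 0]], origin_um=(45.0, 50.0), pitch_um=30.0)
        ref = project_pixels(geom, (60, 60), 1.0)
        # square spans x in [45, 75) clipped at 60 -> 15 columns, y [50, 60) -> 10 rows
        assert (ref.labels == 1).sum() == 15 * 10

    def test_area_per_id_within_1pct(self):
        geom = PixelGeometry([f"p{i}" for i in range(4)],
                             [[0, 0], [1, 0], [0, 1], [1, 1]], pitch_um=30.0)
        ref = project_pixels(geom, (100, 100), 1.0)
        for count in ref.pixel_counts().values():
            assert abs(count - 900) <= 9


class TestFeatureImage:
    def _geom(self, n=50):
        side = int(np.ceil(np.sqrt(n)))
        coords = [(i % side, i // side) for i in range(n)]
        return PixelGeometry([f"p{i}" for i in range(n)], coords, pitch_um=30.0)

    def test_single_channel_passthrough_correlates(self, rng):
        vals = rng.uniform(1, 9, 25)
        geom = self._geom(25)
        table = MeasurementTable(pd.DataFrame({"a": vals},
                                              index=[f"p{i}" for i in range(25)]))
        feat = msi_feature_image(table, geom, target_resolution_um=30.0)
        flat = feat.pixels[geom.grid_xy[:, 1], geom.grid_xy[:, 0]]
        assert abs(np.corrcoef(flat, vals)[0, 1]) > 0.999

    def test_two_correlated_channels_rank_one(self, rng):
        base = rng.normal(0, 1, 36)
        geom = self._geom(36)
        table = MeasurementTable(
            pd.DataFrame({"a": base, "b": 2 * base + 5},
                         index=[f"p{i}" for i in range(36)])
        )
        feat = msi_feature_image(table, geom, target_resolution_um=30.0)
        assert abs(np.corrcoef(feat.scores, base)[0, 1]) > 0.999999

    def test_scores_match_covariance_eigenvector_oracle(self, rng):
        x = rng.normal(0, 1, (50, 20))
        geom = self._geom(50)
        table = MeasurementTable(
            pd.DataFrame(x, index=[f"p{i}" for i in range(50)])
        )
        feat = msi_feature_image(table, geom, target_resolution_um=30.0)
        centered = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(centered.T, bias=True))
        pc1 = centered @ evecs[:, -1]
        r = np.corrcoef(feat.scores, pc1)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8

    def test_constant_spectra_degenerate(self):
        geom = self._geom(9)
        table = MeasurementTable(
            pd.DataFrame({"a": np.ones(9), "b": np.ones(9)},
                         index=[f"p{i}" for i in range(9)])
        )
        with pytest.raises(SectionFuseError, match="degenerate"):
            msi_feature_image(table, geom)


class TestLabelConservation:
    def test_warped_reference_matrix_conserves_ids(self, rng):
        from sectionfuse.synthetic import make_deformation
        from sectionfuse.transforms import warp_labels

        geom = SpotGeometry(
            [f"s{i}" for i in range(9)],
            [(100.0 + 100 * (i % 3), 100.0 + 100 * (i // 3)) for i in range(9)],
        )
        ref = project_spots(geom, (400, 400), 1.0)
        fld = make_deformation(3, (400, 400), amplitude_px=4.0, smoothness_px=120.0)
        warped = warp_labels(ref.labels, fld)
        assert set(np.unique(warped)) <= set(np.unique(ref.labels))
        before = ref.pixel_counts()
        after = np.bincount(warped.ravel(), minlength=10)
        for k, sid in enumerate(geom.ids, start=1):
            assert abs(after[k] - before[sid]) < 0.05 * before[sid]


class TestRigidRegisterMSI:
    def _stained(self):
        from sectionfuse.synthetic import make_tissue_image

        return make_tissue_image(17, size_px=500, n_glands=10)

    def test_identical_feature_recovers_identity(self):
        from sectionfuse.core import Raster2D
        from sectionfuse.omics import rigid_register_msi
        from sectionfuse.registration import RegistrationOptions

        scene = self._stained()
        gray = scene.image.to_gray().pixels
        feature = Raster2D(gray.max() - gray)  # tissue-bright, like a PC1 map
        opts = RegistrationOptions(working_size=256, seed=0, denoise=False)
        aff = rigid_register_msi(feature, scene.image, scene.tissue_mask,
                                 feature_mask=scene.tissue_mask, opts=opts)
        pts = scene.landmarks.points
        err = np.linalg.norm(aff.apply(pts) - pts, axis=1)
        assert np.median(err) < 0.5

    def test_known_rotation_translation_recovered(self):
        from sectionfuse.core import BinaryMask, Raster2D
        from sectionfuse.omics import rigid_register_msi
        from sectionfuse.registration import RegistrationOptions
        from sectionfuse.transforms import (AffineTransform, DisplacementField,
                                            warp_image, warp_mask)

        scene = self._stained()
        gray = scene.image.to_gray().pixels
        inv = Raster2D(gray.max() - gray)
        h, w = inv.shape
        center = ((w - 1) / 2, (h - 1) / 2)
        rig = (AffineTransform.rotation(10.0, center)
               @ AffineTransform.translation(20.0, -5.0))
        fld = DisplacementField.from_affine(rig, (h, w))
        feature = warp_image(inv, fld, fill=0.0)
        feature_mask = warp_mask(scene.tissue_mask, fld)
        opts = RegistrationOptions(working_size=256, seed=0, denoise=False)
        aff = rigid_register_msi(feature, scene.image, scene.tissue_mask,
                                 feature_mask=feature_mask, opts=opts)
        truth = rig.inverse()  # feature (moving) back onto the stained frame
        angle_got = np.degrees(np.arctan2(aff.matrix[1, 0], aff.matrix[0, 0]))
        angle_want = np.degrees(np.arctan2(truth.matrix[1, 0], truth.matrix[0, 0]))
        assert abs(angle_got - angle_want) < 1.0
        pts = scene.landmarks.points
        err = np.linalg.norm(aff.apply(truth.inverse().apply(pts)) - pts, axis=1)
        assert np.median(err) < 2.0  # um at 1 um/px
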