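import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from stitchkit import fixtures, stitcher
from stitchkit.transforms import AffineTransform2D
from stitchkit.visium_io import CaptureArea, ScaleFactors, SPOT_COLUMNS


def _affine_strategy():
    finite = st.floats(-3, 3, allow_nan=False)
    offsets = st.floats(-100, 100, allow_nan=False)
    return (
        st.tuples(finite, finite, finite, finite, offsets, offsets)
        .filter(lambda c: abs(c[0] * c[3] - c[1] * c[2]) > 1e-3)
        .map(lambda c: AffineTransform2D(*c))
    )


class TestApplyAffine:
    def test_identity(self):
        out = stitcher.apply_affine(AffineTransform2D.identity(), [(10, 20)])
        np.testing.assert_allclose(out, [[10, 20]])

    def test_translation(self):
        t = AffineTransform2D.translation(100, 50)
        np.testing.assert_allclose(stitcher.apply_affine(t, [(10, 20)]), [[110, 70]])

    def test_rotation_convention(self):
        t = AffineTransform2D(0, 1, -1, 0, 0, 0)
        np.testing.assert_allclose(stitcher.apply_affine(t, [(1, 0)]), [[0, 1]])

    @given(t=_affine_strategy(), pts=st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_inverse_round_trip(self, t, pts):
        fwd = stitcher.apply_affine(t, pts)
        back = stitcher.apply_affine(t.inverse(), fwd)
        np.testing.assert_allclose(back, np.asarray(pts, float), atol=1e-6)

    def test_singular_transform_unconstructible(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform2D(1, 0, 1, 0, 0, 0)


class TestEstimateAffineFromLandmarks:
    def test_exact_recovery(self):
        t = AffineTransform2D(1.2, -0.3, 0.4, 0.9, 15.0, -7.0)
        src = np.array([(0, 0), (10, 0), (0, 10), (7, 3)], float)
        dst = stitcher.apply_affine(t, src)
        est = stitcher.estimate_affine_from_landmarks(src, dst)
        np.testing.assert_allclose(est.coefficients, t.coefficients, atol=1e-9)

    def test_identity_from_equal_points(self):
        pts = np.array([(0, 0), (5, 1), (2, 8)], float)
        est = stitcher.estimate_affine_from_landmarks(pts, pts)
        np.testing.assert_allclose(est.coefficients, [1, 0, 0, 1, 0, 0], atol=1e-9)

    def test_collinear_rejected(self):
        pts = np.array([(0, 0), (1, 1), (2, 2)], float)
        with pytest.raises(ValueError, match="collinear"):
            stitcher.estimate_affine_from_landmarks(pts, pts)

    def test_too_few_points_rejected(self):
        pts = np.array([(0, 0), (1, 1)], float)
        with pytest.raises(ValueError, match="3"):
            stitcher.estimate_affine_from_landmarks(pts, pts)

    @given(t=_affine_strategy())
    @settings(max_examples=50, deadline=None)
    def test_recovery_property(self, t):
        src = np.array([(0, 0), (20, 0), (0, 20), (13, 7), (5, 17)], float)
        dst = stitcher.apply_affine(t, src)
        est = stitcher.estimate_affine_from_landmarks(src, dst)
        np.testing.assert_allclose(est.coefficients, t.coefficients, atol=1e-6)


class TestTransformSpots:
    def test_identity_suffixes_barcodes(self, small_spec):
        area = fixtures.make_capture_area(small_spec, "A")
        out = stitcher.transform_spots(area, AffineTransform2D.identity())
        np.testing.assert_array_equal(
            out[["pxl_row", "pxl_col"]].to_numpy(),
            area.spots[["pxl_row", "pxl_col"]].to_numpy(),
        )
        assert out["barcode"].str.endswith("-A").all()
        assert (out["section"] == "A").all()

    def test_array_coords_preserved(self, small_spec):
        area = fixtures.make_capture_area(small_spec, "A")
        t = AffineTransform2D(0.5, 0.1, -0.1, 0.5, 30, 40)
        out = stitcher.transform_spots(area, t)
        np.testing.assert_array_equal(
            out[["array_row", "array_col"]].to_numpy(),
            area.spots[["array_row", "array_col"]].to_numpy(),
        )

    def test_matches_ground_truth(self, three_sections):
        areas, transforms = three_sections
        for area, t in zip(areas, transforms):
            out = stitcher.transform_spots(area, t)
            expected = stitcher.apply_affine(
                t, area.spots[["pxl_col", "pxl_row"]].to_numpy(float)
            )
            np.testing.assert_allclose(out["pxl_col"], expected[:, 0], atol=1e-9)
            np.testing.assert_allclose(out["pxl_row"], expected[:, 1], atol=1e-9)

    def test_zero_spots_rejected(self):
        empty = CaptureArea(
            section_id="E",
            spots=pd.DataFrame(columns=SPOT_COLUMNS),
            counts=sp.csr_matrix((3, 0), dtype=np.int64),
            genes=["g1", "g2", "g3"],
            image=np.ones((4, 4), np.float32),
            scale=ScaleFactors(13.0, 0.5, 0.1),
        )
        with pytest.raises(ValueError, match="no spots"):
            stitcher.transform_spots(empty, AffineTransform2D.identity())


class TestCompositeImages:
    def test_single_identity(self):
        img = np.arange(24, dtype=float).reshape(4, 6)
        out, offset = stitcher.composite_images(
            {"A": img}, {"A": AffineTransform2D.identity()}, ["A"]
        )
        assert offset == (0.0, 0.0)
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_overlap_keeps_priority_value(self):
        a = np.full((10, 10), 10.0)
        b = np.full((10, 10), 200.0)
        transforms = {
            "A": AffineTransform2D.identity(),
            "B": AffineTransform2D.translation(5, 0),
        }
        out, offset = stitcher.composite_images(
            {"A": a, "B": b}, transforms, ["A", "B"]
        )
        assert offset == (0.0, 0.0)
        # overlap: columns 5..9 of the canvas lie in both pixel extents
        overlap = out[0:10, 5:10]
        np.testing.assert_allclose(overlap, 10.0)
        np.testing.assert_allclose(out[0:10, 10:15], 200.0)

    def test_disjoint_placements(self):
        a = np.full((4, 4), 7.0)
        b = np.full((4, 4), 9.0)
        transforms = {
            "A": AffineTransform2D.identity(),
            "B": AffineTransform2D.translation(10, 0),
        }
        out, _ = stitcher.composite_images(
            {"A": a, "B": b}, transforms, ["A", "B"], fill=-1.0
        )
        assert (out == 7.0).sum() == 16
        assert (out == 9.0).sum() == 16
        assert (out == -1.0).sum() == out.size - 32

    def test_negative_offset_translated_to_origin(self):
        img = np.ones((4, 4))
        t = AffineTransform2D.translation(-8, -3)
        out, offset = stitcher.composite_images({"A": img}, {"A": t}, ["A"])
        assert offset == (-8.0, -3.0)
        np.testing.assert_allclose(out, 1.0)

    def test_priority_permutation_invariance_for_centre(self):
        imgs = {
            "A": np.full((8, 8), 1.0),
            "B": np.full((8, 8), 2.0),
            "C": np.full((8, 8), 3.0),
        }
        transforms = {
            "A": AffineTransform2D.identity(),
            "B": AffineTransform2D.translation(4, 0),
            "C": AffineTransform2D.translation(0, 4),
        }
        out1, _ = stitcher.composite_images(imgs, transforms, ["A", "B", "C"])
        out2, _ = stitcher.composite_images(imgs, transforms, ["A", "C", "B"])
        centre_covered = out1 == 1.0
        np.testing.assert_array_equal(out2[centre_covered], out1[centre_covered])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no images"):
            stitcher.composite_images({}, {}, [])

    def test_priority_must_cover_all(self):
        img = np.ones((4, 4))
        with pytest.raises(ValueError, match="priority"):
            stitcher.composite_images(
                {"A": img}, {"A": AffineTransform2D.identity()}, []
            )


class TestMergeSections:
    @pytest.fixture
    def merged(self, three_sections):
        areas, transforms = three_sections
        tmap = {a.section_id: t for a, t in zip(areas, transforms)}
        return areas, tmap, stitcher.merge_sections(areas, tmap, centre_id="S1")

    def test_spot_conservation(self, merged):
        areas, _, stitched = merged
        assert len(stitched.spots) == sum(a.n_spots for a in areas)

    def test_shared_gene_list_preserved(self, merged):
        areas, _, stitched = merged
        assert stitched.genes == areas[0].genes

    def test_transform_round_trip_to_source_frames(self, merged):
        areas, tmap, stitched = merged
        ox, oy = stitched.frame_offset
        for area in areas:
            sub = stitched.spots[stitched.spots["section"] == area.section_id]
            xy = np.column_stack(
                [sub["pxl_col"].to_numpy() + ox, sub["pxl_row"].to_numpy() + oy]
            )
            back = stitcher.apply_affine(tmap[area.section_id].inverse(), xy)
            orig = area.spots[["pxl_col", "pxl_row"]].to_numpy(float)
            np.testing.assert_allclose(back, orig, atol=1e-6)

    def test_outer_join_zero_fill(self, small_spec):
        areas, transforms = fixtures.make_overlapping_sections(small_spec, 2)
        # drop last gene from section B entirely
        b = areas[1]
        gene = b.genes[-1]
        b.genes = b.genes[:-1]
        b.counts = b.counts[:-1, :]
        tmap = {a.section_id: t for a, t in zip(areas, transforms)}
        stitched = stitcher.merge_sections(areas, tmap, centre_id="S0")
        gi = stitched.genes.index(gene)
        b_spots = (stitched.spots["section"] == "S1").to_numpy()
        row = stitched.counts[gi].toarray().ravel()
        assert (row[b_spots] == 0).all()
        a_row = areas[0].counts[areas[0].genes.index(gene)].toarray().ravel()
        np.testing.assert_array_equal(row[~b_spots], a_row)

    def test_missing_transform_rejected(self, three_sections):
        areas, transforms = three_sections
        tmap = {a.section_id: t for a, t in zip(areas[:2], transforms)}
        with pytest.raises(ValueError, match="missing transforms"):
            stitcher.merge_sections(areas, tmap, centre_id="S0")

    def test_duplicate_section_ids_rejected(self, small_spec):
        area = fixtures.make_capture_area(small_spec, "A")
        tmap = {"A": AffineTransform2D.identity()}
        with pytest.raises(ValueError, match="duplicate"):
            stitcher.merge_sections([area, area], tmap, centre_id="A")

    def test_unknown_centre_rejected(self, three_sections):
        areas, transforms = three_sections
        tmap = {a.section_id: t for a, t in zip(areas, transforms)}
        with pytest.raises(ValueError, match="centre_id"):
            stitcher.merge_sections(areas, tmap, centre_id="nope")

    def test_mismatched_scale_factors_rejected(self, small_spec):
        areas, transforms = fixtures.make_overlapping_sections(small_spec, 2)
        areas[1].scale = ScaleFactors(20.0, 0.5, 0.1)
        tmap = {a.section_id: t for a, t in zip(areas, transforms)}
        with pytest.raises(ValueError, match="scale factors"):
            stitcher.merge_sections(areas, tmap, centre_id="S0")

    def test_geometry_consistency_outside_overlap(self, small_spec):
        # a constant-free patch far from any overlap must match its source
        ts = [
            AffineTransform2D.identity(),
            AffineTransform2D.translation(200.0, 0.0),  # disjoint
        ]
        areas, _ = fixtures.make_overlapping_sections(small_spec, 2, ts)
        tmap = {a.section_id: t for a, t in zip(areas, ts)}
        stitched = stitcher.merge_sections(areas, tmap, centre_id="S0")
        h, w = small_spec.image_shape
        np.testing.assert_allclose(
            stitched.image[:h, :w], areas[0].image, atol=1e-6
        )
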