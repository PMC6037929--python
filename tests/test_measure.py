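"""Diameter, perpendicular width, volume and record aggregation."""

import numpy as np
import pytest

from lesiontrack.mask import LesionMask, trace_slice_contours
from lesiontrack.measure import (
    MeasurementRecord,
    lesion_volume,
    max_inplane_diameter,
    measure_lesion,
    perpendicular_width,
    rotating_calipers_diameter,
    timepoint_summary,
)
from lesiontrack.phantom import default_geometry, rasterize_ellipsoid

from conftest import make_geometry, random_blob_slice


def slice_mask(fg, col_spacing=1.0, row_spacing=1.0, slice_spacing=2.5, **kw):
    fg = np.asarray(fg, dtype=np.uint8)
    g = make_geometry(n_cols=fg.shape[1], n_rows=fg.shape[0], n_slices=1,
                      col_spacing=col_spacing, row_spacing=row_spacing,
                      slice_spacing=slice_spacing)
    return LesionMask(g, fg[None], **kw)


def all_pairs_diameter(vertices_mm):
    """O(n^2) oracle: maximum pairwise distance over contour vertices."""
    d = np.linalg.norm(vertices_mm[:, None, :] - vertices_mm[None, :, :], axis=2)
    return float(d.max())


def contour_vertices_mm(mask, k=0):
    contours = trace_slice_contours(mask.voxels[k].astype(bool), k)
    verts = np.vstack([c.vertices for c in contours])
    return verts * [mask.geometry.col_spacing, mask.geometry.row_spacing]


class TestDiameter:
    def test_single_pixel_is_one_diagonal(self):
        fg = np.zeros((8, 8))
        fg[3, 3] = 1
        length, endpoints = max_inplane_diameter(slice_mask(fg), 0)
        assert length == pytest.approx(np.sqrt(2))
        assert endpoints is not None

    def test_pixel_row_is_rectangle_diagonal(self):
        fg = np.zeros((8, 8))
        fg[3, 1:6] = 1
        length, _ = max_inplane_diameter(slice_mask(fg), 0)
        assert length == pytest.approx(np.sqrt(26))

    def test_empty_slice_measures_zero(self):
        fg = np.zeros((8, 8))
        length, endpoints = max_inplane_diameter(slice_mask(fg), 0)
        assert length == 0.0 and endpoints is None

    def test_disc_against_all_pairs_oracle_and_analytic_bounds(self):
        g = default_geometry(n_cols=48, n_rows=48, n_slices=1, in_plane=0.7,
                             slice_spacing=5.0, origin=(-16.8, -16.8, 0.0))
        m = rasterize_ellipsoid((0.0, 0.0, 0.0), (7.0, 7.0, 10.0), g)
        length, _ = max_inplane_diameter(m, 0)
        assert length == pytest.approx(all_pairs_diameter(contour_vertices_mm(m)))
        assert 14.0 <= length <= 15.98

    @pytest.mark.parametrize("seed", range(4))
    def test_calipers_equal_all_pairs_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            fg = random_blob_slice(rng, shape=(32, 32))
            if not fg.any():
                continue
            m = slice_mask(fg, col_spacing=rng.uniform(0.5, 1.5),
                           row_spacing=rng.uniform(0.5, 1.5))
            length, _ = max_inplane_diameter(m, 0)
            assert length == pytest.approx(
                all_pairs_diameter(contour_vertices_mm(m)), abs=1e-9)

    def test_anisotropic_spacing_converts_to_mm(self):
        fg = np.zeros((8, 8))
        fg[2, 2:6] = 1  # 4 pixels along columns
        m = slice_mask(fg, col_spacing=2.0, row_spacing=0.5)
        length, _ = max_inplane_diameter(m, 0)
        assert length == pytest.approx(np.hypot(8.0, 0.5))


class TestPerpendicularWidth:
    def test_square_projects_onto_antidiagonal(self):
        fg = np.zeros((8, 8))
        fg[2:5, 2:5] = 1
        m = slice_mask(fg)
        length, (p0, p1) = max_inplane_diameter(m, 0)
        assert length == pytest.approx(3 * np.sqrt(2))
        width = perpendicular_width(m, 0, np.subtract(p1, p0))
        assert width == pytest.approx(3 * np.sqrt(2))

    def test_single_pixel_width_is_diagonal(self):
        fg = np.zeros((8, 8))
        fg[3, 3] = 1
        m = slice_mask(fg)
        assert perpendicular_width(m, 0, (1.0, 1.0)) == pytest.approx(np.sqrt(2))

    def test_matches_projection_oracle_on_random_blobs(self, rng):
        for _ in range(30):
            fg = random_blob_slice(rng, shape=(24, 24))
            if not fg.any():
                continue
            m = slice_mask(fg)
            axis = rng.normal(size=2)
            width = perpendicular_width(m, 0, axis)
            verts = contour_vertices_mm(m)
            perp = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)
            proj = verts @ perp
            assert width == pytest.approx(proj.max() - proj.min())


class TestVolume:
    def test_single_voxel(self):
        fg = np.zeros((4, 4))
        fg[1, 1] = 1
        m = slice_mask(fg, col_spacing=0.5, row_spacing=0.5, slice_spacing=2.0)
        assert lesion_volume(m) == pytest.approx(0.5)

    def test_isotropic_block(self):
        g = make_geometry(n_cols=16, n_rows=16, n_slices=12, col_spacing=1.0,
                          row_spacing=1.0, slice_spacing=1.0)
        v = np.zeros(g.shape, dtype=np.uint8)
        v[1:11, 2:12, 3:13] = 1
        assert lesion_volume(LesionMask(g, v)) == pytest.approx(1000.0)

    def test_rasterized_ellipsoid_close_to_analytic(self):
        g = default_geometry(n_cols=48, n_rows=44, n_slices=36, in_plane=0.5,
                             slice_spacing=0.5, origin=(-11.75, -10.75, 0.0))
        m = rasterize_ellipsoid((0.0, 0.0, 8.75), (10.0, 8.0, 6.0), g)
        analytic = 4.0 / 3.0 * np.pi * 10 * 8 * 6
        assert lesion_volume(m) == pytest.approx(analytic, rel=0.015)

    def test_volume_invariant_under_axis_permutation(self):
        g = make_geometry(n_cols=10, n_rows=10, n_slices=10, col_spacing=1.0,
                          row_spacing=1.0, slice_spacing=1.0)
        v = (np.random.default_rng(5).random(g.shape) < 0.3).astype(np.uint8)
        vols = {lesion_volume(LesionMask(g, np.transpose(v, p).copy()))
                for p in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]}
        assert len(vols) == 1


class TestMeasureLesion:
    def test_sphere_measures_near_analytic(self):
        # pixel-corner vertices bias the diameter upward by up to one
        # pixel diagonal, so the bidimensional product carries roughly
        # twice that relative bias: a 30 mm sphere at 0.5 mm voxels
        # stays within 5% of the analytic product
        g = default_geometry(n_cols=64, n_rows=64, n_slices=64, in_plane=0.5,
                             slice_spacing=0.5, origin=(-15.75, -15.75, 0.0))
        m = rasterize_ellipsoid((0.0, 0.0, 15.75), (15.0, 15.0, 15.0), g)
        rec = measure_lesion(m, "tp0")
        pixel_diag = 0.5 * np.sqrt(2)
        assert abs(rec.unidimensional - 30.0) <= pixel_diag
        assert rec.bidimensional == pytest.approx(900.0, rel=0.05)

    def test_flat_square_record(self):
        fg = np.zeros((8, 8))
        fg[2:5, 2:5] = 1
        m = slice_mask(fg, slice_spacing=2.5)
        rec = measure_lesion(m, "tp0")
        assert rec.unidimensional == pytest.approx(3 * np.sqrt(2))
        assert rec.bidimensional == pytest.approx(18.0)
        assert rec.volume == pytest.approx(9 * 2.5)
        assert rec.diameter_slice == 0
        assert rec.perpendicular_width <= rec.unidimensional + 1e-12

    def test_empty_mask_zero_record(self, geometry):
        m = LesionMask(geometry, np.zeros(geometry.shape, dtype=np.uint8))
        rec = measure_lesion(m, "tp0")
        assert (rec.unidimensional, rec.bidimensional, rec.volume) == (0, 0, 0)

    def test_translation_invariance(self, rng):
        g = make_geometry(n_cols=32, n_rows=32, n_slices=6)
        v = np.zeros(g.shape, dtype=np.uint8)
        v[1:4, 4:9, 5:12] = 1
        base = measure_lesion(LesionMask(g, v), "t")
        shifted = measure_lesion(LesionMask(g, np.roll(v, (2, 7, 9), (0, 1, 2))), "t")
        assert shifted.unidimensional == pytest.approx(base.unidimensional)
        assert shifted.bidimensional == pytest.approx(base.bidimensional)
        assert shifted.volume == pytest.approx(base.volume)

    def test_bidimensional_bounded_by_diameter_squared(self, rng):
        for _ in range(20):
            fg = random_blob_slice(rng, shape=(24, 24))
            if not fg.any():
                continue
            rec = measure_lesion(slice_mask(fg), "t")
            assert rec.bidimensional <= rec.unidimensional**2 + 1e-9

    def test_nodal_short_axis_switch(self):
        fg = np.zeros((12, 12))
        fg[2:5, 2:10] = 1  # 8 x 3 pixels
        m = slice_mask(fg, **{})
        m.organ_label = "lymph_node"
        long_rec = measure_lesion(m, "t")
        short_rec = measure_lesion(m, "t", nodal_short_axis=True)
        assert short_rec.unidimensional < long_rec.unidimensional
        assert short_rec.unidimensional == pytest.approx(
            long_rec.perpendicular_width)


class TestTimepointSummary:
    def test_sld_is_sum_of_diameters(self):
        records = [
            MeasurementRecord("L1", "t1", 30.0, 600.0, 9000.0),
            MeasurementRecord("L2", "t1", 20.0, 300.0, 4000.0),
        ]
        s = timepoint_summary(records)
        assert (s.SLD, s.SPD, s.total_volume, s.n_lesions) == (50.0, 900.0, 13000.0, 2)

    def test_empty_list_gives_zeros(self):
        s = timepoint_summary([])
        assert (s.SLD, s.SPD, s.total_volume, s.n_lesions) == (0, 0, 0, 0)

    def test_mixed_timepoints_rejected(self):
        records = [MeasurementRecord("L1", "t1", 1, 1, 1),
                   MeasurementRecord("L2", "t2", 1, 1, 1)]
        with pytest.raises(ValueError):
            timepoint_summary(records)

    def test_random_records_match_summation_oracle(self, rng):
        records = [
            MeasurementRecord(f"L{i}", "t", *rng.uniform(1, 100, 3)) for i in range(3)
        ]
        s = timepoint_summary(records)
        assert s.SLD == pytest.approx(sum(r.unidimensional for r in records))
        assert s.SPD == pytest.approx(sum(r.bidimensional for r in records))
        assert s.total_volume == pytest.approx(sum(r.volume for r in records))


class TestCalipersPrimitive:
    def test_matches_brute_force_on_random_point_sets(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(rng.integers(1, 40), 2)) * rng.uniform(0.1, 10)
            fast, pair = rotating_calipers_diameter(pts)
            brute = all_pairs_diameter(pts) if len(pts) > 1 else 0.0
            assert fast == pytest.approx(brute, abs=1e-9)
            if pair is not None and len(pts) > 1:
                assert np.linalg.norm(pair[0] - pair[1]) == pytest.approx(fast)

    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        length, (p0, p1) = rotating_calipers_diameter(pts)
        assert length == pytest.approx(3 * np.sqrt(2))
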