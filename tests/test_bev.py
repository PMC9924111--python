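"""BEV projection, MLC conformance, aperture construction and mirroring."""

import numpy as np
import pytest

from fifplan.bev import (
    Aperture,
    BeamGeometry,
    BeamGeometryError,
    BevMap,
    DegenerateApertureError,
    bev_frame,
    conform_mlc,
    make_whole_brain_aperture,
    mirror_aperture,
    project_to_bev,
)
from fifplan.grids import StructureMask


def make_mask(shape, spacing=2.0, center=True):
    n = np.asarray(shape)
    origin = -(n - 1) * spacing / 2.0 if center else np.zeros(3)
    return lambda arr, name="m": StructureMask(
        name, arr, (spacing,) * 3, tuple(origin)
    )


GEOM = BeamGeometry(90.0, (0.0, 0.0, 0.0), 1000.0)


class TestProjection:
    def test_single_voxel_at_isocenter_hits_bev_origin(self):
        arr = np.zeros((11, 11, 11), bool)
        arr[5, 5, 5] = True  # world (0, 0, 0)
        bev = project_to_bev(make_mask((11, 11, 11))(arr), GEOM, 2.0, 20.0)
        uu, vv = bev.coords()
        iu, iv = np.where(bev.values)
        assert bev.values[len(uu) // 2, len(vv) // 2]
        # closing keeps the splat compact around the origin
        assert np.all(np.abs(uu[iu]) <= 2.0) and np.all(np.abs(vv[iv]) <= 2.0)

    def test_divergent_magnification_similar_triangles(self):
        # point 50 mm superior of isocenter and 100 mm closer to the source
        # projects to 50 * 1000/900 = 55.6 mm on the isocenter plane
        arr = np.zeros((111, 11, 61), bool)
        mask = StructureMask("m", arr, (2.0, 2.0, 2.0), (-110.0, -10.0, -60.0))
        # gantry 90: source at +x, so "closer to source" is +x = +100 mm
        ix = int(round((100.0 - -110.0) / 2.0))
        iz = int(round((50.0 - -60.0) / 2.0))
        arr[ix, 5, iz] = True
        bev = project_to_bev(mask, GEOM, 2.0, 80.0)
        uu, vv = bev.coords()
        iu, iv = np.where(bev.values)
        v_hit = vv[iv]
        assert np.abs(v_hit - 55.6).min() <= 1.0  # within half a pixel

    def test_empty_mask_gives_empty_map(self):
        arr = np.zeros((11, 11, 11), bool)
        bev = project_to_bev(make_mask((11, 11, 11))(arr), GEOM, 2.0, 20.0)
        assert not bev.values.any()

    def test_source_inside_mask_rejected(self):
        arr = np.ones((11, 11, 11), bool)
        mask = StructureMask("m", arr, (300.0, 300.0, 300.0), (-1500.0, -1500.0, -1500.0))
        with pytest.raises(BeamGeometryError):
            project_to_bev(mask, GEOM, 2.0, 20.0)

    def test_projection_is_monotone_in_mask(self):
        rng = np.random.default_rng(3)
        small = rng.random((21, 21, 21)) > 0.8
        big = small | (rng.random((21, 21, 21)) > 0.8)
        mk = make_mask((21, 21, 21))
        bev_small = project_to_bev(mk(small), GEOM, 2.0, 40.0)
        bev_big = project_to_bev(mk(big), GEOM, 2.0, 40.0)
        assert not np.any(bev_small.values & ~bev_big.values)


def _frame(n=41, spacing=2.0):
    origin = -spacing * (n // 2)
    return BevMap(np.zeros((n, n), bool), (spacing, spacing), (origin, origin))


class TestConformMLC:
    def test_rectangle_conforms_exactly(self):
        frame = _frame()
        uu, vv = frame.coords()
        region = (np.abs(uu)[:, None] <= 20) & (np.abs(vv)[None, :] <= 10)
        ap = conform_mlc(BevMap(region, frame.spacing, frame.origin), 5.0)
        open_rows = ap.intervals[:, 1] > ap.intervals[:, 0]
        # every open row covers the rectangle's x extent with outer pixel edges
        np.testing.assert_allclose(ap.intervals[open_rows, 0], -21.0)
        np.testing.assert_allclose(ap.intervals[open_rows, 1], 21.0)

    def test_empty_region_all_closed(self):
        frame = _frame()
        ap = conform_mlc(frame, 5.0)
        assert not ap.is_open()
        assert np.all(ap.intervals[:, 0] == ap.intervals[:, 1])

    def test_disk_chords_match_per_row_scan_oracle(self):
        frame = _frame(61)
        uu, vv = frame.coords()
        r = 35.0
        region = uu[:, None] ** 2 + vv[None, :] ** 2 <= r**2
        bev = BevMap(region, frame.spacing, frame.origin)
        ap = conform_mlc(bev, 2.0)  # leaf width = pixel height: row-exact
        du = frame.spacing[0]
        for k in range(ap.n_leaves):
            v_lo = ap.leaf_v0 + k * 2.0
            j = int(round((v_lo + 1.0 - frame.origin[1]) / 2.0))
            if 0 <= j < len(vv):
                cols = np.flatnonzero(region[:, j])
                if cols.size:
                    assert ap.intervals[k, 0] == pytest.approx(uu[cols[0]] - du / 2)
                    assert ap.intervals[k, 1] == pytest.approx(uu[cols[-1]] + du / 2)

    def test_over_cover_property(self):
        rng = np.random.default_rng(5)
        frame = _frame()
        region = rng.random((41, 41)) > 0.7
        bev = BevMap(region, frame.spacing, frame.origin)
        ap = conform_mlc(bev, 5.0)
        uu, vv = frame.coords()
        t = ap.transmission(uu[:, None], vv[None, :]) > 0.5
        assert not np.any(region & ~t)  # region fully covered by the opening

    def test_largest_open_run_keeps_longer_lobe(self):
        frame = _frame()
        uu, vv = frame.coords()
        row_band = np.abs(vv)[None, :] <= 2.0
        region = (np.abs(uu)[:, None] <= 30) & row_band
        # block a strip at u in [10, 20]: left lobe (40 mm) beats right (10 mm)
        block = ((uu[:, None] >= 10) & (uu[:, None] <= 20)) & row_band
        open_region = region & ~block
        ap = conform_mlc(
            BevMap(open_region, frame.spacing, frame.origin), 5.0,
            rule="largest_open_run",
        )
        k = int(np.floor((0.0 - ap.leaf_v0) / 5.0))
        left, right = ap.intervals[k]
        assert left == pytest.approx(-31.0)
        assert right < 10.0


class TestMirror:
    def _blob_aperture(self):
        frame = _frame()
        uu, vv = frame.coords()
        region = ((uu[:, None] - 14) ** 2 + vv[None, :] ** 2) <= 15**2
        return conform_mlc(BevMap(region, frame.spacing, frame.origin), 5.0)

    def test_mirror_twice_is_identity(self):
        ap = self._blob_aperture()
        back = mirror_aperture(mirror_aperture(ap))
        np.testing.assert_allclose(back.intervals, ap.intervals)
        np.testing.assert_array_equal(back.bev.values, ap.bev.values)
        assert back.jaw == pytest.approx(ap.jaw)

    def test_symmetric_aperture_is_fixed_point(self):
        frame = _frame()
        uu, vv = frame.coords()
        region = uu[:, None] ** 2 + vv[None, :] ** 2 <= 20**2
        ap = conform_mlc(BevMap(region, frame.spacing, frame.origin), 5.0)
        m = mirror_aperture(ap)
        np.testing.assert_allclose(m.intervals, ap.intervals)

    def test_off_center_blob_reflected_with_same_area(self):
        ap = self._blob_aperture()
        m = mirror_aperture(ap)
        assert m.open_area_cm2() == pytest.approx(ap.open_area_cm2())
        np.testing.assert_array_equal(m.bev.values, ap.bev.values[::-1, :])
        # centroid flips sign in u
        uu, _ = ap.bev.coords()
        cu = uu[np.where(ap.bev.values)[0]].mean()
        cm = uu[np.where(m.bev.values)[0]].mean()
        assert cm == pytest.approx(-cu, abs=1e-9)


class TestWholeBrainAperture:
    def test_margin_zero_matches_brain_bev_up_to_leaf_rows(self):
        frame = _frame(61)
        uu, vv = frame.coords()
        region = uu[:, None] ** 2 + vv[None, :] ** 2 <= 30**2
        bev = BevMap(region, frame.spacing, frame.origin)
        ap = make_whole_brain_aperture(bev, [], margin_mm=0.0, leaf_width_mm=2.0)
        t = ap.transmission(uu[:, None], vv[None, :]) > 0.5
        assert not np.any(region & ~t)
        # over-cover excess stays within one pixel column per row edge
        assert (t & ~region).sum() <= 2 * region.any(axis=0).sum() + 2 * 30

    def test_dilated_disk_area_analytic(self):
        frame = _frame(101)
        uu, vv = frame.coords()
        region = uu[:, None] ** 2 + vv[None, :] ** 2 <= 70**2
        bev = BevMap(region, frame.spacing, frame.origin)
        ap = make_whole_brain_aperture(bev, [], margin_mm=7.0, leaf_width_mm=2.0)
        expected = np.pi * 7.7**2  # cm^2
        assert ap.open_area_cm2() == pytest.approx(expected, rel=0.04)

    def test_fully_blocked_aperture_rejected(self):
        frame = _frame()
        uu, vv = frame.coords()
        region = uu[:, None] ** 2 + vv[None, :] ** 2 <= 20**2
        bev = BevMap(region, frame.spacing, frame.origin)
        full = BevMap(np.ones_like(region), frame.spacing, frame.origin)
        with pytest.raises(DegenerateApertureError):
            make_whole_brain_aperture(bev, [full], margin_mm=0.0)


def test_opposed_geometry_shares_isocenter_and_axis():
    g = BeamGeometry(90.0, (1.0, 2.0, 3.0), 1000.0)
    o = g.opposed()
    assert o.gantry_deg == 270.0
    assert o.isocenter == g.isocenter
    np.testing.assert_allclose(o.beam_direction, -g.beam_direction, atol=1e-12)
    np.testing.assert_allclose(o.u_axis, -g.u_axis, atol=1e-12)  # mirrored crossplane
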