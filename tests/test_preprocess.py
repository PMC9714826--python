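"""Brain masking, hulls, registration and label transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point

from strokeloc import phantom as ph, preprocess as pp
from strokeloc.errors import GeometryError
from strokeloc.volume_io import LabelMap


# ---------------------------------------------------------------------------
# Brain mask


def test_all_air_slice_yields_empty_flagged_mask():
    bm = pp.extract_brain_mask(np.full((32, 32), -1000.0))
    assert bm.empty and bm.area_px == 0


def test_largest_component_rule():
    hu = np.full((40, 40), -1000.0)
    hu[2:27, 2:22] = 35.0            # 500-px blob
    hu[30:38, 30:40] = 35.0          # 80-px blob
    bm = pp.extract_brain_mask(hu)
    assert bm.area_px == 500
    assert bm.mask[10, 10] and not bm.mask[33, 33]


def test_phantom_mask_matches_analytic_outline(medium_case):
    spec = medium_case.spec
    for s in range(spec.n_slices):
        bm = pp.extract_brain_mask(medium_case.ct.slices[s])
        analytic = ph.brain_ellipse_mask(spec, s)
        inter = (bm.mask & analytic).sum()
        union = (bm.mask | analytic).sum()
        assert inter / union >= 0.98
        # disagreement confined to a 1-px boundary band
        from scipy import ndimage
        band = ndimage.binary_dilation(analytic) & \
            ~ndimage.binary_erosion(analytic)
        assert not ((bm.mask ^ analytic) & ~band).any()


def test_mask_is_idempotent(medium_case):
    sl = medium_case.ct.slices[1]
    bm = pp.extract_brain_mask(sl)
    remasked = np.where(bm.mask, sl, -1000.0)
    bm2 = pp.extract_brain_mask(remasked)
    np.testing.assert_array_equal(bm.mask, bm2.mask)


def test_bone_is_never_foreground(medium_case):
    sl = medium_case.ct.slices[0]
    bm = pp.extract_brain_mask(sl)
    assert not (sl[bm.mask] >= pp.BONE_HU).any()


# ---------------------------------------------------------------------------
# Convex hull


def test_rectangle_hull_vertices():
    mask = np.zeros((20, 30), bool)
    mask[5:15, 4:24] = True
    hull = pp.convex_hull(mask)
    assert not hull.degenerate
    got = {tuple(v) for v in hull.vertices}
    assert got == {(5, 4), (5, 23), (14, 23), (14, 4)}


def test_single_pixel_hull_is_degenerate():
    mask = np.zeros((10, 10), bool)
    mask[3, 7] = True
    hull = pp.convex_hull(mask)
    assert hull.degenerate


def test_empty_mask_hull_raises():
    with pytest.raises(GeometryError):
        pp.convex_hull(np.zeros((5, 5), bool))


def test_random_blob_hull_contains_every_pixel():
    rng = np.random.default_rng(7)
    mask = np.zeros((40, 40), bool)
    pts = rng.integers(5, 35, size=(200, 2))
    mask[pts[:, 0], pts[:, 1]] = True
    hull = pp.convex_hull(mask)
    poly = hull.to_shapely().buffer(1e-9)
    assert hull.area >= 0  # area of polygon >= 0 trivially
    assert poly.area + 1e-9 >= 0
    for r, c in np.argwhere(mask):
        assert poly.contains(Point(c, r))   # brute-force point-in-polygon
    assert poly.area >= mask.sum() * 0  # hull area covers the points


# ---------------------------------------------------------------------------
# Registration


def test_identity_registration(medium_case):
    hull = pp.convex_hull(pp.extract_brain_mask(
        medium_case.ct.slices[2]).mask)
    t = pp.register_hulls(hull, hull)
    assert (t.theta, t.tx, t.ty) == (0.0, 0.0, 0.0)
    assert t.objective == 0.0


def test_known_transform_recovery(medium_case):
    hull = pp.convex_hull(pp.extract_brain_mask(
        medium_case.ct.slices[2]).mask)
    center = (47.5, 47.5)
    true = pp.RigidTransform2D(theta=5.0, tx=3.0, ty=-2.0,
                               center_moving=center, center_fixed=center)
    moving = pp.HullPolygon(true.apply_inverse(hull.vertices))
    rec = pp.register_hulls(hull, moving, center_fixed=center,
                            center_moving=center)
    assert abs(rec.theta - 5.0) <= 0.5
    assert abs(rec.tx - 3.0) <= 0.5
    assert abs(rec.ty + 2.0) <= 0.5


def test_registration_never_worse_than_identity(medium_case):
    hf = pp.convex_hull(pp.extract_brain_mask(
        medium_case.ct.slices[2]).mask)
    hm = pp.convex_hull(medium_case.label_map[2] > 0)
    rec = pp.register_hulls(hf, hm)
    ident = pp.RigidTransform2D(center_moving=rec.center_moving,
                                center_fixed=rec.center_moving)
    ident_obj = pp._poly_of(
        pp.RigidTransform2D(0, 0, 0, 1, 1, rec.center_moving,
                            rec.center_moving),
        np.asarray(hm.vertices)).symmetric_difference(
        hf.to_shapely()).area
    assert rec.objective <= ident_obj + 1e-9


def test_concentric_discs_are_low_confidence():
    rr, cc = np.ogrid[:64, :64]
    disc = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20 ** 2
    hull = pp.convex_hull(disc)
    rec = pp.register_hulls(hull, hull)
    assert rec.theta == 0.0
    assert rec.objective <= 1e-9
    assert rec.low_confidence


def test_transform_composes_with_inverse_to_identity():
    t = pp.RigidTransform2D(theta=7.0, tx=3.5, ty=-1.25, scale_row=1.1,
                            scale_col=0.9, center_moving=(10, 20),
                            center_fixed=(30, 40))
    pts = np.random.default_rng(0).uniform(0, 50, (20, 2))
    back = t.apply_inverse(t.apply(pts))
    assert np.abs(back - pts).max() <= 1e-9


# ---------------------------------------------------------------------------
# Label transfer


def test_identity_transfer_preserves_labels():
    lab = np.random.default_rng(1).integers(0, 4, (2, 20, 20))
    t = pp.RigidTransform2D()
    out = pp.transfer_labels(lab, t, (20, 20))
    np.testing.assert_array_equal(out.labels, lab)


def test_pure_translation_matches_brute_force_inverse_map():
    rng = np.random.default_rng(2)
    lab = rng.integers(0, 4, (1, 24, 24)).astype(np.int16)
    t = pp.RigidTransform2D(tx=0.0, ty=5.0)   # shift 5 rows
    out = pp.transfer_labels(lab, t, (24, 24)).labels[0]
    oracle = np.zeros((24, 24), np.int16)
    for r in range(24):
        for c in range(24):
            sr, sc = r - 5, c                 # brute-force inverse mapping
            if 0 <= sr < 24 and 0 <= sc < 24:
                oracle[r, c] = lab[0, sr, sc]
    np.testing.assert_array_equal(out, oracle)


def test_off_grid_transform_gives_all_background():
    lab = np.ones((1, 10, 10), np.int16)
    t = pp.RigidTransform2D(tx=1000.0, ty=1000.0)
    out = pp.transfer_labels(lab, t, (10, 10))
    assert (out.labels == 0).all()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(-10, 10), st.floats(-10, 10),
       st.floats(-12, 12))
def test_transfer_preserves_label_alphabet(seed, tx, ty, theta):
    rng = np.random.default_rng(seed)
    lab = rng.integers(0, 4, (1, 16, 16))
    t = pp.RigidTransform2D(theta=theta, tx=tx, ty=ty)
    out = pp.transfer_labels(lab, t, (16, 16))
    assert set(np.unique(out.labels)) <= set(np.unique(lab)) | {0}


def test_transfer_requires_3d_labels():
    with pytest.raises(GeometryError):
        pp.transfer_labels(np.zeros((4, 4), np.int16),
                           pp.RigidTransform2D(), (4, 4))
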