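"""Brain-mask extraction, convex-hull registration and label transfer.

The perfusion-derived label map lives on its own pixel grid (different
aspect ratio, rotation and translation than the CT).  Alignment follows
the hull-matching idea: strip the skull, keep the largest connected brain
region per slice, take the convex hulls of one representative slice pair
and find the similarity transform minimising the area of the symmetric
difference between the hulls.  That single transform then resamples the
label map onto the CT grid with nearest-neighbour lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Polygon

from .errors import GeometryError
from .volume_io import LabelMap

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: Standard CT tissue boundaries used for skull stripping (config-exposed).
BONE_HU = 300.0
AIR_HU = -200.0


@dataclass
class BrainMask:
    """Largest connected soft-tissue region of one slice."""

    mask: np.ndarray            # 2-D bool
    area_px: int = 0
    empty: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.mask.sum())
        self.empty = self.area_px == 0


@dataclass
class HullPolygon:
    """Convex hull of a brain mask, vertices (row, col), CCW."""

    vertices: np.ndarray
    degenerate: bool = False

    @property
    def area(self):
        v = self.vertices
        if len(v) < 3:
            return 0.0
        x, y = v[:, 1], v[:, 0]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def to_shapely(self):
        if self.degenerate:
            raise GeometryError("degenerate hull has no polygon")
        return Polygon([(c, r) for r, c in self.vertices])


@dataclass
class RigidTransform2D:
    """Similarity transform mapping moving-frame pixels to the fixed frame.

    A moving point ``q`` (row, col) maps to::

        p = M @ (q - center_moving) + center_fixed + (ty, tx)

    where ``M`` composes per-axis scaling (``scale_row``, ``scale_col``)
    with a rotation by ``theta`` degrees.  The per-axis scales absorb the
    aspect-ratio difference between the two grids; ``scale`` is their
    geometric mean.
    """

    theta: float = 0.0
    tx: float = 0.0              # column shift, px
    ty: float = 0.0              # row shift, px
    scale_row: float = 1.0
    scale_col: float = 1.0
    center_moving: tuple = (0.0, 0.0)
    center_fixed: tuple = (0.0, 0.0)
    objective: float | None = None
    low_confidence: bool = False

    @property
    def scale(self):
        return float(np.sqrt(self.scale_row * self.scale_col))

    def matrix(self):
        """2x2 linear part acting on (row, col) offsets."""
        th = np.deg2rad(self.theta)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c * self.scale_row, s * self.scale_col],
                         [-s * self.scale_row, c * self.scale_col]])

    def apply(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = pts - np.asarray(self.center_moving)
        out = d @ self.matrix().T
        out += np.asarray(self.center_fixed) + np.array([self.ty, self.tx])
        return out

    def apply_inverse(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = pts - np.asarray(self.center_fixed) - np.array([self.ty, self.tx])
        try:
            inv = np.linalg.inv(self.matrix())
        except np.linalg.LinAlgError as exc:
            raise GeometryError("singular transform") from exc
        return d @ inv.T + np.asarray(self.center_moving)


# ---------------------------------------------------------------------------
# Brain mask


def extract_brain_mask(slice_hu, bone_hu=BONE_HU, air_hu=AIR_HU):
    """Strip skull and background, keep the largest connected region.

    Pixels with HU >= ``bone_hu`` (skull/calcification) or <= ``air_hu``
    (air/background) are excluded; among the remaining soft-tissue pixels
    only the largest 4-connected component survives, with interior holes
    filled.  Bone pixels are never foreground, even inside filled holes.
    An all-air slice yields an empty, flagged mask.
    """
    hu = np.asarray(slice_hu, dtype=np.float64)
    soft = (hu > air_hu) & (hu < bone_hu)
    if not soft.any():
        return BrainMask(np.zeros_like(soft))
    lab, n = ndimage.label(soft, structure=FOUR_CONN)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    largest = lab == sizes.argmax()
    filled = ndimage.binary_fill_holes(largest)
    filled &= hu < bone_hu
    return BrainMask(filled)


def extract_brain_mask_volume(volume, bone_hu=BONE_HU, air_hu=AIR_HU):
    """Per-slice brain masks stacked into a (k, H, W) bool array."""
    slices = volume.slices if hasattr(volume, "slices") else np.asarray(volume)
    return np.stack([extract_brain_mask(s, bone_hu, air_hu).mask
                     for s in slices])


def mask_midline_col(mask):
    """Column centroid of a (2-D or 3-D) mask: the per-patient midline.

    Computed from integer sums so that mirroring the mask mirrors the
    midline exactly.
    """
    m = np.asarray(mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise GeometryError("midline of an empty mask is undefined")
    cols = np.nonzero(m)[-1]
    return float(int(cols.sum()) / n)


# ---------------------------------------------------------------------------
# Convex hulls


def convex_hull(brain_mask):
    """Minimal convex polygon containing all foreground pixel centers."""
    mask = brain_mask.mask if isinstance(brain_mask, BrainMask) else \
        np.asarray(brain_mask, dtype=bool)
    pts = np.argwhere(mask).astype(np.float64)
    if len(pts) == 0:
        raise GeometryError("convex hull of an empty mask")
    if len(pts) < 3:
        return HullPolygon(pts, degenerate=True)
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts[:, ::-1])        # qhull in (x=col, y=row)
    except QhullError:
        return HullPolygon(pts, degenerate=True)  # collinear points
    verts = pts[hull.vertices]                  # CCW in (x, y)
    return HullPolygon(verts)


# ---------------------------------------------------------------------------
# Registration


def _poly_of(transform, verts_rc):
    p = transform.apply(verts_rc)
    return Polygon([(c, r) for r, c in p])


def register_hulls(hull_fixed, hull_moving, center_fixed=None,
                   center_moving=None, theta_range=15.0, theta_step=1.0,
                   t_range=20.0, t_step=2.0, refine=True):
    """Similarity registration of two convex hulls.

    Minimises the area of the symmetric difference between the fixed hull
    and the transformed moving hull.  Per-axis scale is initialised from
    the ratio of the hull bounding boxes (absorbing the aspect-ratio
    difference), then a coarse grid over rotation and translation is
    searched, followed by a local simplex polish of all five parameters
    (restarted until converged; rotation and anisotropic scale form a
    correlated valley in which coordinate-wise refinement stalls).  Ties
    on the coarse grid are broken toward the smallest ``|theta|``, then
    smallest ``|tx|+|ty|``.

    ``center_fixed`` / ``center_moving`` set the rotation pivots (row,
    col); they default to the hull centroids.  A transform estimated with
    explicit pivots is directly comparable to a transform defined about
    the same points.

    Returns a :class:`RigidTransform2D` whose ``objective`` field holds
    the achieved symmetric-difference area; ``low_confidence`` is set when
    the objective is flat across the whole coarse grid (e.g. two
    concentric discs, where rotation is unidentifiable).
    """
    if getattr(hull_fixed, "degenerate", False) or \
            getattr(hull_moving, "degenerate", False):
        raise GeometryError("cannot register degenerate hulls")
    pf = hull_fixed.to_shapely()
    pm_verts = np.asarray(hull_moving.vertices, dtype=np.float64)
    area_f = pf.area
    if area_f <= 0 or hull_moving.area <= 0:
        raise GeometryError("cannot register zero-area hulls")

    if center_fixed is None:
        c = pf.centroid
        center_fixed = (c.y, c.x)
    if center_moving is None:
        c = hull_moving.to_shapely().centroid
        center_moving = (c.y, c.x)

    fminx, fminy, fmaxx, fmaxy = pf.bounds
    pm0 = hull_moving.to_shapely()
    mminx, mminy, mmaxx, mmaxy = pm0.bounds
    s_row0 = (fmaxy - fminy) / max(mmaxy - mminy, 1e-9)
    s_col0 = (fmaxx - fminx) / max(mmaxx - mminx, 1e-9)

    def objective(theta, tx, ty, s_r, s_c):
        t = RigidTransform2D(theta, tx, ty, s_r, s_c,
                             center_moving, center_fixed)
        return _poly_of(t, pm_verts).symmetric_difference(pf).area

    # --- coarse grid: theta x (tx, ty), scale fixed at the bbox estimate
    thetas = np.arange(-theta_range, theta_range + theta_step / 2, theta_step)
    shifts = np.arange(-t_range, t_range + t_step / 2, t_step)
    tie_eps = 1e-9 * area_f
    best = None
    best_per_theta = []
    for theta in thetas:
        base_t = RigidTransform2D(theta, 0.0, 0.0, s_row0, s_col0,
                                  center_moving, center_fixed)
        base_poly = _poly_of(base_t, pm_verts)
        area_m = base_poly.area
        theta_best = np.inf
        for ty in shifts:
            for tx in shifts:
                inter = affinity.translate(base_poly, xoff=tx, yoff=ty) \
                    .intersection(pf).area
                obj = area_f + area_m - 2.0 * inter
                theta_best = min(theta_best, obj)
                key = (abs(theta), abs(tx) + abs(ty))
                if best is None or obj < best[0] - tie_eps or (
                        abs(obj - best[0]) <= tie_eps and key < best[1]):
                    best = (obj, key, (theta, tx, ty, s_row0, s_col0))
        best_per_theta.append(theta_best)
    # near-rotationally-symmetric hulls (discs) leave theta essentially
    # unidentified: the best objective barely varies across the theta grid
    low_confidence = (max(best_per_theta) - min(best_per_theta)) \
        < 0.02 * area_f

    obj_best, _, params = best
    # never worse than doing nothing: keep the raw identity as a candidate
    identity = (0.0, 0.0, 0.0, 1.0, 1.0)
    obj_id = objective(*identity)
    if obj_id < obj_best - tie_eps:
        obj_best, params = obj_id, identity

    if refine and obj_best > 1e-6 * area_f:
        from scipy.optimize import minimize

        def fun(p):
            if p[3] <= 0 or p[4] <= 0:
                return 2.0 * (area_f + pm0.area)
            return objective(*p)

        x = np.asarray(params, dtype=np.float64)
        for _ in range(3):
            res = minimize(fun, x, method="Nelder-Mead",
                           options=dict(xatol=1e-3, fatol=1e-9 * area_f,
                                        maxiter=1000))
            x = res.x
            if res.fun < obj_best:
                obj_best, params = float(res.fun), list(res.x)
            if obj_best <= 1e-6 * area_f:
                break

    theta, tx, ty, s_r, s_c = params
    return RigidTransform2D(theta, tx, ty, s_r, s_c, center_moving,
                            center_fixed, objective=float(obj_best),
                            low_confidence=low_confidence)


# ---------------------------------------------------------------------------
# Label transfer


def transfer_labels(labels, transform, target_shape):
    """Resample a label map onto the CT grid with nearest-neighbour lookup.

    ``transform`` maps label-map (moving) pixels to CT (fixed) pixels; the
    same transform is applied to every slice pair.  Target pixels mapping
    outside the source extent become class 0.
    """
    lab = labels.labels if isinstance(labels, LabelMap) else \
        np.asarray(labels)
    if lab.ndim != 3:
        raise GeometryError("transfer_labels expects a (slice,row,col) map")
    k, sh, sw = lab.shape
    H, W = target_shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    src = transform.apply_inverse(pts)
    sr = np.rint(src[:, 0]).astype(np.int64)
    sc = np.rint(src[:, 1]).astype(np.int64)
    valid = (sr >= 0) & (sr < sh) & (sc >= 0) & (sc < sw)
    out = np.zeros((k, H, W), dtype=np.int16)
    flat_idx = np.where(valid, sr * sw + sc, 0)
    for s in range(k):
        vals = lab[s].ravel()[flat_idx]
        vals = np.where(valid, vals, 0)
        out[s] = vals.reshape(H, W)
    return LabelMap(out)
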