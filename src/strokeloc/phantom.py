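"""Seeded synthetic brain phantoms with misaligned perfusion-style labels.

A phantom emulates the structures the pipeline must handle: a high-HU
skull ring around an elliptical brain of noisy soft-tissue HU, and a
subtle hypodense lesion (irreversible core plus a fainter hypoperfused
rim) confined to one hemisphere and contiguous across slices.  The paired
label map is rendered on its own grid under a known similarity transform
with a different aspect ratio, so that registration and label transfer do
real work.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import PhantomSpecError
from .preprocess import RigidTransform2D
from .volume_io import CTVolume

# Label alphabet of the perfusion-style map.
LBL_BACKGROUND, LBL_NORMAL, LBL_CORE, LBL_PENUMBRA = 0, 1, 2, 3

#: Lesion contrast (HU decrease of the core) per difficulty level.
DIFFICULTY_CONTRAST = {"easy": 20.0, "medium": 10.0, "hard": 5.0}


@dataclass
class LabelTransformSpec:
    """Ground-truth label-map-to-CT similarity transform parameters."""

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    scale_row: float = 1.0
    scale_col: float = 1.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic case.

    The defaults put the lesion contrast in the subtle early-infarct
    regime: soft tissue 35 HU with 3 HU noise and a 10 HU core decrease.
    """

    n_slices: int = 4
    image_shape: tuple = (96, 96)
    label_shape: tuple = (128, 128)
    brain_axes: tuple = (44.0, 35.0)        # semi-axes (row, col), px
    brain_taper: float = 0.15               # frontal narrowing of the outline
    skull_thickness: float = 3.0
    skull_hu: float = 1000.0
    tissue_hu: float = 35.0
    noise_sigma: float = 3.0
    lesion_side: str = "left"               # image-left / image-right
    lesion_center: tuple = (48.0, 30.0)     # (row, col) in CT frame
    lesion_radii: tuple = (8.0, 10.0, 10.0, 8.0)   # core radius per slice
    lesion_contrast: float = 10.0           # core HU decrease
    penumbra_width: float = 3.0
    penumbra_contrast_frac: float = 0.6
    transform: LabelTransformSpec = field(default_factory=LabelTransformSpec)
    seed: int = 0

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["transform"] = LabelTransformSpec(**d["transform"])
        for key in ("image_shape", "label_shape", "brain_axes",
                    "lesion_center", "lesion_radii"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomCase:
    """A generated phantom: CT, misaligned labels, and ground truth."""

    ct: CTVolume
    label_map: np.ndarray              # (k, H', W') ints, label frame
    transform: RigidTransform2D        # label frame -> CT frame
    truth: np.ndarray                  # (k, H, W) bool lesion mask, CT frame
    spec: PhantomSpec


def _axes_profile(spec, s):
    """Per-slice brain semi-axes: a symmetric bulge along the stack."""
    k = spec.n_slices
    f = 0.88 + 0.12 * np.sin(np.pi * (s + 0.5) / k)
    return spec.brain_axes[0] * f, spec.brain_axes[1] * f


def _validate(spec):
    cy = (spec.image_shape[0] - 1) / 2.0
    cx = (spec.image_shape[1] - 1) / 2.0
    lr, lc = spec.lesion_center
    for s in range(spec.n_slices):
        r = spec.lesion_radii[s]
        if r <= 0:
            continue
        rout = r + spec.penumbra_width
        a, b = _axes_profile(spec, s)
        # sample the outer lesion circle and require it inside the outline
        ang = np.linspace(0, 2 * np.pi, 64)
        pr = lr - cy + rout * np.sin(ang)
        pc = lc - cx + rout * np.cos(ang)
        width = b * (1.0 - spec.brain_taper * (-pr) / a)
        if np.any((pr / a) ** 2 + (pc / width) ** 2 > 1.0):
            raise PhantomSpecError(
                f"lesion leaves the brain outline on slice {s}")
        if spec.lesion_side == "left" and lc + rout >= cx:
            raise PhantomSpecError("left-side lesion crosses the midline")
        if spec.lesion_side == "right" and lc - rout <= cx:
            raise PhantomSpecError("right-side lesion crosses the midline")
    if spec.lesion_contrast <= 0:
        raise PhantomSpecError("lesion contrast must be positive")


def _brain_quadratic(spec, s, a_off=0.0, b_off=0.0, shape=None):
    """Implicit function of the brain outline; interior where <= 1.

    The outline is an ellipse whose width tapers linearly toward the top
    of the image (``brain_taper``), emulating the narrower frontal lobes
    of a real axial brain section; a pure ellipse would leave the
    orientation of the hull nearly unidentifiable.
    """
    H, W = shape or spec.image_shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    a, b = _axes_profile(spec, s)
    a, b = a + a_off, b + b_off
    rr, cc = np.ogrid[:H, :W]
    width = b * (1.0 - spec.brain_taper * (cy - rr) / a)
    return ((rr - cy) / a) ** 2 + ((cc - cx) / width) ** 2


def brain_ellipse_mask(spec, s, shape=None):
    """Analytic interior of the brain outline for slice ``s``."""
    return _brain_quadratic(spec, s, shape=shape) <= 1.0


def _content_labels(spec, s):
    """Noise-free CT-frame class map {0,1,2,3} for slice ``s``."""
    H, W = spec.image_shape
    brain = brain_ellipse_mask(spec, s)
    lab = np.where(brain, LBL_NORMAL, LBL_BACKGROUND).astype(np.int16)
    r = spec.lesion_radii[s]
    if r > 0:
        rr, cc = np.ogrid[:H, :W]
        d2 = (rr - spec.lesion_center[0]) ** 2 + \
            (cc - spec.lesion_center[1]) ** 2
        core = (d2 <= r ** 2) & brain
        pen = (d2 <= (r + spec.penumbra_width) ** 2) & brain & ~core
        lab[pen] = LBL_PENUMBRA
        lab[core] = LBL_CORE
    return lab


def generate_phantom(spec):
    """Render one phantom case from its spec (bit-deterministic)."""
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    k = spec.n_slices
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0

    ct = np.empty((k, H, W), dtype=np.float64)
    truth = np.zeros((k, H, W), dtype=bool)
    contents = []
    for s in range(k):
        brain = _brain_quadratic(spec, s) <= 1.0
        skull = (_brain_quadratic(spec, s, a_off=spec.skull_thickness,
                                  b_off=spec.skull_thickness) <= 1.0) & ~brain
        lab = _content_labels(spec, s)
        base = np.full((H, W), -1000.0)
        base[skull] = spec.skull_hu
        base[brain] = spec.tissue_hu
        base[lab == LBL_PENUMBRA] -= \
            spec.penumbra_contrast_frac * spec.lesion_contrast
        base[lab == LBL_CORE] -= spec.lesion_contrast
        ct[s] = base + rng.normal(0.0, spec.noise_sigma, (H, W))
        truth[s] = (lab == LBL_CORE) | (lab == LBL_PENUMBRA)
        contents.append(lab)

    t = spec.transform
    transform = RigidTransform2D(
        theta=t.theta, tx=t.tx, ty=t.ty,
        scale_row=t.scale_row, scale_col=t.scale_col,
        center_moving=((spec.label_shape[0] - 1) / 2.0,
                       (spec.label_shape[1] - 1) / 2.0),
        center_fixed=(cy, cx))

    LH, LW = spec.label_shape
    rr, cc = np.meshgrid(np.arange(LH), np.arange(LW), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    src = transform.apply(pts)
    sr = np.rint(src[:, 0]).astype(np.int64)
    sc = np.rint(src[:, 1]).astype(np.int64)
    valid = (sr >= 0) & (sr < H) & (sc >= 0) & (sc < W)
    flat = np.where(valid, sr * W + sc, 0)
    label_map = np.zeros((k, LH, LW), dtype=np.int16)
    for s in range(k):
        vals = contents[s].ravel()[flat]
        label_map[s] = np.where(valid, vals, 0).reshape(LH, LW)

    volume = CTVolume(ct, pixel_spacing=(1.0, 1.0), slice_thickness=5.0,
                      patient_id=f"phantom-{spec.seed}")
    return PhantomCase(volume, label_map, transform, truth, spec)


# ---------------------------------------------------------------------------
# Datasets


def _case_spec(case_seed, side, difficulty, n_slices, image_shape,
               label_shape):
    rng = np.random.default_rng(case_seed)
    contrast = DIFFICULTY_CONTRAST[difficulty]
    H, W = image_shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    scale = min(H, W) / 96.0
    axes = (44.0 * scale, 35.0 * scale)
    pen_w = 3.0 * scale

    base_r = rng.uniform(10.5, 12.5) * scale
    prof = 0.72 + 0.28 * np.sin(np.pi * (np.arange(n_slices) + 0.5)
                                / n_slices)
    radii = tuple(float(r) for r in np.round(base_r * prof, 2))
    rmax = max(radii)
    rout = rmax + pen_w
    offset = rout * 1.08 + rng.uniform(0.5, 2.0)
    row_off = rng.uniform(-7.0, 7.0) * scale
    tf = LabelTransformSpec(theta=rng.uniform(-10, 10),
                            tx=rng.uniform(-10, 10),
                            ty=rng.uniform(-10, 10),
                            scale_row=rng.uniform(1.05, 1.15),
                            scale_col=rng.uniform(0.85, 0.95))
    # deterministically shrink first the vertical offset, then the
    # horizontal offset toward its midline-clearing minimum, until the
    # lesion fits inside the brain outline on every slice
    offset_min = rout + 1.0
    for col_f in np.linspace(1.0, 0.0, 6):
        off = offset_min + (offset - offset_min) * col_f
        col = cx - off if side == "left" else cx + off
        for shrink in np.linspace(1.0, 0.0, 11):
            cand = PhantomSpec(
                n_slices=n_slices, image_shape=tuple(image_shape),
                label_shape=tuple(label_shape), brain_axes=axes,
                penumbra_width=pen_w,
                lesion_side=side,
                lesion_center=(cy + row_off * shrink, col),
                lesion_radii=radii, lesion_contrast=contrast,
                transform=tf, seed=int(case_seed))
            try:
                _validate(cand)
                return cand
            except PhantomSpecError:
                continue
    raise PhantomSpecError("could not place lesion inside the brain")


def generate_dataset(n_cases, difficulty="medium", master_seed=0,
                     n_slices=4, image_shape=(96, 96),
                     label_shape=(128, 128)):
    """Generate a balanced dataset of phantom cases plus its manifest.

    Lesion sides alternate, so side counts differ by at most one (equal
    for even ``n_cases``).  The manifest records every spec and
    regenerates the identical dataset.
    """
    if n_cases < 1:
        raise PhantomSpecError("n_cases must be >= 1")
    if difficulty not in DIFFICULTY_CONTRAST:
        raise PhantomSpecError(f"unknown difficulty {difficulty!r}")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in
             ss.spawn(n_cases)]
    cases = []
    specs = []
    for i, cs in enumerate(seeds):
        side = "left" if i % 2 == 0 else "right"
        spec = _case_spec(cs, side, difficulty, n_slices, image_shape,
                          label_shape)
        specs.append(spec)
        cases.append(generate_phantom(spec))
    manifest = {
        "master_seed": int(master_seed),
        "difficulty": difficulty,
        "n_cases": int(n_cases),
        "cases": [s.to_dict() for s in specs],
    }
    return cases, manifest


def dataset_from_manifest(manifest):
    """Regenerate the exact dataset a manifest describes."""
    if isinstance(manifest, str):
        with open(manifest) as fh:
            manifest = json.load(fh)
    return [generate_phantom(PhantomSpec.from_dict(d))
            for d in manifest["cases"]]
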