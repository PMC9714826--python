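"""Reproducible synthetic benchmarks of the whole pipeline.

These are the studies the package runs on its own phantoms: transform
recovery of the hull registration, the leave-one-out localization
benchmark (including the single-feature-map comparison), and the
hemisphere-postprocessing precision gain under injected contralateral
speckle.  Each is a deterministic function of its seed.
"""

from __future__ import annotations

import numpy as np

from . import evaluate as ev, phantom as ph, pipeline as pl
from .preprocess import (HullPolygon, RigidTransform2D, convex_hull,
                         extract_brain_mask, mask_midline_col,
                         register_hulls)


def run_registration_recovery(seed=0, n_cases=50, theta_max=10.0,
                              t_max=10.0, tol_theta=0.5, tol_t=0.5):
    """Recover known similarity transforms applied to phantom hulls.

    For each case the mid-slice brain hull of a seeded phantom is
    transformed by a known (theta, tx, ty, anisotropic scale) similarity
    and handed to :func:`register_hulls`.  Returns the fraction recovered
    within ``tol_theta`` degrees and ``tol_t`` px, plus error summaries.
    """
    rng = np.random.default_rng(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed).spawn(n_cases)]
    ok = 0
    errs = []
    for i, cs in enumerate(case_seeds):
        spec = ph._case_spec(cs, "left" if i % 2 == 0 else "right",
                             "medium", 4, (96, 96), (128, 128))
        case = ph.generate_phantom(spec)
        mid = spec.n_slices // 2
        hull = convex_hull(extract_brain_mask(case.ct.slices[mid]).mask)
        center = ((spec.image_shape[0] - 1) / 2.0,
                  (spec.image_shape[1] - 1) / 2.0)
        true = RigidTransform2D(
            theta=rng.uniform(-theta_max, theta_max),
            tx=rng.uniform(-t_max, t_max), ty=rng.uniform(-t_max, t_max),
            scale_row=rng.uniform(1.05, 1.15),
            scale_col=rng.uniform(0.85, 0.95),
            center_moving=center, center_fixed=center)
        moving = HullPolygon(true.apply_inverse(hull.vertices))
        rec = register_hulls(hull, moving, center_fixed=center,
                             center_moving=center)
        e = (abs(rec.theta - true.theta), abs(rec.tx - true.tx),
             abs(rec.ty - true.ty))
        errs.append(e)
        ok += e[0] <= tol_theta and e[1] <= tol_t and e[2] <= tol_t
    errs = np.asarray(errs)
    return dict(n=n_cases, recovered_frac=ok / n_cases,
                max_theta_err=float(errs[:, 0].max()),
                max_t_err=float(errs[:, 1:].max()))


def run_rendered_registration_residual(seed=0, n_cases=50):
    """Residual of the fully rendered registration path.

    Labels are rendered on their own misaligned grid, hulls re-extracted
    from the rendered mask, and the symmetric-difference residual
    (relative to the fixed hull area) measured after registration.
    """
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed).spawn(n_cases)]
    resid = []
    for i, cs in enumerate(case_seeds):
        spec = ph._case_spec(cs, "left" if i % 2 == 0 else "right",
                             "medium", 4, (96, 96), (128, 128))
        case = ph.generate_phantom(spec)
        mid = spec.n_slices // 2
        hf = convex_hull(extract_brain_mask(case.ct.slices[mid]).mask)
        hm = convex_hull(case.label_map[mid] > 0)
        rec = register_hulls(
            hf, hm,
            center_fixed=((spec.image_shape[0] - 1) / 2.0,
                          (spec.image_shape[1] - 1) / 2.0),
            center_moving=((spec.label_shape[0] - 1) / 2.0,
                           (spec.label_shape[1] - 1) / 2.0))
        resid.append(rec.objective / hf.to_shapely().area)
    resid = np.asarray(resid)
    return dict(n=n_cases, frac_below_002=float((resid <= 0.02).mean()),
                median_residual=float(np.median(resid)))


def run_loo_benchmark(master_seed=0, n_cases=18, difficulty="medium",
                      block_size=3, config=None, progress=None):
    """The standard leave-one-out phantom benchmark.

    Generates the dataset, prepares every case (registration, label
    transfer, features), runs the leave-one-out harness with single-map
    comparison models, and returns the aggregate plus per-fold results.
    """
    cases, manifest = ph.generate_dataset(n_cases, difficulty,
                                          master_seed=master_seed)
    cfg = config or pl.PipelineConfig(block_size=block_size)
    preps = [pl.prepare_phantom_case(c, cfg, case_id=str(i))
             for i, c in enumerate(cases)]
    truths = [c.truth for c in cases]
    results, agg = pl.leave_one_out(preps, truths, cfg,
                                    master_seed=master_seed,
                                    train_single_map=True,
                                    progress=progress)
    singles = {k: v for k, v in agg.items()
               if k.startswith("single_") and v is not None}
    agg["best_single_pixel_iou"] = max(singles.values()) if singles \
        else None
    return dict(aggregate=agg, folds=results, manifest=manifest)


def run_postprocessing_gain(seed=0, n_cases=50, n_speckles=6,
                            speckle_size=3):
    """Precision before vs after hemisphere selection under speckle.

    Each case takes a phantom's true lesion mask as the detection and
    injects small false-positive speckle components into the
    contralateral hemisphere; hemisphere selection should remove them
    and raise precision.  Returns the fraction of cases with
    precision_after >= precision_before.
    """
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed).spawn(n_cases)]
    gains = []
    for i, cs in enumerate(case_seeds):
        side = "left" if i % 2 == 0 else "right"
        spec = ph._case_spec(cs, side, "medium", 4, (96, 96), (128, 128))
        case = ph.generate_phantom(spec)
        rng = np.random.default_rng(cs + 1)
        masks = np.stack([ph.brain_ellipse_mask(spec, s)
                          for s in range(spec.n_slices)])
        mid = mask_midline_col(masks)
        pred = case.truth.copy()
        k, H, W = pred.shape
        placed = 0
        for _ in range(200):
            if placed >= n_speckles:
                break
            s = int(rng.integers(0, k))
            r = int(rng.integers(0, H))
            c = int(rng.integers(0, W))
            contralateral = (c > mid) if side == "left" else (c < mid)
            if not contralateral or not masks[s, r, c]:
                continue
            r1 = min(r + speckle_size, H)
            c1 = min(c + speckle_size, W)
            pred[s, r:r1, c:c1] |= masks[s, r:r1, c:c1]
            placed += 1
        before = ev.pixel_scores(pred, case.truth)["precision"]
        sel = ev.select_hemisphere(pred, midline_col=mid)
        after = ev.pixel_scores(sel.mask, case.truth)["precision"]
        gains.append(after >= before)
    return dict(n=n_cases, improved_frac=float(np.mean(gains)))
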