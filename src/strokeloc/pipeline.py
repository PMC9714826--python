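"""End-to-end pipeline: preparation, training, prediction, leave-one-out.

One case is a CT volume paired with a perfusion-style label map on its
own grid.  Preparation (unsupervised: masking, hull registration, label
transfer, hand-crafted features) is independent of any training fold and
happens once per case; training fits the three feature extractors, the
F4 pixel net and the ensemble fuser on the training cases of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import deep, ensemble as ens, evaluate as ev, features as feat
from .errors import TrainingError
from .preprocess import (convex_hull, extract_brain_mask_volume,
                         mask_midline_col, register_hulls, transfer_labels)
from .volume_io import LabelMap

LBL_CORE, LBL_PENUMBRA = 2, 3


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline (desk-scale defaults)."""

    block_size: int = 3
    tau: float = ev.DEFAULT_TAU
    eval_cell: int = ev.DEFAULT_EVAL_CELL
    label_positive: str = "core+penumbra"       # or "core"
    feature_config: feat.FeatureConfig = field(
        default_factory=feat.FeatureConfig)
    extractor_specs: tuple = deep.DEFAULT_EXTRACTOR_SPECS
    extractor_train: deep.ExtractorTrainConfig = field(
        default_factory=deep.ExtractorTrainConfig)
    pixelnet_train: feat.PixelNetConfig = field(
        default_factory=lambda: feat.PixelNetConfig(epochs=80,
                                                    max_samples=12000))
    ensemble_train: ens.EnsembleTrainConfig = field(
        default_factory=ens.EnsembleTrainConfig)
    postprocess: bool = True


@dataclass
class PreparedCase:
    """A case after registration, label transfer and feature assembly."""

    case_id: str
    hu: np.ndarray               # (k, H, W) float
    mask: np.ndarray             # (k, H, W) bool brain mask
    labels: np.ndarray           # (k, H, W) aligned classes {0,1,2,3}
    positive: np.ndarray         # (k, H, W) bool training-positive pixels
    target3: np.ndarray          # (k, H, W) {0 bg, 1 normal, 2 infarct}
    pfeat: np.ndarray            # (k, H, W, D) hand-crafted P vectors
    transform: object            # fitted label-map -> CT transform


def prepare_case(ct, label_map, config=None, case_id=""):
    """Mask, register, transfer labels and assemble P features.

    ``label_map`` is the raw perfusion-style map on its own grid; the
    registration uses the mid-stack slice pair, with rotation pivots at
    the two image centers.
    """
    config = config or PipelineConfig()
    hu = ct.slices
    lab = label_map.labels if isinstance(label_map, LabelMap) else \
        np.asarray(label_map)
    k, H, W = hu.shape
    mask = extract_brain_mask_volume(hu)
    mid = k // 2
    hull_fixed = convex_hull(mask[mid])
    hull_moving = convex_hull(lab[mid] > 0)
    tr = register_hulls(
        hull_fixed, hull_moving,
        center_fixed=((H - 1) / 2.0, (W - 1) / 2.0),
        center_moving=((lab.shape[1] - 1) / 2.0, (lab.shape[2] - 1) / 2.0))
    aligned = transfer_labels(lab, tr, (H, W)).labels
    aligned[~mask] = 0
    if config.label_positive == "core":
        positive = aligned == LBL_CORE
    else:
        positive = (aligned == LBL_CORE) | (aligned == LBL_PENUMBRA)
    target3 = np.where(mask, np.where(positive, 2, 1), 0).astype(np.int64)
    pfeat = np.stack([
        feat.assemble_pixel_features(hu[s], mask[s],
                                     config.feature_config)[0]
        for s in range(k)])
    return PreparedCase(case_id, hu, mask, aligned, positive, target3,
                        pfeat, tr)


def prepare_phantom_case(case, config=None, case_id=""):
    from .volume_io import LabelMap as LM
    return prepare_case(case.ct, LM(case.label_map), config,
                        case_id or case.ct.patient_id)


@dataclass
class FittedPipeline:
    extractors: list
    pixel_net: object
    fuser: object
    config: PipelineConfig
    single_map_fusers: dict = field(default_factory=dict)

    def save(self, directory):
        """Persist all trained components into a directory."""
        import json
        import os

        os.makedirs(directory, exist_ok=True)
        for i, ex in enumerate(self.extractors):
            ex.save(os.path.join(directory, f"extractor{i}.npz"))
        self.pixel_net.save(os.path.join(directory, "pixel_net.npz"))
        self.fuser.save(os.path.join(directory, "fuser.npz"))
        manifest = dict(n_extractors=len(self.extractors),
                        block_size=self.config.block_size,
                        tau=self.config.tau,
                        label_positive=self.config.label_positive,
                        scales=list(self.config.feature_config.scales),
                        cell_size=self.config.feature_config.cell_size)
        with open(os.path.join(directory, "pipeline.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory):
        import json
        import os

        with open(os.path.join(directory, "pipeline.json")) as fh:
            man = json.load(fh)
        config = PipelineConfig(
            block_size=man["block_size"], tau=man["tau"],
            label_positive=man["label_positive"],
            feature_config=feat.FeatureConfig(
                scales=tuple(man["scales"]), cell_size=man["cell_size"]))
        extractors = [
            deep.ExtractorModel.load(
                os.path.join(directory, f"extractor{i}.npz"))
            for i in range(man["n_extractors"])]
        pixel_net = feat.PixelNetModel.load(
            os.path.join(directory, "pixel_net.npz"))
        fuser = ens.EnsembleNet.load(os.path.join(directory, "fuser.npz"))
        return cls(extractors, pixel_net, fuser, config)


def _feature_stack(fitted, prep):
    """(k, 4, H, W) stack [F1, F2, F3, F4] for one prepared case."""
    k = prep.hu.shape[0]
    maps = [m.predict_volume(prep.hu, prep.mask)
            for m in fitted.extractors]
    f4 = np.zeros_like(maps[0])
    cfgf = fitted.config.feature_config
    for s in range(k):
        if prep.mask[s].any():
            probs = fitted.pixel_net.predict_proba(
                prep.pfeat[s][prep.mask[s]])
            f4[s][prep.mask[s]] = probs[:, 1]
    return np.stack(maps + [f4], axis=1)


def _blocks_of(fmaps, masks, block_size):
    k = fmaps.shape[0]
    return np.stack([ens.build_input_block(fmaps, masks, c, block_size)
                     for c in range(k)])


def fit(prepared_cases, config=None, seed=0, train_single_map=False):
    """Train extractors, F4 net and the ensemble on the given cases.

    Sub-seeds for each component derive from ``seed``.  With
    ``train_single_map`` four additional fusers are trained, each
    consuming only one feature map (plus mask), for diversity analysis.
    """
    config = config or PipelineConfig()
    if not prepared_cases:
        raise TrainingError("no training cases")
    ss = np.random.SeedSequence(seed)
    subs = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(9)]

    hu = np.concatenate([p.hu for p in prepared_cases])
    mask = np.concatenate([p.mask for p in prepared_cases])
    pos = np.concatenate([p.positive for p in prepared_cases])
    t3 = np.concatenate([p.target3 for p in prepared_cases])

    extractors = []
    for i, spec in enumerate(config.extractor_specs):
        tc = replace(config.extractor_train, seed=subs[i])
        extractors.append(deep.train_extractor(
            spec, hu, pos.astype(np.int64), mask, tc))

    pf = np.concatenate([p.pfeat.reshape(-1, p.pfeat.shape[-1])
                        [p.mask.ravel()] for p in prepared_cases])
    py = np.concatenate([p.positive.ravel()[p.mask.ravel()]
                         for p in prepared_cases]).astype(np.int64)
    names = feat.feature_names(config.feature_config)
    pixel_net = feat.train_pixel_net(pf, py, names, seed=subs[3],
                                     config=config.pixelnet_train)

    fitted = FittedPipeline(extractors, pixel_net, None, config)
    fmaps = np.concatenate([_feature_stack(fitted, p)
                            for p in prepared_cases])
    blocks = _blocks_of(fmaps, mask, config.block_size)
    fitted.fuser = ens.train_ensemble(blocks, mask, t3,
                                      config.ensemble_train, seed=subs[4])
    if train_single_map:
        for j, name in enumerate(["F1", "F2", "F3", "F4"]):
            sel = np.stack([blocks[:, g * 5 + j] for g in
                            range(config.block_size)], axis=1)
            selm = np.stack([blocks[:, g * 5 + 4] for g in
                             range(config.block_size)], axis=1)
            sub_blocks = np.empty(
                (blocks.shape[0], 2 * config.block_size) + blocks.shape[2:],
                np.float32)
            sub_blocks[:, 0::2] = sel
            sub_blocks[:, 1::2] = selm
            fitted.single_map_fusers[name] = ens.train_ensemble(
                sub_blocks, mask, t3, config.ensemble_train,
                seed=subs[5 + j])
    return fitted


def _single_map_blocks(fmaps, masks, j, block_size):
    k = fmaps.shape[0]
    blocks = _blocks_of(fmaps, masks, block_size)
    sel = np.stack([blocks[:, g * 5 + j] for g in range(block_size)], axis=1)
    selm = np.stack([blocks[:, g * 5 + 4] for g in range(block_size)],
                    axis=1)
    out = np.empty((k, 2 * block_size) + fmaps.shape[2:], np.float32)
    out[:, 0::2] = sel
    out[:, 1::2] = selm
    return out


def predict_case(fitted, prep, fuser=None, single_map=None):
    """Infarct probability maps L for one prepared case."""
    fmaps = _feature_stack(fitted, prep)
    cfg = fitted.config
    if single_map is not None:
        j = ["F1", "F2", "F3", "F4"].index(single_map)
        blocks = _single_map_blocks(fmaps, prep.mask, j, cfg.block_size)
        net = fitted.single_map_fusers[single_map]
    else:
        blocks = _blocks_of(fmaps, prep.mask, cfg.block_size)
        net = fuser or fitted.fuser
    from . import nn
    logits = net.forward_logits(blocks, prep.mask.astype(np.float32))
    probs = nn.softmax(logits.astype(np.float64), axis=1)
    return probs[:, ens.CLASS_INFARCT] * prep.mask


def postprocess_and_score(L, prep, truth, config):
    """Threshold, optional hemisphere selection, then both score levels."""
    pred = ev.threshold_probability(L, config.tau, prep.mask)
    if config.postprocess:
        pred = ev.select_hemisphere(pred,
                                    midline_col=mask_midline_col(prep.mask))
    report = ev.evaluate_case(pred.mask, truth, prep.mask, config.eval_cell)
    px = ev.pixel_scores(pred.mask, truth)
    return pred, report, px


def leave_one_out(prepared_cases, truths, config=None, master_seed=0,
                  train_single_map=False, progress=None):
    """The leave-one-out harness over prepared cases.

    For each fold, everything trainable is fitted on the remaining cases
    and evaluated on the held-out one; fold seeds derive from the master
    seed.  Returns (fold results, aggregate).  ``truths`` holds the
    ground-truth pixel lesion masks used for scoring (for phantoms, the
    analytic CT-frame mask).
    """
    config = config or PipelineConfig()
    n = len(prepared_cases)
    if n < 2:
        raise TrainingError("leave-one-out needs at least 2 cases")
    ss = np.random.SeedSequence(master_seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in ss.spawn(n)]
    results = []
    for i in range(n):
        train = [p for j, p in enumerate(prepared_cases) if j != i]
        try:
            fitted = fit(train, config, seed=fold_seeds[i],
                         train_single_map=train_single_map)
            held = prepared_cases[i]
            L = predict_case(fitted, held)
            _, report, px = postprocess_and_score(L, held, truths[i],
                                                  config)
            fold = dict(case=held.case_id or str(i), cells=report.as_dict(),
                        pixel=px, single_map={})
            for name in fitted.single_map_fusers:
                Ls = predict_case(fitted, held, single_map=name)
                _, rep_s, px_s = postprocess_and_score(Ls, held, truths[i],
                                                       config)
                fold["single_map"][name] = dict(cells=rep_s.as_dict(),
                                                pixel=px_s)
        except Exception as exc:
            raise TrainingError(f"fold {i} failed: {exc}") from exc
        results.append(fold)
        if progress:
            progress(i, n, fold)
    return results, aggregate_results(results)


def _mean(values):
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def aggregate_results(results):
    """Mean over folds, skipping undefined (None) values."""
    agg = {
        "pixel_iou": _mean(r["pixel"]["iou"] for r in results),
        "pixel_recall": _mean(r["pixel"]["recall"] for r in results),
        "pixel_precision": _mean(r["pixel"]["precision"] for r in results),
    }
    for key in ("accuracy", "precision", "recall", "f1"):
        agg[f"cell_{key}"] = _mean(r["cells"][key] for r in results)
    names = sorted({n for r in results for n in r["single_map"]})
    for name in names:
        agg[f"single_{name}_pixel_iou"] = _mean(
            r["single_map"][name]["pixel"]["iou"] for r in results)
    return agg
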