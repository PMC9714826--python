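"""Thresholding, hemisphere selection and the cell-wise evaluation.

Infarcts appear on one side of the brain; speckle on the other side is
noise.  Postprocessing therefore keeps only the hemisphere with the
largest connected infarct region.  Evaluation follows the cell-wise
protocol: the pixel masks are subsampled into 32x32 cells by majority
rule and precision, recall and F1 are computed from the cell confusion
counts; IoU is computed on pixels (cell-level optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .preprocess import FOUR_CONN, mask_midline_col

DEFAULT_TAU = 0.5
DEFAULT_EVAL_CELL = 32


@dataclass
class BinaryLesionMask:
    mask: np.ndarray             # (k, H, W) bool
    threshold: float = DEFAULT_TAU

    def __post_init__(self):
        self.mask = np.atleast_3d(np.asarray(self.mask, dtype=bool))


@dataclass
class CellLabelGrid:
    labels: np.ndarray           # (k, nr, nc) bool
    occupancy: np.ndarray        # in-mask pixel count per cell (validity)
    cell_size: int = DEFAULT_EVAL_CELL


@dataclass
class EvaluationReport:
    """Cell confusion counts and the derived classification measures.

    ``precision``/``recall``/``f1`` are None when their denominator is
    zero (undefined, excluded from aggregates).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    iou: float | None = None

    def as_dict(self):
        return dict(tp=self.tp, fp=self.fp, fn=self.fn, tn=self.tn,
                    accuracy=self.accuracy, precision=self.precision,
                    recall=self.recall, f1=self.f1, iou=self.iou)


def threshold_probability(prob, tau=DEFAULT_TAU, brain_mask=None):
    """Binary lesion mask: pixel positive iff L >= tau (and in-mask)."""
    if not 0.0 < tau < 1.0:
        raise ParameterError(f"threshold {tau} outside (0, 1)")
    L = np.atleast_3d(np.asarray(prob, dtype=np.float64))
    pos = L >= tau
    if brain_mask is not None:
        pos &= np.atleast_3d(np.asarray(brain_mask, dtype=bool))
    return BinaryLesionMask(pos, tau)


def select_hemisphere(lesion_mask, midline_col=None, brain_mask=None):
    """Zero all positives on the side with the weaker infarct evidence.

    Components are 4-connected per slice; each side's score is the sum
    over slices of its largest component size, so one side is kept for
    the whole volume.  Ties go to the larger total positive count, then
    to image-left.  The midline defaults to the brain-mask column
    centroid (same convention as the contralateral features).
    """
    m = lesion_mask.mask if isinstance(lesion_mask, BinaryLesionMask) else \
        np.atleast_3d(np.asarray(lesion_mask, dtype=bool))
    if not m.any():
        return BinaryLesionMask(m.copy())
    if midline_col is None:
        ref = brain_mask if brain_mask is not None else m
        midline_col = mask_midline_col(ref)
    cols = np.arange(m.shape[2])
    left_cols = cols < midline_col
    sides = {}
    for name, side_sel in (("left", left_cols), ("right", ~left_cols)):
        side = m & side_sel[None, None, :]
        largest = 0
        for s in range(m.shape[0]):
            lab, n = ndimage.label(side[s], structure=FOUR_CONN)
            if n:
                largest += int(np.bincount(lab.ravel())[1:].max())
        sides[name] = (side, largest, int(side.sum()))
    (lm, lscore, lcount) = sides["left"]
    (rm, rscore, rcount) = sides["right"]
    if (lscore, lcount) >= (rscore, rcount):
        keep = lm
    else:
        keep = rm
    out = BinaryLesionMask(keep)
    out.threshold = getattr(lesion_mask, "threshold", DEFAULT_TAU)
    return out


def cell_majority_labels(pixel_mask, cell_size=DEFAULT_EVAL_CELL,
                         brain_mask=None):
    """Subsample a pixel mask onto a cell grid by the majority rule.

    A cell is positive iff strictly more than half of its pixels are
    positive (an exact half is negative).  ``occupancy`` counts in-mask
    pixels per cell, used to exclude cells without brain tissue from the
    confusion matrix.
    """
    if cell_size < 1:
        raise ParameterError("cell size must be >= 1")
    m = np.atleast_3d(np.asarray(pixel_mask, dtype=bool))
    k, H, W = m.shape
    nr = -(-H // cell_size)
    nc = -(-W // cell_size)
    labels = np.zeros((k, nr, nc), dtype=bool)
    occ = np.zeros((k, nr, nc), dtype=np.int64)
    bm = None if brain_mask is None else \
        np.atleast_3d(np.asarray(brain_mask, dtype=bool))
    for i in range(nr):
        r0, r1 = i * cell_size, min((i + 1) * cell_size, H)
        for j in range(nc):
            c0, c1 = j * cell_size, min((j + 1) * cell_size, W)
            cell = m[:, r0:r1, c0:c1]
            npix = (r1 - r0) * (c1 - c0)
            labels[:, i, j] = cell.sum(axis=(1, 2)) * 2 > npix
            if bm is None:
                occ[:, i, j] = npix
            else:
                occ[:, i, j] = bm[:, r0:r1, c0:c1].sum(axis=(1, 2))
    return CellLabelGrid(labels, occ, cell_size)


def compute_metrics(pred, truth):
    """Confusion counts and the classification measures over valid cells.

    ``pred`` and ``truth`` are :class:`CellLabelGrid`; cells without any
    in-mask pixel (occupancy 0 in either grid) are excluded.  Accuracy is
    (TP+TN)/(all valid cells); precision TP/(TP+FP); recall TP/(TP+FN);
    F1 the harmonic mean.  A zero denominator yields None.
    """
    if pred.labels.shape != truth.labels.shape:
        raise GeometryError("cell grids have different shapes")
    valid = (pred.occupancy > 0) & (truth.occupancy > 0)
    p = pred.labels[valid]
    t = truth.labels[valid]
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    total = tp + fp + fn + tn

    def ratio(num, den):
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = None
    if precision is not None and recall is not None and \
            (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return EvaluationReport(tp, fp, fn, tn, ratio(tp + tn, total),
                            precision, recall, f1)


def compute_iou(pred_pixels, truth_pixels):
    """|A∩B| / |A∪B| over pixels; both empty -> 1.0, one empty -> 0.0."""
    a = np.asarray(pred_pixels, dtype=bool)
    b = np.asarray(truth_pixels, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("masks have different shapes")
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def pixel_scores(pred_pixels, truth_pixels):
    """Pixel-level iou/precision/recall (None when undefined)."""
    a = np.asarray(pred_pixels, dtype=bool)
    b = np.asarray(truth_pixels, dtype=bool)
    tp = int((a & b).sum())
    return dict(
        iou=compute_iou(a, b),
        precision=tp / a.sum() if a.sum() else None,
        recall=tp / b.sum() if b.sum() else None,
    )


def evaluate_case(pred_pixels, truth_pixels, brain_mask,
                  cell_size=DEFAULT_EVAL_CELL):
    """Full per-case report: cell-wise protocol plus pixel IoU."""
    pred_cells = cell_majority_labels(pred_pixels, cell_size, brain_mask)
    truth_cells = cell_majority_labels(truth_pixels, cell_size, brain_mask)
    report = compute_metrics(pred_cells, truth_cells)
    report.iou = compute_iou(pred_pixels, truth_pixels)
    return report
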