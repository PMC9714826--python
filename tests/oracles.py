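"""Independent brute-force oracles used by the tests.

Everything here is written as direct per-pixel enumeration, deliberately
avoiding the vectorised machinery of the package, so that agreement is a
genuine two-route check.
"""

import numpy as np


def brute_cell_stats(slice_hu, mask, cell_size):
    """Per-cell (max, mean, median) by direct enumeration."""
    H, W = slice_hu.shape
    nr = -(-H // cell_size)
    nc = -(-W // cell_size)
    out = np.full((nr, nc, 3), np.nan)
    for i in range(nr):
        for j in range(nc):
            vals = []
            for r in range(i * cell_size, min((i + 1) * cell_size, H)):
                for c in range(j * cell_size, min((j + 1) * cell_size, W)):
                    if mask[r, c]:
                        vals.append(slice_hu[r, c])
            if vals:
                out[i, j] = (max(vals), float(np.mean(vals)),
                             float(np.median(vals)))
    return out


def brute_window_stats(slice_hu, mask, nominal_size, r, c):
    """(max, mean, median) of the symmetric clipped window at (r, c)."""
    rad = nominal_size // 2
    H, W = slice_hu.shape
    vals = [slice_hu[i, j]
            for i in range(max(0, r - rad), min(H, r + rad + 1))
            for j in range(max(0, c - rad), min(W, c + rad + 1))
            if mask[i, j]]
    if not vals:
        return (np.nan, np.nan, np.nan)
    return (max(vals), float(np.mean(vals)), float(np.median(vals)))


def brute_window_maps(slice_hu, mask, nominal_size):
    """Full (max, mean, median) maps by an explicit per-pixel loop.

    Each pixel's clipped symmetric window is gathered by direct slicing,
    independent of the package's sliding-window machinery.
    """
    rad = nominal_size // 2
    H, W = slice_hu.shape
    out = np.full((H, W, 3), np.nan)
    for r in range(H):
        for c in range(W):
            win = slice_hu[max(0, r - rad):r + rad + 1,
                           max(0, c - rad):c + rad + 1]
            wm = mask[max(0, r - rad):r + rad + 1,
                      max(0, c - rad):c + rad + 1]
            vals = win[wm]
            if vals.size:
                out[r, c] = (vals.max(), vals.mean(), np.median(vals))
    return out


def brute_bilateral_map(slice_hu, sigma_spatial=3.0, sigma_color=10.0,
                        truncate=3.0):
    """Full bilateral-filter map by an explicit per-pixel loop."""
    H, W = slice_hu.shape
    R = max(1, int(round(truncate * sigma_spatial)))
    yy, xx = np.mgrid[-R:R + 1, -R:R + 1]
    spatial = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma_spatial ** 2))
    out = np.empty((H, W))
    for r in range(H):
        for c in range(W):
            r0, r1 = max(0, r - R), min(H, r + R + 1)
            c0, c1 = max(0, c - R), min(W, c + R + 1)
            win = slice_hu[r0:r1, c0:c1]
            sp = spatial[r0 - r + R:r1 - r + R, c0 - c + R:c1 - c + R]
            w = sp * np.exp(-(win - slice_hu[r, c]) ** 2
                            / (2 * sigma_color ** 2))
            out[r, c] = (w * win).sum() / w.sum()
    return out


def brute_global_stats(slice_hu, mask):
    vals = slice_hu[mask]
    return (vals.max(), float(vals.mean()), float(np.median(vals)))


def brute_bilateral(slice_hu, r, c, sigma_spatial=3.0, sigma_color=10.0,
                    truncate=3.0):
    """Bilateral-filtered value at one pixel by direct summation."""
    H, W = slice_hu.shape
    R = max(1, int(round(truncate * sigma_spatial)))
    num = den = 0.0
    x0 = slice_hu[r, c]
    for i in range(max(0, r - R), min(H, r + R + 1)):
        for j in range(max(0, c - R), min(W, c + R + 1)):
            d2 = (i - r) ** 2 + (j - c) ** 2
            w = np.exp(-d2 / (2 * sigma_spatial ** 2)
                       - (slice_hu[i, j] - x0) ** 2
                       / (2 * sigma_color ** 2))
            num += w * slice_hu[i, j]
            den += w
    return num / den


def brute_confusion(pred, truth, valid):
    """Confusion counts by direct enumeration over valid cells."""
    tp = fp = fn = tn = 0
    for p, t, v in zip(pred.ravel(), truth.ravel(), valid.ravel()):
        if not v:
            continue
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_iou(a, b):
    inter = union = 0
    for x, y in zip(a.ravel(), b.ravel()):
        if x or y:
            union += 1
            if x and y:
                inter += 1
    return 1.0 if union == 0 else inter / union


def brute_majority(mask2d, cell_size):
    """Cell majority labels of one slice by direct counting."""
    H, W = mask2d.shape
    nr = -(-H // cell_size)
    nc = -(-W // cell_size)
    out = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            npix = pos = 0
            for r in range(i * cell_size, min((i + 1) * cell_size, H)):
                for c in range(j * cell_size, min((j + 1) * cell_size, W)):
                    npix += 1
                    pos += bool(mask2d[r, c])
            out[i, j] = pos * 2 > npix
    return out
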