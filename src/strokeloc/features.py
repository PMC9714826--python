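"""Contralateral, local and global hand-crafted features, and the F4 net.

Early infarcts are only subtly hypodense, and the healthy hemisphere is
the best patient-internal reference: the contralateral feature C compares
each cell of a slice with its mirror cell across the patient midline,
the local feature K summarises a sliding window around each pixel (plus a
bilateral-filtered value), and the global feature G summarises the whole
brain.  Per pixel these concatenate into the feature vector P, which a
small fully-connected network turns into the per-pixel infarct
probability map F4.

Numerical conventions (all deliberate, so that horizontally mirroring a
slice+mask mirrors the C and K maps *bit-exactly*):

* statistics are computed over sorted values, making them independent of
  pixel enumeration order;
* the patient midline is the column centroid of the brain mask, carried
  as an exact integer ratio; contralateral cell pairing is decided in
  integer arithmetic;
* an even nominal window size ``w`` denotes the symmetric window of
  radius ``w//2`` (so ``(w+1)^2`` pixels in the interior), clipped at the
  image border and restricted to in-mask pixels;
* the bilateral filter accumulates mirrored offset pairs together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .errors import GeometryError, ParameterError, StateError, TrainingError

__all__ = [
    "FeatureConfig", "CellGrid", "cell_statistics", "contralateral_pair",
    "cell_feature_maps", "local_window_features", "global_features",
    "bilateral_filter", "assemble_pixel_features", "feature_names",
    "PixelNetConfig", "PixelNetModel", "train_pixel_net", "predict_f4",
    "mask_midline",
]


@dataclass
class FeatureConfig:
    """Configuration of the hand-crafted feature vector.

    ``scales`` are the nominal sliding-window sizes; the single-scale
    setting ``(16,)`` yields the literal 13-component vector, the default
    three scales yield 21 components.
    """

    scales: tuple = (8, 16, 32)
    cell_size: int = 16
    bilateral_sigma_spatial: float = 3.0   # px
    bilateral_sigma_color: float = 10.0    # HU

    @property
    def n_features(self):
        return 6 + 4 * len(self.scales) + 3


def feature_names(config):
    names = ["C_own_max", "C_own_mean", "C_own_median",
             "C_contra_max", "C_contra_mean", "C_contra_median"]
    for w in config.scales:
        names += [f"K{w}_max", f"K{w}_mean", f"K{w}_median", f"K{w}_bilat"]
    names += ["G_max", "G_mean", "G_median"]
    return tuple(names)


def _sorted_stats(values):
    """(max, mean, median) of a 1-D array, order-canonical; NaNs if empty."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    if n == 0:
        return np.nan, np.nan, np.nan
    mean = float(v.sum() / n)
    med = float((v[(n - 1) // 2] + v[n // 2]) / 2.0)
    return float(v[-1]), mean, med


def mask_midline(mask):
    """Midline as the exact integer ratio (column_sum, count)."""
    m = np.asarray(mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise GeometryError("midline of an empty mask is undefined")
    return int(np.nonzero(m)[-1].sum()), n


# ---------------------------------------------------------------------------
# Cell grid and contralateral pairing


@dataclass
class CellGrid:
    """Per-cell max/mean/median of in-mask HU over a rectangular tiling.

    Edge cells may be smaller; cells without in-mask pixels carry NaN and
    are imputed with the global in-mask mean downstream.
    """

    cell_h: int
    cell_w: int
    stat_max: np.ndarray
    stat_mean: np.ndarray
    stat_median: np.ndarray
    occupancy: np.ndarray
    row_edges: np.ndarray
    col_edges: np.ndarray

    @property
    def shape(self):
        return self.occupancy.shape

    @property
    def col_centers(self):
        """Cell column centers, exact halves: (first + last pixel) / 2."""
        return (self.col_edges[:-1] + self.col_edges[1:] - 1) / 2.0


def cell_statistics(slice_hu, mask, cell_size):
    """Tile the slice into cells and summarise in-mask HU per cell."""
    a = np.asarray(slice_hu, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if a.shape != m.shape:
        raise GeometryError("slice and mask shapes differ")
    if np.isscalar(cell_size):
        ch = cw = int(cell_size)
    else:
        ch, cw = map(int, cell_size)
    H, W = a.shape
    if ch > H or cw > W or ch < 1 or cw < 1:
        raise ParameterError(f"cell size {(ch, cw)} invalid for slice "
                             f"{(H, W)}")
    row_edges = np.arange(0, H + ch, ch)
    row_edges[-1] = min(row_edges[-1], H)
    row_edges = np.unique(row_edges)
    col_edges = np.arange(0, W + cw, cw)
    col_edges[-1] = min(col_edges[-1], W)
    col_edges = np.unique(col_edges)
    nr, nc = len(row_edges) - 1, len(col_edges) - 1
    smax = np.full((nr, nc), np.nan)
    smean = np.full((nr, nc), np.nan)
    smed = np.full((nr, nc), np.nan)
    occ = np.zeros((nr, nc), dtype=np.int64)
    for i in range(nr):
        r0, r1 = row_edges[i], row_edges[i + 1]
        for j in range(nc):
            c0, c1 = col_edges[j], col_edges[j + 1]
            vals = a[r0:r1, c0:c1][m[r0:r1, c0:c1]]
            occ[i, j] = vals.size
            if vals.size:
                smax[i, j], smean[i, j], smed[i, j] = _sorted_stats(vals)
    return CellGrid(ch, cw, smax, smean, smed, occ, row_edges, col_edges)


def _pair_columns(grid, midline):
    """Contralateral cell column for every column; -1 where off-grid.

    ``midline`` is the exact (column_sum, count) ratio.  The mirror of a
    cell center c is 2*S/n - c; we pick the nearest cell center, deciding
    in integers: D_j = |n*(2*c_j + 2*c) - 4*S| is exact because doubled
    centers are integers.  A mirror farther than half a cell from every
    center falls off the grid.
    """
    S, n = midline
    c2 = np.rint(2.0 * grid.col_centers).astype(np.int64)   # exact doubles
    pairs = np.full(len(c2), -1, dtype=np.int64)
    for j, cj in enumerate(c2):
        D = np.abs(n * (c2 + cj) - 4 * S)
        jbest = int(np.argmin(D))
        if D[jbest] <= 2 * n * grid.cell_w:
            pairs[j] = jbest
    return pairs


def contralateral_pair(cell_index, midline_col, grid):
    """Mirror cell of ``cell_index`` (row, col) across the midline.

    ``midline_col`` may be a float column or the exact (sum, count) pair
    from :func:`mask_midline`.  Returns (row, col') or None when the
    mirror falls outside the grid.
    """
    if isinstance(midline_col, tuple):
        midline = midline_col
    else:
        midline = (int(round(float(midline_col) * 2 ** 20)), 2 ** 20)
    pairs = _pair_columns(grid, midline)
    r, c = cell_index
    if pairs[c] < 0:
        return None
    return (r, int(pairs[c]))


def cell_feature_maps(slice_hu, mask, config):
    """Per-pixel C features: own-cell and contralateral-cell statistics."""
    grid = cell_statistics(slice_hu, mask, config.cell_size)
    midline = mask_midline(mask)
    pairs = _pair_columns(grid, midline)
    H, W = np.asarray(slice_hu).shape
    ri = np.minimum(np.arange(H) // grid.cell_h, grid.shape[0] - 1)
    ci = np.minimum(np.arange(W) // grid.cell_w, grid.shape[1] - 1)
    own = np.stack([grid.stat_max, grid.stat_mean, grid.stat_median], -1)
    # append a NaN sentinel cell for off-grid mirrors
    padded = np.concatenate([own, np.full((own.shape[0], 1, 3), np.nan)], 1)
    contra = padded[:, pairs, :]            # pairs == -1 -> sentinel column
    out = np.empty((H, W, 6))
    out[..., :3] = own[np.ix_(ri, ci)]
    out[..., 3:] = contra[np.ix_(ri, ci)]
    return out


# ---------------------------------------------------------------------------
# Local sliding-window and global features


def _sliding_stats(arr_nan, radius):
    """(max, mean, median) maps over clipped symmetric windows.

    ``arr_nan`` holds the HU with NaN outside the mask; windows are
    (2*radius+1)^2, clipped at the border via NaN padding.  Sorting each
    window makes every statistic independent of enumeration order.
    """
    H, W = arr_nan.shape
    r = radius
    pad = np.pad(arr_nan, r, constant_values=np.nan)
    win = sliding_window_view(pad, (2 * r + 1, 2 * r + 1))
    flat = np.sort(win.reshape(H, W, -1), axis=-1)     # NaNs sort last
    cnt = flat.shape[-1] - np.isnan(flat).sum(axis=-1)
    has = cnt > 0
    idx = np.maximum(cnt - 1, 0)
    kmax = np.take_along_axis(flat, idx[..., None], -1)[..., 0]
    lo = np.take_along_axis(flat, (np.maximum(cnt - 1, 0) // 2)[..., None],
                            -1)[..., 0]
    hi = np.take_along_axis(flat, (np.where(has, cnt // 2, 0))[..., None],
                            -1)[..., 0]
    kmed = (lo + hi) / 2.0
    ksum = np.nansum(flat, axis=-1)                    # canonical order
    with np.errstate(invalid="ignore"):
        kmean = np.where(has, ksum / np.maximum(cnt, 1), np.nan)
    kmax = np.where(has, kmax, np.nan)
    kmed = np.where(has, kmed, np.nan)
    return kmax, kmean, kmed


def bilateral_filter(slice_hu, sigma_spatial=3.0, sigma_color=10.0,
                     truncate=3.0):
    """Edge-preserving bilateral filter of one slice.

    Plain Gaussian range/domain kernels, truncated at ``truncate`` spatial
    sigmas, normalised over the in-image support.  Mirrored horizontal
    offsets are accumulated as pairs so that the output of a mirrored
    image is exactly the mirrored output.
    """
    x = np.asarray(slice_hu, dtype=np.float64)
    H, W = x.shape
    R = max(1, int(round(truncate * sigma_spatial)))
    pad = np.pad(x, R, constant_values=np.nan)
    inv2ss = 1.0 / (2.0 * sigma_spatial ** 2)
    inv2sc = 1.0 / (2.0 * sigma_color ** 2)
    num = np.zeros_like(x)
    den = np.zeros_like(x)

    def term(di, dj):
        v = pad[R + di:R + di + H, R + dj:R + dj + W]
        w = np.exp(-(di * di + dj * dj) * inv2ss
                   - (v - x) ** 2 * inv2sc)
        w = np.where(np.isnan(v), 0.0, w)
        return w * np.nan_to_num(v), w

    for di in range(-R, R + 1):
        n0, d0 = term(di, 0)
        num += n0
        den += d0
        for dj in range(1, R + 1):
            na, da = term(di, dj)
            nb, db = term(di, -dj)
            num += na + nb
            den += da + db
    return num / den


def local_window_features(slice_hu, mask, window_sizes=(8, 16, 32),
                          sigma_spatial=3.0, sigma_color=10.0):
    """Per-pixel K features for each window scale (ascending).

    For each nominal size ``w`` (even, >= 2): max/mean/median of in-mask
    HU over the symmetric radius-``w//2`` window centered at the pixel,
    plus the bilateral-filtered value at the pixel (the filter is applied
    once per slice, not per window).  Pixels whose window holds no in-mask
    pixel get NaN, imputed with the global in-mask mean downstream.
    """
    a = np.asarray(slice_hu, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if a.shape != m.shape:
        raise GeometryError("slice and mask shapes differ")
    sizes = tuple(sorted(int(w) for w in window_sizes))
    for w in sizes:
        if w < 2 or w % 2:
            raise ParameterError(f"window size {w} must be even and >= 2")
    arr = np.where(m, a, np.nan)
    bilat = bilateral_filter(a, sigma_spatial, sigma_color)
    out = np.empty(a.shape + (4 * len(sizes),))
    for i, w in enumerate(sizes):
        kmax, kmean, kmed = _sliding_stats(arr, w // 2)
        out[..., 4 * i:4 * i + 3] = np.stack([kmax, kmean, kmed], -1)
        out[..., 4 * i + 3] = bilat
    return out


def global_features(slice_hu, mask):
    """(max, mean, median) of HU over the in-mask pixels."""
    a = np.asarray(slice_hu, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise GeometryError("global features of an empty mask")
    return np.array(_sorted_stats(a[m]))


def assemble_pixel_features(slice_hu, mask, config=None):
    """Concatenate C, K and G into the per-pixel feature stack.

    Order: own-cell C (3), contralateral C (3), K per ascending scale
    (4 each), G (3); 13 components at a single scale, 21 at the default
    three.  NaN components (empty cells/windows, off-grid mirrors) are
    imputed with the global in-mask mean.  Returns ``(features, names)``
    with ``features`` of shape (H, W, D).
    """
    config = config or FeatureConfig()
    m = np.asarray(mask, dtype=bool)
    names = feature_names(config)
    H, W = np.asarray(slice_hu).shape
    if not m.any():
        return np.zeros((H, W, len(names))), names
    c6 = cell_feature_maps(slice_hu, m, config)
    k = local_window_features(slice_hu, m, config.scales,
                              config.bilateral_sigma_spatial,
                              config.bilateral_sigma_color)
    g = global_features(slice_hu, m)
    out = np.concatenate(
        [c6, k, np.broadcast_to(g, (H, W, 3))], axis=-1)
    out = np.where(np.isnan(out), g[1], out)
    return out, names


# ---------------------------------------------------------------------------
# F4: pixel-wise network


@dataclass
class PixelNetConfig:
    hidden: tuple = (64, 32)
    lr: float = 1e-3
    epochs: int = 150
    val_frac: float = 0.15
    patience: int = 15
    max_samples: int = 20000
    weight_cap: float = 50.0


class PixelNetModel:
    """Trained pixel-feature classifier with its standardisation."""

    def __init__(self, layers, feat_names, mean, std, seed, loss_curve):
        self.layers = layers
        self.feature_names = tuple(feat_names)
        self.mean = mean
        self.std = std
        self.seed = seed
        self.loss_curve = loss_curve

    def _forward(self, X):
        h = X
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def predict_proba(self, X):
        Z = ((np.asarray(X, dtype=np.float64) - self.mean)
             / self.std).astype(np.float32)
        return nn.softmax(self._forward(Z), axis=1)

    def save(self, path):
        arrays = nn.state_arrays(self.layers)
        np.savez(path, mean=self.mean, std=self.std, seed=self.seed,
                 loss_curve=np.asarray(self.loss_curve),
                 feature_names=np.array(self.feature_names),
                 n_in=len(self.mean), **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            names = tuple(str(s) for s in z["feature_names"])
            model = _build_pixel_net(int(z["n_in"]), int(z["seed"]))
            nn.load_state_arrays(model, {k: z[k] for k in z.files
                                         if k.startswith("p")})
            return cls(model, names, z["mean"], z["std"], int(z["seed"]),
                       list(z["loss_curve"]))


def _build_pixel_net(n_in, seed, hidden=(64, 32)):
    rng = np.random.default_rng(seed)
    layers = []
    prev = n_in
    for h in hidden:
        layers += [nn.Dense(rng, prev, h), nn.ReLU()]
        prev = h
    # small final init keeps the untrained network near-uniform
    layers.append(nn.Dense(rng, prev, 2, init_scale=0.01))
    return layers


def train_pixel_net(features, labels, feat_names, seed=0, config=None):
    """Train the F4 pixel classifier on (N, D) features, binary labels.

    Class-weighted cross-entropy, Adam, early stopping on a held-out
    validation split; standardisation parameters are learned on the
    training split only.  Bit-reproducible from the seed.
    """
    config = config or PixelNetConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ParameterError("features must be (N, D) matching labels")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    if len(idx) > config.max_samples:
        idx = idx[:config.max_samples]
    X, y = X[idx], y[idx]
    n_val = max(1, int(len(y) * config.val_frac))
    Xv, yv = X[:n_val], y[:n_val]
    Xt, yt = X[n_val:], y[n_val:]
    if len(np.unique(yt)) < 2:
        raise TrainingError("training split lost a class; need more data")
    mean = Xt.mean(axis=0)
    std = np.maximum(Xt.std(axis=0), 1e-6)
    Zt = ((Xt - mean) / std).astype(np.float32)
    Zv = ((Xv - mean) / std).astype(np.float32)
    counts = np.bincount(yt, minlength=2).astype(np.float64)
    cw = np.minimum(len(yt) / (2.0 * np.maximum(counts, 1.0)),
                    config.weight_cap)
    wt = cw[yt].astype(np.float32)
    wv = cw[yv].astype(np.float32)

    layers = _build_pixel_net(X.shape[1], seed, config.hidden)
    params = [p for l in layers for p in l.params]
    opt = nn.Adam(params, lr=config.lr)
    best = (np.inf, None, 0)
    curve = []
    for epoch in range(config.epochs):
        h = Zt
        for layer in layers:
            h = layer.forward(h)
        loss, d = nn.weighted_softmax_xent(h, yt, wt)
        for layer in reversed(layers):
            d = layer.backward(d)
        opt.step()
        hv = Zv
        for layer in layers:
            hv = layer.forward(hv)
        vloss, _ = nn.weighted_softmax_xent(hv, yv, wv)
        curve.append((loss, vloss))
        if vloss < best[0] - 1e-9:
            best = (vloss, [p.value.copy() for p in params], epoch)
        elif epoch - best[2] >= config.patience:
            break
    if best[1] is not None:
        for p, v in zip(params, best[1]):
            p.value = v
    return PixelNetModel(layers, feat_names, mean, std, seed, curve)


def predict_f4(model, slice_hu, mask, config=None):
    """Per-pixel infarct probability map F4 in [0, 1]; 0 out of mask."""
    config = config or FeatureConfig()
    m = np.asarray(mask, dtype=bool)
    H, W = np.asarray(slice_hu).shape
    out = np.zeros((H, W))
    if not m.any():
        return out
    feats, names = assemble_pixel_features(slice_hu, m, config)
    if names != model.feature_names:
        raise StateError("feature configuration differs from the one the "
                         "model was trained with")
    probs = model.predict_proba(feats[m])
    out[m] = probs[:, 1]
    return out
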