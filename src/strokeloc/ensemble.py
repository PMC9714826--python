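"""Fusion of the four feature maps over neighboring-slice blocks.

The ensemble is deliberately small: one 3x3 convolution with 64 kernels
(stride 1, ReLU), whose activations are gated by the center-slice brain
mask, followed by a 1x1 convolution with 3 kernels (ReLU) and a softmax
over the three output classes {background, normal tissue, infarct}.  Its
input block stacks, for each slice of a 1-, 3- or 5-slice neighborhood,
the five channels [F1, F2, F3, F4, mask]; volume ends are padded by edge
replication.  The infarct-class channel L is the per-pixel infarct
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import DependencyError, GeometryError, TrainingError

CHANNELS_PER_SLICE = 5
N_CLASSES = 3
#: Output-class convention: L is the infarct channel.
CLASS_BACKGROUND, CLASS_NORMAL, CLASS_INFARCT = 0, 1, 2


@dataclass
class EnsembleTrainConfig:
    steps: int = 40
    batch: int = 4
    lr: float = 3e-3
    weight_cap: float = 50.0
    seed: int = 0


def build_input_block(feature_maps, masks, c, block_size):
    """Stack the 5-channel groups of a slice neighborhood.

    ``feature_maps`` is a (k, 4, H, W) array of per-slice [F1, F2, F3,
    F4]; ``masks`` a (k, H, W) bool array.  Channels run over slices
    ``c - b//2 ... c + b//2`` (clipped to the volume, i.e. edge
    replication), within each slice in the order [F1, F2, F3, F4, h].
    """
    if block_size not in (1, 3, 5):
        raise GeometryError(f"block size {block_size} not in {{1, 3, 5}}")
    f = np.asarray(feature_maps)
    m = np.asarray(masks, dtype=bool)
    if f.ndim != 4 or f.shape[1] != 4:
        raise DependencyError("feature maps must be (k, 4, H, W)")
    if np.isnan(f).any():
        bad = int(np.where(np.isnan(f).any(axis=(1, 2, 3)))[0][0])
        raise DependencyError(f"feature map of slice {bad} is invalid")
    k = f.shape[0]
    if not 0 <= c < k:
        raise DependencyError(f"no feature maps for slice {c}")
    half = block_size // 2
    groups = []
    for s in range(c - half, c + half + 1):
        s = min(max(s, 0), k - 1)
        groups.append(np.concatenate([f[s], m[s][None]], axis=0))
    return np.concatenate(groups, axis=0).astype(np.float32)


class EnsembleNet:
    """The two-layer convolutional fuser with its training manifest."""

    def __init__(self, in_channels, seed=0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.seed = seed
        self.conv1 = nn.Conv2d(rng, in_channels, 64, 3, dtype=dtype)
        self.conv2 = nn.Conv2d(rng, 64, N_CLASSES, 1, dtype=dtype,
                               init_scale=0.1)
        # the second layer is ReLU-then-softmax: a class channel whose
        # pre-activation starts all-negative would be permanently dead,
        # so its bias starts slightly positive
        self.conv2.b.value[:] = 0.1
        # final ReLU precedes the softmax: pixels where every class
        # pre-activation is negative would otherwise receive no gradient
        # at all and freeze at uniform probabilities, so its backward
        # pass leaks
        self.r1, self.r2 = nn.ReLU(), nn.ReLU(leak_grad=0.1)
        self.loss_curve = []
        self.trained = False
        self._gate = None

    @property
    def layers(self):
        return [self.conv1, self.conv2]

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def forward_logits(self, blocks, center_masks):
        """Pre-softmax class maps; layer-1 activations gated by the mask."""
        x = np.asarray(blocks, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.in_channels:
            raise GeometryError(
                f"block has {x.shape[1]} channels, weights expect "
                f"{self.in_channels}")
        gate = np.asarray(center_masks, dtype=np.float32)
        if gate.ndim == 2:
            gate = gate[None]
        a1 = self.r1.forward(self.conv1.forward(x))
        self._gate = gate[:, None]
        a1 = a1 * self._gate
        return self.r2.forward(self.conv2.forward(a1))

    def backward(self, dlogits):
        d = self.conv2.backward(self.r2.backward(dlogits))
        d = d * self._gate
        d = self.conv1.backward(self.r1.backward(d))
        self._gate = None
        return d

    def save(self, path):
        np.savez(path, in_channels=self.in_channels, seed=self.seed,
                 loss_curve=np.asarray(self.loss_curve),
                 **nn.state_arrays(self.layers))

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            net = cls(int(z["in_channels"]), int(z["seed"]))
            nn.load_state_arrays(net.layers,
                                 {k: z[k] for k in z.files
                                  if k.startswith("p")})
            net.loss_curve = list(z["loss_curve"])
            net.trained = True
            return net


def ensemble_forward(net, block, center_mask=None):
    """Probability maps of one input block.

    Returns (3, H, W) class probabilities summing to 1 per pixel.  When
    ``center_mask`` is omitted it is taken from the block's center mask
    channel.
    """
    block = np.asarray(block, dtype=np.float32)
    if center_mask is None:
        b = block.shape[0] // CHANNELS_PER_SLICE
        center_mask = block[(b // 2) * CHANNELS_PER_SLICE + 4]
    logits = net.forward_logits(block[None], center_mask[None])
    return nn.softmax(logits.astype(np.float64), axis=1)[0]


def train_ensemble(blocks, center_masks, targets, config=None, seed=None):
    """Train the fuser on (N, C, H, W) blocks and 3-class pixel targets.

    Class-weighted cross-entropy over all pixels (class frequencies from
    the training stack, capped); Adam; minibatches of whole blocks.
    Reproducible from the seed.
    """
    config = config or EnsembleTrainConfig()
    if seed is not None:
        config = EnsembleTrainConfig(**{**config.__dict__, "seed": seed})
    x = np.asarray(blocks, dtype=np.float32)
    t = np.asarray(targets).astype(np.int64)
    m = np.asarray(center_masks, dtype=bool)
    if x.ndim != 4 or t.shape != x.shape[:1] + x.shape[2:]:
        raise TrainingError("blocks and targets are misaligned")
    counts = np.bincount(t.ravel(), minlength=N_CLASSES).astype(np.float64)
    if (counts > 0).sum() < 2:
        raise TrainingError("training targets hold a single class")
    cw = np.minimum(t.size / (N_CLASSES * np.maximum(counts, 1.0)),
                    config.weight_cap)
    net = EnsembleNet(x.shape[1], seed=config.seed)
    opt = nn.Adam(net.params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    for _ in range(config.steps):
        idx = rng.choice(n, size=min(config.batch, n), replace=False)
        logits = net.forward_logits(x[idx], m[idx])
        w = cw[t[idx]].astype(np.float32)
        loss, d = nn.image_xent(logits, t[idx], w)
        net.backward(d)
        opt.step()
        net.loss_curve.append(loss)
    net.trained = True
    return net


def predict_volume(net, feature_maps, masks, block_size):
    """Per-slice infarct probability maps L for a whole volume.

    Out-of-mask infarct probability is forced to 0.  Returns a
    (k, H, W) array; the full 3-class maps are available via
    :func:`ensemble_forward`.
    """
    f = np.asarray(feature_maps)
    m = np.asarray(masks, dtype=bool)
    k = f.shape[0]
    blocks = np.stack([build_input_block(f, m, c, block_size)
                       for c in range(k)])
    logits = net.forward_logits(blocks, m.astype(np.float32))
    probs = nn.softmax(logits.astype(np.float64), axis=1)
    L = probs[:, CLASS_INFARCT]
    return L * m
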