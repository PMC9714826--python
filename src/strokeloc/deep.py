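"""Pluggable slice-to-feature-map extractors (the F1-F3 pathway).

Each extractor is a miniature encoder-decoder for per-pixel infarct
classification: a three-level strided-convolution encoder, a dilated
middle block (dilations 2 and 4) that widens the receptive field without
losing coverage, and a bilinear-upsampling decoder with one skip
connection.  Three variants differing in width and seed provide the
feature diversity that the ensemble fuses; the extracted feature map is
the infarct-probability channel of the decoder output, masked to the
brain region.

Labels are used only as the training target, never as an inference
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import StateError, TrainingError

#: HU normalisation applied to the input channel (soft-tissue centred).
HU_CENTER, HU_SCALE = 35.0, 15.0


@dataclass
class FeatureExtractorSpec:
    """Architecture/seed configuration of one extractor variant."""

    name: str = "f1"
    width: int = 8
    dilations: tuple = (2, 4)
    output_channels: int = 1
    seed: int = 0


#: Three differently-sized/seeded variants emulating backbone diversity.
DEFAULT_EXTRACTOR_SPECS = (
    FeatureExtractorSpec("f1", width=6, seed=11),
    FeatureExtractorSpec("f2", width=8, seed=22),
    FeatureExtractorSpec("f3", width=10, seed=33),
)


@dataclass
class ExtractorTrainConfig:
    steps: int = 45
    batch: int = 6
    lr: float = 1e-3
    weight_cap: float = 50.0
    seed: int = 0            # minibatch-order seed


class MiniEncoderDecoder:
    """Encoder-decoder with dilated middle block; shape-preserving."""

    DOWN = 8   # total downsampling factor of the encoder

    def __init__(self, spec, in_ch=2, n_classes=2, dtype=np.float32):
        rng = np.random.default_rng(spec.seed)
        w = spec.width
        self.spec = spec
        self.enc1 = nn.Conv2d(rng, in_ch, w, 3, stride=2, dtype=dtype)
        self.enc2 = nn.Conv2d(rng, w, 2 * w, 3, stride=2, dtype=dtype)
        self.enc3 = nn.Conv2d(rng, 2 * w, 4 * w, 3, stride=2, dtype=dtype)
        self.dil = [nn.Conv2d(rng, 4 * w, 4 * w, 3, dilation=d, dtype=dtype)
                    for d in spec.dilations]
        self.dec1 = nn.Conv2d(rng, 5 * w, 2 * w, 3, dtype=dtype)
        self.dec2 = nn.Conv2d(rng, 2 * w, n_classes, 3, dtype=dtype,
                              init_scale=0.01)
        self.relus = [nn.ReLU() for _ in range(4 + len(self.dil))]
        self._ups = {}
        self._cache = None

    @property
    def layers(self):
        return [self.enc1, self.enc2, self.enc3, *self.dil, self.dec1,
                self.dec2]

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def _up(self, hw_in, hw_out, dtype):
        key = (hw_in, hw_out)
        if key not in self._ups:
            self._ups[key] = nn.BilinearUpsample(hw_in, hw_out, dtype)
        return self._ups[key]

    def forward(self, x):
        B, C, H, W = x.shape
        ph = (-H) % self.DOWN
        pw = (-W) % self.DOWN
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        r = self.relus
        e1 = r[0].forward(self.enc1.forward(xp))
        e2 = r[1].forward(self.enc2.forward(e1))
        h = r[2].forward(self.enc3.forward(e2))
        for i, conv in enumerate(self.dil):
            h = r[3 + i].forward(conv.forward(h))
        up1 = self._up(h.shape[2:], e1.shape[2:], h.dtype)
        hu = up1.forward(h)
        cat = np.concatenate([hu, e1], axis=1)
        d1 = r[-1].forward(self.dec1.forward(cat))
        up2 = self._up(d1.shape[2:], xp.shape[2:], d1.dtype)
        logits = self.dec2.forward(up2.forward(d1))
        self._cache = (up1, up2, hu.shape[1], (H, W), (ph, pw))
        return logits[:, :, :H, :W]

    def backward(self, dlogits):
        up1, up2, c_deep, (H, W), (ph, pw) = self._cache
        d = np.pad(dlogits, ((0, 0), (0, 0), (0, ph), (0, pw)))
        d = up2.backward(self.dec2.backward(d))
        d = self.dec1.backward(self.relus[-1].backward(d))
        dh, de1 = d[:, :c_deep], d[:, c_deep:]
        d = up1.backward(dh)
        for i in range(len(self.dil) - 1, -1, -1):
            d = self.dil[i].backward(self.relus[3 + i].backward(d))
        d = self.enc3.backward(self.relus[2].backward(d))
        d = self.enc2.backward(self.relus[1].backward(d))
        d += de1
        d = self.enc1.backward(self.relus[0].backward(d))
        self._cache = None
        return d[:, :, :d.shape[2] - ph if ph else None,
                 :d.shape[3] - pw if pw else None]


class ExtractorModel:
    """A trained extractor plus its training manifest."""

    def __init__(self, net, loss_curve=None, trained=False):
        self.net = net
        self.loss_curve = loss_curve or []
        self.trained = trained

    @property
    def spec(self):
        return self.net.spec

    def predict_volume(self, slices_hu, masks):
        """Infarct-probability feature maps for a (k, H, W) stack."""
        if not self.trained:
            raise StateError("extractor has not been trained")
        x = _prep_input(slices_hu, masks)
        logits = self.net.forward(x)
        probs = nn.softmax(logits.astype(np.float64), axis=1)[:, 1]
        return probs * np.asarray(masks, dtype=bool)

    def save(self, path):
        arrays = nn.state_arrays(self.net.layers)
        s = self.net.spec
        np.savez(path, name=s.name, width=s.width,
                 dilations=np.asarray(s.dilations), seed=s.seed,
                 loss_curve=np.asarray(self.loss_curve), **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            spec = FeatureExtractorSpec(
                name=str(z["name"]), width=int(z["width"]),
                dilations=tuple(int(d) for d in z["dilations"]),
                seed=int(z["seed"]))
            net = MiniEncoderDecoder(spec)
            nn.load_state_arrays(net.layers,
                                 {k: z[k] for k in z.files
                                  if k.startswith("p")})
            return cls(net, list(z["loss_curve"]), trained=True)


def _prep_input(slices_hu, masks):
    hu = np.asarray(slices_hu, dtype=np.float32)
    m = np.asarray(masks, dtype=bool)
    if hu.ndim == 2:
        hu, m = hu[None], m[None]
    x = np.empty((hu.shape[0], 2) + hu.shape[1:], np.float32)
    x[:, 0] = np.where(m, (hu - HU_CENTER) / HU_SCALE, 0.0)
    x[:, 1] = m
    return x


def train_extractor(spec, slices_hu, targets, masks, config=None):
    """Train one extractor for per-pixel infarct classification.

    ``targets`` holds binary infarct labels aligned to the slices; the
    loss is class-weighted cross-entropy restricted to in-mask pixels.
    Minibatch order derives from ``config.seed``, weights from
    ``spec.seed``; the result is bit-reproducible.
    """
    config = config or ExtractorTrainConfig()
    hu = np.asarray(slices_hu, dtype=np.float32)
    t = np.asarray(targets).astype(np.int64)
    m = np.asarray(masks, dtype=bool)
    if hu.shape != t.shape or hu.shape != m.shape or hu.ndim != 3:
        raise TrainingError("slices, targets and masks must share one "
                            "(k, H, W) shape")
    pos = int((t[m] == 1).sum())
    neg = int(m.sum()) - pos
    if pos == 0 or neg == 0:
        raise TrainingError("training data holds a single class")
    x = _prep_input(hu, m)
    total = pos + neg
    cw = np.minimum(np.array([total / (2.0 * neg), total / (2.0 * pos)]),
                    config.weight_cap)
    wmap = np.where(m, cw[t], 0.0).astype(np.float32)

    net = MiniEncoderDecoder(spec)
    opt = nn.Adam(net.params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    curve = []
    for _ in range(config.steps):
        idx = rng.choice(n, size=min(config.batch, n), replace=False)
        logits = net.forward(x[idx])
        loss, d = nn.image_xent(logits, t[idx], wmap[idx])
        net.backward(d)
        opt.step()
        curve.append(loss)
    return ExtractorModel(net, curve, trained=True)


def extract_feature_map(model, slice_hu, mask):
    """Feature map of one slice: infarct probability, 0 outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(np.asarray(slice_hu).shape)
    return model.predict_volume(np.asarray(slice_hu)[None],
                                mask[None])[0]
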