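"""Slow-fusion video regression network.

Parallel temporal pathways over a 20-frame clip fuse progressively with
depth: stage-1 convolutions see 8-frame windows (stride 4 -> 4 pathways),
stage-2 convolutions fuse adjacent pathways (12-frame receptive field,
3 pathways), stage 3 fuses everything (full 20 frames), followed by a
fully connected layer (FC4), dropout, and a single-unit regression head.
Pathways within a stage share one filter bank by default, so a "unit" is
one filter whose per-stimulus response concatenates its activation maps
across pathways.

Implemented directly on NumPy (see ``_nn``) with SGD + momentum + L2.
The estimator surface (`SlowFusionRegressor`) is scikit-learn compatible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _nn

__all__ = [
    "SlowFusionConfig",
    "TrainingHistory",
    "UnitRegistry",
    "SlowFusionNet",
    "SlowFusionRegressor",
    "build_network",
    "temporal_receptive_field",
    "train",
    "predict",
    "collect_activations",
    "lesion_units",
    "fit_linear_decoder",
    "LinearDecoder",
    "retrain_head",
    "retrain_scene_head",
    "grayscale",
]

RELU_LAYERS = ("relu1", "relu2", "relu3", "relu4")


@dataclass(frozen=True)
class SlowFusionConfig:
    """Architecture and optimizer settings.

    Defaults are the full-scale reference settings (channel counts
    256/64/100, 4096-unit FC4, lr 1.110510e-5, momentum 0.43325, L2 4e-9,
    dropout 0.5, 30 epochs).  Kernel sizes and spatial strides were tuned
    by Bayesian optimization at full scale and are not part of the
    reference configuration; the
    defaults here keep the FC4 input modest and are fully configurable.
    """

    frames: int = 20
    height: int = 64
    width: int = 64
    channels: int = 3
    t_extent1: int = 8
    t_stride: int = 4
    t_extent2: int = 12
    channels1: int = 256
    channels2: int = 64
    channels3: int = 100
    kernel1: int = 5
    kernel2: int = 3
    kernel3: int = 3
    stride1: int = 2
    stride2: int = 1
    stride3: int = 1
    pool1: int = 2
    pool2: int = 2
    pool3: int = 2
    fc4: int = 4096
    dropout: float = 0.5
    lr: float = 1.110510e-5
    momentum: float = 0.43325
    l2: float = 4e-9
    epochs: int = 30
    batch_size: int = 32
    max_grad_norm: float | None = None
    shared_pathway_filters: bool = True

    @property
    def n_pathways1(self) -> int:
        return (self.frames - self.t_extent1) // self.t_stride + 1

    @property
    def n_fuse2(self) -> int:
        return (self.t_extent2 - self.t_extent1) // self.t_stride + 1

    @property
    def n_pathways2(self) -> int:
        return self.n_pathways1 - self.n_fuse2 + 1

    def validate(self) -> None:
        if (self.frames - self.t_extent1) % self.t_stride != 0:
            raise ValueError("stage-1 windows at the given stride do not tile the clip")
        if (self.t_extent2 - self.t_extent1) % self.t_stride != 0:
            raise ValueError("stage-2 extent is not reachable by fusing stage-1 pathways")
        rf2 = (self.n_fuse2 - 1) * self.t_stride + self.t_extent1
        if rf2 != self.t_extent2:
            raise ValueError("inconsistent temporal geometry for stage 2")
        if temporal_receptive_field(self, 3) != self.frames:
            raise ValueError("stage-3 pathways do not cover the full clip")
        for f in ("channels1", "channels2", "channels3", "fc4"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


def temporal_receptive_field(config: SlowFusionConfig, stage: int) -> int:
    """Number of input frames influencing one unit of the given stage."""
    if stage == 1:
        return config.t_extent1
    if stage == 2:
        return (config.n_fuse2 - 1) * config.t_stride + config.t_extent1
    if stage in (3, 4):
        return (config.n_pathways1 - 1) * config.t_stride + config.t_extent1
    raise ValueError(f"unknown stage {stage}; expected 1..4")


@dataclass
class TrainingHistory:
    """Per-epoch errors (RMSE, rating-scale units)."""

    train_physical: list = field(default_factory=list)     # running mean, last 10 batches
    val_physical: list = field(default_factory=list)
    val_perceived: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_physical)


class UnitRegistry:
    """Maps global unit ids to (layer, channel) for the conv stages and FC4."""

    def __init__(self, config: SlowFusionConfig) -> None:
        self.layer_sizes = {
            "relu1": config.channels1,
            "relu2": config.channels2,
            "relu3": config.channels3,
            "relu4": config.fc4,
        }
        self._offsets = {}
        off = 0
        for layer in RELU_LAYERS:
            self._offsets[layer] = off
            off += self.layer_sizes[layer]
        self.n_total = off
        self.n_conv = sum(self.layer_sizes[l] for l in RELU_LAYERS[:3])

    def unit_ids(self, layer: str) -> np.ndarray:
        off = self._offsets[layer]
        return np.arange(off, off + self.layer_sizes[layer])

    def conv_unit_ids(self) -> np.ndarray:
        return np.arange(self.n_conv)

    def locate(self, unit_id: int) -> tuple[str, int]:
        if not 0 <= unit_id < self.n_total:
            raise KeyError(f"unit id {unit_id} not in registry (0..{self.n_total - 1})")
        for layer in RELU_LAYERS:
            off = self._offsets[layer]
            if unit_id < off + self.layer_sizes[layer]:
                return layer, unit_id - off
        raise KeyError(unit_id)  # pragma: no cover


def _clip_to_pathways(x: np.ndarray, config: SlowFusionConfig) -> list[np.ndarray]:
    """(n, frames, h, w, c) -> list of (n, t_extent1*c, h, w) pathway inputs."""
    paths = []
    for i in range(config.n_pathways1):
        t0 = i * config.t_stride
        win = x[:, t0:t0 + config.t_extent1]                      # (n, T, h, w, c)
        n, T, h, w, c = win.shape
        paths.append(np.ascontiguousarray(
            win.transpose(0, 1, 4, 2, 3).reshape(n, T * c, h, w)))
    return paths


class SlowFusionNet:
    """The network itself: forward, backward, activation capture, lesions."""

    def __init__(self, config: SlowFusionConfig, seed: int = 0) -> None:
        config.validate()
        self.config = config
        self.seed = seed
        self.registry = UnitRegistry(config)
        rng = np.random.default_rng(seed)
        c = config
        in1 = c.t_extent1 * c.channels
        n_banks1 = 1 if c.shared_pathway_filters else c.n_pathways1
        n_banks2 = 1 if c.shared_pathway_filters else c.n_pathways2
        self.conv1 = [_nn.Conv2d(in1, c.channels1, c.kernel1, c.stride1, rng)
                      for _ in range(n_banks1)]
        self.conv2 = [_nn.Conv2d(c.n_fuse2 * c.channels1, c.channels2, c.kernel2,
                                 c.stride2, rng) for _ in range(n_banks2)]
        self.conv3 = [_nn.Conv2d(c.n_pathways2 * c.channels2, c.channels3, c.kernel3,
                                 c.stride3, rng)]
        # derive spatial geometry
        h = w = c.height
        h, w = self.conv1[0].out_size(h, w)
        h, w = h // c.pool1, w // c.pool1
        h, w = self.conv2[0].out_size(h, w)
        h, w = max(h // c.pool2, 1), max(w // c.pool2, 1)
        h, w = self.conv3[0].out_size(h, w)
        h, w = max(h // c.pool3, 1), max(w // c.pool3, 1)
        self.flat_dim = c.channels3 * h * w
        self.fc4 = _nn.Dense(self.flat_dim, c.fc4, rng)
        self.out = _nn.Dense(c.fc4, 1, rng)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        # lesion masks: 1 = intact, 0 = clamped to zero after the ReLU
        self.masks = {layer: np.ones(self.registry.layer_sizes[layer], dtype=np.float32)
                      for layer in RELU_LAYERS}
        # affine output calibration (set by train(): targets are standardized
        # internally for SGD conditioning; predictions map back to 1..16)
        self.out_mu = 0.0
        self.out_sd = 1.0

    # -- bookkeeping ---------------------------------------------------

    def layers(self):
        return [*self.conv1, *self.conv2, *self.conv3, self.fc4, self.out]

    def lesioned(self, unit_ids) -> "SlowFusionNet":
        """A new handle sharing weights, with the listed units clamped to zero."""
        other = copy.copy(self)
        other.masks = {k: v.copy() for k, v in self.masks.items()}
        for uid in np.atleast_1d(np.asarray(unit_ids, dtype=int)):
            layer, ch = self.registry.locate(int(uid))
            other.masks[layer][ch] = 0.0
        return other

    # -- forward / backward -------------------------------------------

    def _bank(self, banks, i):
        return banks[0] if len(banks) == 1 else banks[i]

    def forward(self, x: np.ndarray, train: bool = False,
                capture: tuple[str, ...] = ()):
        """x: (n, frames, h, w, c) in [0,1].  Returns (pred, acts, cache)."""
        c = self.config
        if x.shape[1:] != (c.frames, c.height, c.width, c.channels):
            raise ValueError(f"clip batch has shape {x.shape[1:]}, expected "
                             f"{(c.frames, c.height, c.width, c.channels)}")
        x = x.astype(np.float32, copy=False)
        acts: dict[str, np.ndarray] = {}
        cache: dict = {"paths": []}
        paths = _clip_to_pathways(x, c)

        def stage(conv_banks, inputs, mask, pool_k, tag):
            outs, st_cache = [], []
            relus = []
            for i, xi in enumerate(inputs):
                conv = self._bank(conv_banks, i)
                y, cc = conv.forward(xi)
                r, rm = _nn.relu_forward(y)
                r = r * mask[None, :, None, None]
                p, pc = _nn.maxpool_forward(r, pool_k)
                outs.append(p)
                st_cache.append((conv, cc, rm, pc, xi.shape))
                relus.append(r)
            if tag in capture:
                acts[tag] = np.stack(relus, axis=2)   # (n, C, n_path, h, w)
            return outs, st_cache

        p1, cache["s1"] = stage(self.conv1, paths, self.masks["relu1"], c.pool1, "relu1")
        in2 = [np.concatenate(p1[i:i + c.n_fuse2], axis=1) for i in range(c.n_pathways2)]
        p2, cache["s2"] = stage(self.conv2, in2, self.masks["relu2"], c.pool2, "relu2")
        in3 = [np.concatenate(p2, axis=1)]
        p3, cache["s3"] = stage(self.conv3, in3, self.masks["relu3"], c.pool3, "relu3")
        n = x.shape[0]
        flat = p3[0].reshape(n, -1)
        cache["flat_shape"] = p3[0].shape
        h4, cache["fc4"] = self.fc4.forward(flat)
        r4, cache["rm4"] = _nn.relu_forward(h4)
        r4 = r4 * self.masks["relu4"][None, :]
        if "relu4" in capture:
            acts["relu4"] = r4
        d4, cache["do4"] = _nn.dropout_forward(r4, c.dropout, self._dropout_rng, train)
        pred, cache["out"] = self.out.forward(d4)
        return pred[:, 0], acts, cache

    def backward(self, gpred: np.ndarray, cache: dict,
                 need_input_grad: bool = False) -> np.ndarray | None:
        """gpred: (n,) gradient at the output; returns the gradient with
        respect to the input clip when ``need_input_grad`` (used by
        activation maximization), else None."""
        c = self.config
        g = self.out.backward(gpred[:, None], cache["out"])
        g = _nn.dropout_backward(g, cache["do4"])
        g = g * self.masks["relu4"][None, :]
        g = _nn.relu_backward(g, cache["rm4"])
        g = self.fc4.backward(g, cache["fc4"])
        g = g.reshape(cache["flat_shape"])

        def stage_back(st_cache, gouts, mask, need_dx=True):
            gins = []
            for (conv, cc, rm, pc, xshape), go in zip(st_cache, gouts):
                gr = _nn.maxpool_backward(go, pc)
                gr = gr * mask[None, :, None, None]
                gr = _nn.relu_backward(gr, rm)
                gins.append(conv.backward(gr, cc, need_dx=need_dx))
            return gins

        g3 = stage_back(cache["s3"], [g], self.masks["relu3"])
        # split stage-3 input gradient back into stage-2 pathway outputs
        g2outs = np.split(g3[0], c.n_pathways2, axis=1)
        g2 = stage_back(cache["s2"], g2outs, self.masks["relu2"])
        # accumulate overlapping stage-2 windows onto stage-1 pathway outputs
        g1outs = None
        for i, gi in enumerate(g2):
            parts = np.split(gi, c.n_fuse2, axis=1)
            if g1outs is None:
                g1outs = [np.zeros_like(parts[0]) for _ in range(c.n_pathways1)]
            for j, pj in enumerate(parts):
                g1outs[i + j] += pj
        g1 = stage_back(cache["s1"], g1outs, self.masks["relu1"],
                        need_dx=need_input_grad)
        if not need_input_grad:
            return None
        # fold pathway input gradients back onto the clip
        gx = np.zeros((g.shape[0], c.frames, c.height, c.width, c.channels),
                      dtype=np.float32)
        for i, gpi in enumerate(g1):
            n, fc_, h, w = gpi.shape
            gwin = gpi.reshape(n, c.t_extent1, c.channels, h, w).transpose(0, 1, 3, 4, 2)
            t0 = i * c.t_stride
            gx[:, t0:t0 + c.t_extent1] += gwin
        return gx

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        preds = []
        for i in range(0, len(x), batch_size):
            p, _, _ = self.forward(x[i:i + batch_size], train=False)
            preds.append(p)
        raw = np.concatenate(preds) if preds else np.empty(0)
        return raw * self.out_sd + self.out_mu


def grayscale(clips: np.ndarray) -> np.ndarray:
    """Replace channels by Rec. 709 luminance replicated x3."""
    lum = clips @ np.array([0.2126, 0.7152, 0.0722], dtype=clips.dtype)
    return np.repeat(lum[..., None], 3, axis=-1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_network(config: SlowFusionConfig | None = None, seed: int = 0) -> SlowFusionNet:
    return SlowFusionNet(config or SlowFusionConfig(), seed)


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def train(net: SlowFusionNet, clips: np.ndarray, labels: np.ndarray,
          val_clips: np.ndarray | None = None,
          val_physical: np.ndarray | None = None,
          val_perceived: np.ndarray | None = None,
          epochs: int | None = None, seed: int = 0,
          lr: float | None = None) -> TrainingHistory:
    """SGD training on physical labels (1..16 linear scale), in place."""
    labels = np.asarray(labels, dtype=np.float32)
    if len(clips) == 0:
        raise ValueError("empty training set")
    if labels.min() < 1 or labels.max() > 16:
        raise ValueError("labels must lie on the 1..16 linear scale")
    c = net.config
    epochs = c.epochs if epochs is None else epochs
    opt = _nn.SGDMomentum(net.layers(), lr if lr is not None else c.lr,
                          c.momentum, c.l2, max_grad_norm=c.max_grad_norm)
    rng = np.random.default_rng(seed)
    hist = TrainingHistory()
    n = len(clips)
    net.out_mu = float(labels.mean())
    net.out_sd = float(labels.std()) or 1.0
    z = (labels - net.out_mu) / net.out_sd
    for _epoch in range(epochs):
        order = rng.permutation(n)
        batch_rmses = []
        for i in range(0, n, c.batch_size):
            idx = order[i:i + c.batch_size]
            xb, yb = clips[idx], z[idx]
            opt.zero_grad()
            pred, _, cache = net.forward(xb, train=True)
            err = pred - yb
            net.backward(err.astype(np.float32) / len(idx), cache)
            opt.step()
            batch_rmses.append(float(np.sqrt(np.mean(err ** 2))) * net.out_sd)
        hist.train_physical.append(float(np.mean(batch_rmses[-10:])))
        if val_clips is not None and len(val_clips):
            vp = net.predict(val_clips)
            hist.val_physical.append(
                _rmse(vp, val_physical) if val_physical is not None else np.nan)
            hist.val_perceived.append(
                _rmse(vp, val_perceived) if val_perceived is not None else np.nan)
    return hist


def predict(net: SlowFusionNet, clips: np.ndarray,
            input_transform: str | None = None) -> np.ndarray:
    if input_transform not in (None, "none", "grayscale"):
        raise ValueError(f"unknown input transform {input_transform!r}")
    if input_transform == "grayscale":
        clips = grayscale(clips)
    return net.predict(clips)


def collect_activations(net: SlowFusionNet, clips: np.ndarray, layer: str,
                        batch_size: int = 64) -> "ActivationRecord":
    """Per-unit responses at a ReLU layer.

    Conv units: the flattened activation map of one filter concatenated
    across parallel pathways, shape (n_stimuli, n_units, map_size).
    FC4 units: scalars, shape (n_stimuli, n_units, 1).
    """
    if layer not in RELU_LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {RELU_LAYERS}")
    chunks = []
    for i in range(0, len(clips), batch_size):
        _, acts, _ = net.forward(clips[i:i + batch_size], capture=(layer,))
        a = acts[layer]
        if a.ndim == 5:                       # (n, C, n_path, h, w)
            n, C = a.shape[:2]
            chunks.append(a.reshape(n, C, -1))
        else:                                 # (n, fc4)
            chunks.append(a[:, :, None])
    resp = np.concatenate(chunks, axis=0)
    return ActivationRecord(layer=layer, responses=resp,
                            unit_ids=net.registry.unit_ids(layer))


@dataclass
class ActivationRecord:
    layer: str
    responses: np.ndarray          # (n_stimuli, n_units, map_size)
    unit_ids: np.ndarray

    @property
    def n_units(self) -> int:
        return self.responses.shape[1]

    def dead_units(self) -> np.ndarray:
        """Units with all-zero response over the probe set (registry ids)."""
        dead = ~np.any(self.responses != 0, axis=(0, 2))
        return self.unit_ids[dead]

    def pooled(self, how: str = "sum") -> np.ndarray:
        """Scalar response per stimulus per unit."""
        if how == "sum":
            return self.responses.sum(axis=2)
        if how == "mean":
            return self.responses.mean(axis=2)
        if how == "max":
            return self.responses.max(axis=2)
        raise ValueError(f"unknown pooling {how!r}")

    def layer_matrix(self) -> np.ndarray:
        """(n_stimuli, n_units*map_size) concatenation for layer-level RSA."""
        return self.responses.reshape(self.responses.shape[0], -1)


def lesion_units(net: SlowFusionNet, unit_ids) -> SlowFusionNet:
    """Non-destructive lesion: returns a new handle with units clamped to 0."""
    return net.lesioned(unit_ids)


# ---------------------------------------------------------------------------
# linear decoders and head retraining
# ---------------------------------------------------------------------------

class LinearDecoder(BaseEstimator, RegressorMixin):
    """Single linear readout trained by full-batch gradient descent.

    Features are standardized internally; the step size is set from the
    largest eigenvalue of the feature Gram matrix, so the realizable case
    converges to machine-level RMSE within the epoch budget.
    """

    def __init__(self, epochs: int = 800):
        self.epochs = epochs

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.degenerate_ = bool(np.all(sd == 0))
        if self.degenerate_:
            import warnings
            warnings.warn("zero-variance activations; decoder fits intercept only")
        self.scale_ = np.where(sd == 0, 1.0, sd)
        Z = (X - self.mean_) / self.scale_
        n, d = Z.shape
        w = np.zeros(d)
        b = float(y.mean())
        # Lipschitz constant of the least-squares gradient
        L = (np.linalg.norm(Z, 2) ** 2) / n + 1e-12
        step = 1.0 / L
        for _ in range(self.epochs):
            r = Z @ w + b - y
            w -= step * (Z.T @ r) / n
            b -= step * r.mean()
        self.coef_ = w
        self.intercept_ = b
        return self

    def predict(self, X):
        Z = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_


def fit_linear_decoder(activations: np.ndarray, targets: np.ndarray,
                       epochs: int = 800, test_fraction: float = 0.2,
                       seed: int = 0) -> tuple[LinearDecoder, float]:
    """Fit a linear readout on a train split; report held-out RMSE."""
    X = np.asarray(activations, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n = len(X)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test, tr = order[:n_test], order[n_test:]
    dec = LinearDecoder(epochs=epochs).fit(X[tr], y[tr])
    return dec, _rmse(dec.predict(X[test]), y[test])


class _Head:
    """FC4-and-later replacement head operating on cached prefix features.

    Inputs and (regression) targets are standardized internally for SGD
    conditioning; ``forward`` consumes standardized features."""

    def __init__(self, in_dim: int, width: int, out_dim: int, dropout: float,
                 rng: np.random.Generator):
        self.fc = _nn.Dense(in_dim, width, rng)
        self.out = _nn.Dense(width, out_dim, rng)
        self.dropout = dropout
        self.rng = rng
        self.x_mu = np.zeros(in_dim, dtype=np.float32)
        self.x_sd = np.ones(in_dim, dtype=np.float32)
        self.y_mu = 0.0
        self.y_sd = 1.0

    def standardize(self, x):
        return ((x - self.x_mu) / self.x_sd).astype(np.float32)

    def set_input_stats(self, X):
        self.x_mu = X.mean(axis=0).astype(np.float32)
        sd = X.std(axis=0)
        self.x_sd = np.where(sd == 0, 1.0, sd).astype(np.float32)

    def forward(self, x, train=False):
        h, c1 = self.fc.forward(x)
        r, rm = _nn.relu_forward(h)
        d, dm = _nn.dropout_forward(r, self.dropout, self.rng, train)
        y, c2 = self.out.forward(d)
        return y, (c1, rm, dm, c2)

    def backward(self, gy, cache):
        c1, rm, dm, c2 = cache
        g = self.out.backward(gy, c2)
        g = _nn.dropout_backward(g, dm)
        g = _nn.relu_backward(g, rm)
        self.fc.backward(g, c1)

    def layers(self):
        return [self.fc, self.out]


def prefix_features(net: SlowFusionNet, clips: np.ndarray,
                    batch_size: int = 64) -> np.ndarray:
    """Activations entering FC4 (output of the frozen convolutional prefix)."""
    feats = []
    c = net.config
    for i in range(0, len(clips), batch_size):
        x = clips[i:i + batch_size].astype(np.float32, copy=False)
        paths = _clip_to_pathways(x, c)
        p1 = []
        for j, xi in enumerate(paths):
            y, _ = net._bank(net.conv1, j).forward(xi)
            r, _ = _nn.relu_forward(y)
            r = r * net.masks["relu1"][None, :, None, None]
            p, _ = _nn.maxpool_forward(r, c.pool1)
            p1.append(p)
        p2 = []
        for j in range(c.n_pathways2):
            xi = np.concatenate(p1[j:j + c.n_fuse2], axis=1)
            y, _ = net._bank(net.conv2, j).forward(xi)
            r, _ = _nn.relu_forward(y)
            r = r * net.masks["relu2"][None, :, None, None]
            p, _ = _nn.maxpool_forward(r, c.pool2)
            p2.append(p)
        xi = np.concatenate(p2, axis=1)
        y, _ = net.conv3[0].forward(xi)
        r, _ = _nn.relu_forward(y)
        r = r * net.masks["relu3"][None, :, None, None]
        p, _ = _nn.maxpool_forward(r, c.pool3)
        feats.append(p.reshape(len(x), -1))
    return np.concatenate(feats, axis=0)


def _train_head(head: _Head, X, y, X_val, epochs, lr, momentum, l2, batch_size,
                rng, classify=False):
    head.set_input_stats(X)
    X = head.standardize(X)
    X_val = head.standardize(X_val)
    if not classify:
        head.y_mu = float(np.mean(y))
        head.y_sd = float(np.std(y)) or 1.0
        y = ((y - head.y_mu) / head.y_sd).astype(np.float32)
    opt = _nn.SGDMomentum(head.layers(), lr, momentum, l2)
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            opt.zero_grad()
            out, cache = head.forward(X[idx], train=True)
            if classify:
                z = out - out.max(axis=1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(axis=1, keepdims=True)
                g = p.copy()
                g[np.arange(len(idx)), y[idx]] -= 1.0
                g /= len(idx)
            else:
                g = (out[:, 0] - y[idx])[:, None] / len(idx)
            head.backward(g.astype(np.float32), cache)
            opt.step()
    out, _ = head.forward(X_val, train=False)
    if not classify:
        out = out * head.y_sd + head.y_mu
    return out


def retrain_head(net: SlowFusionNet, width: int, clips: np.ndarray,
                 labels: np.ndarray, val_clips: np.ndarray,
                 val_targets: np.ndarray, repeats: int = 10, epochs: int = 10,
                 lr: float = 1e-2, seed: int = 0,
                 features: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> tuple["RetrainedHead", list[float]]:
    """Retrain FC4 (new width) + output with the convolutional prefix frozen.

    Best of ``repeats`` runs by validation RMSE against ``val_targets``
    (perceived labels by convention).  Precomputed prefix features for
    (train, val) can be passed to avoid repeated forward passes.
    """
    if width < 1:
        raise ValueError("FC4 width must be >= 1")
    if features is None:
        Xtr, Xval = prefix_features(net, clips), prefix_features(net, val_clips)
    else:
        Xtr, Xval = features
    Xtr = Xtr.astype(np.float32)
    Xval = Xval.astype(np.float32)
    y = np.asarray(labels, dtype=np.float32)
    rmses, heads = [], []
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, width, r]))
        head = _Head(Xtr.shape[1], width, 1, net.config.dropout, rng)
        out = _train_head(head, Xtr, y, Xval, epochs, lr, net.config.momentum,
                          net.config.l2, net.config.batch_size, rng)
        rmses.append(_rmse(out[:, 0], val_targets))
        heads.append(head)
    best = int(np.argmin(rmses))
    return RetrainedHead(net=net, head=heads[best], width=width), rmses


@dataclass
class RetrainedHead:
    """A frozen convolutional prefix with a retrained FC4-and-later head."""

    net: SlowFusionNet
    head: _Head
    width: int

    def predict(self, clips: np.ndarray) -> np.ndarray:
        return self.predict_features(prefix_features(self.net, clips))

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.head.forward(self.head.standardize(X), train=False)
        return out[:, 0] * self.head.y_sd + self.head.y_mu

    def head_activations(self, clips: np.ndarray) -> np.ndarray:
        """Post-ReLU FC4 responses of the retrained head."""
        X = self.head.standardize(prefix_features(self.net, clips))
        h, _ = self.head.fc.forward(X)
        r, _ = _nn.relu_forward(h)
        return r


def retrain_scene_head(net: SlowFusionNet, clips: np.ndarray,
                       scene_labels: np.ndarray, val_clips: np.ndarray,
                       val_labels: np.ndarray, width: int | None = None,
                       epochs: int = 8, lr: float = 1e-2, seed: int = 0,
                       features: tuple[np.ndarray, np.ndarray] | None = None):
    """Transfer learning: retrain FC4-and-later with a softmax scene head.

    Returns (accuracy, mean one-vs-rest AUC, class-probability matrix,
    head).  The probability matrix row i is the mean predicted class
    distribution over validation stimuli whose true class is i.
    """
    from sklearn.metrics import roc_auc_score

    classes = np.unique(scene_labels)
    if len(classes) < 2:
        raise ValueError("scene classification needs at least two classes")
    cls_index = {c: i for i, c in enumerate(classes)}
    ytr = np.array([cls_index[c] for c in scene_labels])
    yval = np.array([cls_index[c] for c in val_labels])
    if features is None:
        Xtr, Xval = prefix_features(net, clips), prefix_features(net, val_clips)
    else:
        Xtr, Xval = features
    rng = np.random.default_rng(seed)
    head = _Head(Xtr.shape[1], width or net.config.fc4, len(classes),
                 net.config.dropout, rng)
    out = _train_head(head, Xtr.astype(np.float32), ytr, Xval.astype(np.float32),
                      epochs, lr, net.config.momentum, net.config.l2,
                      net.config.batch_size, rng, classify=True)
    z = out - out.max(axis=1, keepdims=True)
    proba = np.exp(z)
    proba /= proba.sum(axis=1, keepdims=True)
    acc = float(np.mean(proba.argmax(axis=1) == yval))
    if len(classes) == 2:
        auc = float(roc_auc_score(yval, proba[:, 1]))
    else:
        auc = float(roc_auc_score(yval, proba, multi_class="ovr", average="macro",
                                  labels=np.arange(len(classes))))
    pmat = np.vstack([proba[yval == i].mean(axis=0) if np.any(yval == i)
                      else np.full(len(classes), np.nan)
                      for i in range(len(classes))])
    return acc, auc, pmat, head


# ---------------------------------------------------------------------------
# sklearn estimator surface
# ---------------------------------------------------------------------------

class SlowFusionRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapping the slow-fusion network.

    Parameters mirror `SlowFusionConfig`; `fit(X, y)` takes clips of shape
    (n, 20, 64, 64, 3) and physical viscosity labels on the 1..16 scale.
    """

    def __init__(self, seed=0, frames=20, height=64, width=64, channels=3,
                 t_extent1=8, t_stride=4, t_extent2=12,
                 channels1=256, channels2=64, channels3=100,
                 kernel1=5, kernel2=3, kernel3=3,
                 stride1=2, stride2=1, stride3=1,
                 pool1=2, pool2=2, pool3=2,
                 fc4=4096, dropout=0.5, lr=1.110510e-5, momentum=0.43325,
                 l2=4e-9, epochs=30, batch_size=32, max_grad_norm=None,
                 shared_pathway_filters=True):
        args = dict(locals())
        args.pop("self")
        for name, value in args.items():
            setattr(self, name, value)

    def config(self) -> SlowFusionConfig:
        return SlowFusionConfig(**{f.name: getattr(self, f.name)
                                   for f in fields(SlowFusionConfig)})

    def fit(self, X, y, X_val=None, y_val_physical=None, y_val_perceived=None,
            epochs=None, train_seed=0, lr=None):
        self.net_ = build_network(self.config(), self.seed)
        self.history_ = train(self.net_, np.asarray(X), np.asarray(y),
                              X_val if X_val is None else np.asarray(X_val),
                              y_val_physical, y_val_perceived,
                              epochs=epochs, seed=train_seed, lr=lr)
        return self

    def predict(self, X, input_transform=None):
        return predict(self.net_, np.asarray(X), input_transform)
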