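"""Fully convolutional DenseNet with multi-scale stem and scSE recalibration.

The segmentation network is an encoder-decoder DenseNet: a stem
convolution (single 3x3, or three parallel 3x3/5x5/7x7 branches whose
outputs are channel-concatenated), five dense blocks with transition-down
blocks on the encoder, a bottleneck dense block, and a mirrored decoder of
transition-up blocks with skip concatenations, closed by a 1x1 convolution
and per-pixel softmax.  Inside a dense block each layer (batch norm ->
ELU -> 3x3 conv -> dropout) emits ``growth_rate`` feature maps that are
concatenated onto everything before them, so a block with L layers grows
the channel count by exactly L*k.

Squeeze-and-excitation recalibration (scSE) multiplies a feature map by a
spatial gate (1x1 convolution over channels + sigmoid) and by a channel
gate (global average pool -> bottleneck MLP + sigmoid) and sums the two
recalibrated maps.  With the default ``per_block`` placement one scSE
module follows each dense block: on the encoder it sees the block's full
concatenation, on the bottleneck and decoder it sees the newly created
feature maps (the only ones that propagate forward there).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .nn import (
    Adam,  # noqa: F401  (re-exported for convenience)
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Dropout,
    ELU,
    GlobalAvgPool,
    Layer,
    MaxPool2x2,
    ReLU,
    Sequential,
    Sigmoid,
    softmax,
)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class MultiScaleStem(Layer):
    """Parallel same-padding convolutions with different kernel sizes.

    The branch outputs are channel-concatenated in kernel order, so the
    output width is ``len(kernels) * filters_per_branch``.
    """

    def __init__(self, in_ch: int, kernels, filters_per_branch: int, rng):
        self.branches = [Conv2d(in_ch, filters_per_branch, k, rng) for k in kernels]
        self.filters = filters_per_branch

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train=False):
        return np.concatenate([b.forward(x, train) for b in self.branches], axis=1)

    def backward(self, dy):
        f = self.filters
        dx = None
        for i, b in enumerate(self.branches):
            d = b.backward(dy[:, i * f:(i + 1) * f])
            dx = d if dx is None else dx + d
        return dx


class DenseLayer(Layer):
    """Composite function H_l: batch norm -> ELU -> 3x3 conv -> dropout."""

    def __init__(self, in_ch: int, growth_rate: int, dropout: float, rng):
        self.in_ch = in_ch
        self.growth_rate = growth_rate
        self.net = Sequential(
            BatchNorm2d(in_ch),
            ELU(),
            Conv2d(in_ch, growth_rate, 3, rng),
            Dropout(dropout, rng),
        )

    def params(self):
        return self.net.params()

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def backward(self, dy):
        return self.net.backward(dy)


class SpatialSE(Layer):
    """Spatial squeeze: 1x1 conv across channels -> sigmoid gate per pixel."""

    def __init__(self, ch: int, rng):
        self.conv = Conv2d(ch, 1, 1, rng)
        self.gate = Sigmoid()

    def params(self):
        return self.conv.params()

    def forward(self, x, train=False):
        self._x = x
        self._g = self.gate.forward(self.conv.forward(x, train))
        return x * self._g

    def backward(self, dy):
        dgate = (dy * self._x).sum(axis=1, keepdims=True)
        dx_gate = self.conv.backward(self.gate.backward(dgate))
        return dy * self._g + dx_gate


class ChannelSE(Layer):
    """Channel squeeze: global average pool -> C -> C/r -> C MLP -> sigmoid."""

    def __init__(self, ch: int, reduction: int, rng):
        hidden = ch // reduction
        if hidden < 1:
            raise ValueError(f"channel count {ch} smaller than reduction {reduction}")
        self.pool = GlobalAvgPool()
        self.fc = Sequential(Dense(ch, hidden, rng), ReLU(), Dense(hidden, ch, rng))
        self.gate = Sigmoid()

    def params(self):
        return self.fc.params()

    def forward(self, x, train=False):
        self._x = x
        z = self.pool.forward(x, train)
        self._g = self.gate.forward(self.fc.forward(z, train))
        return x * self._g[:, :, None, None]

    def backward(self, dy):
        dgate = (dy * self._x).sum(axis=(2, 3))
        dz = self.fc.backward(self.gate.backward(dgate))
        return dy * self._g[:, :, None, None] + self.pool.backward(dz)


class ScSE(Layer):
    """Concurrent spatial and channel recalibration: U_sSE + U_cSE."""

    def __init__(self, ch: int, reduction: int, rng):
        self.sse = SpatialSE(ch, rng)
        self.cse = ChannelSE(ch, reduction, rng)

    def params(self):
        return self.sse.params() + self.cse.params()

    def forward(self, x, train=False):
        return self.sse.forward(x, train) + self.cse.forward(x, train)

    def backward(self, dy):
        return self.sse.backward(dy) + self.cse.backward(dy)


class DenseBlock(Layer):
    """Iteratively concatenating dense block; outputs the full concatenation.

    ``forward`` returns ``[input, y_1, ..., y_L]`` stacked on the channel
    axis; callers slice off the trailing ``L*k`` channels when only the new
    feature maps should propagate (bottleneck and decoder convention).
    Optional per-layer scSE modules recalibrate each layer's k new maps.
    """

    def __init__(self, in_ch: int, n_layers: int, growth_rate: int, dropout: float,
                 rng, scse_reduction: int | None = None):
        self.in_ch = in_ch
        self.n_layers = n_layers
        self.growth_rate = growth_rate
        self.layers = []
        self.layer_scse = []
        ch = in_ch
        for _ in range(n_layers):
            self.layers.append(DenseLayer(ch, growth_rate, dropout, rng))
            if scse_reduction is not None:
                self.layer_scse.append(ScSE(growth_rate, scse_reduction, rng))
            ch += growth_rate
        self.out_ch = ch

    def params(self):
        out = []
        for i, l in enumerate(self.layers):
            out.extend(l.params())
            if self.layer_scse:
                out.extend(self.layer_scse[i].params())
        return out

    def forward(self, x, train=False):
        feats = [x]
        for i, layer in enumerate(self.layers):
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            y = layer.forward(inp, train)
            if self.layer_scse:
                y = self.layer_scse[i].forward(y, train)
            feats.append(y)
        self._widths = [f.shape[1] for f in feats]
        return feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)

    def backward(self, dy):
        widths = self._widths
        offsets = np.cumsum([0] + widths)
        grads = [dy[:, offsets[i]:offsets[i + 1]].copy() for i in range(len(widths))]
        for i in range(self.n_layers - 1, -1, -1):
            g = grads[i + 1]
            if self.layer_scse:
                g = self.layer_scse[i].backward(g)
            dinp = self.layers[i].backward(g)
            # dinp covers concat(feats[0..i]); scatter back
            off = 0
            for j in range(i + 1):
                grads[j] += dinp[:, off:off + widths[j]]
                off += widths[j]
        return grads[0]


class TransitionDown(Layer):
    """BN -> ELU -> depth-preserving 1x1 conv -> dropout -> 2x2 max pool."""

    def __init__(self, ch: int, dropout: float, rng):
        self.net = Sequential(
            BatchNorm2d(ch),
            ELU(),
            Conv2d(ch, ch, 1, rng),
            Dropout(dropout, rng),
            MaxPool2x2(),
        )

    def params(self):
        return self.net.params()

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def backward(self, dy):
        return self.net.backward(dy)


class TransitionUp(Layer):
    """Stride-2 3x3 transposed convolution doubling the spatial size."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        if out_ch < 1:
            raise ValueError("out_channels must be >= 1")
        self.tconv = ConvTranspose2d(in_ch, out_ch, rng)

    def params(self):
        return self.tconv.params()

    def forward(self, x, train=False):
        return self.tconv.forward(x, train)

    def backward(self, dy):
        return self.tconv.backward(dy)


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class SegmentationNetwork(Layer):
    """Encoder-decoder DenseNet producing per-pixel class logits."""

    def __init__(self, config: NetworkConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        k = config.growth_rate
        rho = config.dropout
        per_layer = config.scse and config.scse_placement == "per_layer"
        layer_red = config.scse_reduction if per_layer else None

        if config.multiscale:
            self.stem = MultiScaleStem(config.in_channels, config.ms_kernels,
                                       config.branch_filters, rng)
            ch = config.branch_filters * len(config.ms_kernels)
        else:
            self.stem = Conv2d(config.in_channels, config.initial_channels, 3, rng)
            ch = config.initial_channels

        per_block = config.scse and config.scse_placement == "per_block"
        self.down_blocks: list[DenseBlock] = []
        self.down_scse: list[ScSE | None] = []
        self.transitions_down: list[TransitionDown] = []
        skip_channels = []
        for n_layers in config.down_blocks:
            block = DenseBlock(ch, n_layers, k, rho, rng, scse_reduction=layer_red)
            ch = block.out_ch
            self.down_blocks.append(block)
            self.down_scse.append(ScSE(ch, config.scse_reduction, rng) if per_block else None)
            skip_channels.append(ch)
            self.transitions_down.append(TransitionDown(ch, rho, rng))

        self.bottleneck = DenseBlock(ch, config.bottleneck_layers, k, rho, rng,
                                     scse_reduction=layer_red)
        new_ch = config.bottleneck_layers * k
        self.bottleneck_scse = ScSE(new_ch, config.scse_reduction, rng) if per_block else None

        self.transitions_up: list[TransitionUp] = []
        self.up_blocks: list[DenseBlock] = []
        self.up_scse: list[ScSE | None] = []
        for i, n_layers in enumerate(reversed(config.down_blocks)):
            self.transitions_up.append(TransitionUp(new_ch, new_ch, rng))
            in_ch = new_ch + skip_channels[-1 - i]
            block = DenseBlock(in_ch, n_layers, k, rho, rng, scse_reduction=layer_red)
            self.up_blocks.append(block)
            new_ch = n_layers * k
            self.up_scse.append(ScSE(new_ch, config.scse_reduction, rng) if per_block else None)
        self.head = Conv2d(self.up_blocks[-1].out_ch, config.num_classes, 1, rng)

    # -- parameters ------------------------------------------------------
    def params(self):
        out = list(self.stem.params())
        for i, b in enumerate(self.down_blocks):
            out.extend(b.params())
            if self.down_scse[i] is not None:
                out.extend(self.down_scse[i].params())
            out.extend(self.transitions_down[i].params())
        out.extend(self.bottleneck.params())
        if self.bottleneck_scse is not None:
            out.extend(self.bottleneck_scse.params())
        for i in range(len(self.up_blocks)):
            out.extend(self.transitions_up[i].params())
            out.extend(self.up_blocks[i].params())
            if self.up_scse[i] is not None:
                out.extend(self.up_scse[i].params())
        out.extend(self.head.params())
        return out

    # -- forward / backward ---------------------------------------------
    def _check_input(self, x):
        if x.ndim != 4:
            raise ValueError("expected input of shape (n, channels, height, width)")
        f = self.config.pool_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} not divisible by {f}; "
                "resize or pad the input")
        if x.shape[1] == 1 and self.config.in_channels > 1:
            x = np.repeat(x, self.config.in_channels, axis=1)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels")
        return np.ascontiguousarray(x, dtype=np.float32)

    def forward(self, x, train=False):
        """Return per-pixel class logits of shape (n, num_classes, h, w)."""
        x = self._check_input(x)
        self._replicated = x.shape[1] != 1
        y = self.stem.forward(x, train)
        skips = []
        for i, block in enumerate(self.down_blocks):
            y = block.forward(y, train)
            if self.down_scse[i] is not None:
                y = self.down_scse[i].forward(y, train)
            skips.append(y)
            y = self.transitions_down[i].forward(y, train)
        full = self.bottleneck.forward(y, train)
        new = full[:, -self.bottleneck.n_layers * self.config.growth_rate:]
        self._bott_in_ch = self.bottleneck.in_ch
        if self.bottleneck_scse is not None:
            new = self.bottleneck_scse.forward(new, train)
        self._up_in_ch = []
        for i in range(len(self.up_blocks)):
            up = self.transitions_up[i].forward(new, train)
            y = np.concatenate([up, skips[-1 - i]], axis=1)
            self._up_in_ch.append(up.shape[1])
            full = self.up_blocks[i].forward(y, train)
            if i < len(self.up_blocks) - 1:
                new = full[:, self.up_blocks[i].in_ch:]
                if self.up_scse[i] is not None:
                    new = self.up_scse[i].forward(new, train)
        if self.up_scse[-1] is not None:
            n_new = self.up_blocks[-1].n_layers * self.config.growth_rate
            head_in = np.concatenate(
                [full[:, :-n_new], self.up_scse[-1].forward(full[:, -n_new:], train)], axis=1)
        else:
            head_in = full
        return self.head.forward(head_in, train)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        n_new = self.up_blocks[-1].n_layers * self.config.growth_rate
        if self.up_scse[-1] is not None:
            dnew = self.up_scse[-1].backward(d[:, -n_new:])
            d = np.concatenate([d[:, :-n_new], dnew], axis=1)
        dskips = [None] * len(self.down_blocks)
        for i in range(len(self.up_blocks) - 1, -1, -1):
            dfull = d
            dinp = self.up_blocks[i].backward(dfull)
            up_ch = self._up_in_ch[i]
            dup, dskip = dinp[:, :up_ch], dinp[:, up_ch:]
            dskips[len(self.down_blocks) - 1 - i] = dskip  # skip used by up block i
            dnew = self.transitions_up[i].backward(dup)
            if i > 0:
                prev = i - 1
                if self.up_scse[prev] is not None:
                    dnew = self.up_scse[prev].backward(dnew)
                dfull_prev = np.zeros(
                    (dnew.shape[0], self.up_blocks[prev].out_ch) + dnew.shape[2:],
                    dtype=dnew.dtype)
                dfull_prev[:, self.up_blocks[prev].in_ch:] = dnew
                d = dfull_prev
            else:
                if self.bottleneck_scse is not None:
                    dnew = self.bottleneck_scse.backward(dnew)
                dfull_b = np.zeros(
                    (dnew.shape[0], self.bottleneck.out_ch) + dnew.shape[2:], dtype=dnew.dtype)
                dfull_b[:, self._bott_in_ch:] = dnew
                d = self.bottleneck.backward(dfull_b)
        for i in range(len(self.down_blocks) - 1, -1, -1):
            d = self.transitions_down[i].backward(d)
            d = d + dskips[i]
            if self.down_scse[i] is not None:
                d = self.down_scse[i].backward(d)
            d = self.down_blocks[i].backward(d)
        dx = self.stem.backward(d)
        if self._replicated:
            dx = dx.sum(axis=1, keepdims=True)
        return dx

    def predict_proba(self, x):
        """Per-pixel class probabilities (softmax over the channel axis)."""
        return softmax(self.forward(x, train=False), axis=1)

    # -- persistence -----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        state = [p.v.copy() for p in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[:len(ps)]):
            p.v[...] = v
        rest = state[len(ps):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self):
        out = []

        def visit(layer):
            if isinstance(layer, BatchNorm2d):
                out.append(layer)
            for attr in ("net", "layers", "branches", "down_blocks", "transitions_down",
                         "bottleneck", "transitions_up", "up_blocks"):
                sub = getattr(layer, attr, None)
                if isinstance(sub, Layer):
                    visit(sub)
                elif isinstance(sub, list):
                    for s in sub:
                        if isinstance(s, Layer):
                            visit(s)
        visit(self)
        return out

    def save(self, path: str | Path) -> None:
        """Serialize weights (.npz) plus a JSON sidecar with the config."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        state = self.get_weights()
        np.savez_compressed(path, **{f"arr_{i}": a for i, a in enumerate(state)})
        path.with_suffix(".json").write_text(json.dumps(self.config.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationNetwork":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = path.with_suffix(".json")
        config = NetworkConfig.from_dict(json.loads(sidecar.read_text()))
        model = cls(config, seed=0)
        with np.load(path) as data:
            state = [data[f"arr_{i}"] for i in range(len(data.files))]
        model.set_weights(state)
        return model


def build_network(config: NetworkConfig, seed: int | None = None) -> SegmentationNetwork:
    """Construct the segmentation network for a given configuration."""
    return SegmentationNetwork(config, seed=seed)


def count_parameters(model: Layer) -> int:
    """Exact number of trainable scalar weights and biases in ``model``."""
    return int(sum(p.size for p in model.params()))


# ---------------------------------------------------------------------------
# functional single-map wrappers (H x W x C arrays)
# ---------------------------------------------------------------------------

def _to_batch(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.float32)
    if u.ndim == 2:
        u = u[:, :, None]
    return u.transpose(2, 0, 1)[None]


def _from_batch(y: np.ndarray) -> np.ndarray:
    return y[0].transpose(1, 2, 0)


def multiscale_forward(image: np.ndarray, stem: MultiScaleStem) -> np.ndarray:
    """Run the multi-scale stem on a single H x W x C map."""
    return _from_batch(stem.forward(_to_batch(image)))


def dense_block_forward(u: np.ndarray, block: DenseBlock,
                        include_input_in_output: bool = True) -> np.ndarray:
    """Run a dense block on a single H x W x C map.

    With ``include_input_in_output`` the result carries C + L*k channels
    (encoder convention), otherwise only the L*k new feature maps.
    """
    full = _from_batch(block.forward(_to_batch(u)))
    if include_input_in_output:
        return full
    return full[:, :, block.in_ch:]


def sse_forward(u: np.ndarray, sse: SpatialSE) -> np.ndarray:
    return _from_batch(sse.forward(_to_batch(u)))


def cse_forward(u: np.ndarray, cse: ChannelSE) -> np.ndarray:
    return _from_batch(cse.forward(_to_batch(u)))


def scse_forward(u: np.ndarray, scse: ScSE) -> np.ndarray:
    return _from_batch(scse.forward(_to_batch(u)))


def transition_down_forward(u: np.ndarray, td: TransitionDown) -> np.ndarray:
    return _from_batch(td.forward(_to_batch(u)))


def transition_up_forward(u: np.ndarray, tu: TransitionUp) -> np.ndarray:
    return _from_batch(tu.forward(_to_batch(u)))
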