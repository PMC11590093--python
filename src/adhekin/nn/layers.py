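"""Minimal numpy neural-network layers with manual backpropagation.

The classifier inputs are tiny — (t, 8, 8) single-channel videos — so a
compact, dependency-free stack is sufficient: 3D convolution (im2col),
layer normalization, max / adaptive-average pooling, dropout, dense
layers and a multi-layer LSTM, each implementing ``forward`` and
``backward`` with explicit caches. All layers are deterministic given
their seed.

Tensors are laid out (B, C, D, H, W) for volumetric layers, with D the
temporal axis, and (B, T, F) for the recurrent layer.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    """Base layer: forward caches what backward needs."""

    training: bool = False

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad5(x: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    pd, ph, pw = pad
    if pd == ph == pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))


class Conv3d(Layer):
    """Stride-1 3D convolution with 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 rng: np.random.Generator | None = None, name: str = "conv"):
        kd, kh, kw = kernel
        self.kernel = kernel
        self.pad = (kd // 2, kh // 2, kw // 2)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kd * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias")
        self.in_channels = in_channels
        self.out_channels = out_channels

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel
        xp = _pad5(x, self.pad)
        win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        # win: (B, C, D, H, W, kd, kh, kw) -> (B*D*H*W, C*kd*kh*kw)
        B, C, D, H, W = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B * D * H * W, C * kd * kh * kw)
        return np.ascontiguousarray(cols), (B, D, H, W)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (B, D, H, W) = self._im2col(x)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.weight.value.T + self.bias.value
        return out.reshape(B, D, H, W, self.out_channels).transpose(0, 4, 1, 2, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, Co, D, H, W = grad.shape
        gmat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, Co)
        self.weight.grad += gmat.T @ self._cols
        self.bias.grad += gmat.sum(axis=0)
        # dX as a full convolution of grad with the flipped, transposed kernel
        kd, kh, kw = self.kernel
        w = self.weight.value.reshape(Co, self.in_channels, kd, kh, kw)
        wflip = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).reshape(
            self.in_channels, Co * kd * kh * kw
        )
        gpad = _pad5(grad, (kd - 1 - self.pad[0], kh - 1 - self.pad[1], kw - 1 - self.pad[2]))
        win = np.lib.stride_tricks.sliding_window_view(gpad, (kd, kh, kw), axis=(2, 3, 4))
        Bg, Cg, Dg, Hg, Wg = win.shape[:5]
        gcols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(Bg * Dg * Hg * Wg, Cg * kd * kh * kw)
        dx = (gcols @ wflip.T).reshape(Bg, Dg, Hg, Wg, self.in_channels)
        dx = dx.transpose(0, 4, 1, 2, 3)
        self._cols = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float = 0.2, seed: int = 0):
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class LayerNorm(Layer):
    """Per-sample normalization over (C, D, H, W) with per-channel affine."""

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "ln"):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        g = self.gamma.value.reshape((1, -1) + (1,) * (x.ndim - 2))
        b = self.beta.value.reshape((1, -1) + (1,) * (x.ndim - 2))
        return g * self._xhat + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(1, grad.ndim))
        reduce_affine = (0,) + tuple(range(2, grad.ndim))
        self.gamma.grad += (grad * self._xhat).sum(axis=reduce_affine)
        self.beta.grad += grad.sum(axis=reduce_affine)
        g = self.gamma.value.reshape((1, -1) + (1,) * (grad.ndim - 2))
        dxhat = grad * g
        m = np.prod([grad.shape[a] for a in axes])
        mean_d = dxhat.mean(axis=axes, keepdims=True)
        mean_dx = (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        return self._inv * (dxhat - mean_d - self._xhat * mean_dx)


class MaxPool3d(Layer):
    """Non-overlapping max pooling; trailing remainder frames are dropped."""

    def __init__(self, kernel: tuple[int, int, int]):
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel
        B, C, D, H, W = x.shape
        Do, Ho, Wo = D // kd, H // kh, W // kw
        if min(Do, Ho, Wo) < 1:
            raise ValueError(f"input {x.shape} too small for pool kernel {self.kernel}")
        xt = x[:, :, : Do * kd, : Ho * kh, : Wo * kw]
        win = xt.reshape(B, C, Do, kd, Ho, kh, Wo, kw)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, Do, Ho, Wo, kd * kh * kw)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel
        B, C, D, H, W = self._in_shape
        Do, Ho, Wo = D // kd, H // kh, W // kw
        dwin = np.zeros((B, C, Do, Ho, Wo, kd * kh * kw))
        np.put_along_axis(dwin, self._arg[..., None], grad[..., None], axis=-1)
        dwin = dwin.reshape(B, C, Do, Ho, Wo, kd, kh, kw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros(self._in_shape)
        dx[:, :, : Do * kd, : Ho * kh, : Wo * kw] = dwin.reshape(
            B, C, Do * kd, Ho * kh, Wo * kw
        )
        return dx


class AdaptiveAvgPoolTemporal(Layer):
    """Average the temporal axis into a fixed number of contiguous bins."""

    def __init__(self, out_frames: int = 4):
        self.out_frames = out_frames

    def _bins(self, D: int) -> list[tuple[int, int]]:
        L = self.out_frames
        if D < L:
            raise ValueError(f"temporal size {D} < requested {L} output frames")
        return [(i * D // L, ((i + 1) * D + L - 1) // L) for i in range(L)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        bins = self._bins(x.shape[2])
        self._bin_edges = bins
        return np.stack([x[:, :, a:b].mean(axis=2) for a, b in bins], axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        for i, (a, b) in enumerate(self._bin_edges):
            dx[:, :, a:b] += grad[:, :, i][:, :, None] / (b - a)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features), f"{name}.bias")

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            layer.training = self.training
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Layer):
    """Basic (non-bottleneck) residual block: two 3x3x3 convs + shortcut.

    When the channel count changes, a 1x1x1 convolution projects the
    shortcut; otherwise it is the identity.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, name: str = "res"):
        self.path = Sequential(
            Conv3d(in_channels, out_channels, rng=rng, name=f"{name}.conv1"),
            LayerNorm(out_channels, name=f"{name}.ln1"),
            ReLU(),
            Conv3d(out_channels, out_channels, rng=rng, name=f"{name}.conv2"),
            LayerNorm(out_channels, name=f"{name}.ln2"),
        )
        self.shortcut = (
            None
            if in_channels == out_channels
            else Conv3d(in_channels, out_channels, kernel=(1, 1, 1), rng=rng,
                        name=f"{name}.proj")
        )
        self.relu = ReLU()

    def parameters(self) -> list[Parameter]:
        params = self.path.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.path.training = self.training
        main = self.path.forward(x)
        skip = x if self.shortcut is None else self.shortcut.forward(x)
        return self.relu.forward(main + skip)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu.backward(grad)
        dmain = self.path.backward(grad)
        dskip = grad if self.shortcut is None else self.shortcut.backward(grad)
        return dmain + dskip


class DenseBlock(Layer):
    """DenseNet block: each layer sees the concatenation of all inputs."""

    def __init__(self, in_channels: int, n_layers: int, growth: int,
                 rng: np.random.Generator, name: str = "dense"):
        self.convs: list[Sequential] = []
        channels = in_channels
        for i in range(n_layers):
            self.convs.append(
                Sequential(
                    LayerNorm(channels, name=f"{name}.{i}.ln"),
                    ReLU(),
                    Conv3d(channels, growth, rng=rng, name=f"{name}.{i}.conv"),
                )
            )
            channels += growth
        self.out_channels = channels
        self.growth = growth

    def parameters(self) -> list[Parameter]:
        return [p for conv in self.convs for p in conv.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        for conv in self.convs:
            conv.training = self.training
            feats.append(conv.forward(np.concatenate(feats, axis=1)))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # split the incoming gradient back onto each concatenated feature
        splits = np.cumsum(self._widths)[:-1]
        grads = list(np.split(grad, splits, axis=1))
        for i in reversed(range(len(self.convs))):
            dcat = self.convs[i].backward(grads[i + 1])
            widths = self._widths[: i + 1]
            for j, piece in enumerate(np.split(dcat, np.cumsum(widths)[:-1], axis=1)):
                grads[j] = grads[j] + piece
        return grads[0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
                    np.exp(np.clip(z, -60, 60)) / (1.0 + np.exp(np.clip(z, -60, 60))))


class LSTM(Layer):
    """Multi-layer LSTM over (B, T, F); returns the last hidden state.

    Gates are ordered (input, forget, cell, output). Weights use the
    standard +/- 1/sqrt(hidden) uniform initialization; the forget-gate
    bias starts at 1 to ease gradient flow early in training.
    """

    def __init__(self, input_size: int, hidden_size: int, n_layers: int,
                 rng: np.random.Generator, name: str = "lstm"):
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.w_ih: list[Parameter] = []
        self.w_hh: list[Parameter] = []
        self.b: list[Parameter] = []
        bound = 1.0 / np.sqrt(hidden_size)
        for layer in range(n_layers):
            fin = input_size if layer == 0 else hidden_size
            self.w_ih.append(Parameter(
                rng.uniform(-bound, bound, size=(4 * hidden_size, fin)),
                f"{name}.{layer}.w_ih"))
            self.w_hh.append(Parameter(
                rng.uniform(-bound, bound, size=(4 * hidden_size, hidden_size)),
                f"{name}.{layer}.w_hh"))
            bias = np.zeros(4 * hidden_size)
            bias[hidden_size : 2 * hidden_size] = 1.0
            self.b.append(Parameter(bias, f"{name}.{layer}.b"))

    def parameters(self) -> list[Parameter]:
        return [*self.w_ih, *self.w_hh, *self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        Hs = self.hidden_size
        self._caches = []
        seq = x
        for layer in range(self.n_layers):
            h = np.zeros((B, Hs))
            c = np.zeros((B, Hs))
            wi, wh, b = self.w_ih[layer].value, self.w_hh[layer].value, self.b[layer].value
            steps = []
            outs = np.empty((B, T, Hs))
            for t in range(T):
                xt = seq[:, t]
                z = xt @ wi.T + h @ wh.T + b
                i = _sigmoid(z[:, :Hs])
                f = _sigmoid(z[:, Hs : 2 * Hs])
                g = np.tanh(z[:, 2 * Hs : 3 * Hs])
                o = _sigmoid(z[:, 3 * Hs :])
                c_new = f * c + i * g
                tanh_c = np.tanh(c_new)
                h_new = o * tanh_c
                steps.append((xt, h, c, i, f, g, o, c_new, tanh_c))
                h, c = h_new, c_new
                outs[:, t] = h
            self._caches.append(steps)
            seq = outs
        self._T = T
        return seq[:, -1]

    def backward(self, grad_last: np.ndarray) -> np.ndarray:
        B = grad_last.shape[0]
        Hs = self.hidden_size
        T = self._T
        # gradient w.r.t. each layer's full output sequence
        dseq = np.zeros((B, T, Hs))
        dseq[:, -1] = grad_last
        dx_seq = None
        for layer in reversed(range(self.n_layers)):
            steps = self._caches[layer]
            wi, wh = self.w_ih[layer].value, self.w_hh[layer].value
            dwi = np.zeros_like(wi)
            dwh = np.zeros_like(wh)
            db = np.zeros(4 * Hs)
            fin = wi.shape[1]
            dx_seq = np.zeros((B, T, fin))
            dh_next = np.zeros((B, Hs))
            dc_next = np.zeros((B, Hs))
            for t in reversed(range(T)):
                xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c = steps[t]
                dh = dseq[:, t] + dh_next
                do = dh * tanh_c
                dc = dc_next + dh * o * (1 - tanh_c**2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                    axis=1,
                )
                dwi += dz.T @ xt
                dwh += dz.T @ h_prev
                db += dz.sum(axis=0)
                dx_seq[:, t] = dz @ wi
                dh_next = dz @ wh
                dc_next = dc * f
            self.w_ih[layer].grad += dwi
            self.w_hh[layer].grad += dwh
            self.b[layer].grad += db
            dseq = dx_seq
        self._caches = None
        return dx_seq


class TemporalFeatures(Layer):
    """(B, C, D, 1, 1) feature volume -> (B, D, C) frame-feature sequence."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        if H != 1 or W != 1:
            raise ValueError(f"expected fully pooled spatial dims, got {x.shape}")
        self._in_shape = x.shape
        return x[:, :, :, 0, 0].transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.transpose(0, 2, 1).reshape(self._in_shape)


class AddChannel(Layer):
    """(B, D, H, W) input video -> single-channel (B, 1, D, H, W)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, 0]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
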