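"""Attention-augmented convolutional networks for connectivity matrices.

Two small architectures operate on a single-channel p x p functional
connectivity matrix:

* ``vgg5`` — four 3x3 convolution layers interleaved with 2x2 max pooling,
  then global average pooling and a fully connected layer (five weight
  layers in the trunk+head).
* ``resnet5`` — one 3x3 convolution followed by four residual blocks
  (two 3x3 convolutions each, identity or 1x1-projection shortcut), then
  global average pooling and a fully connected layer.

Soft attention is attached to layers 3 and 4 of either trunk, before the
final pooling.  Each attention block projects per-position feature vectors
x_i through two learned maps M(x) = W_m x and N(x) = W_n x whose output
dimension is ratio*c (ratio 1/2 at the first attention layer, 1/4 at the
second).  A compatibility score per position combines the pairwise term
<M(x_i), mean_j N(x_j)> with a global term <M(x_i), W_g g>, where g is the
global-average-pooled trunk output; the attention weights lambda are the
softmax of these scores over spatial positions, and the attended
descriptor is the lambda-weighted sum of the original per-position
features.  Descriptors from both attention layers are concatenated with g
before the fully connected head.

The classification head ends in a 4-way softmax; the regression head is a
single linear output (predicted age in years).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d, maxpool2x2, softmax

__all__ = ["ModelSpec", "AttentionBlock", "Network", "build_model", "kaiming_init", "predict"]

ARCHITECTURES = ("vgg5", "resnet5")
TASKS = ("classification", "regression")


@dataclass
class ModelSpec:
    """Frozen architecture configuration.

    channels is the layer/block schedule; attention_ratios follow the
    1/2-then-1/4 schedule for the two attention layers.
    """

    architecture: str = "resnet5"
    task: str = "classification"
    input_size: int = 32
    n_classes: int = 4
    attention: bool = True
    uniform_attention: bool = False  # ablation: force lambda uniform
    channels: tuple[int, int, int, int] = (16, 32, 64, 64)
    attention_ratios: tuple[float, float] = (0.5, 0.25)
    hidden_units: int = 64

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4 (two 2x stride reductions)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        d["attention_ratios"] = tuple(d["attention_ratios"])
        return cls(**d)


class _Param:
    """Named trainable tensor with its Kaiming fan-in."""

    def __init__(self, name: str, shape: tuple[int, ...], fan_in: int, is_bias: bool = False):
        self.name = name
        self.fan_in = fan_in
        self.is_bias = is_bias
        self.tensor = Tensor(np.zeros(shape), requires_grad=True)

    @property
    def data(self) -> np.ndarray:
        return self.tensor.data


class AttentionBlock:
    """Soft attention over the spatial positions of a feature map."""

    def __init__(self, name: str, channels: int, g_dim: int, ratio: float, register):
        self.channels = channels
        self.ratio = ratio
        self.proj_dim = max(1, int(round(channels * ratio)))
        self.w_m = register(_Param(f"{name}.w_m", (channels, self.proj_dim), fan_in=channels))
        self.w_n = register(_Param(f"{name}.w_n", (channels, self.proj_dim), fan_in=channels))
        self.w_g = register(_Param(f"{name}.w_g", (g_dim, self.proj_dim), fan_in=g_dim))

    def forward(self, feat: Tensor, g: Tensor, uniform: bool = False) -> tuple[Tensor, Tensor]:
        """Return (attended descriptor (B, c), lambda (B, n_positions))."""
        b, c, h, w = feat.shape
        if c != self.channels:
            raise ValueError(f"attention block expects {self.channels} channels, got {c}")
        n = h * w
        x_pos = feat.reshape(b, c, n).transpose(0, 2, 1)  # (B, n, c)
        if uniform:
            lam = Tensor(np.full((b, n), 1.0 / n))
        else:
            m_proj = x_pos @ self.w_m.tensor            # (B, n, d)
            n_proj = x_pos @ self.w_n.tensor            # (B, n, d)
            n_bar = n_proj.mean(axis=1, keepdims=True)  # (B, 1, d) pairwise mean over j
            g_proj = (g @ self.w_g.tensor).reshape(b, 1, self.proj_dim)
            # scaled dot-product keeps softmax inputs O(1) in d
            scores = (m_proj * (n_bar + g_proj)).sum(axis=2) * (1.0 / np.sqrt(self.proj_dim))
            lam = softmax(scores, axis=-1)              # (B, n)
        desc = (x_pos * lam.reshape(b, n, 1)).sum(axis=1)  # (B, c)
        return desc, lam


def _spatial_subsample(x: Tensor, stride: int) -> Tensor:
    """Strided spatial subsampling (the shortcut path of a downsampling block)."""
    data = x.data[:, :, ::stride, ::stride]
    out = Tensor(data, _prev=(x,))
    shape = x.data.shape

    def _bwd(g):
        if x.requires_grad:
            full = np.zeros(shape)
            full[:, :, ::stride, ::stride] = g
            x._accum(full)

    out._backward = _bwd
    return out


class Network:
    """A trainable map from p x p matrices to class logits or a scalar age."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.params: list[_Param] = []
        c1, c2, c3, c4 = spec.channels

        def reg(p: _Param) -> _Param:
            self.params.append(p)
            return p

        self._reg = reg
        if spec.architecture == "vgg5":
            self._conv_specs = [("conv1", 1, c1), ("conv2", c1, c2), ("conv3", c2, c3), ("conv4", c3, c4)]
            for name, cin, cout in self._conv_specs:
                reg(_Param(f"{name}.w", (cout, cin, 3, 3), fan_in=cin * 9))
                reg(_Param(f"{name}.b", (cout,), fan_in=cin * 9, is_bias=True))
        else:  # resnet5
            reg(_Param("conv1.w", (c1, 1, 3, 3), fan_in=9))
            reg(_Param("conv1.b", (c1,), fan_in=9, is_bias=True))
            self._block_specs = [
                ("block1", c1, c1, 2),
                ("block2", c1, c2, 2),
                ("block3", c2, c3, 2),
                ("block4", c3, c4, 1),
            ]
            for name, cin, cout, stride in self._block_specs:
                reg(_Param(f"{name}.conv_a.w", (cout, cin, 3, 3), fan_in=cin * 9))
                reg(_Param(f"{name}.conv_a.b", (cout,), fan_in=cin * 9, is_bias=True))
                reg(_Param(f"{name}.conv_b.w", (cout, cout, 3, 3), fan_in=cout * 9))
                reg(_Param(f"{name}.conv_b.b", (cout,), fan_in=cout * 9, is_bias=True))
                if cin != cout or stride != 1:
                    reg(_Param(f"{name}.proj.w", (cin, cout), fan_in=cin))

        g_dim = c4
        self.attn3: AttentionBlock | None = None
        self.attn4: AttentionBlock | None = None
        if spec.attention and not spec.uniform_attention:
            self.attn3 = AttentionBlock("attn3", c3, g_dim, spec.attention_ratios[0], reg)
            self.attn4 = AttentionBlock("attn4", c4, g_dim, spec.attention_ratios[1], reg)

        head_in = g_dim + (c3 + c4 if spec.attention else 0)
        reg(_Param("fc.w", (head_in, spec.hidden_units), fan_in=head_in))
        reg(_Param("fc.b", (spec.hidden_units,), fan_in=head_in, is_bias=True))
        out_dim = spec.n_classes if spec.task == "classification" else 1
        reg(_Param("out.w", (spec.hidden_units, out_dim), fan_in=spec.hidden_units))
        reg(_Param("out.b", (out_dim,), fan_in=spec.hidden_units, is_bias=True))
        self._by_name = {p.name: p for p in self.params}

    # -- forward -------------------------------------------------------
    def _p(self, name: str) -> Tensor:
        return self._by_name[name].tensor

    def _trunk(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Run the convolutional trunk; return (layer-3 map, layer-4 map)."""
        if self.spec.architecture == "vgg5":
            h = conv2d(x, self._p("conv1.w"), self._p("conv1.b")).relu()
            h = maxpool2x2(h)
            h = conv2d(h, self._p("conv2.w"), self._p("conv2.b")).relu()
            h = maxpool2x2(h)
            f3 = conv2d(h, self._p("conv3.w"), self._p("conv3.b")).relu()
            f4 = conv2d(f3, self._p("conv4.w"), self._p("conv4.b")).relu()
            return f3, f4
        h = conv2d(x, self._p("conv1.w"), self._p("conv1.b")).relu()
        feats = []
        for name, cin, cout, stride in self._block_specs:
            y = conv2d(h, self._p(f"{name}.conv_a.w"), self._p(f"{name}.conv_a.b"), stride=stride).relu()
            y = conv2d(y, self._p(f"{name}.conv_b.w"), self._p(f"{name}.conv_b.b"))
            if cin != cout or stride != 1:
                sc = _spatial_subsample(h, stride) if stride != 1 else h
                b, _, hh, ww = sc.shape
                sc = (sc.reshape(b, cin, hh * ww).transpose(0, 2, 1) @ self._p(f"{name}.proj.w"))
                sc = sc.transpose(0, 2, 1).reshape(b, cout, hh, ww)
            else:
                sc = h
            h = (y + sc).relu()
            feats.append(h)
        return feats[2], feats[3]

    def forward(self, x: Tensor, return_attention: bool = False):
        """Map (B, 1, p, p) input to raw head output (logits or age).

        With ``return_attention=True`` also returns the per-layer lambda
        maps (empty dict when attention is off or forced uniform).
        """
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"expected input (B, 1, {self.spec.input_size}, {self.spec.input_size}), got {x.shape}"
            )
        f3, f4 = self._trunk(x)
        b = x.shape[0]
        g = f4.mean(axis=(2, 3))  # global average pool, (B, c4)
        lams: dict[str, Tensor] = {}
        if self.spec.attention:
            if self.spec.uniform_attention:
                n3 = f3.shape[2] * f3.shape[3]
                n4 = f4.shape[2] * f4.shape[3]
                lam3 = Tensor(np.full((b, n3), 1.0 / n3))
                lam4 = Tensor(np.full((b, n4), 1.0 / n4))
                d3 = (f3.reshape(b, f3.shape[1], n3).transpose(0, 2, 1) * lam3.reshape(b, n3, 1)).sum(axis=1)
                d4 = (f4.reshape(b, f4.shape[1], n4).transpose(0, 2, 1) * lam4.reshape(b, n4, 1)).sum(axis=1)
            else:
                d3, lam3 = self.attn3.forward(f3, g)
                d4, lam4 = self.attn4.forward(f4, g)
            lams = {"layer3": lam3, "layer4": lam4}
            feats = concat([g, d3, d4], axis=1)
        else:
            feats = g
        h = (feats @ self._p("fc.w") + self._p("fc.b")).relu()
        out = h @ self._p("out.w") + self._p("out.b")
        if return_attention:
            return out, lams
        return out

    # -- utilities -----------------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in state dict")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.tensor.data = np.asarray(state[p.name], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.params:
            p.tensor.zero_grad()


def build_model(spec: ModelSpec, seed: int = 0) -> Network:
    """Construct a network and Kaiming-initialize it under ``seed``."""
    net = Network(spec)
    kaiming_init(net, seed)
    return net


def kaiming_init(model: Network, seed: int) -> Network:
    """He-normal initialization: weights ~ N(0, 2/fan_in), biases zero.

    Parameters are visited in their fixed registration order, so the
    result is bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    for p in model.params:
        if p.is_bias:
            p.tensor.data = np.zeros(p.data.shape)
        else:
            std = np.sqrt(2.0 / p.fan_in)
            p.tensor.data = rng.normal(0.0, std, size=p.data.shape)
    return model


def predict(model: Network, matrices: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Deterministic inference on a stack of connectivity matrices.

    ``matrices`` is (n, p, p).  Classification returns (n, 4) softmax
    probabilities; regression returns (n,) predicted ages.  Outputs are
    independent of how the stack is batched.
    """
    x = np.asarray(matrices, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != model.spec.input_size or x.shape[2] != model.spec.input_size:
        raise ValueError(f"expected (n, {model.spec.input_size}, {model.spec.input_size}) input, got {x.shape}")
    outs = []
    for start in range(0, x.shape[0], batch_size):
        xb = Tensor(x[start : start + batch_size, None, :, :])
        raw = model.forward(xb)
        if model.spec.task == "classification":
            outs.append(softmax(raw, axis=-1).data)
        else:
            outs.append(raw.data[:, 0])
    return np.concatenate(outs, axis=0)
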