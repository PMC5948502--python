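"""Declarative builders for LiteNet and the four comparison networks.

The Lite module
---------------
The module is a squeeze convolution feeding an inception-style arrangement of
heterogeneous-kernel branches whose outputs are concatenated::

    in ──► squeeze 1×1 → 3 ch ──┬──► standard 1×1 → 6 ─────────────────────────┐
                                ├──► standard 1×2 → 6 → depthwise 1×2 → pointwise 1×1 → 6 ─┤ concat → 18
                                └──► standard 1×3 → 6 → depthwise 1×3 → pointwise 1×1 → 6 ─┘

with LeakyReLU after every convolution and an optional residual connection
from the module input (added through a 1×1 projection when the channel counts
differ).  This branch composition is the unique arrangement that consumes
each configured layer exactly once and produces the 18 concatenated channels
the surrounding network expects at its second max-pool.

Basic LiteNet is: standard conv 1×5 (5 filters) → max-pool 1×2/2 → one Lite
module → max-pool 1×2/2 → flatten → dense 30 → dropout 0.3 → dense 20 →
dropout 0.3 → 5-way softmax.  The extended variant stacks several Lite
modules, each followed by a max-pool.

The four baselines (1-D miniatures of AlexNet, GoogLeNet, SqueezeNet and
MobileNets) share LiteNet's dense/softmax head so that the model-size metric
PC — which excludes dense layers — compares conv bodies like for like.
"""

from __future__ import annotations

from .network import LayerSpec, NetworkSpec

DROPOUT_RATE = 0.3
LEAKY_SLOPE = 0.01

ARCHITECTURES = (
    "litenet-basic",
    "litenet-extended",
    "alexnet1d",
    "googlenet1d",
    "squeezenet1d",
    "mobilenets1d",
)


class _Builder:
    """Accumulates LayerSpec nodes; every helper returns the new node name."""

    def __init__(self, input_length: int, in_channels: int = 1, n_classes: int = 5):
        self.nodes: list[LayerSpec] = [LayerSpec("input", "input")]
        self.input_length = input_length
        self.in_channels = in_channels
        self.n_classes = n_classes

    def add(self, name: str, kind: str, inputs: str | tuple[str, ...], **kw) -> str:
        if isinstance(inputs, str):
            inputs = (inputs,)
        self.nodes.append(LayerSpec(name, kind, inputs, **kw))
        return name

    def conv(self, name: str, src: str, kind: str, k: int, out_channels: int) -> str:
        """A convolution followed by LeakyReLU."""
        c = self.add(name, kind, src, kernel_size=k, out_channels=out_channels)
        return self.add(f"{name}/act", "activation", c, activation_slope=LEAKY_SLOPE)

    def head(self, src: str) -> str:
        """Flatten → dense 30 → dropout → dense 20 → dropout → dense 5 → softmax."""
        x = self.add("flatten", "flatten", src)
        x = self.add("fc1", "dense", x, out_channels=30)
        x = self.add("fc1/act", "activation", x, activation_slope=LEAKY_SLOPE)
        x = self.add("fc1/drop", "dropout", x, dropout_rate=DROPOUT_RATE)
        x = self.add("fc2", "dense", x, out_channels=20)
        x = self.add("fc2/act", "activation", x, activation_slope=LEAKY_SLOPE)
        x = self.add("fc2/drop", "dropout", x, dropout_rate=DROPOUT_RATE)
        x = self.add("logits", "dense", x, out_channels=self.n_classes)
        return self.add("softmax", "softmax", x)

    def spec(self) -> NetworkSpec:
        return NetworkSpec(self.nodes, self.input_length, self.in_channels, self.n_classes)


def _lite_module(b: _Builder, src: str, in_channels: int, residual: bool, prefix: str) -> str:
    """Append one Lite module; returns the output node name (18 channels)."""
    sq = b.conv(f"{prefix}/squeeze", src, "squeeze_conv", 1, 3)
    # branch a: standard 1x1
    ba = b.conv(f"{prefix}/a_conv1", sq, "standard_conv", 1, 6)
    # branch b: standard 1x2 -> depthwise 1x2 -> pointwise 1x1
    bb = b.conv(f"{prefix}/b_conv2", sq, "standard_conv", 2, 6)
    bb = b.conv(f"{prefix}/b_dw2", bb, "depthwise_conv", 2, 6)
    bb = b.conv(f"{prefix}/b_pw", bb, "pointwise_conv", 1, 6)
    # branch c: standard 1x3 -> depthwise 1x3 -> pointwise 1x1
    bc = b.conv(f"{prefix}/c_conv3", sq, "standard_conv", 3, 6)
    bc = b.conv(f"{prefix}/c_dw3", bc, "depthwise_conv", 3, 6)
    bc = b.conv(f"{prefix}/c_pw", bc, "pointwise_conv", 1, 6)
    out = b.add(f"{prefix}/concat", "concat", (ba, bb, bc))
    if residual:
        shortcut = src
        if in_channels != 18:
            shortcut = b.add(
                f"{prefix}/proj", "pointwise_conv", src, kernel_size=1, out_channels=18
            )
        out = b.add(f"{prefix}/residual", "residual_add", (out, shortcut))
    return out


def build_lite_module(in_channels: int, residual: bool = False) -> NetworkSpec:
    """A standalone Lite-module fragment on an ``in_channels`` input.

    The returned spec ends at the module output (no classifier head); it is
    meant for inspection — shape propagation and the parameter ledger — and
    validates with ``require_head=False``.
    """
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    b = _Builder(input_length=32, in_channels=in_channels)
    _lite_module(b, "input", in_channels, residual, "lite")
    spec = b.spec()
    spec.validate(require_head=False)
    return spec


def build_litenet_extended(input_length: int, n_modules: int = 1,
                           residual: bool = False) -> NetworkSpec:
    """LiteNet with ``n_modules`` stacked Lite modules, a max-pool after each.

    ``n_modules=1`` is exactly the basic network.  Raises
    :class:`~litenet.network.SpecError` (naming the offending depth) if the
    feature-map length underflows.
    """
    if input_length < 8:
        raise ValueError("input_length must be >= 8")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    b = _Builder(input_length)
    x = b.conv("stem", "input", "standard_conv", 5, 5)
    x = b.add("pool0", "maxpool", x, kernel_size=2, stride=2)
    channels = 5
    for i in range(1, n_modules + 1):
        x = _lite_module(b, x, channels, residual, f"lite{i}")
        x = b.add(f"pool{i}", "maxpool", x, kernel_size=2, stride=2)
        channels = 18
    b.head(x)
    spec = b.spec()
    spec.validate()
    return spec


def build_litenet_basic(input_length: int, residual: bool = False) -> NetworkSpec:
    """The basic (single-module) LiteNet; see the module docstring."""
    return build_litenet_extended(input_length, n_modules=1, residual=residual)


def _build_alexnet1d(b: _Builder) -> str:
    x = b.conv("conv1", "input", "standard_conv", 5, 5)
    x = b.add("pool0", "maxpool", x, kernel_size=2, stride=2)
    x = b.conv("conv2", x, "standard_conv", 3, 10)
    x = b.conv("conv3", x, "standard_conv", 3, 20)
    return b.add("pool1", "maxpool", x, kernel_size=2, stride=2)


def _build_googlenet1d(b: _Builder) -> str:
    x = b.conv("stem", "input", "standard_conv", 5, 10)
    x = b.add("pool0", "maxpool", x, kernel_size=2, stride=2)
    # one inception module: parallel 1x1 / 1x2 / 1x3 branches, 8 filters each
    ba = b.conv("inc/conv1", x, "standard_conv", 1, 8)
    bb = b.conv("inc/conv2", x, "standard_conv", 2, 8)
    bc = b.conv("inc/conv3", x, "standard_conv", 3, 8)
    x = b.add("inc/concat", "concat", (ba, bb, bc))
    x = b.conv("conv_out", x, "standard_conv", 2, 10)
    return b.add("pool1", "maxpool", x, kernel_size=2, stride=2)


def _fire(b: _Builder, src: str, prefix: str) -> str:
    """Fire module: squeeze 1x1 (3 filters), expand 1x1 + 1x3 (8 each)."""
    sq = b.conv(f"{prefix}/squeeze", src, "squeeze_conv", 1, 3)
    e1 = b.conv(f"{prefix}/expand1", sq, "standard_conv", 1, 8)
    e3 = b.conv(f"{prefix}/expand3", sq, "standard_conv", 3, 8)
    return b.add(f"{prefix}/concat", "concat", (e1, e3))


def _build_squeezenet1d(b: _Builder) -> str:
    x = b.conv("stem", "input", "standard_conv", 5, 10)
    x = b.add("pool0", "maxpool", x, kernel_size=2, stride=2)
    x = _fire(b, x, "fire1")
    x = _fire(b, x, "fire2")
    return b.add("pool1", "maxpool", x, kernel_size=2, stride=2)


def _separable(b: _Builder, src: str, out_channels: int, prefix: str) -> str:
    """Depthwise (1x3) + pointwise separable convolution block."""
    x = b.conv(f"{prefix}/dw", src, "depthwise_conv", 3, _channels_of(b, src))
    return b.conv(f"{prefix}/pw", x, "pointwise_conv", 1, out_channels)


def _channels_of(b: _Builder, name: str) -> int:
    spec = NetworkSpec(b.nodes, b.input_length, b.in_channels, b.n_classes)
    return spec.validate(require_head=False)[name][1]


def _build_mobilenets1d(b: _Builder) -> str:
    x = b.conv("stem", "input", "standard_conv", 5, 10)
    x = b.add("pool0", "maxpool", x, kernel_size=2, stride=2)
    x = _separable(b, x, 10, "sep1")
    x = _separable(b, x, 15, "sep2")
    return b.add("pool1", "maxpool", x, kernel_size=2, stride=2)


_BASELINES = {
    "alexnet1d": _build_alexnet1d,
    "googlenet1d": _build_googlenet1d,
    "squeezenet1d": _build_squeezenet1d,
    "mobilenets1d": _build_mobilenets1d,
}


def build_baseline(name: str, input_length: int) -> NetworkSpec:
    """Build one of the four 1-D comparison networks by name.

    All four end in the same flatten/dense/softmax head as LiteNet.
    """
    if name not in _BASELINES:
        raise ValueError(
            f"unknown baseline {name!r}; valid names: {sorted(_BASELINES)}"
        )
    b = _Builder(input_length)
    tail = _BASELINES[name](b)
    b.head(tail)
    spec = b.spec()
    spec.validate()
    return spec


def build_architecture(name: str, input_length: int, n_modules: int = 2) -> NetworkSpec:
    """Build any named architecture (LiteNet variants or a baseline)."""
    if name == "litenet-basic":
        return build_litenet_basic(input_length)
    if name == "litenet-extended":
        return build_litenet_extended(input_length, n_modules=n_modules)
    if name in _BASELINES:
        return build_baseline(name, input_length)
    raise ValueError(f"unknown architecture {name!r}; valid names: {list(ARCHITECTURES)}")
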