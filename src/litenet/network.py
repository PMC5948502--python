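"""Declarative layer graphs: specs, shape inference, parameter ledger, and a
seeded executable network with forward and backward passes.

A :class:`NetworkSpec` is an ordered DAG of :class:`LayerSpec` nodes.  The
first node is the single ``input``; the last is the single ``softmax``.
Branch/merge structure is explicit: every node names its input nodes, and
``concat`` / ``residual_add`` take several.  Validation propagates shapes
through the graph (feature maps as ``(channels, length)``, flattened vectors
as a feature count) and rejects any bookkeeping inconsistency by node name.

The parameter ledger reports weight and bias counts per layer.  The headline
model-size metric ``PC`` counts parameters of convolutional layers only
(standard, squeeze, depthwise, pointwise — weights plus biases), excluding
dense/softmax layers; the full total is reported alongside so alternative
counting conventions can be recomputed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn_core

CONV_KINDS = frozenset({"standard_conv", "squeeze_conv", "depthwise_conv", "pointwise_conv"})
ALL_KINDS = CONV_KINDS | {
    "input", "maxpool", "dense", "dropout", "activation",
    "softmax", "flatten", "concat", "residual_add",
}


class SpecError(ValueError):
    """A network spec violates shape, channel, or graph constraints."""


@dataclass(frozen=True)
class LayerSpec:
    """One node of a layer graph.

    ``out_channels`` doubles as the unit count for dense layers; it is ignored
    by shape-preserving kinds.  ``activation_slope`` is the LeakyReLU negative
    slope; ``dropout_rate`` the drop probability.
    """

    name: str
    kind: str
    inputs: tuple[str, ...] = ()
    kernel_size: int = 1
    stride: int = 1
    out_channels: int = 0
    activation_slope: float = 0.01
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise SpecError(f"{self.name}: unknown layer kind {self.kind!r}")
        if self.kernel_size < 1 or self.stride < 1:
            raise SpecError(f"{self.name}: kernel_size and stride must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise SpecError(f"{self.name}: dropout_rate must lie in [0, 1)")
        if self.kind == "pointwise_conv" and self.kernel_size != 1:
            raise SpecError(f"{self.name}: pointwise convolution requires kernel_size 1")


# Shapes during inference: ("map", channels, length) or ("vec", features).
Shape = tuple


@dataclass
class NetworkSpec:
    """An ordered layer DAG plus input geometry and class count."""

    nodes: list[LayerSpec]
    input_length: int
    in_channels: int = 1
    n_classes: int = 5

    def node(self, name: str) -> LayerSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    # -- validation / shape propagation ------------------------------------

    def validate(self, require_head: bool = True) -> dict[str, Shape]:
        """Propagate shapes through the graph; raise :class:`SpecError` on any
        inconsistency.  Returns the shape of every node's output.

        With ``require_head=False`` the single-softmax/terminal checks are
        skipped, which allows validating architecture fragments (e.g. a lone
        module ending at its concat node).
        """
        if not self.nodes or self.nodes[0].kind != "input":
            raise SpecError("first node must be the single 'input' node")
        if sum(1 for n in self.nodes if n.kind == "input") != 1:
            raise SpecError("exactly one input node is required")
        if require_head:
            if sum(1 for n in self.nodes if n.kind == "softmax") != 1:
                raise SpecError("exactly one softmax node is required")
            if self.nodes[-1].kind != "softmax":
                raise SpecError("the softmax node must be terminal")
        shapes: dict[str, Shape] = {}
        for node in self.nodes:
            if node.name in shapes:
                raise SpecError(f"duplicate node name {node.name!r}")
            ins = []
            for src in node.inputs:
                if src not in shapes:
                    raise SpecError(
                        f"{node.name}: input {src!r} undefined or later in the graph"
                    )
                ins.append(shapes[src])
            shapes[node.name] = self._infer(node, ins)
        if require_head:
            out = shapes[self.nodes[-1].name]
            if out != ("vec", self.n_classes):
                raise SpecError(
                    f"softmax output must have {self.n_classes} units, got {out}"
                )
        return shapes

    def _infer(self, node: LayerSpec, ins: list[Shape]) -> Shape:
        kind = node.kind
        if kind == "input":
            return ("map", self.in_channels, self.input_length)
        if len(ins) != 1 and kind not in ("concat", "residual_add"):
            raise SpecError(f"{node.name}: expects exactly one input")
        if kind in ("standard_conv", "squeeze_conv", "pointwise_conv"):
            _, c, L = _want_map(node, ins[0])
            L_out = -(-L // node.stride)  # ceil
            return ("map", node.out_channels, L_out)
        if kind == "depthwise_conv":
            _, c, L = _want_map(node, ins[0])
            if node.out_channels != c:
                raise SpecError(
                    f"{node.name}: depthwise out_channels {node.out_channels} "
                    f"!= input channels {c}"
                )
            return ("map", c, -(-L // node.stride))
        if kind == "maxpool":
            _, c, L = _want_map(node, ins[0])
            L_out = L // node.kernel_size
            if L_out < 1:
                raise SpecError(f"{node.name}: length underflow (pooling length {L})")
            return ("map", c, L_out)
        if kind in ("activation", "dropout"):
            return ins[0]
        if kind == "flatten":
            _, c, L = _want_map(node, ins[0])
            return ("vec", c * L)
        if kind == "dense":
            if ins[0][0] != "vec":
                raise SpecError(f"{node.name}: dense requires a flattened input")
            return ("vec", node.out_channels)
        if kind == "softmax":
            if ins[0][0] != "vec":
                raise SpecError(f"{node.name}: softmax requires a flattened input")
            return ins[0]
        if kind == "concat":
            if len(ins) < 2:
                raise SpecError(f"{node.name}: concat needs >= 2 inputs")
            maps = [_want_map(node, s) for s in ins]
            lengths = {m[2] for m in maps}
            if len(lengths) != 1:
                raise SpecError(f"{node.name}: concat inputs have unequal lengths {lengths}")
            return ("map", sum(m[1] for m in maps), lengths.pop())
        if kind == "residual_add":
            if len(ins) != 2:
                raise SpecError(f"{node.name}: residual_add needs exactly 2 inputs")
            if ins[0] != ins[1]:
                raise SpecError(f"{node.name}: residual shapes differ: {ins[0]} vs {ins[1]}")
            return ins[0]
        raise SpecError(f"{node.name}: unhandled kind {kind!r}")  # pragma: no cover

    def shape_trace(self) -> list[tuple[str, str, Shape]]:
        """(name, kind, output shape) for every node, in graph order."""
        shapes = self.validate()
        return [(n.name, n.kind, shapes[n.name]) for n in self.nodes]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_length": self.input_length,
                "in_channels": self.in_channels,
                "n_classes": self.n_classes,
                "nodes": [asdict(n) for n in self.nodes],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        nodes = [
            LayerSpec(**{**nd, "inputs": tuple(nd["inputs"])}) for nd in d["nodes"]
        ]
        return cls(nodes, d["input_length"], d["in_channels"], d["n_classes"])


def _want_map(node: LayerSpec, shape: Shape) -> Shape:
    if shape[0] != "map":
        raise SpecError(f"{node.name}: expects a feature map, got {shape}")
    return shape


# ---------------------------------------------------------------------------
# Parameter ledger

@dataclass(frozen=True)
class LedgerEntry:
    name: str
    kind: str
    weights: int
    biases: int


@dataclass
class ParameterLedger:
    """Per-layer weight/bias counts with conv-only (PC) and full totals."""

    entries: list[LedgerEntry]

    @property
    def pc(self) -> int:
        """Model-size metric: conv-layer weights+biases, dense excluded."""
        return sum(e.weights + e.biases for e in self.entries if e.kind in CONV_KINDS)

    @property
    def total(self) -> int:
        return sum(e.weights + e.biases for e in self.entries)

    @property
    def total_weights(self) -> int:
        return sum(e.weights for e in self.entries)

    @property
    def total_biases(self) -> int:
        return sum(e.biases for e in self.entries)


def count_parameters(spec: NetworkSpec) -> ParameterLedger:
    """Weight/bias counts per layer under the shapes the spec implies."""
    shapes = spec.validate(require_head=False)
    entries: list[LedgerEntry] = []
    for node in spec.nodes:
        w = b = 0
        if node.kind in ("standard_conv", "squeeze_conv", "pointwise_conv"):
            c_in = shapes[node.inputs[0]][1]
            w = node.kernel_size * c_in * node.out_channels
            b = node.out_channels
        elif node.kind == "depthwise_conv":
            c = shapes[node.inputs[0]][1]
            w = node.kernel_size * c
            b = c
        elif node.kind == "dense":
            f = shapes[node.inputs[0]][1]
            w = f * node.out_channels
            b = node.out_channels
        if w or b:
            entries.append(LedgerEntry(node.name, node.kind, w, b))
    return ParameterLedger(entries)


# ---------------------------------------------------------------------------
# Executable network

class Network:
    """A seeded, trainable instantiation of a :class:`NetworkSpec`.

    Weights use He-style fan-in-scaled uniform initialization
    ``U(-√(6/fan_in), +√(6/fan_in))``; biases start at zero.  The classifier
    head (the dense layer feeding the softmax) is drawn at 1/20 of that
    scale so the initial predictive distribution is near-uniform and the
    initial loss on K classes sits at ≈ ln K.  Parameters are drawn in graph
    order from a single generator, so a seed pins them.
    """

    _HEAD_SCALE = 0.05

    def __init__(self, spec: NetworkSpec, seed: int | np.random.Generator = 0):
        self.spec = spec
        self.shapes = spec.validate()
        self._head_dense = spec.nodes[-1].inputs[0]
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.params: dict[str, dict[str, np.ndarray]] = {}
        for node in spec.nodes:
            p = self._init_node(node, rng)
            if p:
                self.params[node.name] = p
        self._values: dict[str, np.ndarray] | None = None
        self._cache: dict[str, object] = {}

    def _init_node(self, node: LayerSpec, rng) -> dict[str, np.ndarray]:
        k = node.kernel_size
        if node.kind in ("standard_conv", "squeeze_conv", "pointwise_conv"):
            c_in = self.shapes[node.inputs[0]][1]
            fan_in = k * c_in
            lim = np.sqrt(6.0 / fan_in)
            return {
                "W": rng.uniform(-lim, lim, (k, c_in, node.out_channels)),
                "b": np.zeros(node.out_channels),
            }
        if node.kind == "depthwise_conv":
            c = self.shapes[node.inputs[0]][1]
            lim = np.sqrt(6.0 / k)
            return {"W": rng.uniform(-lim, lim, (k, c)), "b": np.zeros(c)}
        if node.kind == "dense":
            f = self.shapes[node.inputs[0]][1]
            lim = np.sqrt(6.0 / f)
            if node.name == self._head_dense:
                lim *= self._HEAD_SCALE
            return {"W": rng.uniform(-lim, lim, (f, node.out_channels)),
                    "b": np.zeros(node.out_channels)}
        return {}

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Run the graph on a batch; returns class probabilities (B, n_classes).

        ``X`` may be (B, L) for single-channel input or (B, C, L).  With
        ``train=True`` dropout is active and consumes ``rng`` in graph order.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, None, :]
        values: dict[str, np.ndarray] = {}
        cache: dict[str, object] = {}
        for node in self.spec.nodes:
            ins = [values[s] for s in node.inputs]
            kind = node.kind
            if kind == "input":
                if X.shape[1:] != (self.spec.in_channels, self.spec.input_length):
                    raise ValueError(
                        f"input shape {X.shape[1:]} != "
                        f"({self.spec.in_channels}, {self.spec.input_length})"
                    )
                values[node.name] = X
            elif kind in ("standard_conv", "squeeze_conv", "pointwise_conv"):
                p = self.params[node.name]
                values[node.name] = nn_core.conv_forward(ins[0], p["W"], p["b"], node.stride)
            elif kind == "depthwise_conv":
                p = self.params[node.name]
                values[node.name] = nn_core.depthwise_forward(ins[0], p["W"], p["b"], node.stride)
            elif kind == "maxpool":
                y, idx = nn_core.maxpool_forward(ins[0], node.kernel_size)
                values[node.name] = y
                cache[node.name] = idx
            elif kind == "activation":
                values[node.name] = nn_core.leaky_relu(ins[0], node.activation_slope)
            elif kind == "dropout":
                y, mask = nn_core.dropout_forward(ins[0], node.dropout_rate, rng, train)
                values[node.name] = y
                cache[node.name] = mask
            elif kind == "flatten":
                B = ins[0].shape[0]
                values[node.name] = ins[0].reshape(B, -1)
            elif kind == "dense":
                p = self.params[node.name]
                values[node.name] = nn_core.dense_forward(ins[0], p["W"], p["b"])
            elif kind == "concat":
                values[node.name] = np.concatenate(ins, axis=1)
            elif kind == "residual_add":
                values[node.name] = ins[0] + ins[1]
            elif kind == "softmax":
                values[node.name] = nn_core.softmax(ins[0])
        self._values = values
        self._cache = cache
        return values[self.spec.nodes[-1].name]

    # -- backward -----------------------------------------------------------

    def backward(self, Y: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Gradients of the mean cross-entropy loss w.r.t. every parameter.

        ``Y`` is the (B, n_classes) matrix of expected distributions (one-hot
        for hard labels).  Requires a cached forward pass.  The softmax +
        cross-entropy head differentiates jointly to ``(q - p) / B``.
        """
        if self._values is None:
            raise RuntimeError("backward requires a cached forward pass")
        values, cache = self._values, self._cache
        softmax_node = self.spec.nodes[-1]
        probs = values[softmax_node.name]
        Y = np.asarray(Y, dtype=np.float64)
        if Y.shape != probs.shape:
            raise ValueError(f"target shape {Y.shape} != output shape {probs.shape}")
        B = probs.shape[0]
        gy_by_node: dict[str, np.ndarray] = {softmax_node.inputs[0]: (probs - Y) / B}
        grads: dict[str, dict[str, np.ndarray]] = {}
        for node in reversed(self.spec.nodes[:-1]):  # softmax handled above
            gy = gy_by_node.pop(node.name, None)
            if gy is None:
                continue
            ins = [values[s] for s in node.inputs]
            kind = node.kind
            gxs: list[np.ndarray]
            if kind == "input":
                continue
            elif kind in ("standard_conv", "squeeze_conv", "pointwise_conv"):
                gx, gW, gb = nn_core.conv_backward(
                    ins[0], self.params[node.name]["W"], node.stride, gy
                )
                grads[node.name] = {"W": gW, "b": gb}
                gxs = [gx]
            elif kind == "depthwise_conv":
                gx, gW, gb = nn_core.depthwise_backward(
                    ins[0], self.params[node.name]["W"], node.stride, gy
                )
                grads[node.name] = {"W": gW, "b": gb}
                gxs = [gx]
            elif kind == "maxpool":
                gxs = [nn_core.maxpool_backward(
                    ins[0].shape, node.kernel_size, cache[node.name], gy
                )]
            elif kind == "activation":
                gxs = [nn_core.leaky_relu_backward(ins[0], node.activation_slope, gy)]
            elif kind == "dropout":
                gxs = [nn_core.dropout_backward(cache[node.name], gy)]
            elif kind == "flatten":
                gxs = [gy.reshape(ins[0].shape)]
            elif kind == "dense":
                gx, gW, gb = nn_core.dense_backward(ins[0], self.params[node.name]["W"], gy)
                grads[node.name] = {"W": gW, "b": gb}
                gxs = [gx]
            elif kind == "concat":
                gxs = []
                start = 0
                for x_in in ins:
                    c = x_in.shape[1]
                    gxs.append(gy[:, start : start + c, :])
                    start += c
            elif kind == "residual_add":
                gxs = [gy, gy]
            else:  # pragma: no cover
                raise RuntimeError(f"no backward rule for {kind}")
            for src, gx in zip(node.inputs, gxs):
                if src in gy_by_node:
                    gy_by_node[src] = gy_by_node[src] + gx
                else:
                    gy_by_node[src] = gx
        return grads

    # -- convenience --------------------------------------------------------

    def loss(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Mean cross-entropy of the network's predictions against ``Y``."""
        probs = self.forward(X, train=train, rng=rng)
        return nn_core.cross_entropy(Y, probs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- text serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": json.loads(self.spec.to_json()),
                "params": {
                    name: {k: v.tolist() for k, v in p.items()}
                    for name, p in self.params.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Network":
        d = json.loads(text)
        spec = NetworkSpec.from_json(json.dumps(d["spec"]))
        net = cls(spec, seed=0)
        for name, p in d["params"].items():
            for k, v in p.items():
                net.params[name][k] = np.asarray(v, dtype=np.float64)
        return net


def save_model(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write(net.to_json())


def load_model(path) -> Network:
    with open(path, "r") as fh:
        return Network.from_json(fh.read())
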