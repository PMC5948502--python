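import numpy as np
import pytest

from litenet.network import (
    LayerSpec,
    Network,
    NetworkSpec,
    SpecError,
    count_parameters,
    load_model,
    save_model,
)
from litenet.nn_core import cross_entropy
from litenet.architectures import build_litenet_extended


def _mini_spec(nodes, input_length=12, in_channels=1):
    return NetworkSpec(
        [LayerSpec("input", "input")] + nodes, input_length, in_channels, 5
    )


def _head(src, prefix=""):
    return [
        LayerSpec(f"{prefix}flat", "flatten", (src,)),
        LayerSpec(f"{prefix}fc", "dense", (f"{prefix}flat",), out_channels=5),
        LayerSpec(f"{prefix}softmax", "softmax", (f"{prefix}fc",)),
    ]


def numeric_grad_check(spec, seed=0, batch=2, n_coords=4, eps=1e-4, tol=1e-5):
    """Compare every parameter gradient against central finite differences.

    Dropout stays active: the forward pass is re-seeded identically at every
    evaluation so the mask is frozen and differencing is well defined.  The
    relative error uses a small denominator floor so that cancellation noise
    on near-zero gradients is not mistaken for a wrong derivative.
    """
    net = Network(spec, seed=seed)
    r = np.random.default_rng(seed + 1)
    if spec.in_channels == 1:
        X = r.normal(size=(batch, spec.input_length))
    else:
        X = r.normal(size=(batch, spec.in_channels, spec.input_length))
    y = r.integers(0, spec.n_classes, size=batch)
    Y = np.zeros((batch, spec.n_classes))
    Y[np.arange(batch), y] = 1.0

    def loss():
        return cross_entropy(Y, net.forward(X, train=True, rng=np.random.default_rng(99)))

    net.forward(X, train=True, rng=np.random.default_rng(99))
    grads = net.backward(Y)
    assert grads, "network has no parameters to check"
    coord_rng = np.random.default_rng(7)
    worst = 0.0
    for name, layer_grads in grads.items():
        for pname, g in layer_grads.items():
            theta = net.params[name][pname].ravel()
            gflat = g.ravel()
            picks = coord_rng.choice(theta.size, size=min(n_coords, theta.size), replace=False)
            for i in picks:
                old = theta[i]
                theta[i] = old + eps
                lp = loss()
                theta[i] = old - eps
                lm = loss()
                theta[i] = old
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(gflat[i]), 1e-4)
                worst = max(worst, abs(num - gflat[i]) / denom)
    assert worst < tol, f"worst relative gradient error {worst}"


class TestGradients:
    @pytest.mark.parametrize("kind,extra", [
        ("standard_conv", dict(kernel_size=3, out_channels=4)),
        ("standard_conv", dict(kernel_size=2, out_channels=3)),
        ("squeeze_conv", dict(kernel_size=1, out_channels=2)),
        ("pointwise_conv", dict(kernel_size=1, out_channels=4)),
    ])
    def test_single_conv_layer(self, kind, extra):
        nodes = [
            LayerSpec("conv", kind, ("input",), **extra),
            LayerSpec("act", "activation", ("conv",)),
        ] + _head("act")
        numeric_grad_check(_mini_spec(nodes))

    def test_depthwise_layer(self):
        nodes = [
            LayerSpec("up", "standard_conv", ("input",), kernel_size=1, out_channels=3),
            LayerSpec("dw", "depthwise_conv", ("up",), kernel_size=3, out_channels=3),
            LayerSpec("act", "activation", ("dw",)),
        ] + _head("act")
        numeric_grad_check(_mini_spec(nodes))

    def test_maxpool_dense_dropout(self):
        nodes = [
            LayerSpec("conv", "standard_conv", ("input",), kernel_size=3, out_channels=2),
            LayerSpec("pool", "maxpool", ("conv",), kernel_size=2, stride=2),
            LayerSpec("flat", "flatten", ("pool",)),
            LayerSpec("fc1", "dense", ("flat",), out_channels=8),
            LayerSpec("act", "activation", ("fc1",)),
            LayerSpec("drop", "dropout", ("act",), dropout_rate=0.3),
            LayerSpec("fc2", "dense", ("drop",), out_channels=5),
            LayerSpec("softmax", "softmax", ("fc2",)),
        ]
        numeric_grad_check(_mini_spec(nodes))

    def test_concat_and_residual(self):
        nodes = [
            LayerSpec("a", "standard_conv", ("input",), kernel_size=1, out_channels=2),
            LayerSpec("b", "standard_conv", ("input",), kernel_size=3, out_channels=2),
            LayerSpec("cat", "concat", ("a", "b")),
            LayerSpec("proj", "pointwise_conv", ("input",), kernel_size=1, out_channels=4),
            LayerSpec("res", "residual_add", ("cat", "proj")),
        ] + _head("res")
        numeric_grad_check(_mini_spec(nodes))

    def test_composed_litenet_with_residual_on_short_input(self):
        """Gradient check of the full architecture on a 20-sample input."""
        spec = build_litenet_extended(20, n_modules=1, residual=True)
        numeric_grad_check(spec, n_coords=3)

    def test_softmax_cross_entropy_head_gradient_is_q_minus_p(self):
        nodes = [
            LayerSpec("flat0", "flatten", ("input",)),
            LayerSpec("fc0", "dense", ("flat0",), out_channels=5),
            LayerSpec("softmax", "softmax", ("fc0",)),
        ]
        spec = _mini_spec(nodes, input_length=6)
        net = Network(spec, seed=1)
        X = np.random.default_rng(2).normal(size=(4, 6))
        probs = net.forward(X)
        Y = np.zeros((4, 5))
        Y[np.arange(4), [0, 1, 2, 3]] = 1.0
        grads = net.backward(Y)
        # logits gradient (q - p)/B shows up through the dense layer's bias
        assert np.allclose(grads["fc0"]["b"], (probs - Y).sum(axis=0) / 4)

    def test_zero_loss_gives_zero_gradients(self):
        nodes = [
            LayerSpec("flat0", "flatten", ("input",)),
            LayerSpec("fc0", "dense", ("flat0",), out_channels=5),
            LayerSpec("softmax", "softmax", ("fc0",)),
        ]
        spec = _mini_spec(nodes, input_length=6)
        net = Network(spec, seed=1)
        X = np.random.default_rng(2).normal(size=(3, 6))
        probs = net.forward(X)
        grads = net.backward(probs)  # expected distribution == prediction
        for layer_grads in grads.values():
            for g in layer_grads.values():
                assert np.allclose(g, 0.0, atol=1e-15)

    def test_backward_requires_cached_forward(self):
        spec = build_litenet_extended(16, 1)
        net = Network(spec)
        with pytest.raises(RuntimeError, match="forward"):
            net.backward(np.zeros((1, 5)))


class TestSpecValidation:
    def test_rejects_undefined_input_reference(self):
        nodes = [
            LayerSpec("fc", "dense", ("ghost",), out_channels=5),
            LayerSpec("softmax", "softmax", ("fc",)),
        ]
        with pytest.raises(SpecError, match="undefined"):
            _mini_spec(nodes).validate()

    def test_rejects_missing_softmax(self):
        spec = _mini_spec([LayerSpec("flat", "flatten", ("input",))])
        with pytest.raises(SpecError, match="softmax"):
            spec.validate()

    def test_rejects_channel_mismatch_in_depthwise(self):
        nodes = [
            LayerSpec("dw", "depthwise_conv", ("input",), kernel_size=3, out_channels=4),
        ] + _head("dw")
        with pytest.raises(SpecError, match="depthwise"):
            _mini_spec(nodes).validate()

    def test_rejects_concat_length_mismatch(self):
        nodes = [
            LayerSpec("a", "maxpool", ("input",), kernel_size=2, stride=2),
            LayerSpec("cat", "concat", ("a", "input")),
        ] + _head("cat")
        with pytest.raises(SpecError, match="unequal lengths"):
            _mini_spec(nodes).validate()

    def test_pointwise_requires_k1(self):
        with pytest.raises(SpecError, match="pointwise"):
            LayerSpec("pw", "pointwise_conv", ("input",), kernel_size=3, out_channels=2)

    def test_dimension_error_names_layer(self):
        nodes = [
            LayerSpec("pool9", "maxpool", ("input",), kernel_size=2, stride=2),
        ] + _head("pool9")
        spec = _mini_spec(nodes, input_length=1)
        with pytest.raises(SpecError, match="pool9"):
            spec.validate()


class TestLedger:
    def test_single_conv_example(self):
        nodes = [
            LayerSpec("conv", "standard_conv", ("input",), kernel_size=5, out_channels=5),
        ] + _head("conv")
        ledger = count_parameters(_mini_spec(nodes, input_length=12))
        entry = next(e for e in ledger.entries if e.name == "conv")
        assert entry.weights == 25 and entry.biases == 5
        assert ledger.pc == 30  # dense layers excluded from PC

    def test_parameter_free_network_counts_zero(self):
        nodes = [
            LayerSpec("flat", "flatten", ("input",)),
            LayerSpec("softmax", "softmax", ("flat",)),
        ]
        ledger = count_parameters(_mini_spec(nodes, input_length=5))
        assert ledger.pc == 0 and ledger.total == 0

    def test_totals_are_sums_of_entries(self):
        spec = build_litenet_extended(360, 1)
        ledger = count_parameters(spec)
        assert ledger.total == ledger.total_weights + ledger.total_biases
        assert ledger.total == sum(e.weights + e.biases for e in ledger.entries)


class TestSerialization:
    def test_spec_roundtrip_identity(self):
        spec = build_litenet_extended(360, 2)
        back = NetworkSpec.from_json(spec.to_json())
        assert back == spec

    def test_model_roundtrip_preserves_predictions(self, tmp_path):
        spec = build_litenet_extended(16, 1)
        net = Network(spec, seed=4)
        X = np.random.default_rng(5).normal(size=(3, 16))
        p1 = net.predict_proba(X)
        path = tmp_path / "model.json"
        save_model(net, path)
        p2 = load_model(path).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_seeded_init_is_deterministic(self):
        spec = build_litenet_extended(16, 1)
        n1, n2 = Network(spec, seed=8), Network(spec, seed=8)
        for name in n1.params:
            for p in n1.params[name]:
                assert np.array_equal(n1.params[name][p], n2.params[name][p])
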