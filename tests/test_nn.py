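"""Engine correctness: finite-difference gradient checks and the
equivalence of the FFT-fused entry block with its naive layer chain."""

import numpy as np
import pytest

from mbeeg.nn import (
    AvgPool,
    BatchNorm,
    Dense,
    DepthwiseSpatialConv,
    Dropout,
    ELU,
    Flatten,
    FusedEntry,
    LogActivation,
    SeparableConv,
    SpatialConv,
    Square,
    TemporalConv,
    softmax,
    softmax_cross_entropy,
)

RNG = np.random.default_rng(2024)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def check_layer_grads(layer, x, training=True, rtol=1e-5, check_input=True, rng_seed=None):
    """Analytic vs central-difference gradients for params and the input."""
    r = np.abs(RNG.standard_normal(1))  # keep RNG progressing between calls

    def run():
        rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
        out = layer.forward(x, training=training, rng=rng)
        return float((out * weights).sum())

    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    out = layer.forward(x, training=training, rng=rng)
    weights = np.asarray(RNG.standard_normal(out.shape))
    # rebuild forward with the fixed projection
    loss = run()
    for p in layer.params():
        p.zero_grad()
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    layer.forward(x, training=training, rng=rng)
    dx = layer.backward(weights.astype(x.dtype))
    for p in layer.params():
        num = numeric_grad(run, p.value)
        np.testing.assert_allclose(p.grad, num, rtol=rtol, atol=1e-6, err_msg=p.name)
    if check_input and dx is not None:
        num = numeric_grad(run, x)
        np.testing.assert_allclose(dx, num, rtol=rtol, atol=1e-6)


@pytest.mark.parametrize(
    "layer_factory,shape,kwargs",
    [
        (lambda: TemporalConv(3, 5, "same", rng=np.random.default_rng(1), dtype=np.float64), (2, 3, 12), {}),
        (lambda: TemporalConv(2, 4, "valid", rng=np.random.default_rng(2), dtype=np.float64), (2, 3, 12), {}),
        (lambda: DepthwiseSpatialConv(3, 2, 2, rng=np.random.default_rng(3), dtype=np.float64), (2, 3, 7, 2), {}),
        (lambda: SpatialConv(3, 2, 4, rng=np.random.default_rng(4), dtype=np.float64), (2, 3, 7, 2), {}),
        (lambda: BatchNorm(3, dtype=np.float64), (4, 6, 3), {}),
        (lambda: SeparableConv(3, 4, 5, rng=np.random.default_rng(5), dtype=np.float64), (2, 9, 3), {}),
        (lambda: Dense(5, 3, rng=np.random.default_rng(6), dtype=np.float64), (4, 5), {}),
        (lambda: AvgPool(3), (2, 9, 3), {}),
        (lambda: AvgPool(4, 2), (2, 11, 3), {}),
        (lambda: ELU(), (3, 5, 2), {}),
        (lambda: Square(), (3, 5, 2), {}),
        (lambda: LogActivation(), (3, 5, 2), {"positive": True}),
    ],
)
def test_layer_gradients_match_finite_differences(layer_factory, shape, kwargs):
    x = RNG.standard_normal(shape)
    if kwargs.get("positive"):
        x = np.abs(x) + 0.5
    check_layer_grads(layer_factory(), x)


def test_batchnorm_inference_gradients():
    bn = BatchNorm(3, dtype=np.float64)
    bn.running_mean[:] = [0.3, -0.2, 0.1]
    bn.running_var[:] = [1.5, 0.7, 2.0]
    x = RNG.standard_normal((4, 6, 3))
    check_layer_grads(bn, x, training=False)


def test_dropout_scales_and_masks():
    drop = Dropout(0.5)
    x = np.ones((200, 50))
    out = drop.forward(x, training=True, rng=np.random.default_rng(0))
    kept = out != 0
    assert out[kept].mean() == pytest.approx(2.0)  # inverted scaling
    assert 0.4 < kept.mean() < 0.6
    # inference is identity
    np.testing.assert_array_equal(drop.forward(x, training=False), x)
    # rate 0 is identity even in training
    d0 = Dropout(0.0)
    np.testing.assert_array_equal(d0.forward(x, training=True, rng=np.random.default_rng(0)), x)


def test_softmax_cross_entropy_reference_values():
    logits = np.zeros((2, 4))
    labels = np.array([0, 3])
    loss, grad = softmax_cross_entropy(logits, labels)
    assert loss == pytest.approx(np.log(4))  # uniform prediction over 4 classes
    # one-hot-correct prediction has ~zero loss
    hot = np.full((1, 4), -1e3)
    hot[0, 2] = 1e3
    loss_hot, _ = softmax_cross_entropy(hot, np.array([2]))
    assert loss_hot == pytest.approx(0.0, abs=1e-6)
    # base-2 evaluation rescales by 1/log(2)
    loss2, _ = softmax_cross_entropy(logits, labels, log_base=2.0)
    assert loss2 == pytest.approx(2.0)  # log2(4)


def test_softmax_cross_entropy_gradient():
    logits = RNG.standard_normal((3, 4))
    labels = np.array([1, 0, 3])

    def f():
        return softmax_cross_entropy(logits, labels)[0]

    _, grad = softmax_cross_entropy(logits, labels)
    num = numeric_grad(f, logits)
    np.testing.assert_allclose(grad, num, rtol=1e-6, atol=1e-8)


def test_softmax_rows_are_probabilities():
    p = softmax(RNG.standard_normal((10, 4)) * 10)
    assert np.all(p >= 0)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestFusedEntryEquivalence:
    """The FFT-fused block must match temporal conv -> BN -> depthwise exactly."""

    @pytest.mark.parametrize("n,e,t,ke,f1,d", [
        (3, 5, 50, 7, 3, 2),    # odd kernel, fast Gram path
        (2, 4, 40, 8, 2, 1),    # even kernel, D = 1
        (4, 22, 200, 64, 4, 2), # realistic electrode count, large kernel
        (2, 3, 16, 16, 2, 2),   # tiny input: direct Gram fallback, KE = T
        (3, 2, 9, 7, 3, 2),     # tiny input, odd sizes
    ])
    @pytest.mark.parametrize("training", [True, False])
    def test_forward_backward_and_stats_match_naive_path(self, n, e, t, ke, f1, d, training):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((n, e, t))
        fused = FusedEntry(e, t, f1, ke, d, dtype=np.float64, rng=np.random.default_rng(7))
        conv = TemporalConv(f1, ke, "same", rng=np.random.default_rng(1), dtype=np.float64)
        bn = BatchNorm(f1, dtype=np.float64)
        dw = DepthwiseSpatialConv(e, f1, d, rng=np.random.default_rng(2), dtype=np.float64)
        conv.w.value[...] = fused.wt.value
        dw.w.value[...] = fused.wdw.value
        gamma, beta = rng.standard_normal(f1), rng.standard_normal(f1)
        for obj in (fused, bn):
            obj.gamma.value[...] = gamma
            obj.beta.value[...] = beta

        out_f = fused.forward(x, training=training)
        out_n = dw.forward(bn.forward(conv.forward(x, training=training), training=training),
                           training=training)
        np.testing.assert_allclose(out_f, out_n, atol=1e-10)

        dz = rng.standard_normal(out_f.shape)
        fused.backward(dz)
        conv.backward(bn.backward(dw.backward(dz)))
        np.testing.assert_allclose(fused.wt.grad, conv.w.grad, atol=1e-10)
        np.testing.assert_allclose(fused.gamma.grad, bn.gamma.grad, atol=1e-10)
        np.testing.assert_allclose(fused.beta.grad, bn.beta.grad, atol=1e-10)
        np.testing.assert_allclose(fused.wdw.grad, dw.w.grad, atol=1e-10)
        if training:
            np.testing.assert_allclose(fused.running_mean, bn.running_mean, atol=1e-12)
            np.testing.assert_allclose(fused.running_var, bn.running_var, atol=1e-12)

    def test_shared_fft_length_is_equivalent(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((2, 4, 60))
        a = FusedEntry(4, 60, 2, 8, 2, dtype=np.float64, rng=np.random.default_rng(3))
        b = FusedEntry(4, 60, 2, 8, 2, fft_length=256, dtype=np.float64,
                       rng=np.random.default_rng(3))
        np.testing.assert_allclose(a.forward(x, training=True), b.forward(x, training=True),
                                   atol=1e-10)

    def test_float32_training_matches_float64_closely(self):
        rng = np.random.default_rng(11)
        x64 = rng.standard_normal((4, 6, 100))
        f64 = FusedEntry(6, 100, 3, 16, 2, dtype=np.float64, rng=np.random.default_rng(4))
        f32 = FusedEntry(6, 100, 3, 16, 2, dtype=np.float32, rng=np.random.default_rng(4))
        out64 = f64.forward(x64, training=True)
        out32 = f32.forward(x64.astype(np.float32), training=True)
        np.testing.assert_allclose(out32, out64, atol=5e-3)
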