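"""Finite-difference verification of every backward pass in the NN core."""

import numpy as np
import pytest

from lesionseg import nn


def numerical_grad(f, x, eps=1e-3):
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(build_loss, tensors, rtol=2e-2, atol=2e-3):
    """Compare analytic gradients of a scalar loss against finite differences."""
    loss = build_loss()
    loss.backward()
    for t in tensors:
        assert t.grad is not None
        ng = numerical_grad(lambda: float(build_loss().data), t.data)
        np.testing.assert_allclose(t.grad, ng, rtol=rtol, atol=atol)


def _loss_of(t):
    """Smooth scalar functional of a tensor output for gradient checking."""
    return nn.bce_loss(nn.sigmoid(t), np.zeros(t.data.shape, dtype=np.float32))


@pytest.mark.parametrize("stride,pad,kernel", [(1, 1, 3), (2, 0, 1), (1, 0, 1)])
def test_conv2d_gradients(rng, stride, pad, kernel):
    x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32), requires_grad=True)
    w = nn.Tensor(0.4 * rng.normal(size=(4, 3, kernel, kernel)).astype(np.float32), requires_grad=True)
    b = nn.Tensor(rng.normal(size=4).astype(np.float32) * 0.1, requires_grad=True)
    assert_grad_matches(lambda: _loss_of(nn.conv2d(x, w, b, stride=stride, pad=pad)), [x, w, b])


def test_conv2d_channel_mismatch_raises(rng):
    x = nn.Tensor(rng.normal(size=(1, 2, 4, 4)))
    w = nn.Tensor(rng.normal(size=(4, 3, 3, 3)))
    with pytest.raises(ValueError, match="channel mismatch"):
        nn.conv2d(x, w, None, pad=1)


@pytest.mark.parametrize("training", [True, False])
def test_batch_norm_gradients(rng, training):
    x = nn.Tensor(rng.normal(size=(3, 2, 4, 4)).astype(np.float32), requires_grad=True)
    gamma = nn.Tensor(rng.uniform(0.5, 1.5, 2).astype(np.float32), requires_grad=True)
    beta = nn.Tensor(rng.normal(size=2).astype(np.float32), requires_grad=True)

    def build():
        # fresh buffers per call so training-mode running stats do not drift
        rm = np.zeros(2, dtype=np.float32)
        rv = np.ones(2, dtype=np.float32)
        return _loss_of(nn.batch_norm2d(x, gamma, beta, rm, rv, training=training))

    assert_grad_matches(build, [x, gamma, beta])


def test_batch_norm_eval_uses_running_stats(rng):
    x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)).astype(np.float32))
    gamma = nn.Tensor(np.ones(3), requires_grad=True)
    beta = nn.Tensor(np.zeros(3), requires_grad=True)
    rm = np.zeros(3, dtype=np.float32)
    rv = np.ones(3, dtype=np.float32)
    out = nn.batch_norm2d(x, gamma, beta, rm, rv, training=False, eps=0.0)
    np.testing.assert_allclose(out.data, x.data, rtol=1e-6)


def test_max_pool_gradients(rng):
    x = nn.Tensor(rng.normal(size=(2, 2, 4, 4)).astype(np.float32), requires_grad=True)
    assert_grad_matches(lambda: _loss_of(nn.max_pool2x2(x)), [x])


def test_max_pool_odd_dims_raise(rng):
    with pytest.raises(ValueError, match="even"):
        nn.max_pool2x2(nn.Tensor(rng.normal(size=(1, 1, 3, 4))))


def test_upsample_nearest_gradients(rng):
    x = nn.Tensor(rng.normal(size=(2, 2, 3, 3)).astype(np.float32), requires_grad=True)
    assert_grad_matches(lambda: _loss_of(nn.upsample_nearest2x(x)), [x])


def test_bilinear_resize_gradients(rng):
    x = nn.Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32), requires_grad=True)
    assert_grad_matches(lambda: _loss_of(nn.resize_bilinear(x, (6, 6))), [x])


def test_bilinear_resize_identity(rng):
    x = nn.Tensor(rng.normal(size=(1, 1, 5, 7)).astype(np.float32))
    np.testing.assert_allclose(nn.resize_bilinear(x, (5, 7)).data, x.data, atol=1e-6)


def test_bilinear_resize_preserves_constant(rng):
    x = nn.Tensor(np.full((1, 1, 4, 4), 3.25, dtype=np.float32))
    out = nn.resize_bilinear(x, (8, 8)).data
    np.testing.assert_allclose(out, 3.25, rtol=1e-6)


def test_concat_and_mul_gradients(rng):
    a = nn.Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32), requires_grad=True)
    b = nn.Tensor(rng.normal(size=(1, 3, 3, 3)).astype(np.float32), requires_grad=True)
    alpha = nn.Tensor(rng.uniform(0.1, 0.9, (1, 1, 3, 3)).astype(np.float32), requires_grad=True)

    def build():
        cat = nn.concat_channels([a, b])
        return _loss_of(nn.mul(alpha, cat))  # broadcast over channels

    assert_grad_matches(build, [a, b, alpha])


def test_bce_loss_gradients(rng):
    logits = nn.Tensor(rng.normal(size=(2, 1, 3, 3)).astype(np.float32), requires_grad=True)
    y = (rng.random((2, 1, 3, 3)) < 0.5).astype(np.float32)
    assert_grad_matches(lambda: nn.bce_loss(nn.sigmoid(logits), y), [logits])


def test_soft_dice_loss_gradients(rng):
    logits = nn.Tensor(rng.normal(size=(2, 1, 3, 3)).astype(np.float32), requires_grad=True)
    y = (rng.random((2, 1, 3, 3)) < 0.5).astype(np.float32)
    assert_grad_matches(lambda: nn.soft_dice_loss(nn.sigmoid(logits), y), [logits])


def test_adam_minimizes_quadratic():
    p = nn.Tensor(np.array([5.0, -3.0], dtype=np.float32), requires_grad=True)
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        p.grad = 2.0 * p.data  # gradient of |p|^2
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_module_state_dict_round_trip(rng):
    conv = nn.Conv2d(3, 4, 3, rng=rng)
    bn = nn.BatchNorm2d(4)

    class Net(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = conv
            self.bn = bn

        def forward(self, x):
            return nn.relu(self.bn(self.conv(x)))

    net = Net()
    state = net.state_dict()
    net2 = Net()
    net2.conv.weight.data[...] = 0.0
    net2.load_state_dict(state)
    x = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)
    net.eval(), net2.eval()
    np.testing.assert_array_equal(net(nn.Tensor(x)).data, net2(nn.Tensor(x)).data)


def test_load_state_dict_rejects_extra_keys(rng):
    conv = nn.Conv2d(2, 2, 1, pad=0, rng=rng)

    class Net(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = conv

    net = Net()
    state = net.state_dict()
    state["bogus"] = np.zeros(1)
    with pytest.raises(ValueError, match="state mismatch"):
        net.load_state_dict(state)
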