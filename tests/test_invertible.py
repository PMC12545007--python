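"""Contracts of the invertible layer primitives: exact inverses, analytic
log-determinants against brute-force Jacobians, and the fixed hand-computed
examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegflow.autodiff import Tensor
from eegflow.invertible import (
    ActNorm,
    AdditiveCoupling,
    HaarSqueeze,
    InvLinear,
    actnorm_apply,
    additive_coupling_apply,
    haar_squeeze,
    invlinear_apply,
)

from conftest import brute_force_logdet

rng = np.random.default_rng(7)


def _random_actnorm(c):
    p = ActNorm(c)
    p.log_scale.data = rng.standard_normal(c) * 0.5
    p.shift.data = rng.standard_normal(c)
    return p


def _random_coupling(c, swap=False):
    layer = AdditiveCoupling(c, swap=swap, rng=rng)
    layer.subnet.w2.data = rng.standard_normal(layer.subnet.w2.data.shape) * 0.5
    layer.subnet.b2.data = rng.standard_normal(layer.subnet.b2.data.shape) * 0.1
    return layer


# ---------------------------------------------------------------- actnorm
def test_actnorm_identity_at_init():
    x = rng.standard_normal((3, 6))
    y, logdet = actnorm_apply(x, ActNorm(3))
    np.testing.assert_array_equal(y, x)
    assert logdet == 0.0


def test_actnorm_hand_example():
    # 1 channel, scale 2, shift 1: [[1,2]] -> [[3,5]], logdet = 2 ln 2
    p = ActNorm(1)
    p.log_scale.data = np.array([np.log(2.0)])
    p.shift.data = np.array([1.0])
    y, logdet = actnorm_apply(np.array([[1.0, 2.0]]), p)
    np.testing.assert_allclose(y, [[3.0, 5.0]])
    np.testing.assert_allclose(logdet, 2 * np.log(2.0))


def test_actnorm_shape_error_names_channels():
    with pytest.raises(ValueError, match="expected 3 channels"):
        actnorm_apply(np.zeros((4, 5)), ActNorm(3))


# ---------------------------------------------------------------- invlinear
def test_invlinear_identity():
    x = rng.standard_normal((4, 5))
    y, logdet = invlinear_apply(x, InvLinear(4))
    np.testing.assert_array_equal(y, x)
    assert logdet == 0.0


def test_invlinear_diagonal_logdet():
    p = InvLinear(2)
    p.weight.data = np.array([[2.0, 0.0], [0.0, 3.0]])
    x = rng.standard_normal((2, 4))
    _, logdet = invlinear_apply(x, p)
    np.testing.assert_allclose(logdet, 4 * np.log(6.0))


def test_invlinear_orthogonal_logdet_zero():
    p = InvLinear(5, rng=rng)  # random orthogonal init
    _, logdet = invlinear_apply(rng.standard_normal((5, 3)), p)
    assert abs(logdet) < 1e-5


def test_invlinear_singular_weight_rejected():
    p = InvLinear(2)
    p.weight.data = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(np.linalg.LinAlgError, match="singular"):
        invlinear_apply(rng.standard_normal((2, 3)), p)


# ---------------------------------------------------------------- coupling
def test_coupling_zero_init_is_identity():
    layer = AdditiveCoupling(4, rng=rng)  # final conv zero-initialized
    x = rng.standard_normal((4, 6))
    y, logdet = additive_coupling_apply(x, layer)
    np.testing.assert_array_equal(y, x)
    assert logdet == 0.0


@pytest.mark.parametrize("swap", [False, True])
def test_coupling_logdet_always_zero_and_passthrough_half(swap):
    layer = _random_coupling(6, swap=swap)
    x = rng.standard_normal((6, 8))
    y, logdet = additive_coupling_apply(x, layer)
    assert logdet == 0.0
    if swap:
        np.testing.assert_array_equal(y[:3], x[:3])
        assert not np.allclose(y[3:], x[3:])
    else:
        np.testing.assert_array_equal(y[3:], x[3:])
        assert not np.allclose(y[:3], x[:3])


def test_coupling_odd_channels_rejected():
    with pytest.raises(ValueError, match="even channel count"):
        AdditiveCoupling(5)


# ---------------------------------------------------------------- haar
def test_haar_hand_example():
    y, logdet = haar_squeeze(np.array([[1.0, 3.0]]))
    np.testing.assert_allclose(y, [[2.0], [-2.0]])
    assert logdet == 0.0


def test_haar_constant_signal_zero_differences():
    x = np.full((3, 8), 4.2)
    y, _ = haar_squeeze(x)
    np.testing.assert_array_equal(y[3:], np.zeros((3, 4)))
    np.testing.assert_allclose(y[:3], np.full((3, 4), 4.2))


def test_haar_preserves_total_dimension():
    x = rng.standard_normal((3, 8))
    y, _ = haar_squeeze(x)
    assert y.size == x.size and y.shape == (6, 4)


def test_haar_odd_time_rejected():
    with pytest.raises(ValueError, match="even number of time points"):
        haar_squeeze(np.zeros((2, 5)))


# ------------------------------------------------------- shared properties
LAYER_FACTORIES = {
    "actnorm": lambda: _random_actnorm(4),
    "invlinear": lambda: InvLinear(4, rng=rng),
    "coupling": lambda: _random_coupling(4),
    "coupling-swap": lambda: _random_coupling(4, swap=True),
    "haar": lambda: HaarSqueeze(),
}


@pytest.mark.parametrize("name", list(LAYER_FACTORIES))
@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_roundtrip_identity(name, seed):
    layer = LAYER_FACTORIES[name]()
    x = np.random.default_rng(seed).standard_normal((4, 8))
    if name == "haar":
        y, _ = haar_squeeze(x)
        xr, _ = haar_squeeze(y, "inverse")
    else:
        apply = {"actnorm": actnorm_apply, "invlinear": invlinear_apply}.get(
            name, additive_coupling_apply
        )
        y, ld_f = apply(x, layer)
        xr, ld_i = apply(y, layer, "inverse")
        assert abs(ld_f + ld_i) < 1e-9  # inverse logdet is the negative
    np.testing.assert_allclose(xr, x, atol=1e-9)


@pytest.mark.parametrize("name", list(LAYER_FACTORIES))
def test_analytic_logdet_matches_brute_force_jacobian(name):
    layer = LAYER_FACTORIES[name]()
    x0 = np.random.default_rng(3).standard_normal((4, 2))
    if name == "haar":
        fwd = lambda v: haar_squeeze(v)[0].ravel()
        _, analytic = haar_squeeze(x0)
    else:
        apply = {"actnorm": actnorm_apply, "invlinear": invlinear_apply}.get(
            name, additive_coupling_apply
        )
        fwd = lambda v: apply(v, layer)[0].ravel()
        _, analytic = apply(x0, layer)
    np.testing.assert_allclose(analytic, brute_force_logdet(fwd, x0), atol=1e-3)


def test_stack_logdet_is_sum_of_layers():
    layers = [_random_actnorm(4), InvLinear(4, rng=rng), _random_coupling(4)]
    applies = [actnorm_apply, invlinear_apply, additive_coupling_apply]
    x = rng.standard_normal((4, 6))
    total = 0.0
    parts = []
    h = x
    for layer, apply in zip(layers, applies):
        h, ld = apply(h, layer)
        parts.append(ld)
        total += ld
    # brute-force on the composed map
    def composed(v):
        out = v
        for layer, apply in zip(layers, applies):
            out, _ = apply(out, layer)
        return out.ravel()

    np.testing.assert_allclose(total, sum(parts))
    x_small = rng.standard_normal((4, 2))
    per_layer_sum, h = 0.0, x_small
    for layer, apply in zip(layers, applies):
        h, ld = apply(h, layer)
        per_layer_sum += ld
    np.testing.assert_allclose(brute_force_logdet(composed, x_small), per_layer_sum, atol=1e-3)


def test_nonfinite_input_rejected():
    x = np.full((4, 4), np.nan)
    with pytest.raises(ValueError, match="non-finite"):
        actnorm_apply(x, ActNorm(4))
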