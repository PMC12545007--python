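import numpy as np
import pytest

from eegflow.invnet import EEGInvNet, EEGInvNetConfig
from eegflow.synthetic import GeneratorConfig, generate_windows


def numerical_gradient(fn, x, eps=1e-6):
    """Central finite-difference gradient of scalar fn at x (any shape)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


def brute_force_logdet(fn, x0, eps=1e-6):
    """log|det J| of a vector-to-vector map by finite differences."""
    v0 = x0.ravel()
    d = v0.size
    J = np.zeros((d, d))
    for i in range(d):
        vp, vm = v0.copy(), v0.copy()
        vp[i] += eps
        vm[i] -= eps
        J[:, i] = (fn(vp.reshape(x0.shape)) - fn(vm.reshape(x0.shape))) / (2 * eps)
    sign, ld = np.linalg.slogdet(J)
    assert sign != 0
    return ld


@pytest.fixture(scope="session")
def tiny_trained_invnet():
    """A small invertible classifier trained briefly on a small synthetic set.

    Shared across tests that need *a* trained model but not a high-accuracy one.
    """
    store = generate_windows(GeneratorConfig(n_recordings_per_class=20, duration_s=20.0, seed=11))
    train, evaluation = store.train_eval()
    model = EEGInvNet(EEGInvNetConfig(n_stages=2, blocks_per_stage=2), seed=11)
    model.train((train.windows, train.labels), epochs=4, seed=11)
    return model, store


@pytest.fixture(scope="session")
def small_store():
    return generate_windows(GeneratorConfig(n_recordings_per_class=10, duration_s=10.0, seed=5))
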