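"""Model-level contracts of the invertible generative classifier: stage
shapes, bijectivity, likelihood against a brute-force oracle, the
classification rule, the combined loss, and the training loop contracts."""

import numpy as np
import pytest

from eegflow.invertible import ActNorm, AdditiveCoupling
from eegflow.invnet import EEGInvNet, EEGInvNetConfig
from eegflow.optim import cosine_restart_lr
from eegflow.synthetic import GeneratorConfig, generate_windows

from conftest import brute_force_logdet

rng = np.random.default_rng(13)


def _randomize(model, scale=0.3, seed=1):
    r = np.random.default_rng(seed)
    for layer in model.layers:
        if isinstance(layer, AdditiveCoupling):
            layer.subnet.w2.data = r.standard_normal(layer.subnet.w2.data.shape) * scale
        if isinstance(layer, ActNorm):
            layer.log_scale.data = r.standard_normal(layer.log_scale.data.shape) * scale
            layer.shift.data = r.standard_normal(layer.shift.data.shape) * scale
    return model


def _tiny_model(seed=2):
    cfg = EEGInvNetConfig(n_electrodes=2, window_samples=4, n_stages=1, blocks_per_stage=2)
    return _randomize(EEGInvNet(cfg, seed=seed), seed=seed)


def test_stage_shapes_for_default_config():
    cfg = EEGInvNetConfig()
    assert cfg.stage_shapes == [(42, 64), (84, 32), (168, 16)]
    assert cfg.dim == 21 * 128 == 2688


def test_window_samples_must_be_divisible_by_squeezes():
    with pytest.raises(ValueError, match="divisible"):
        EEGInvNetConfig(window_samples=100, n_stages=3)


def test_full_net_roundtrip_and_shape_errors():
    model = _randomize(EEGInvNet(EEGInvNetConfig(n_stages=2, blocks_per_stage=2), seed=0))
    x = rng.standard_normal((4, 21, 128))
    state = model.net_forward(x)
    assert state.z.shape == (4, 2688)
    np.testing.assert_allclose(model.net_inverse(state.z), x, atol=1e-9)
    with pytest.raises(ValueError, match="does not match"):
        model.net_forward(np.zeros((4, 20, 128)))


def test_logdet_is_sum_of_layer_logdets():
    model = _tiny_model()
    x = rng.standard_normal((1, 2, 4))
    total = model.net_forward(x).logdet
    from eegflow.autodiff import Tensor

    h, acc = Tensor(x), 0.0
    for layer in model.layers:
        h, ld = layer.forward(h)
        acc += float(ld.data)
    np.testing.assert_allclose(total, acc, rtol=1e-12)


def test_log_prob_standard_normal_at_mode():
    # identity flow (couplings zero-initialized, actnorm/invlinear at identity):
    # log p of the zero window under a standard-normal prior is -(d/2) ln(2 pi)
    cfg = EEGInvNetConfig(n_electrodes=2, window_samples=4, n_stages=1, blocks_per_stage=1)
    model = EEGInvNet(cfg, seed=99)
    # reset the invertible linear layer to the identity
    for layer in model.layers:
        if hasattr(layer, "weight"):
            layer.weight.data = np.eye(layer.weight.data.shape[0])
    x = np.zeros((2, 4))
    d = cfg.dim
    np.testing.assert_allclose(model.log_prob(x, 0), -(d / 2) * np.log(2 * np.pi), rtol=1e-12)


def test_log_prob_matches_brute_force_oracle():
    model = _tiny_model(seed=3)
    x0 = rng.standard_normal((2, 4))
    z = model.net_forward(x0[None]).z[0]
    fwd = lambda v: model.net_forward(v[None]).z[0]
    ld = brute_force_logdet(fwd, x0)
    mean, log_std = model.class_means.data[1], model.class_log_stds.data[1]
    std = np.exp(log_std)
    prior = -0.5 * np.sum(((z - mean) / std) ** 2) - np.sum(log_std) - (len(z) / 2) * np.log(2 * np.pi)
    np.testing.assert_allclose(model.log_prob(x0, 1), prior + ld, atol=1e-3)


def test_log_prob_decreases_away_from_prior_mean():
    model = _tiny_model(seed=4)
    z0 = model.class_means.data[0].copy()
    lps = []
    for r in (0.0, 1.0, 3.0):
        z = z0 + r * np.ones_like(z0)
        x = model.net_inverse(z)
        lps.append(model.log_prob(x, 0))
    assert lps[0] > lps[1] > lps[2]


def test_classify_symmetry_and_bayes_agreement():
    model = _tiny_model(seed=5)
    x = rng.standard_normal((3, 2, 4))
    # equal priors for both classes -> posterior (0.5, 0.5) for any x
    model.class_means.data[1] = model.class_means.data[0]
    model.class_log_stds.data[1] = model.class_log_stds.data[0]
    np.testing.assert_allclose(model.classify(x), 0.5)
    # distinct priors: agreement with Bayes rule from the two log-probs
    model.class_means.data[1] += 0.7
    lp = model.log_prob_all(x) / model.temperature
    expected = np.exp(lp) / np.exp(lp).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(model.classify(x), expected, atol=1e-12)
    # posterior sums to one and is invariant to a constant shift of both log-probs
    np.testing.assert_allclose(model.classify(x).sum(axis=1), 1.0)


def test_temperature_limit_flattens_posterior():
    model = _tiny_model(seed=6)
    model.class_means.data[1] += 2.0
    x = rng.standard_normal((2, 2, 4))
    model.log_t.data = np.array(30.0)  # t = e^30
    np.testing.assert_allclose(model.classify(x), 0.5, atol=1e-6)


def test_loss_alpha_from_config_and_ln2_at_equal_likelihoods():
    cfg = EEGInvNetConfig()
    assert cfg.alpha == 1.0 / 2688
    model = _tiny_model(seed=7)
    model.class_means.data[1] = model.class_means.data[0]
    model.class_log_stds.data[1] = model.class_log_stds.data[0]
    x = rng.standard_normal((2, 4))
    # both class log-probs equal -> classification term is exactly ln 2
    loss = model.training_loss(x, 1)
    lp = model.log_prob_all(x)
    scale_const = 0.0  # channel_scale is ones here
    expected = np.log(2.0) - model.alpha * (lp[1] - scale_const)
    np.testing.assert_allclose(loss, expected, rtol=1e-10)


def test_loss_equals_hand_assembled_terms():
    model = _tiny_model(seed=8)
    model.class_means.data[1] += 0.5
    x = rng.standard_normal((2, 4))
    lp = model.log_prob_all(x)
    t = model.temperature
    logits = lp / t
    clf = -(logits[1] - np.log(np.exp(logits).sum()))
    gen = -model.alpha * lp[1]
    np.testing.assert_allclose(model.training_loss(x, 1), clf + gen, rtol=1e-10)


def test_restart_schedule_returns_to_maximum():
    lrs = [cosine_restart_lr(1e-3, e, period=25) for e in range(76)]
    assert lrs[0] == lrs[25] == lrs[50] == lrs[75] == 1e-3
    assert lrs[12] < lrs[0]
    assert lrs[24] == min(lrs[:25])


def test_training_is_deterministic_and_recovers_planted_shift():
    store = generate_windows(GeneratorConfig(n_recordings_per_class=15, duration_s=16.0, seed=21))
    train, evaluation = store.train_eval()
    cfg = EEGInvNetConfig(n_stages=1, blocks_per_stage=2)

    def run():
        m = EEGInvNet(cfg, seed=0)
        h = m.train((train.windows, train.labels), epochs=3, seed=0)
        return m, h

    m1, h1 = run()
    m2, h2 = run()
    assert h1.loss == h2.loss  # bitwise-identical loss curves
    for (k, p1), p2 in zip(m1.named_parameters().items(), m2.named_parameters().values()):
        np.testing.assert_array_equal(p1.data, p2.data, err_msg=k)
    assert h1.accuracy[-1] > 0.8  # planted class differences are learnable


def test_training_roundtrip_preserved_and_history_logged(tiny_trained_invnet):
    model, store = tiny_trained_invnet
    x = store.windows[:8] / model.channel_scale[:, None]
    z = model.net_forward(x).z
    np.testing.assert_allclose(model.net_inverse(z), x, atol=1e-6)
    model.check_invertible_weights()


def test_checkpoint_roundtrip(tmp_path, tiny_trained_invnet):
    model, store = tiny_trained_invnet
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = type(model).load(path)
    x = store.windows[:5]
    np.testing.assert_array_equal(loaded.predict(x), model.predict(x))
    np.testing.assert_allclose(loaded.log_prob_all(x), model.log_prob_all(x), rtol=1e-12)
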