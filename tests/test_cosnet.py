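"""The compact cosine-similarity network: forward contracts, distillation,
and the filter-to-pattern (Haufe) transforms."""

import numpy as np
import pytest

from eegflow.cosnet import (
    EEGCosNet,
    PatternSet,
    agreement,
    cosnet_forward,
    distill,
    rank_filters,
    to_patterns,
)
from eegflow.synthetic import single_source_windows

rng = np.random.default_rng(51)


def _toy_net(n_electrodes=1, n_filters=1, filter_length=2):
    net = EEGCosNet(n_electrodes, n_filters, filter_length, seed=0)
    net.Ws.data = np.ones((n_electrodes, n_filters))
    return net


def test_hand_computed_single_offset():
    # 1 electrode, x = [3, 4], f = [1, 0]: |cos| = 3/5
    net = _toy_net()
    net.f.data = np.array([[1.0, 0.0]])
    net.Wc.data = np.array([[1.0]])
    p, h3 = cosnet_forward(np.array([[3.0, 4.0]]), net)
    np.testing.assert_allclose(h3, [0.6])
    np.testing.assert_allclose(p, 1 / (1 + np.exp(-0.6)))


def test_collinear_segment_gives_one_orthogonal_gives_zero():
    net = _toy_net(filter_length=4)
    net.f.data = rng.standard_normal((1, 4))
    for factor in (2.5, -1.25):
        _, h3 = cosnet_forward(factor * net.f.data, net)
        np.testing.assert_allclose(h3, [1.0])
    # signal orthogonal to f at every offset
    f = np.array([[1.0, 0.0, -1.0, 0.0]])
    net.f.data = f
    x = np.array([[1.0, 0.0, 1.0, 0.0]])
    _, h3 = cosnet_forward(x, net)
    np.testing.assert_allclose(h3, [0.0], atol=1e-12)


def test_feature_bounds_and_offset_count():
    net = EEGCosNet(n_electrodes=21, n_filters=16, filter_length=64, seed=1)
    x = rng.standard_normal((8, 21, 128))
    from eegflow.autodiff import Tensor

    _, h3, h2 = net._forward_t(Tensor(x))
    assert h2.shape == (8, 16, 65)  # T=128, L=64 -> 65 valid offsets
    assert np.all(h2.data >= 0) and np.all(h2.data <= 1 + 1e-12)
    assert np.all(h3.data >= 0) and np.all(h3.data <= 1 + 1e-12)


def test_sign_flip_invariance_of_paired_filters():
    net = EEGCosNet(n_electrodes=4, n_filters=3, filter_length=8, seed=2)
    net.Wc.data = rng.standard_normal((3, 1))
    x = rng.standard_normal((5, 4, 16))
    p0, _ = net.forward(x)
    net.Ws.data[:, 1] *= -1
    net.f.data[1] *= -1
    p1, _ = net.forward(x)
    np.testing.assert_allclose(p0, p1, rtol=1e-12)


def test_window_shorter_than_filter_rejected():
    net = EEGCosNet(n_electrodes=2, n_filters=2, filter_length=8, seed=0)
    with pytest.raises(ValueError, match="filter length"):
        net.forward(np.zeros((2, 4)))


def test_zero_norm_filter_rejected():
    net = EEGCosNet(n_electrodes=2, n_filters=2, filter_length=4, seed=0)
    net.f.data[0] = 0.0
    with pytest.raises(ValueError, match="nonzero norm"):
        net.forward(np.zeros((2, 8)))


# ------------------------------------------------------------ distillation
def test_distill_misaligned_lengths_rejected():
    net = EEGCosNet(2, 2, 4, seed=0)
    with pytest.raises(ValueError, match="teacher probabilities"):
        distill(net, np.zeros((4, 2, 8)), np.full(3, 0.5), epochs=1)


def test_degenerate_teacher_drives_output_to_half():
    r = np.random.default_rng(123)
    net = EEGCosNet(n_electrodes=3, n_filters=4, filter_length=8, seed=3)
    net.Wc.data = r.standard_normal((4, 1))
    x = r.standard_normal((256, 3, 16))
    distill(net, x, np.full(256, 0.5), epochs=60, seed=0, lr=2e-2)
    p = net.predict_proba(x)
    np.testing.assert_allclose(p, 0.5, atol=0.02)
    assert p.std() < 0.01  # constant output, no residual class evidence


def test_self_distillation_recovers_teacher_labels():
    x = rng.standard_normal((600, 4, 32))
    x_eval = rng.standard_normal((200, 4, 32))
    teacher = EEGCosNet(n_electrodes=4, n_filters=4, filter_length=16, seed=4)
    teacher.Wc.data = rng.standard_normal((4, 1)) * 4.0
    teacher.bias.data = np.array(-np.median(rng.standard_normal(1)))
    probs = teacher.predict_proba(x)
    student = EEGCosNet(n_electrodes=4, n_filters=8, filter_length=16, seed=5)
    history = distill(student, x, probs, epochs=30, seed=5)
    assert "agreement" in history and len(history["agreement"]) == 30
    assert agreement(student, x_eval, teacher.predict(x_eval)) >= 0.95


# ------------------------------------------------------------ patterns
def test_white_noise_covariance_gives_patterns_equal_filters():
    net = EEGCosNet(n_electrodes=5, n_filters=3, filter_length=8, seed=6)
    x = np.random.default_rng(0).standard_normal((300, 5, 32))
    patterns = to_patterns(net, x)
    # empirical covariance of white noise is close to the identity
    np.testing.assert_allclose(patterns.electrode_covariance, np.eye(5), atol=0.05)
    np.testing.assert_allclose(patterns.spatial_patterns, net.Ws.data, atol=0.15)


def test_classifier_pattern_sign_matches_weights():
    net = EEGCosNet(n_electrodes=4, n_filters=6, filter_length=8, seed=7)
    net.Wc.data = rng.standard_normal((6, 1))
    x = rng.standard_normal((50, 4, 16))
    patterns = to_patterns(net, x)
    nonzero = patterns.classifier_patterns != 0
    assert np.all(
        np.sign(patterns.classifier_patterns[nonzero]) == np.sign(net.Wc.data[nonzero, 0])
    )


def test_covariance_needs_enough_samples():
    net = EEGCosNet(n_electrodes=8, n_filters=2, filter_length=2, seed=0)
    with pytest.raises(ValueError, match="covariance"):
        to_patterns(net, np.zeros((1, 8, 2)))


def test_haufe_recovery_on_planted_single_source():
    windows, labels, a = single_source_windows(1200, seed=3)
    student = EEGCosNet(n_electrodes=21, n_filters=6, filter_length=64, seed=8)
    soft = labels * 0.96 + 0.02
    distill(student, windows, soft, epochs=12, seed=8)
    patterns = to_patterns(student, windows)
    lead = rank_filters(patterns).order[0]
    r = np.corrcoef(patterns.spatial_patterns[:, lead], a)[0, 1]
    assert abs(r) > 0.9


# ------------------------------------------------------------ ranking
def test_rank_filters_ties_scale_invariance_and_topk():
    patterns = PatternSet(np.zeros((4, 5)), np.array([0.3, -0.1, 0.3, 0.8, -0.5]), np.eye(4))
    ranking = rank_filters(patterns, k=2)
    np.testing.assert_array_equal(ranking.order, [3, 0, 2, 1, 4])  # stable ties 0 before 2
    np.testing.assert_array_equal(ranking.top_pathological, [3, 0])
    np.testing.assert_array_equal(ranking.top_healthy, [4, 1])
    scaled = PatternSet(patterns.spatial_patterns, patterns.classifier_patterns * 7.3, np.eye(4))
    np.testing.assert_array_equal(rank_filters(scaled, k=2).order, ranking.order)
    allk = rank_filters(patterns, k=99)
    assert len(allk.top_pathological) == 5 and len(allk.top_healthy) == 5


def test_equal_weights_order_stable_by_index():
    patterns = PatternSet(np.zeros((2, 4)), np.ones(4), np.eye(2))
    np.testing.assert_array_equal(rank_filters(patterns).order, [0, 1, 2, 3])


def test_cosnet_checkpoint_roundtrip(tmp_path):
    net = EEGCosNet(n_electrodes=3, n_filters=4, filter_length=8, seed=9)
    net.Wc.data = rng.standard_normal((4, 1))
    net.save(tmp_path / "cosnet.npz")
    loaded = EEGCosNet.load(tmp_path / "cosnet.npz")
    x = rng.standard_normal((4, 3, 16))
    np.testing.assert_array_equal(loaded.predict_proba(x), net.predict_proba(x))
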