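import numpy as np
import pytest

from nodulefpr.network import NetworkConfig, build_network
from nodulefpr.train import (
    LossConfig,
    OptimConfig,
    assign_pseudo_labels,
    combined_loss,
    consistency_loss,
    focal_loss,
    focal_loss_grad_logit,
    train,
)
from tests.conftest import make_blob_rois


# ---------------------------------------------------------------------------
# focal loss


def test_focal_loss_closed_form_value():
    # -16 * (1 - 0.5)^2 * ln(0.5) = 16 * 0.25 * ln 2
    expected = 16.0 * 0.25 * np.log(2.0)
    assert focal_loss(0.5, 1, alpha=16.0, gamma=2.0) == pytest.approx(expected, abs=1e-9)


def test_focal_loss_vanishes_for_perfect_prediction():
    assert focal_loss(1.0 - 1e-9, 1) == pytest.approx(0.0, abs=1e-4)
    assert focal_loss(1e-9, 0) == pytest.approx(0.0, abs=1e-4)


def test_focal_reduces_to_binary_cross_entropy(rng):
    """alpha=1, gamma=0 recovers textbook BCE on 1000 random cases."""
    p = rng.uniform(1e-6, 1 - 1e-6, size=1000)
    y = rng.integers(0, 2, size=1000).astype(float)
    bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))  # independent oracle
    assert focal_loss(p, y, alpha=1.0, gamma=0.0) == pytest.approx(bce, abs=1e-12)


@pytest.mark.parametrize("gamma", [0.0, 2.0])
def test_focal_gradient_matches_finite_difference(rng, gamma):
    z = rng.normal(scale=2, size=50)
    y = rng.integers(0, 2, size=50).astype(float)
    grad = focal_loss_grad_logit(z, y, alpha=16.0, gamma=gamma)
    eps = 1e-6
    from nodulefpr.nn import sigmoid

    for i in range(0, 50, 7):
        up = focal_loss(sigmoid(z[i] + eps), y[i], 16.0, gamma)
        dn = focal_loss(sigmoid(z[i] - eps), y[i], 16.0, gamma)
        assert grad[i] == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# consistency / pseudo-labels / combination


def test_consistency_gate_threshold():
    lu, gate = consistency_loss([0.97, 0.60], [0.9, 0.4], tau_c=0.95)
    assert gate.tolist() == [True, False]
    assert lu == pytest.approx(focal_loss(0.9, 1.0))


def test_consistency_gates_confident_negative():
    # weak score 0.03 has confidence 0.97: gated with hard label 0
    lu, gate = consistency_loss([0.03], [0.2], tau_c=0.95)
    assert gate.tolist() == [True]
    assert lu == pytest.approx(focal_loss(0.2, 0.0))


def test_consistency_zero_when_nothing_confident():
    lu, gate = consistency_loss([0.6, 0.4, 0.5], [0.9, 0.1, 0.5], tau_c=0.95)
    assert lu == 0.0
    assert not gate.any()


def test_pseudo_label_thresholds():
    labels = assign_pseudo_labels([0.005, 0.5, 0.995], lo=0.01, hi=0.99)
    assert labels == ["negative", "abstain", "positive"]
    # degenerate thresholds: only exact endpoints assign
    labels = assign_pseudo_labels([0.0, 0.3, 0.7, 1.0], lo=0.0, hi=1.0)
    assert labels == ["negative", "abstain", "abstain", "positive"]
    assert assign_pseudo_labels([]) == []


def test_pseudo_label_purity_beats_plain_thresholding(rng):
    """High-confidence pseudo-labels are purer than abstention-free labels.

    Simulated teacher: scores concentrate near the correct extreme with a
    heavy error tail.  Labels assigned only at (0.01, 0.99) must have an
    error rate no higher than labeling every sample at 0.5.
    """
    y = rng.integers(0, 2, size=20_000)
    correct = rng.beta(0.3, 4.0, size=y.size)  # near 0
    scores = np.where(y == 1, 1 - correct, correct)
    flip = rng.uniform(size=y.size) < 0.15
    scores = np.where(flip, 1 - scores, scores)
    labels = np.array(assign_pseudo_labels(scores, 0.01, 0.99))
    assigned = labels != "abstain"
    pseudo_err = np.mean((labels[assigned] == "positive") != (y[assigned] == 1))
    plain_err = np.mean((scores >= 0.5) != (y == 1))
    assert assigned.sum() > 100
    assert pseudo_err <= plain_err


def test_combined_loss_arithmetic():
    assert combined_loss(0.8, 0.4, 0.2, 0.5, 0.5) == pytest.approx(1.1)
    assert combined_loss(0.8, 0.4, 0.2, 0.0, 0.0) == pytest.approx(0.8)
    assert combined_loss(0.0, 0.0, 0.0) == 0.0


# ---------------------------------------------------------------------------
# training loop

_TINY_NET = NetworkConfig(conv_kernels=(2, 3, 4), fc_nodes=(6, 6),
                          conv_dropout=0.0, fc_dropout=0.0, input_shape=(8, 8, 8))
_TINY_OPT = OptimConfig(lr=3e-3, epochs=3, batch_labeled=8, batch_unlabeled=8,
                        steps_per_epoch=4)


def test_empty_unlabeled_gives_zero_unsupervised_terms(blob_rois):
    net, history = train(blob_rois, [], net_cfg=_TINY_NET, opt_cfg=_TINY_OPT, seed=0)
    assert all(state.lu == 0.0 and state.lp == 0.0 for state in history)
    with pytest.raises(ValueError):
        train([], [], net_cfg=_TINY_NET, opt_cfg=_TINY_OPT)


def test_training_deterministic(blob_rois):
    _, hist_a = train(blob_rois, [], net_cfg=_TINY_NET, opt_cfg=_TINY_OPT, seed=3)
    _, hist_b = train(blob_rois, [], net_cfg=_TINY_NET, opt_cfg=_TINY_OPT, seed=3)
    assert hist_a[-1].total == hist_b[-1].total
    assert [s.ls for s in hist_a] == [s.ls for s in hist_b]


def test_zero_lambdas_match_empty_unlabeled_weights(blob_rois):
    """With lambda1 = lambda2 = 0 and no unlabeled data the loop is the plain
    supervised focal trainer."""
    cfg0 = LossConfig(lambda1=0.0, lambda2=0.0)
    net_a, _ = train(blob_rois, [], net_cfg=_TINY_NET, loss_cfg=cfg0,
                     opt_cfg=_TINY_OPT, seed=5)
    net_b, _ = train(blob_rois, [], net_cfg=_TINY_NET, loss_cfg=LossConfig(),
                     opt_cfg=_TINY_OPT, seed=5)
    for pa, pb in zip(net_a.params(), net_b.params()):
        assert np.array_equal(pa["value"], pb["value"])


def test_loss_decomposition_identity_every_step(blob_rois):
    """Logged total equals ls + λ1·lu + λ2·lp at every step, exactly."""
    unlabeled = [r.patch for r in make_blob_rois(10, seed=9)]
    teacher, _ = train(blob_rois, [], net_cfg=_TINY_NET, opt_cfg=_TINY_OPT, seed=1)
    _, history = train(blob_rois, unlabeled, net_cfg=_TINY_NET,
                       opt_cfg=_TINY_OPT, seed=2, teacher=teacher)
    lam1 = lam2 = 0.5
    n_steps = 0
    for state in history:
        for step in state.steps:
            assert step["total"] == step["ls"] + lam1 * step["lu"] + lam2 * step["lp"]
            n_steps += 1
    assert n_steps == _TINY_OPT.epochs * _TINY_OPT.steps_per_epoch


def test_gate_fraction_grows_with_training():
    """Confidence rises as training progresses: the consistency gate passes
    more unlabeled samples at the end than at the start (majority of seeds)."""
    opt = OptimConfig(lr=3e-3, epochs=5, batch_labeled=8, batch_unlabeled=8,
                      steps_per_epoch=6)
    wins = 0
    for seed in range(5):
        labeled = make_blob_rois(20, seed=100 + seed)
        unlabeled = [r.patch for r in make_blob_rois(15, seed=200 + seed)]
        _, history = train(labeled, unlabeled, net_cfg=_TINY_NET,
                           opt_cfg=opt, seed=seed)
        if history[0].gate_fraction <= history[-1].gate_fraction:
            wins += 1
    assert wins >= 3


def test_history_is_valid_state(blob_rois):
    _, history = train(blob_rois, [], net_cfg=_TINY_NET, opt_cfg=_TINY_OPT, seed=0)
    assert [s.epoch for s in history] == list(range(_TINY_OPT.epochs))
    for state in history:
        assert 0.0 <= state.gate_fraction <= 1.0
        assert state.ls >= 0.0 and np.isfinite(state.total)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(consistency_threshold=1.5)
    with pytest.raises(ValueError):
        LossConfig(pseudo_lo=0.9, pseudo_hi=0.1)
    with pytest.raises(ValueError):
        LossConfig(focal_alpha=-1.0)
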