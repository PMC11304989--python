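"""The composite training objective and loop: L = ls + λ1·lu + λ2·lp.

Three loss terms, all focal:

* ``ls`` — supervised focal loss on the labeled stream (each sample passes
  through one uniformly chosen augmentation, identity included);
* ``lu`` — consistency loss on the unlabeled stream: the prediction on a
  strongly augmented view is pulled toward the hard label implied by the
  weakly augmented view, but only for samples whose weak-view confidence
  max(p, 1 − p) reaches a gate (0.95 by default) — early in training the
  gate passes few samples and the labeled data dominate;
* ``lp`` — pseudo-label loss: a teacher fully trained on phantom data
  scores the unlabeled set once before training; scores ≤ 0.01 / ≥ 0.99
  become negative / positive pseudo-labels, everything else abstains.

Focal loss FL(p, y) = −α (1 − p_t)^γ log p_t with p_t = p when y = 1 and
1 − p otherwise; α = 16 and γ = 2 by default (α = 1, γ = 0 recovers plain
binary cross-entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from nodulefpr import nn
from nodulefpr.augment import (
    FULL_MENU,
    STRONG_MENU,
    labeled_augment,
    strong_augment,
    weak_augment,
)
from nodulefpr.network import Network, NetworkConfig, build_network
from nodulefpr.preprocess import ROI
from nodulefpr.volumes import POSITIVE

__all__ = [
    "LossConfig",
    "OptimConfig",
    "TrainState",
    "TrainingDivergedError",
    "PSEUDO_NEGATIVE",
    "PSEUDO_POSITIVE",
    "PSEUDO_ABSTAIN",
    "focal_loss",
    "focal_loss_grad_logit",
    "consistency_loss",
    "assign_pseudo_labels",
    "combined_loss",
    "train",
]

_EPS = 1e-7

PSEUDO_NEGATIVE = "negative"
PSEUDO_POSITIVE = "positive"
PSEUDO_ABSTAIN = "abstain"


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries a state dump."""

    def __init__(self, message: str, state: Optional["TrainState"] = None):
        super().__init__(message)
        self.state = state


@dataclass
class LossConfig:
    """Weights and thresholds of the composite objective."""

    lambda1: float = 0.5  # weight of the consistency term lu
    lambda2: float = 0.5  # weight of the pseudo-label term lp
    consistency_threshold: float = 0.95
    pseudo_lo: float = 0.01
    pseudo_hi: float = 0.99
    focal_alpha: float = 16.0
    focal_gamma: float = 2.0
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.consistency_threshold < 1.0:
            raise ValueError("consistency_threshold must lie in (0, 1)")
        if not self.pseudo_lo < self.pseudo_hi:
            raise ValueError("pseudo_lo must be below pseudo_hi")
        if self.focal_alpha <= 0 or self.focal_gamma < 0:
            raise ValueError("focal parameters must satisfy alpha > 0, gamma >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")


@dataclass
class OptimConfig:
    """Optimizer / schedule knobs (free constants of the procedure)."""

    lr: float = 1e-3
    epochs: int = 50
    batch_labeled: int = 32
    batch_unlabeled: int = 32
    steps_per_epoch: Optional[int] = None  # default: labeled set / batch
    augment_magnitude: float = 1.0


@dataclass
class TrainState:
    """Per-epoch summary of the loss terms and the confidence gate."""

    epoch: int
    ls: float
    lu: float
    lp: float
    total: float
    gate_fraction: float
    steps: List[Dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gate_fraction <= 1.0:
            raise ValueError("gate fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# loss primitives


def _pt(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    return np.where(y >= 0.5, p, 1.0 - p)


def focal_loss(
    p: Union[float, np.ndarray],
    y: Union[int, np.ndarray],
    alpha: float = 16.0,
    gamma: float = 2.0,
) -> float:
    """Mean focal loss −α (1 − p_t)^γ log p_t over a batch.

    ``p`` holds predicted probabilities (epsilon-clamped away from 0 and 1),
    ``y`` the binary targets.
    """
    pt = _pt(np.atleast_1d(p), np.atleast_1d(y))
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


def focal_loss_grad_logit(
    z: np.ndarray, y: np.ndarray, alpha: float = 16.0, gamma: float = 2.0
) -> np.ndarray:
    """Per-sample ∂FL/∂logit for a sigmoid head (no batch reduction)."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    s = nn.sigmoid(z)
    pt = np.clip(np.where(y >= 0.5, s, 1.0 - s), _EPS, 1.0 - _EPS)
    one_m = 1.0 - pt
    # dL/dpt; the gamma term vanishes identically at gamma == 0
    if gamma == 0.0:
        dl_dpt = -alpha / pt
    else:
        dl_dpt = alpha * gamma * one_m ** (gamma - 1.0) * np.log(pt) - alpha * one_m**gamma / pt
    dpt_dz = np.where(y >= 0.5, s * (1.0 - s), -s * (1.0 - s))
    return dl_dpt * dpt_dz


def consistency_loss(
    weak_scores: Sequence[float],
    strong_scores: Sequence[float],
    tau_c: float = 0.95,
    alpha: float = 16.0,
    gamma: float = 2.0,
) -> Tuple[float, np.ndarray]:
    """Confidence-gated consistency term on the unlabeled stream.

    Per sample the weak-view confidence is max(p, 1 − p); samples at or
    above ``tau_c`` contribute FL(p_strong, [p_weak ≥ 0.5]).  Returns the
    mean over gated samples (exactly 0 when none pass) and the boolean gate
    mask.  Gradients never flow through the weak branch.
    """
    pw = np.asarray(weak_scores, dtype=np.float64)
    ps = np.asarray(strong_scores, dtype=np.float64)
    if pw.shape != ps.shape:
        raise ValueError("weak and strong score lists must have equal length")
    conf = np.maximum(pw, 1.0 - pw)
    gate = conf >= tau_c
    if not gate.any():
        return 0.0, gate
    hard = (pw[gate] >= 0.5).astype(np.float64)
    return focal_loss(ps[gate], hard, alpha, gamma), gate


def assign_pseudo_labels(
    teacher_scores: Sequence[float], lo: float = 0.01, hi: float = 0.99
) -> List[str]:
    """Teacher score → {negative, positive, abstain} by the two thresholds.

    A score at or below ``lo`` is a negative pseudo-label, at or above
    ``hi`` a positive one; everything between abstains.  Meant to be
    computed once before training with a teacher fully trained on phantom
    data only.
    """
    scores = np.asarray(list(teacher_scores), dtype=np.float64)
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("teacher scores must lie in [0, 1]")
    out = []
    for s in scores:
        if s <= lo:
            out.append(PSEUDO_NEGATIVE)
        elif s >= hi:
            out.append(PSEUDO_POSITIVE)
        else:
            out.append(PSEUDO_ABSTAIN)
    return out


def combined_loss(ls: float, lu: float, lp: float,
                  lambda1: float = 0.5, lambda2: float = 0.5) -> float:
    """L = ls + λ1·lu + λ2·lp."""
    return float(ls) + float(lambda1) * float(lu) + float(lambda2) * float(lp)


# ---------------------------------------------------------------------------
# training loop


def _labels_to_binary(rois: Sequence[ROI]) -> np.ndarray:
    return np.array([1.0 if r.label == POSITIVE else 0.0 for r in rois])


def train(
    labeled_rois: Sequence[ROI],
    unlabeled_rois: Sequence[Union[ROI, np.ndarray]],
    net_cfg: Optional[NetworkConfig] = None,
    loss_cfg: Optional[LossConfig] = None,
    opt_cfg: Optional[OptimConfig] = None,
    seed: int = 0,
    teacher: Optional[Network] = None,
    labeled_menu: Sequence[str] = FULL_MENU,
    strong_menu: Sequence[str] = STRONG_MENU,
) -> Tuple[Network, List[TrainState]]:
    """Train the classifier on labeled patches plus an unlabeled stream.

    Each step draws a labeled batch (one random augmentation per sample,
    identity included) and, when unlabeled data are present, an unlabeled
    batch in weak and strong views; the combined objective
    L = ls + λ1·lu + λ2·lp is backpropagated and Adam applies the update
    with decoupled weight decay on the convolution kernels.  With an empty
    unlabeled set, lu = lp = 0 identically and the loop reduces to plain
    supervised focal-loss training.  ``teacher`` provides the pseudo-label
    scores; without one the pseudo-label term is inactive.

    Deterministic given ``seed``.  Returns the trained network and the
    per-epoch history; raises :class:`TrainingDivergedError` on a
    non-finite loss.
    """
    if len(labeled_rois) == 0:
        raise ValueError("labeled set must be non-empty")
    net_cfg = net_cfg or NetworkConfig()
    loss_cfg = loss_cfg or LossConfig()
    opt_cfg = opt_cfg or OptimConfig()
    rng = np.random.default_rng(seed)
    net = build_network(net_cfg, seed=int(rng.integers(2**31 - 1)))
    optimizer = nn.Adam(net.params(), lr=opt_cfg.lr,
                        weight_decay=loss_cfg.weight_decay)

    labeled_patches = [np.asarray(r.patch, dtype=np.float32) for r in labeled_rois]
    labeled_y = _labels_to_binary(labeled_rois)
    unl_patches = [
        np.asarray(r.patch if isinstance(r, ROI) else r, dtype=np.float32)
        for r in unlabeled_rois
    ]
    use_unlabeled = len(unl_patches) > 0 and opt_cfg.batch_unlabeled > 0

    # pseudo-labels: assigned once, before training
    pseudo_y = np.full(len(unl_patches), -1.0)  # -1 == abstain
    if use_unlabeled and teacher is not None:
        labels = assign_pseudo_labels(
            teacher.predict(unl_patches),
            loss_cfg.pseudo_lo, loss_cfg.pseudo_hi,
        )
        pseudo_y = np.array([
            {PSEUDO_NEGATIVE: 0.0, PSEUDO_POSITIVE: 1.0, PSEUDO_ABSTAIN: -1.0}[l]
            for l in labels
        ])

    steps_per_epoch = opt_cfg.steps_per_epoch or max(
        len(labeled_patches) // opt_cfg.batch_labeled, 1
    )
    alpha, gamma = loss_cfg.focal_alpha, loss_cfg.focal_gamma
    lam1, lam2 = loss_cfg.lambda1, loss_cfg.lambda2

    history: List[TrainState] = []
    for epoch in range(opt_cfg.epochs):
        step_log: List[Dict] = []
        for _ in range(steps_per_epoch):
            net.zero_grad()
            # ---- labeled stream -------------------------------------
            idx = rng.integers(len(labeled_patches), size=opt_cfg.batch_labeled)
            xb = np.stack([
                labeled_augment(labeled_patches[i], rng,
                                opt_cfg.augment_magnitude, menu=labeled_menu)
                for i in idx
            ])
            yb = labeled_y[idx]
            z = net.forward_logits(xb, train=True, rng=rng)
            p = nn.sigmoid(z)
            ls = focal_loss(p, yb, alpha, gamma)
            dz = focal_loss_grad_logit(z, yb, alpha, gamma) / len(z)
            net.model.backward(dz[:, None].astype(np.float32))

            # ---- unlabeled stream -----------------------------------
            lu = 0.0
            lp = 0.0
            gate_fraction = 0.0
            if use_unlabeled:
                uidx = rng.integers(len(unl_patches), size=opt_cfg.batch_unlabeled)
                weak = np.stack([
                    weak_augment(unl_patches[i], rng, opt_cfg.augment_magnitude)
                    for i in uidx
                ])
                strong = np.stack([
                    strong_augment(unl_patches[i], rng, opt_cfg.augment_magnitude,
                                   menu=strong_menu)
                    for i in uidx
                ])
                # weak view: reference predictions, no dropout, no gradient
                p_weak = nn.sigmoid(net.forward_logits(weak, train=False))
                z_strong = net.forward_logits(strong, train=True, rng=rng)
                p_strong = nn.sigmoid(z_strong)

                lu, gate = consistency_loss(
                    p_weak, p_strong, loss_cfg.consistency_threshold, alpha, gamma
                )
                gate_fraction = float(gate.mean())
                dz_u = np.zeros(len(uidx))
                if gate.any():
                    hard = (p_weak[gate] >= 0.5).astype(np.float64)
                    dz_u[gate] = lam1 * focal_loss_grad_logit(
                        z_strong[gate], hard, alpha, gamma
                    ) / int(gate.sum())
                yb_p = pseudo_y[uidx]
                keep = yb_p >= 0.0
                if keep.any():
                    lp = focal_loss(p_strong[keep], yb_p[keep], alpha, gamma)
                    dz_u[keep] += lam2 * focal_loss_grad_logit(
                        z_strong[keep], yb_p[keep], alpha, gamma
                    ) / int(keep.sum())
                if np.any(dz_u):
                    net.model.backward(dz_u[:, None].astype(np.float32))

            total = combined_loss(ls, lu, lp, lam1, lam2)
            if not np.isfinite(total):
                state = TrainState(epoch=epoch, ls=float(ls), lu=float(lu),
                                   lp=float(lp), total=float(total),
                                   gate_fraction=gate_fraction, steps=step_log)
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: "
                    f"ls={ls}, lu={lu}, lp={lp}", state,
                )
            optimizer.step()
            step_log.append({"ls": ls, "lu": lu, "lp": lp, "total": total,
                             "gate_fraction": gate_fraction})

        history.append(TrainState(
            epoch=epoch,
            ls=float(np.mean([s["ls"] for s in step_log])),
            lu=float(np.mean([s["lu"] for s in step_log])),
            lp=float(np.mean([s["lp"] for s in step_log])),
            total=float(np.mean([s["total"] for s in step_log])),
            gate_fraction=float(np.mean([s["gate_fraction"] for s in step_log])),
            steps=step_log,
        ))
    return net, history
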