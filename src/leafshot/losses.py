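"""Metric-learning objectives: triplet loss and its adversarial extension.

The triplet loss on an (anchor, positive, negative) feature triplet is the
hinge

    L_t = max(0, D(f_a, f_p)^2 - D(f_a, f_n)^2 + m),

with D the Euclidean distance and m the margin (default 1).  The adversarial
variant (deep adversarial metric learning) trains, jointly with the metric,
a three-layer fully connected generator that synthesizes a hard negative
f̃_n from the concatenated triplet.  The generator objective is

    J_gen = J_hard + λ1 J_reg + λ2 J_adv
          = ||f̃_n - f_a||^2 + λ1 ||f̃_n - f_n||^2
            + λ2 max(0, D(f_a, f̃_n)^2 - D(f_a, f_p)^2 - α),

pulling the synthetic negative toward the anchor (hard), keeping it close to
the real negative (plausible), and capping how far inside the margin it may
fall (adversarial).  The metric is then trained with the triplet hinge using
f̃_n in place of f_n, and the combined objective is J_gen + λ J_m.

All loss functions return batch means and, where needed for training, the
gradients with respect to their feature inputs.  Distances enter the
formulas squared, so no square roots (and no epsilons) appear anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class MetricParams:
    """Margins and balance weights of the adversarial metric objective."""

    m: float = 1.0       # triplet margin
    alpha: float = 1.0   # adversarial margin
    lam: float = 1.0     # weight of the metric loss in the joint objective
    lam1: float = 1.0    # weight of the regularization term J_reg
    lam2: float = 1.0    # weight of the adversarial term J_adv

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("margin m must be > 0")
        if min(self.lam, self.lam1, self.lam2) < 0:
            raise ValueError("balance weights must be >= 0")


def _pair(a, b):
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("feature batches must share a shape")
    return a, b


def triplet_loss(
    anchors, positives, negatives, m: float = 1.0, with_grads: bool = False
):
    """Mean hinge max(0, D(a,p)^2 - D(a,n)^2 + m) over the batch.

    With ``with_grads`` also returns the gradients w.r.t. (a, p, n).
    """
    a, p = _pair(anchors, positives)
    a, n = _pair(a, negatives)
    d_ap = ((a - p) ** 2).sum(axis=1)
    d_an = ((a - n) ** 2).sum(axis=1)
    per = np.maximum(0.0, d_ap - d_an + m)
    loss = float(per.mean())
    if not with_grads:
        return loss
    act = (per > 0).astype(np.float64)[:, None] / a.shape[0]
    ga = act * 2 * (n - p)
    gp = act * (-2) * (a - p)
    gn = act * 2 * (a - n)
    return loss, (ga, gp, gn)


def generator_loss(
    anchors,
    positives,
    negatives,
    generated,
    params: MetricParams,
    with_grads: bool = False,
):
    """Hard-negative generator objective J_hard + λ1 J_reg + λ2 J_adv.

    Returns the batch-mean loss (and the gradient w.r.t. the generated
    features when requested).
    """
    a, p = _pair(anchors, positives)
    a, n = _pair(a, negatives)
    a, g = _pair(a, generated)
    j_hard = ((g - a) ** 2).sum(axis=1)
    j_reg = ((g - n) ** 2).sum(axis=1)
    d_ag = ((a - g) ** 2).sum(axis=1)
    d_ap = ((a - p) ** 2).sum(axis=1)
    adv = np.maximum(0.0, d_ag - d_ap - params.alpha)
    per = j_hard + params.lam1 * j_reg + params.lam2 * adv
    loss = float(per.mean())
    if not with_grads:
        return loss
    b = a.shape[0]
    act = (adv > 0).astype(np.float64)[:, None]
    dgen = (2 * (g - a) + params.lam1 * 2 * (g - n) + params.lam2 * act * 2 * (g - a)) / b
    return loss, dgen


def daml_metric_loss(
    anchors, positives, generated, m: float = 1.0, with_grads: bool = False
):
    """Triplet hinge with the synthetic hard negative in the negative slot."""
    if with_grads:
        return triplet_loss(anchors, positives, generated, m, with_grads=True)
    return triplet_loss(anchors, positives, generated, m)


def daml_total(anchors, positives, negatives, generated, params: MetricParams) -> float:
    """Joint objective J_gen + λ J_m of adversarial metric learning."""
    jg = generator_loss(anchors, positives, negatives, generated, params)
    jm = daml_metric_loss(anchors, positives, generated, params.m)
    return jg + params.lam * jm


class HardNegativeGenerator:
    """Three fully connected layers mapping a concatenated triplet to f̃_n.

    Hidden widths are (2d, d) with ReLU activations and a linear output, so
    the synthetic negative lives in the same d-dimensional feature space.
    """

    def __init__(self, dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.net = nn.Sequential(
            nn.Linear(3 * dim, 2 * dim, rng=rng),
            nn.ReLU(),
            nn.Linear(2 * dim, dim, rng=rng),
            nn.ReLU(),
            nn.Linear(dim, dim, rng=rng),
        )

    def parameters(self) -> list[nn.Param]:
        return self.net.parameters()

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def generate(self, anchors, positives, negatives) -> np.ndarray:
        a, p = _pair(anchors, positives)
        a, n = _pair(a, negatives)
        x = np.concatenate([a, p, n], axis=1).astype(np.float32)
        return self.net.forward(x)

    def backward(self, grad_generated: np.ndarray) -> np.ndarray:
        """Backpropagate into the generator; returns grad w.r.t. the input."""
        return self.net.backward(np.asarray(grad_generated, dtype=np.float32))
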