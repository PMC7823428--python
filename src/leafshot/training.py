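"""Source-domain training and target-domain few-shot adaptation.

Four learning strategies share one protocol: train an embedder on the large
source label space, then adapt it to novel classes from K examples each.

* ``baseline``      — embedder + linear-softmax classifier trained jointly
  with cross-entropy (Adam, lr 1e-4, 30 epochs); adaptation trains a fresh
  linear head on the frozen embedder (SGD lr 0.01, momentum 0.9, weight
  decay 1e-3, 100 epochs).
* ``baseline_pp``   — as above with a cosine-similarity prototype head.
* ``triplet``       — metric learning with the triplet hinge (margin 1,
  Adam, 15 epochs) on a 128-d embedding head; adaptation fits a one-vs-all
  linear SVM on support embeddings.
* ``daml``          — triplet learning with an adversarially generated hard
  negative: alternating updates of the generator (its own objective) and
  the embedder (triplet hinge against the synthetic negative); SVM
  adaptation as for ``triplet``.

The "best epoch" checkpoint is chosen on a 10% held-out slice of the source
training data (accuracy for the classifier methods, metric loss for the
metric methods).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import nn
from .backbones import Embedder, stack_images
from .catalog import AugmentConfig, augment
from .heads import CosineHead, LinearSoftmaxHead, SvmModel, svm_fit
from .losses import HardNegativeGenerator, MetricParams, generator_loss, triplet_loss
from .synthetic import LabeledImage

METHODS = ("baseline", "baseline_pp", "triplet", "daml")


@dataclass(frozen=True)
class SourceTrainConfig:
    method: str = "baseline"
    epochs: int | None = None  # default: 30 for classifier methods, 15 for metric
    lr: float = 1e-4
    batch_size: int = 16
    seed: int = 0
    input_size: int = 32
    val_fraction: float = 0.1
    augment: bool = True
    metric_params: MetricParams = field(default_factory=MetricParams)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")

    @property
    def n_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return 30 if self.method in ("baseline", "baseline_pp") else 15


@dataclass(frozen=True)
class FinetuneConfig:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.001
    epochs: int = 100
    seed: int = 0


@dataclass
class SourceTrainResult:
    embedder: Embedder
    head: LinearSoftmaxHead | CosineHead | None
    generator: HardNegativeGenerator | None
    log: pd.DataFrame
    best_epoch: int
    config: SourceTrainConfig
    class_names: tuple[str, ...]


def _augmented_batch(
    images: Sequence[LabeledImage], idx: np.ndarray, cfg: SourceTrainConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    aug_cfg = AugmentConfig(out_size=cfg.input_size)
    if cfg.augment:
        batch = [augment(images[i], int(rng.integers(2**31)), aug_cfg) for i in idx]
    else:
        batch = [images[i] for i in idx]
    return stack_images(batch, size=cfg.input_size)


def _labels(images: Sequence[LabeledImage]) -> tuple[np.ndarray, tuple[str, ...]]:
    names = tuple(sorted({im.disease for im in images}))
    lut = {n: i for i, n in enumerate(names)}
    return np.array([lut[im.disease] for im in images]), names


def triplet_sampler(
    labels: np.ndarray, batch_size: int, seed: int
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Endless stream of (anchor, positive, negative) index batches.

    Anchors are drawn uniformly; the positive is a different image of the
    anchor's class and the negative an image of a different class.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("triplet sampling needs at least two classes")
    by_class = {c: np.nonzero(labels == c)[0] for c in classes}
    if any(len(v) < 2 for v in by_class.values()):
        raise ValueError("each class needs at least two images for triplets")
    rng = np.random.default_rng(seed)
    n = len(labels)
    while True:
        a = rng.integers(n, size=batch_size)
        p = np.empty_like(a)
        ng = np.empty_like(a)
        for i, ai in enumerate(a):
            pool = by_class[labels[ai]]
            pi = ai
            while pi == ai:
                pi = pool[rng.integers(len(pool))]
            p[i] = pi
            neg_class = classes[classes != labels[ai]][rng.integers(len(classes) - 1)]
            ng[i] = by_class[neg_class][rng.integers(len(by_class[neg_class]))]
        yield a, p, ng


def _full_state(embedder: Embedder, head=None, generator=None) -> list[np.ndarray]:
    state = nn.get_state(embedder.backbone)
    if embedder.head is not None:
        state += nn.get_state(embedder.head)
    for extra in (head, generator):
        if extra is not None:
            state += [p.data.copy() for p in extra.parameters()]
    return state


def _restore_state(embedder: Embedder, state: list[np.ndarray], head=None, generator=None):
    n_bb = len(nn.get_state(embedder.backbone))
    nn.set_state(embedder.backbone, state[:n_bb])
    pos = n_bb
    if embedder.head is not None:
        n_h = len(nn.get_state(embedder.head))
        nn.set_state(embedder.head, state[pos : pos + n_h])
        pos += n_h
    for extra in (head, generator):
        if extra is not None:
            for p in extra.parameters():
                p.data[...] = state[pos]
                pos += 1


def train_source(
    images: Sequence[LabeledImage],
    embedder: Embedder,
    config: SourceTrainConfig,
) -> SourceTrainResult:
    """Train the embedder (and source classifier) on the source domain.

    Returns the checkpoint of the best epoch by the held-out criterion,
    together with a per-epoch training log.
    """
    y_all, names = _labels(images)
    if len(names) < 2:
        raise ValueError("source training needs at least two classes")
    rng = np.random.default_rng(config.seed)

    # stratified 10% held-out slice for best-epoch selection (at least two
    # per class so metric validation triplets always exist)
    val_parts, train_parts = [], []
    for c in range(len(names)):
        members = rng.permutation(np.nonzero(y_all == c)[0])
        k = min(len(members) - 1, max(2, int(round(config.val_fraction * len(members)))))
        val_parts.append(members[:k])
        train_parts.append(members[k:])
    val_idx = np.concatenate(val_parts)
    train_idx = rng.permutation(np.concatenate(train_parts))
    x_val = stack_images([images[i] for i in val_idx], size=config.input_size)
    y_val = y_all[val_idx]

    if config.method in ("baseline", "baseline_pp"):
        return _train_classifier(
            images, y_all, train_idx, x_val, y_val, embedder, config, names, rng
        )
    return _train_metric(
        images, y_all, train_idx, x_val, y_val, embedder, config, names, rng
    )


def _train_classifier(images, y_all, train_idx, x_val, y_val, embedder, config, names, rng):
    head_cls = LinearSoftmaxHead if config.method == "baseline" else CosineHead
    head = head_cls(embedder.out_dim, len(names), seed=config.seed + 17)
    opt = nn.Adam(embedder.parameters() + head.parameters(), lr=config.lr)
    log, best = [], (-np.inf, 0, None)
    for epoch in range(config.n_epochs):
        embedder.train(True)
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs >1 sample
            x = _augmented_batch(images, idx, config, rng)
            f = embedder.forward(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))
            logits = head.logits(f)
            loss, dlogits = nn.cross_entropy(logits, y_all[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            df = head.backward(dlogits)
            embedder.backward(np.asarray(df, dtype=np.float32))
            opt.step()
            losses.append(loss)
        f_val = embedder.embed(x_val)
        acc = float((head.predict(f_val) == y_val).mean())
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": acc})
        if acc > best[0]:
            best = (acc, epoch, _full_state(embedder, head=head))
    _restore_state(embedder, best[2], head=head)
    return SourceTrainResult(
        embedder, head, None, pd.DataFrame(log), best[1], config, names
    )


def _train_metric(images, y_all, train_idx, x_val, y_val, embedder, config, names, rng):
    if embedder.head is None:
        raise ValueError("metric methods require an embedder with a 128-d head")
    mp = config.metric_params
    sampler = triplet_sampler(y_all[train_idx], config.batch_size, config.seed + 29)
    generator = None
    if config.method == "daml":
        generator = HardNegativeGenerator(embedder.out_dim, seed=config.seed + 31)
        gen_opt = nn.Adam(generator.parameters(), lr=config.lr)
    opt = nn.Adam(embedder.parameters(), lr=config.lr)

    # fixed validation triplets for best-epoch selection
    y_vl = y_val
    val_sampler = triplet_sampler(y_vl, min(64, 4 * len(y_vl)), config.seed + 37)
    va, vp, vn = next(val_sampler)

    n_batches = max(1, len(train_idx) // config.batch_size)
    log, best = [], (np.inf, 0, None)
    for epoch in range(config.n_epochs):
        embedder.train(True)
        losses = []
        for _ in range(n_batches):
            a, p, ng = next(sampler)
            idx = np.concatenate([train_idx[a], train_idx[p], train_idx[ng]])
            x = _augmented_batch(images, idx, config, rng)
            f = embedder.forward(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))
            b = len(a)
            fa, fp, fn_ = f[:b], f[b : 2 * b], f[2 * b :]
            opt.zero_grad()
            if config.method == "triplet":
                loss, (ga, gp, gn) = triplet_loss(fa, fp, fn_, mp.m, with_grads=True)
                grad_f = np.concatenate([ga, gp, gn]).astype(np.float32)
            else:
                # generator step: its own objective on detached features
                gen_opt.zero_grad()
                f_tilde = generator.generate(fa, fp, fn_)
                _, dgen = generator_loss(fa, fp, fn_, f_tilde, mp, with_grads=True)
                generator.backward(dgen)
                gen_opt.step()
                # embedder step: triplet hinge against the (fixed) synthetic negative
                f_tilde = generator.generate(fa, fp, fn_)
                loss, (ga, gp, _gn) = triplet_loss(fa, fp, f_tilde, mp.m, with_grads=True)
                grad_f = np.concatenate(
                    [ga, gp, np.zeros_like(ga)]
                ).astype(np.float32)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            embedder.backward(grad_f)
            opt.step()
            losses.append(loss)
        f_val = embedder.embed(x_val)
        vloss = triplet_loss(f_val[va], f_val[vp], f_val[vn], mp.m)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": vloss}
        )
        if vloss < best[0]:
            best = (vloss, epoch, _full_state(embedder, generator=generator))
    _restore_state(embedder, best[2], generator=generator)
    return SourceTrainResult(
        embedder, None, generator, pd.DataFrame(log), best[1], config, names
    )


# ---------------------------------------------------------------------------
# Target-domain adaptation


def finetune_head(
    features: np.ndarray,
    labels: np.ndarray,
    head_kind: str,
    config: FinetuneConfig = FinetuneConfig(),
) -> LinearSoftmaxHead | CosineHead:
    """Train a fresh classifier head on fixed support features."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fine-tuning needs at least two classes in the support set")
    n_classes = int(classes.max()) + 1
    head_cls = {"linear": LinearSoftmaxHead, "cosine": CosineHead}[head_kind]
    head = head_cls(features.shape[1], n_classes, seed=config.seed)
    if head_kind == "cosine":
        # weight imprinting: start each prototype at the normalized mean of
        # its support embeddings, then refine by gradient descent
        x64 = np.asarray(features, dtype=np.float64)
        for c in classes:
            mean = x64[y == c].mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                head.prototypes.data[int(c)] = (mean / norm).astype(np.float32)
    opt = nn.SGD(
        head.parameters(),
        lr=config.lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    x = np.asarray(features, dtype=np.float32)
    for _ in range(config.epochs):
        logits = head.logits(x)
        _, dlogits = nn.cross_entropy(logits, y)
        opt.zero_grad()
        head.backward(dlogits)
        opt.step()
    return head


def finetune_target(
    embedder: Embedder,
    support: Sequence[tuple[LabeledImage, int]],
    config: FinetuneConfig = FinetuneConfig(),
    head_kind: str = "linear",
    input_size: int | None = None,
) -> LinearSoftmaxHead | CosineHead:
    """Adapt to a support set by training a new head on the frozen embedder.

    Only head parameters are updated; the embedder is used purely as a
    feature extractor and its weights are bit-identical before and after.
    """
    size = input_size or embedder.config.input_size
    x = stack_images([im for im, _ in support], size=size)
    feats = embedder.embed(x)
    y = np.array([ci for _, ci in support])
    return finetune_head(feats, y, head_kind, config)


def adapt_svm(
    embedder: Embedder,
    support: Sequence[tuple[LabeledImage, int]],
    C: float = 1.0,
    input_size: int | None = None,
) -> SvmModel:
    """Fit the one-vs-all linear SVM on support-embedding vectors."""
    size = input_size or embedder.config.input_size
    x = stack_images([im for im, _ in support], size=size)
    feats = embedder.embed(x)
    y = np.array([ci for _, ci in support])
    return svm_fit(feats, y, C=C)
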