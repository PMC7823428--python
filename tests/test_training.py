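"""Tests of source-domain training and few-shot adaptation."""

import hashlib
import itertools

import numpy as np
import pytest

from leafshot.backbones import BackboneConfig, build_backbone, stack_images
from leafshot.synthetic import DiseaseClassSpec, LAB_DOMAIN, generate_dataset
from leafshot.training import (
    FinetuneConfig,
    SourceTrainConfig,
    adapt_svm,
    finetune_head,
    finetune_target,
    train_source,
    triplet_sampler,
)

THREE_CLASS_SPECS = [
    DiseaseClassSpec("healthy", "none", (0, 0), (0.01, 0.02), (0.0, 0.0, 0.0)),
    DiseaseClassSpec("mosaic virus", "mosaic", (1, 1), (0.05, 0.1), (0.85, 0.85, 0.2)),
    DiseaseClassSpec("leaf scorch", "scorch", (1, 1), (0.05, 0.1), (0.5, 0.15, 0.05)),
]


@pytest.fixture(scope="module")
def three_class_data():
    images, _ = generate_dataset(THREE_CLASS_SPECS, 60, LAB_DOMAIN, 0.8, seed=5, size=32)
    return (
        [im for im in images if im.split == "train"],
        [im for im in images if im.split == "test"],
    )


def _support_from(images, k):
    names = sorted({im.disease for im in images})
    out = []
    for ci, name in enumerate(names):
        members = [im for im in images if im.disease == name][:k]
        out.extend((im, ci) for im in members)
    return out


def _weight_hash(embedder) -> str:
    h = hashlib.sha256()
    for p in embedder.parameters():
        h.update(p.data.tobytes())
    return h.hexdigest()


class TestTripletSampler:
    def test_only_valid_triplets_by_exhaustive_enumeration(self):
        """2 classes x 2 images: brute-force enumeration gives exactly 8
        valid (a, p, n) orderings; the sampler emits only members."""
        labels = np.array([0, 0, 1, 1])
        valid = {
            (a, p, n)
            for a, p, n in itertools.product(range(4), repeat=3)
            if labels[a] == labels[p] and a != p and labels[n] != labels[a]
        }
        assert len(valid) == 8
        sampler = triplet_sampler(labels, batch_size=16, seed=0)
        for _ in range(5):
            a, p, n = next(sampler)
            for t in zip(a.tolist(), p.tolist(), n.tolist()):
                assert t in valid

    def test_no_self_pairs_and_label_constraint(self):
        labels = np.array([0] * 5 + [1] * 5 + [2] * 5)
        sampler = triplet_sampler(labels, batch_size=32, seed=1)
        for _ in range(5):
            a, p, n = next(sampler)
            assert (a != p).all()
            assert (labels[a] == labels[p]).all()
            assert (labels[a] != labels[n]).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            next(triplet_sampler(np.zeros(6, dtype=int), 4, seed=0))

    def test_deterministic_given_seed(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        a1 = next(triplet_sampler(labels, 8, seed=3))
        a2 = next(triplet_sampler(labels, 8, seed=3))
        for x, y in zip(a1, a2):
            assert np.array_equal(x, y)


class TestTrainSource:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            SourceTrainConfig("baseline", epochs=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            SourceTrainConfig("prototypical")

    def test_baseline_learns_separable_classes(self, three_class_data):
        """On three color-separable classes the trained model classifies the
        held-out split far above 1/3 chance; a raw-pixel nearest-centroid
        oracle confirms the fixture itself is separable."""
        train, test = three_class_data
        # oracle: nearest centroid on raw pixels
        names = sorted({im.disease for im in train})
        Xtr = np.stack([im.pixels.reshape(-1) for im in train])
        ytr = np.array([names.index(im.disease) for im in train])
        Xte = np.stack([im.pixels.reshape(-1) for im in test])
        yte = np.array([names.index(im.disease) for im in test])
        cents = np.stack([Xtr[ytr == c].mean(axis=0) for c in range(3)])
        oracle = (np.linalg.norm(Xte[:, None] - cents[None], axis=2).argmin(1) == yte).mean()
        assert oracle > 0.7

        emb = build_backbone(BackboneConfig("tiny", 32, seed=5))
        res = train_source(
            train, emb, SourceTrainConfig("baseline", epochs=15, seed=5, input_size=32)
        )
        f = emb.embed(stack_images(test, size=32))
        acc = (res.head.predict(f) == yte).mean()
        assert acc >= 0.70
        assert len(res.log) == 15
        assert np.isfinite(res.log["train_loss"]).all()

    def test_triplet_training_shrinks_within_class_distances(self, three_class_data):
        """After metric training, mean within-class embedding distance is
        smaller than mean between-class distance on held-out images."""
        train, test = three_class_data
        emb = build_backbone(BackboneConfig("tiny", 32, seed=5), with_head=True)
        train_source(
            train, emb, SourceTrainConfig("triplet", epochs=5, seed=5, input_size=32)
        )
        f = emb.embed(stack_images(test, size=32))
        names = sorted({im.disease for im in test})
        y = np.array([names.index(im.disease) for im in test])
        D = np.linalg.norm(f[:, None] - f[None], axis=2)
        same = (y[:, None] == y[None]) & ~np.eye(len(y), dtype=bool)
        assert D[same].mean() < D[y[:, None] != y[None]].mean()

    def test_metric_method_requires_head(self, three_class_data):
        train, _ = three_class_data
        emb = build_backbone(BackboneConfig("tiny", 32, seed=0))  # no head
        with pytest.raises(ValueError, match="head"):
            train_source(train, emb, SourceTrainConfig("triplet", epochs=1))

    def test_training_deterministic_given_seed(self, three_class_data):
        train, _ = three_class_data
        logs = []
        for _ in range(2):
            emb = build_backbone(BackboneConfig("tiny", 32, seed=3))
            res = train_source(
                train, emb, SourceTrainConfig("baseline", epochs=2, seed=3, input_size=32)
            )
            logs.append(res.log)
        assert logs[0].equals(logs[1])


class TestAdaptation:
    def test_embedder_frozen_through_finetune(self, three_class_data):
        train, _ = three_class_data
        emb = build_backbone(BackboneConfig("tiny", 32, seed=7))
        support = _support_from(train, k=5)
        before = _weight_hash(emb)
        finetune_target(emb, support, FinetuneConfig(epochs=20), head_kind="linear")
        assert _weight_hash(emb) == before

    def test_separable_support_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        means = 3.0 * np.eye(3, 8)
        feats = np.vstack([rng.normal(means[c], 0.1, size=(5, 8)) for c in range(3)])
        y = np.repeat(np.arange(3), 5)
        head = finetune_head(feats, y, "linear")
        assert (head.predict(feats) == y).all()

    def test_single_class_support_rejected(self):
        feats = np.ones((4, 8))
        with pytest.raises(ValueError, match="two classes"):
            finetune_head(feats, np.zeros(4, dtype=int), "linear")

    def test_adapt_svm_fits_on_embeddings(self, three_class_data):
        train, _ = three_class_data
        emb = build_backbone(BackboneConfig("tiny", 32, seed=7), with_head=True)
        support = _support_from(train, k=10)
        model = adapt_svm(emb, support)
        feats = emb.embed(stack_images([im for im, _ in support], size=32))
        preds = model.predict(feats)
        assert preds.shape == (len(support),)
        assert set(preds) <= {0, 1, 2}
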