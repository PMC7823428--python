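"""The desk-scale synthetic few-shot benchmark.

A fixed configuration of the leaf simulator that mirrors the structure of
the full study at a size a CPU can train in minutes: five well-separated
source disease classes and three novel target classes, rendered at 32x32,
with a tiny residual backbone.  The target pool can be rendered in the same
"lab" domain as the source (small shift) or in the "field" domain (large
shift).

All four learning strategies are trained on the same source images and
evaluated episodically on the target pool; this is the configuration the
integration tests and the acceptance script run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbones import BackboneConfig, Embedder, build_backbone
from .evaluation import FinetuneMethod, SvmMethod
from .synthetic import (
    FIELD_DOMAIN,
    LAB_DOMAIN,
    LabeledImage,
    benchmark_class_specs,
    generate_dataset,
)
from .training import SourceTrainConfig, SourceTrainResult, train_source

IMAGE_SIZE = 32
N_SOURCE_PER_CLASS = 40
N_TARGET_PER_CLASS = 80
# source-training epochs follow the study protocol (30 for the classifier
# baselines, 15 for the metric methods)
EPOCHS = {"baseline": 30, "baseline_pp": 30, "triplet": 15, "daml": 15}


@dataclass
class Benchmark:
    source_train: list[LabeledImage]
    source_test: list[LabeledImage]
    target_pool: list[LabeledImage]
    source_classes: tuple[str, ...]
    target_classes: tuple[str, ...]
    size: int


def make_benchmark(seed: int, target_domain: str = "lab") -> Benchmark:
    """Generate the benchmark datasets (source 5 classes, target 3 novel)."""
    specs = benchmark_class_specs()
    src_specs, tgt_specs = specs[:5], specs[5:]
    dom = {"lab": LAB_DOMAIN, "field": FIELD_DOMAIN}[target_domain]
    src, _ = generate_dataset(
        src_specs, N_SOURCE_PER_CLASS, LAB_DOMAIN, 0.8, seed=seed, size=IMAGE_SIZE
    )
    tgt, _ = generate_dataset(
        tgt_specs, N_TARGET_PER_CLASS, dom, 0.8, seed=seed + 1, size=IMAGE_SIZE
    )
    return Benchmark(
        source_train=[im for im in src if im.split == "train"],
        source_test=[im for im in src if im.split == "test"],
        target_pool=tgt,
        source_classes=tuple(s.name for s in src_specs),
        target_classes=tuple(s.name for s in tgt_specs),
        size=IMAGE_SIZE,
    )


def train_method(
    method: str, source_train, seed: int, epochs: int | None = None
) -> SourceTrainResult:
    """Train one strategy on the benchmark source domain (tiny backbone)."""
    with_head = method in ("triplet", "daml")
    emb = build_backbone(
        BackboneConfig("tiny", IMAGE_SIZE, seed=seed), with_head=with_head
    )
    cfg = SourceTrainConfig(
        method=method,
        epochs=epochs if epochs is not None else EPOCHS[method],
        seed=seed,
        input_size=IMAGE_SIZE,
    )
    return train_source(source_train, emb, cfg)


def episode_method(method: str, result: SourceTrainResult):
    """Wrap a trained model as an episodic-evaluation method."""
    if method == "baseline":
        return FinetuneMethod("baseline", result.embedder, "linear")
    if method == "baseline_pp":
        return FinetuneMethod("baseline_pp", result.embedder, "cosine")
    return SvmMethod(method, result.embedder)


def random_embedder_control(seed: int = 12345) -> FinetuneMethod:
    """Baseline fine-tuning on a frozen, untrained (random-weight) embedder."""
    emb = build_backbone(BackboneConfig("tiny", IMAGE_SIZE, seed=seed))
    return FinetuneMethod("random_control", emb, "linear")
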