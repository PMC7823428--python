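"""Shared fixtures.

The expensive session fixture trains all four learning strategies on the
synthetic benchmark once; the integration and protocol tests then evaluate
those models from many angles without retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from leafshot import benchmark as bm
from leafshot.synthetic import LabeledImage

BENCH_SEED = 11


@pytest.fixture(scope="session")
def bench():
    return bm.make_benchmark(seed=BENCH_SEED, target_domain="lab")


@pytest.fixture(scope="session")
def trained(bench):
    """All four strategies trained on the benchmark source domain."""
    return {
        m: bm.train_method(m, bench.source_train, seed=BENCH_SEED)
        for m in ("baseline", "baseline_pp", "triplet", "daml")
    }


@pytest.fixture(scope="session")
def benchmark_grid(bench, trained):
    """Episodic evaluation of the four trained models plus the
    frozen-random-embedder control, at K in {5, 25}."""
    from leafshot.evaluation import EvalGridConfig, run_grid

    methods = [bm.episode_method(m, r) for m, r in trained.items()]
    methods.append(bm.random_embedder_control())
    cfg = EvalGridConfig(
        K_values=(5, 25), n_repeats=30, n_query_per_class=50, base_seed=BENCH_SEED
    )
    return run_grid(bench.target_pool, list(bench.target_classes), methods, cfg)


def make_dummy_pool(n_classes: int, n_per_class: int, size: int = 32):
    """A lightweight labeled pool (shared zero rasters) for protocol tests
    that never look at pixel content."""
    px = np.zeros((size, size, 3), dtype=np.float32)
    return [
        LabeledImage(px, "synthetic", f"class_{c:02d}", "lab", "train")
        for c in range(n_classes)
        for _ in range(n_per_class)
    ]


@pytest.fixture
def dummy_pool6():
    return make_dummy_pool(6, 60)
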