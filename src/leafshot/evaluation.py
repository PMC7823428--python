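"""Episodic C-way/K-shot evaluation and result reporting.

For every (method, backbone, K) cell the evaluator samples repeated
episodes from the novel-class pool — K support and Q query images per class,
disjoint — adapts the method on the support set and scores it on the query
set.  Results are reported as mean error (100 − mean accuracy, percent)
with its standard error over repeats, as a long-form table and as
error-vs-K curves.

C (the number of ways) is always the full novel label space of the target
dataset rather than a sampled subset.  Repeat ``r`` of a cell derives its
episode seed from ``base_seed + r`` (mixed with K), so repeats are
independent and the whole grid is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .backbones import Embedder, stack_images
from .catalog import Episode, sample_episode
from .heads import SvmModel, svm_fit
from .synthetic import LabeledImage
from .training import FinetuneConfig, finetune_head


@dataclass(frozen=True)
class EvalGridConfig:
    K_values: tuple[int, ...] = tuple(range(5, 55, 5))
    n_repeats: int = 100
    n_query_per_class: int = 50
    base_seed: int = 0

    def __post_init__(self):
        if any(k < 1 for k in self.K_values) or self.n_repeats < 1:
            raise ValueError("K values and repeat count must be >= 1")


class EpisodeMethod(Protocol):
    """Adapt on a support set and predict query labels.

    ``query_labels`` is provided solely so that oracle stubs (used to
    calibrate the episodic protocol) can be expressed in the same
    interface; real methods must ignore it.
    """

    name: str

    def run_episode(
        self,
        support_feats: np.ndarray,
        support_labels: np.ndarray,
        query_feats: np.ndarray,
        query_labels: np.ndarray,
        seed: int,
    ) -> np.ndarray: ...


@dataclass
class FinetuneMethod:
    """Baseline / Baseline++ adaptation: train a fresh head, frozen features."""

    name: str
    embedder: Embedder
    head_kind: str = "linear"
    config: FinetuneConfig = dc_field(default_factory=FinetuneConfig)

    def run_episode(self, support_feats, support_labels, query_feats, query_labels, seed):
        cfg = FinetuneConfig(
            lr=self.config.lr,
            momentum=self.config.momentum,
            weight_decay=self.config.weight_decay,
            epochs=self.config.epochs,
            seed=seed,
        )
        head = finetune_head(support_feats, support_labels, self.head_kind, cfg)
        return head.predict(query_feats)


@dataclass
class SvmMethod:
    """Metric-learning adaptation: one-vs-all linear SVM on embeddings."""

    name: str
    embedder: Embedder
    C: float = 1.0

    def run_episode(self, support_feats, support_labels, query_feats, query_labels, seed):
        model = svm_fit(support_feats, support_labels, C=self.C)
        return model.predict(query_feats)


@dataclass
class PerfectStub:
    """Oracle returning the true query labels (protocol calibration)."""

    name: str = "perfect"
    embedder: Embedder | None = None

    def run_episode(self, support_feats, support_labels, query_feats, query_labels, seed):
        return np.asarray(query_labels).copy()


@dataclass
class UniformRandomStub:
    """Uniform guess over the C ways (protocol calibration)."""

    name: str = "uniform"
    embedder: Embedder | None = None

    def run_episode(self, support_feats, support_labels, query_feats, query_labels, seed):
        rng = np.random.default_rng(seed)
        classes = np.unique(support_labels)
        return rng.choice(classes, size=len(query_feats))


@dataclass
class ResultGrid:
    records: pd.DataFrame  # method, backbone, K, mean_error, std_error, n_repeats
    skipped: list[dict] = dc_field(default_factory=list)

    def cell(self, method: str, K: int) -> float:
        df = self.records
        row = df[(df["method"] == method) & (df["K"] == K)]
        return float(row["mean_error"].iloc[0])


def _episode_seed(base_seed: int, r: int, K: int) -> int:
    return int(
        np.random.SeedSequence([base_seed + r, K]).generate_state(1)[0] % 2**31
    )


def run_grid(
    images: Sequence[LabeledImage],
    classes: Sequence[str],
    methods: Sequence[EpisodeMethod],
    config: EvalGridConfig,
) -> ResultGrid:
    """Evaluate every method over the K grid with repeated episodes.

    Features for the whole novel-class pool are computed once per distinct
    embedder (the embedders stay frozen during evaluation), so episodes
    only index into the cached feature matrix.
    """
    feats_cache: dict[int, np.ndarray] = {}
    for m in methods:
        emb = getattr(m, "embedder", None)
        if emb is not None and id(emb) not in feats_cache:
            x = stack_images(images, size=emb.config.input_size)
            feats_cache[id(emb)] = emb.embed(x)

    pool_sizes: dict[str, int] = {c: 0 for c in classes}
    for im in images:
        if im.disease in pool_sizes:
            pool_sizes[im.disease] += 1

    rows, skipped = [], []
    Q = config.n_query_per_class
    for K in config.K_values:
        infeasible = [c for c, nc in pool_sizes.items() if nc < K + Q]
        if infeasible:
            skipped.append(
                {"K": K, "reason": f"classes lack K+Q={K + Q} images: {infeasible}"}
            )
            continue
        episodes = [
            sample_episode(images, classes, K, Q, _episode_seed(config.base_seed, r, K))
            for r in range(config.n_repeats)
        ]
        for m in methods:
            emb = getattr(m, "embedder", None)
            feats = feats_cache.get(id(emb)) if emb is not None else None
            accs = []
            for r, ep in enumerate(episodes):
                sy = np.array([ci for _, ci in ep.support])
                qy = np.array([ci for _, ci in ep.query])
                if feats is not None:
                    sf = feats[ep.support_indices]
                    qf = feats[ep.query_indices]
                else:
                    sf = np.zeros((len(sy), 1))
                    qf = np.zeros((len(qy), 1))
                pred = m.run_episode(sf, sy, qf, qy, _episode_seed(config.base_seed, r, K) + 1)
                accs.append(float((np.asarray(pred) == qy).mean()))
            accs = np.array(accs)
            err = 100.0 * (1.0 - accs)
            backbone = emb.config.fingerprint() if emb is not None else "none"
            rows.append(
                {
                    "method": m.name,
                    "backbone": backbone,
                    "K": K,
                    "mean_error": float(err.mean()),
                    "std_error": float(err.std(ddof=1) / np.sqrt(len(err)))
                    if len(err) > 1
                    else 0.0,
                    "n_repeats": len(err),
                }
            )
    return ResultGrid(pd.DataFrame(rows), skipped)


def summarize(grid: ResultGrid) -> pd.DataFrame:
    """Method-by-K table of mean errors; the per-column minimum (and any
    ties) is marked with ``*``, mirroring boldface in a printed table."""
    piv = grid.records.pivot_table(
        index="method", columns="K", values="mean_error", aggfunc="first"
    )
    marked = piv.copy().astype(object)
    for K in piv.columns:
        col = piv[K]
        mn = col.min()
        for meth in piv.index:
            v = col[meth]
            marked.loc[meth, K] = f"{v:.2f}*" if np.isclose(v, mn) else f"{v:.2f}"
    return marked


def report(grid: ResultGrid, outdir: str | Path, prefix: str = "results") -> list[Path]:
    """Write the long-form CSV, the marked summary table, and per-backbone
    error-vs-K plots.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    long_path = outdir / f"{prefix}.csv"
    grid.records.to_csv(long_path, index=False)
    paths.append(long_path)
    summary_path = outdir / f"{prefix}_summary.csv"
    summarize(grid).to_csv(summary_path)
    paths.append(summary_path)

    for backbone, df in grid.records.groupby("backbone"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for method, mdf in df.groupby("method"):
            mdf = mdf.sort_values("K")
            ax.errorbar(mdf["K"], mdf["mean_error"], yerr=mdf["std_error"], label=method,
                        marker="o", capsize=3)
        ax.set_xlabel("shots per class, K")
        ax.set_ylabel("mean error (%)")
        ax.set_title(backbone)
        ax.set_xticks(sorted(df["K"].unique()))
        ax.legend()
        fig.tight_layout()
        p = outdir / f"{prefix}_{backbone.replace('/', '_')}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
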