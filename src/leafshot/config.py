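"""Experiment configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import EvalGridConfig
from .losses import MetricParams
from .training import FinetuneConfig, SourceTrainConfig


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one experiment end to end.

    ``dataset`` is either the literal ``"synthetic"`` (the packaged
    benchmark simulator) or a path to a dataset directory with a manifest.
    """

    formulation: str = "crop_disease"
    dataset: str = "synthetic"
    backbone: str = "tiny"
    input_size: int = 32
    base_seed: int = 0
    train: SourceTrainConfig = field(default_factory=SourceTrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    eval: EvalGridConfig = field(default_factory=EvalGridConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if "metric_params" in t and isinstance(t["metric_params"], dict):
                t["metric_params"] = MetricParams(**t["metric_params"])
            if "epochs" in t and t["epochs"] is not None:
                t["epochs"] = int(t["epochs"])
            d["train"] = SourceTrainConfig(**t)
        if "finetune" in d and isinstance(d["finetune"], dict):
            d["finetune"] = FinetuneConfig(**d["finetune"])
        if "eval" in d and isinstance(d["eval"], dict):
            e = dict(d["eval"])
            if "K_values" in e:
                e["K_values"] = tuple(int(k) for k in e["K_values"])
            d["eval"] = EvalGridConfig(**e)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
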