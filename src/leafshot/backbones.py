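"""Residual-network feature extractors and the 128-d metric head.

Three standard residual topologies are provided — 18 and 34 layers with
basic blocks (512-d features) and 50 layers with bottleneck blocks (2048-d
features) — plus a ``tiny`` four-block variant (64-d) sized for CPU-scale
experiments and tests.  All map an RGB image batch to a feature vector via
global average pooling; an optional fully connected + ReLU head projects
features to a 128-dimensional metric-learning embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

_FEATURE_DIMS = {"18": 512, "34": 512, "50": 2048, "tiny": 64}
EMBEDDING_DIM = 128


@dataclass(frozen=True)
class BackboneConfig:
    depth: str = "tiny"  # one of {"18", "34", "50", "tiny"}
    input_size: int = 224
    seed: int = 0

    def __post_init__(self):
        if str(self.depth) not in _FEATURE_DIMS:
            raise ValueError(f"depth: unknown backbone depth {self.depth!r}")

    @property
    def feature_dim(self) -> int:
        return _FEATURE_DIMS[str(self.depth)]

    def fingerprint(self) -> str:
        return f"resnet{self.depth}/in{self.input_size}"


def _make_stage(block, in_ch, ch, n_blocks, stride, rng):
    layers = [block(in_ch, ch, stride, rng)]
    for _ in range(n_blocks - 1):
        layers.append(block(ch * block.expansion, ch, 1, rng))
    return layers, ch * block.expansion


def _resnet(depth: str, rng: np.random.Generator) -> nn.Sequential:
    plan = {
        "18": (nn.BasicBlock, [2, 2, 2, 2]),
        "34": (nn.BasicBlock, [3, 4, 6, 3]),
        "50": (nn.Bottleneck, [3, 4, 6, 3]),
    }[depth]
    block, counts = plan
    layers: list[nn.Layer] = [
        nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, 1),
    ]
    in_ch = 64
    for ch, n, stride in zip([64, 128, 256, 512], counts, [1, 2, 2, 2]):
        stage, in_ch = _make_stage(block, in_ch, ch, n, stride, rng)
        layers.extend(stage)
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


def _tiny(rng: np.random.Generator) -> nn.Sequential:
    """Four residual blocks on a 16-channel stem; 64-d features."""
    return nn.Sequential(
        nn.Conv2d(3, 16, 3, rng=rng),
        nn.BatchNorm2d(16),
        nn.ReLU(),
        nn.BasicBlock(16, 16, 1, rng),
        nn.BasicBlock(16, 32, 2, rng),
        nn.BasicBlock(32, 64, 2, rng),
        nn.BasicBlock(64, 64, 1, rng),
        nn.GlobalAvgPool(),
    )


class EmbeddingHead(nn.Sequential):
    """Fully connected layer + ReLU mapping features to a 128-d embedding."""

    def __init__(self, in_dim: int, out_dim: int = EMBEDDING_DIM, seed: int = 0):
        rng = np.random.default_rng(seed)
        super().__init__(nn.Linear(in_dim, out_dim, rng=rng), nn.ReLU())
        self.out_dim = out_dim


class Embedder:
    """A backbone (optionally with a metric head) mapping images to features.

    ``embed`` runs in evaluation mode (batch-norm running statistics), so it
    is a pure function of the weights; training pipelines drive the layers
    directly in train mode.
    """

    def __init__(self, config: BackboneConfig, head: EmbeddingHead | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        depth = str(config.depth)
        self.backbone = _tiny(rng) if depth == "tiny" else _resnet(depth, rng)
        self.head = head
        self.feature_dim = config.feature_dim

    @property
    def out_dim(self) -> int:
        return self.head.out_dim if self.head is not None else self.feature_dim

    def parameters(self) -> list[nn.Param]:
        ps = self.backbone.parameters()
        if self.head is not None:
            ps = ps + self.head.parameters()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True) -> None:
        self.backbone.train(mode)
        if self.head is not None:
            self.head.train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.backbone.forward(x)
        if self.head is not None:
            f = self.head.forward(f)
        return f

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.head is not None:
            grad = self.head.backward(grad)
        return self.backbone.backward(grad)

    def embed(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Map an NHWC or NCHW float image batch to feature vectors (eval mode)."""
        x = as_nchw(images)
        if x.shape[2] != x.shape[3]:
            raise ValueError("embed: images must be square")
        self.train(False)
        outs = [
            self.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- checkpointing ------------------------------------------------------

    def state(self) -> dict:
        model: list[nn.Layer] = [self.backbone] + ([self.head] if self.head else [])
        arrays = [a for m in model for a in nn.get_state(m)]
        return {"fingerprint": self.config.fingerprint(), "arrays": arrays}

    def load_state(self, state: dict) -> None:
        if state["fingerprint"] != self.config.fingerprint():
            raise ValueError(
                f"checkpoint fingerprint {state['fingerprint']!r} does not match "
                f"model {self.config.fingerprint()!r}"
            )
        arrays = state["arrays"]
        n_bb = len(nn.get_state(self.backbone))
        nn.set_state(self.backbone, arrays[:n_bb])
        if self.head is not None:
            nn.set_state(self.head, arrays[n_bb:])

    def save(self, path) -> None:
        state = self.state()
        np.savez(
            path,
            fingerprint=np.array(state["fingerprint"]),
            **{f"a{i}": a for i, a in enumerate(state["arrays"])},
        )

    def load(self, path) -> None:
        z = np.load(path, allow_pickle=False)
        arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
        self.load_state({"fingerprint": str(z["fingerprint"]), "arrays": arrays})


def build_backbone(config: BackboneConfig, with_head: bool = False) -> Embedder:
    """Construct a trainable image-to-feature embedder per the config."""
    head = EmbeddingHead(config.feature_dim, seed=config.seed + 1) if with_head else None
    return Embedder(config, head)


def as_nchw(images: np.ndarray) -> np.ndarray:
    """Accept NHWC (channel-last) or NCHW float arrays; return NCHW float32."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("images: expected a 4-d batch")
    if x.shape[-1] == 3 and x.shape[1] != 3:
        x = x.transpose(0, 3, 1, 2)
    return np.ascontiguousarray(x)


def stack_images(images, size: int | None = None) -> np.ndarray:
    """Stack LabeledImage pixel rasters into an NHWC batch, resizing if asked."""
    from skimage.transform import resize

    arrs = []
    for im in images:
        px = im.pixels if hasattr(im, "pixels") else np.asarray(im)
        if size is not None and px.shape[0] != size:
            px = resize(px, (size, size), preserve_range=True, anti_aliasing=True)
        arrs.append(px.astype(np.float32))
    return np.stack(arrs)
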