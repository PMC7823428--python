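"""Class catalogs, domain splits, episode sampling and augmentation.

The package ships the class tables of the two leaf-disease corpora it
models: the 38 crop-disease classes of the PlantVillage collection (with
the preset 80/20 train/test counts), the same collection rearranged by
common disease name, and the six-class Arabica coffee-leaf table.  On top
of the catalogs this module provides

* the crop-disease -> disease-name remapping (merging every disease that
  affects several crops into one class and pooling a "Healthy" class of
  roughly 5000 images subsampled from all healthy plants),
* source/target domain splits for the two problem formulations,
* C-way/K-shot episode sampling with disjoint support and query sets, and
* the stochastic training augmentation (flips, rotation up to 30 degrees,
  color jitter by a factor of 0.1, center crop).
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rotate as _sk_rotate

from .synthetic import LabeledImage

HEALTHY = "Healthy"


@dataclass(frozen=True)
class CropDiseaseClass:
    class_id: str
    crop: str
    disease: str
    n_train: int
    n_test: int

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


@dataclass(frozen=True)
class DiseaseNameClass:
    class_id: str
    disease: str
    affected_plants: tuple[str, ...]
    n_train: int
    n_test: int

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


@dataclass(frozen=True)
class DomainSplit:
    source_classes: tuple[str, ...]
    target_classes: tuple[str, ...]

    def __post_init__(self):
        if set(self.source_classes) & set(self.target_classes):
            raise ValueError("source and target class sets must be disjoint")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("leafshot.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_crop_disease_catalog(path: str | Path | None = None) -> list[CropDiseaseClass]:
    """The 38-class crop-disease table (54,305 images in total)."""
    df = pd.read_csv(path) if path is not None else _read_packaged(
        "plantvillage_crop_disease.csv"
    )
    return [
        CropDiseaseClass(r.class_id, r.crop, r.disease, int(r.n_train), int(r.n_test))
        for r in df.itertuples()
    ]


def load_disease_name_catalog(path: str | Path | None = None) -> list[DiseaseNameClass]:
    """The published 21-class disease-name table (as printed, incl. its
    known bookkeeping quirks); see :func:`remap_by_disease_name` for the
    derivation from the crop-disease table."""
    df = pd.read_csv(path) if path is not None else _read_packaged(
        "plantvillage_disease_name.csv"
    )
    return [
        DiseaseNameClass(
            r.class_id,
            r.disease,
            tuple(str(r.affected_plants).split(";")),
            int(r.n_train),
            int(r.n_test),
        )
        for r in df.itertuples()
    ]


def load_coffee_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """The six-class coffee-leaf table (1,747 images, field conditions)."""
    return pd.read_csv(path) if path is not None else _read_packaged("coffee_leaf.csv")


def coffee_as_catalog(df: pd.DataFrame | None = None) -> list[CropDiseaseClass]:
    """View the coffee-leaf table as a catalog (all images counted as test,
    since the collection is never used for source training)."""
    if df is None:
        df = load_coffee_catalog()
    return [
        CropDiseaseClass(r.class_id, "Coffee", r.disease, 0, int(r.n_samples))
        for r in df.itertuples()
    ]


def remap_by_disease_name(
    catalog: Sequence[CropDiseaseClass],
    healthy_target_size: int = 5000,
    seed: int = 0,
) -> list[DiseaseNameClass]:
    """Rearrange a crop-disease catalog by common disease name.

    Every non-healthy disease becomes one class whose train/test counts are
    the sums over the merged source rows; all healthy rows are pooled and
    subsampled to approximately ``healthy_target_size`` images (split
    proportionally between train and test).  Class ids are assigned
    alphabetically by disease name, with the healthy class last.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    non_healthy: dict[str, list[CropDiseaseClass]] = {}
    healthy_rows = []
    for row in catalog:
        if row.disease == HEALTHY:
            healthy_rows.append(row)
        else:
            non_healthy.setdefault(row.disease, []).append(row)

    out: list[DiseaseNameClass] = []
    for i, disease in enumerate(sorted(non_healthy, key=str.lower), start=1):
        rows = non_healthy[disease]
        out.append(
            DiseaseNameClass(
                class_id=f"CD{i}",
                disease=disease,
                affected_plants=tuple(sorted({r.crop for r in rows})),
                n_train=sum(r.n_train for r in rows),
                n_test=sum(r.n_test for r in rows),
            )
        )
    if healthy_rows:
        pool_train = sum(r.n_train for r in healthy_rows)
        pool_test = sum(r.n_test for r in healthy_rows)
        total = pool_train + pool_test
        size = min(healthy_target_size, total)
        n_train = int(round(size * pool_train / total))
        out.append(
            DiseaseNameClass(
                class_id=f"CD{len(out) + 1}",
                disease=HEALTHY,
                affected_plants=tuple(sorted({r.crop for r in healthy_rows})),
                n_train=n_train,
                n_test=size - n_train,
            )
        )
    return out


def make_domain_split(
    catalog: Sequence[CropDiseaseClass] | Sequence[DiseaseNameClass],
    formulation: str,
    all_target: bool = False,
) -> DomainSplit:
    """Source/target class split for a problem formulation.

    ``crop_disease``: the six classes C1-C6 are the novel target domain and
    C7-C38 the source.  ``disease_name``: the three diseases with the fewest
    images (CD1, CD4, CD19) are the target and the remaining 18 classes the
    source.  With ``all_target=True`` (external catalogs such as the coffee
    table) every class is a novel target class and the source is empty.
    """
    ids = [c.class_id for c in catalog]
    if all_target:
        return DomainSplit((), tuple(ids))
    if formulation == "crop_disease":
        target = [f"C{i}" for i in range(1, 7)]
    elif formulation == "disease_name":
        target = ["CD1", "CD4", "CD19"]
    else:
        raise ValueError(f"unknown formulation {formulation!r}")
    missing = set(target) - set(ids)
    if missing:
        raise ValueError(f"catalog lacks expected class ids: {sorted(missing)}")
    source = tuple(i for i in ids if i not in set(target))
    return DomainSplit(source, tuple(target))


# ---------------------------------------------------------------------------
# Episodes


@dataclass
class Episode:
    """A C-way/K-shot episode: support and disjoint query sets."""

    support: list[tuple[LabeledImage, int]]
    query: list[tuple[LabeledImage, int]]
    C: int
    K: int
    Q: int
    class_names: tuple[str, ...] = ()
    support_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    query_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def to_manifest(self) -> dict:
        return {
            "C": self.C,
            "K": self.K,
            "Q": self.Q,
            "classes": list(self.class_names),
            "support": [int(i) for i in self.support_indices],
            "query": [int(i) for i in self.query_indices],
        }


def sample_episode(
    images: Sequence[LabeledImage],
    classes: Sequence[str],
    K: int,
    Q: int,
    seed: int,
) -> Episode:
    """Sample K support and Q query images per class, without replacement.

    Class indices are assigned alphabetically by class name; support and
    query sets are disjoint by construction.  Images are matched to classes
    by their ``disease`` label.
    """
    names = tuple(sorted(classes))
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {c: [] for c in names}
    for i, img in enumerate(images):
        if img.disease in by_class:
            by_class[img.disease].append(i)
    support, query, s_idx, q_idx = [], [], [], []
    for ci, name in enumerate(names):
        pool = by_class[name]
        if len(pool) < K + Q:
            raise ValueError(
                f"class {name!r} has {len(pool)} images, needs K+Q={K + Q}"
            )
        pick = rng.choice(len(pool), size=K + Q, replace=False)
        for j in pick[:K]:
            support.append((images[pool[j]], ci))
            s_idx.append(pool[j])
        for j in pick[K:]:
            query.append((images[pool[j]], ci))
            q_idx.append(pool[j])
    return Episode(
        support,
        query,
        C=len(names),
        K=K,
        Q=Q,
        class_names=names,
        support_indices=np.array(s_idx),
        query_indices=np.array(q_idx),
    )


# ---------------------------------------------------------------------------
# Augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation: flips, rotation 0-30 degrees, color
    jitter by a factor of 0.1, and a center crop of 0.875 of the side."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotation_range: tuple[float, float] = (0.0, 30.0)
    jitter: float = 0.1
    crop_fraction: float = 0.875
    out_size: int | None = None


def center_crop(pixels: np.ndarray, fraction: float, out_size: int | None = None) -> np.ndarray:
    h, w = pixels.shape[:2]
    side = max(1, int(round(fraction * min(h, w))))
    y0, x0 = (h - side) // 2, (w - side) // 2
    out = pixels[y0 : y0 + side, x0 : x0 + side]
    if out_size is not None and out_size != side:
        from skimage.transform import resize

        out = resize(out, (out_size, out_size), preserve_range=True, anti_aliasing=True)
    return out.astype(pixels.dtype)


def augment(
    image: LabeledImage, seed: int, config: AugmentConfig = AugmentConfig()
) -> LabeledImage:
    """Randomly augmented copy of an image; labels are preserved.

    Operations, in order: horizontal flip (p=0.5), vertical flip (p=0.5),
    counter-clockwise rotation uniform in the configured range (bilinear,
    reflect padding), hue/saturation/brightness/contrast jitter with the
    configured factor, center crop.
    """
    rng = np.random.default_rng(seed)
    px = np.asarray(image.pixels, dtype=np.float64)

    if rng.random() < config.p_hflip:
        px = px[:, ::-1]
    if rng.random() < config.p_vflip:
        px = px[::-1, :]

    lo, hi = config.rotation_range
    angle = rng.uniform(lo, hi)
    if angle != 0.0:
        px = _sk_rotate(px, angle, resize=False, order=1, mode="reflect")

    j = config.jitter
    if j > 0:
        hsv = rgb2hsv(px.clip(0, 1))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-j, j)) % 1.0
        hsv[..., 1] = (hsv[..., 1] * rng.uniform(1 - j, 1 + j)).clip(0, 1)
        hsv[..., 2] = (hsv[..., 2] * rng.uniform(1 - j, 1 + j)).clip(0, 1)
        px = hsv2rgb(hsv)
        c = rng.uniform(1 - j, 1 + j)
        px = ((px - px.mean()) * c + px.mean()).clip(0, 1)

    px = center_crop(px, config.crop_fraction, config.out_size)
    return LabeledImage(
        px.astype(np.float32), image.crop, image.disease, image.domain, image.split
    )


def catalog_to_frame(catalog) -> pd.DataFrame:
    """Tabular view of a catalog (round-trips through CSV)."""
    rows = []
    for c in catalog:
        d = {"class_id": c.class_id, "disease": c.disease, "n_train": c.n_train,
             "n_test": c.n_test}
        if isinstance(c, CropDiseaseClass):
            d["crop"] = c.crop
        else:
            d["affected_plants"] = ";".join(c.affected_plants)
        rows.append(d)
    return pd.DataFrame(rows)
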