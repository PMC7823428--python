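"""Procedural generation of labeled leaf-disease images.

Real leaf-disease corpora (tens of thousands of photographs) are impractical
for desk-scale testing, so this module synthesizes small RGB images with a
known class structure: a randomized leaf silhouette on a background, with
class-conditional lesions (spots, pustules, blotches, mosaic mottling,
marginal scorch) drawn inside the silhouette.  A :class:`DomainSpec` applies
an appearance transform (background type, illumination gain, blur, hue
shift) so that a "lab" and a "field" rendering of the same classes differ in
their channel statistics — a controllable stand-in for the domain shift
between bench photographs and field photographs.

Everything is deterministic given the argument tuple and an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

LESION_KINDS = ("spots", "pustules", "blotch", "mosaic", "scorch", "none")

_LEAF_GREEN = np.array([0.20, 0.45, 0.15])
_PLAIN_BG = np.array([0.82, 0.80, 0.78])


@dataclass(frozen=True)
class DiseaseClassSpec:
    """Appearance recipe for one disease class.

    ``lesion_radius_range`` is expressed as a fraction of the image side,
    so recipes are resolution independent.
    """

    name: str
    lesion_kind: str = "spots"
    lesion_count_range: tuple[int, int] = (4, 8)
    lesion_radius_range: tuple[float, float] = (0.03, 0.06)
    lesion_color: tuple[float, float, float] = (0.45, 0.30, 0.10)
    color_jitter: float = 0.02
    crop: str = "synthetic"

    def validate(self) -> None:
        if self.lesion_kind not in LESION_KINDS:
            raise ValueError(f"lesion_kind: unknown kind {self.lesion_kind!r}")
        lo, hi = self.lesion_count_range
        if lo < 0 or lo > hi:
            raise ValueError("lesion_count_range: need 0 <= lo <= hi")
        if self.lesion_kind == "none" and (lo, hi) != (0, 0):
            raise ValueError("lesion_count_range: must be (0, 0) when lesion_kind='none'")
        rlo, rhi = self.lesion_radius_range
        if not (0.0 < rlo <= rhi < 0.5):
            raise ValueError("lesion_radius_range: need 0 < lo <= hi < 0.5")
        if any(not (0.0 <= c <= 1.0) for c in self.lesion_color):
            raise ValueError("lesion_color: components must lie in [0, 1]")
        if self.color_jitter < 0:
            raise ValueError("color_jitter: must be >= 0")


@dataclass(frozen=True)
class DomainSpec:
    """Appearance conditions of an acquisition domain."""

    name: str
    background: str = "plain"
    illumination_gain_range: tuple[float, float] = (0.95, 1.05)
    blur_sigma: float = 0.0
    hue_shift: float = 0.0

    def validate(self) -> None:
        if self.background not in ("plain", "cluttered"):
            raise ValueError(f"background: unknown background {self.background!r}")
        lo, hi = self.illumination_gain_range
        if not (0 < lo <= hi):
            raise ValueError("illumination_gain_range: need 0 < lo <= hi")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma: must be >= 0")


#: Bench-style acquisition: uniform background, even illumination, sharp focus.
LAB_DOMAIN = DomainSpec("lab", "plain", (0.95, 1.05), 0.0, 0.0)
#: Field-style acquisition: cluttered background, darker and more variable
#: illumination, mild defocus and a hue cast.
FIELD_DOMAIN = DomainSpec("field", "cluttered", (0.55, 0.90), 1.0, 0.08)


@dataclass
class LabeledImage:
    """An RGB raster with its crop/disease/domain labels and split tag.

    Generated images are always at least 32x32; augmentation crops may be
    smaller (they exist only as transient training inputs).
    """

    pixels: np.ndarray  # H x W x 3 float32 in [0, 1]
    crop: str
    disease: str
    domain: str
    split: str = "train"


def _rng_for(seed: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *extra]))


def _leaf_mask(size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth closed silhouette: radially perturbed ellipse.

    Returns the boolean mask and the elliptical "radius fraction" field used
    to locate the leaf margin (values near 1 are at the edge).
    """
    a = rng.uniform(0.33, 0.42) * size
    b = rng.uniform(0.24, 0.33) * size
    phase = rng.uniform(0, 2 * np.pi, size=4)
    amp = rng.uniform(0.0, 0.07, size=4)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - size / 2, yy - size / 2
    theta = np.arctan2(dy, dx)
    wobble = 1.0 + sum(
        amp[k] * np.cos((k + 2) * theta + phase[k]) for k in range(4)
    )
    efrac = np.sqrt((dx / (a * wobble)) ** 2 + (dy / (b * wobble)) ** 2)
    return efrac <= 1.0, efrac


def _place_disks(
    mask: np.ndarray,
    count: int,
    r_px: float,
    rng: np.random.Generator,
    *,
    separate: bool,
    max_tries: int = 4000,
) -> np.ndarray:
    """Boolean map of ``count`` disks inside ``mask``.

    With ``separate=True`` the disks are pairwise disjoint and fully inside
    the silhouette, so the connected-component count of the result equals
    ``count`` exactly.
    """
    size = mask.shape[0]
    inner = ndimage.binary_erosion(mask, iterations=max(1, int(np.ceil(r_px))))
    ys, xs = np.nonzero(inner)
    if len(ys) == 0:
        raise ValueError("lesion_radius_range: lesions too large for the leaf silhouette")
    yy, xx = np.mgrid[0:size, 0:size]
    # disks of radius r on a grid cannot touch if centers are > 2r + 1.5 apart
    min_d2 = (2 * r_px + 1.5) ** 2
    for _restart in range(20):
        centers: list[tuple[int, int]] = []
        # greedy sweep over a shuffled list of valid centers approximates a
        # maximal packing, far more reliable than rejection sampling
        for i in rng.permutation(len(ys)):
            cy, cx = int(ys[i]), int(xs[i])
            if separate and any(
                (cy - py) ** 2 + (cx - px) ** 2 <= min_d2 for py, px in centers
            ):
                continue
            centers.append((cy, cx))
            if len(centers) == count:
                break
        if len(centers) == count:
            out = np.zeros_like(mask)
            for cy, cx in centers:
                out |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
            return out
    raise ValueError(
        "lesion_count_range: could not place "
        f"{count} non-overlapping lesions of radius {r_px:.1f}px"
    )


def _smooth_field(size: int, rng: np.random.Generator, grid: int = 6) -> np.ndarray:
    coarse = rng.normal(size=(grid, grid))
    f = ndimage.zoom(coarse, size / grid, order=3)[:size, :size]
    f = ndimage.gaussian_filter(f, sigma=size / 24)
    return (f - f.min()) / (np.ptp(f) + 1e-12)


def generate_leaf_image(
    class_spec: DiseaseClassSpec,
    domain: DomainSpec,
    seed: int,
    size: int = 64,
) -> LabeledImage:
    """Render one labeled leaf image; deterministic in (spec, domain, seed)."""
    class_spec.validate()
    domain.validate()
    if size < 32:
        raise ValueError("size: image must be at least 32x32")
    rng = _rng_for(seed)

    mask, efrac = _leaf_mask(size, rng)

    # Background
    if domain.background == "plain":
        img = np.ones((size, size, 3)) * _PLAIN_BG
        img += rng.normal(0, 0.01, size=img.shape)
    else:
        img = np.stack(
            [_smooth_field(size, rng) for _ in range(3)], axis=-1
        ) * np.array([0.45, 0.40, 0.25]) + np.array([0.15, 0.20, 0.08])

    # Leaf body with gentle shading texture
    leaf_col = _LEAF_GREEN + rng.normal(0, 0.03, size=3)
    shading = 0.85 + 0.3 * _smooth_field(size, rng)
    img[mask] = (leaf_col[None, :] * shading[mask, None]).clip(0, 1)

    # Lesions
    lesion_col = np.clip(
        np.asarray(class_spec.lesion_color)
        + rng.normal(0, class_spec.color_jitter, size=3),
        0,
        1,
    )
    lo, hi = class_spec.lesion_count_range
    count = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    rlo, rhi = class_spec.lesion_radius_range
    r_px = rng.uniform(rlo, rhi) * size
    kind = class_spec.lesion_kind
    if kind == "spots" and count > 0:
        lm = _place_disks(mask, count, max(r_px, 1.2), rng, separate=True)
        img[lm] = lesion_col
    elif kind == "pustules" and count > 0:
        lm = _place_disks(mask, count, max(r_px * 0.5, 1.0), rng, separate=False)
        img[lm] = lesion_col
    elif kind == "blotch" and count > 0:
        blotches = np.zeros_like(mask)
        for _ in range(count):
            b_rng = np.random.default_rng(rng.integers(2**31))
            sub, _ = _leaf_mask(max(int(4 * r_px), 8), b_rng)
            cy, cx = _disk_center(mask, r_px, rng)
            blotches |= _paste(mask.shape, sub, cy, cx)
        blotches &= mask
        img[blotches] = 0.6 * lesion_col + 0.4 * img[blotches]
    elif kind == "mosaic":
        f = _smooth_field(size, rng, grid=10)
        mm = mask & (f > 0.6)
        img[mm] = 0.7 * lesion_col + 0.3 * img[mm]
    elif kind == "scorch":
        band = mask & (efrac > 0.72)
        img[band] = 0.8 * lesion_col + 0.2 * img[band]

    # Domain appearance transform
    gain = rng.uniform(*domain.illumination_gain_range)
    img = img * gain
    if domain.hue_shift:
        hsv = rgb2hsv(img.clip(0, 1))
        hsv[..., 0] = (hsv[..., 0] + domain.hue_shift) % 1.0
        img = hsv2rgb(hsv)
    if domain.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(domain.blur_sigma, domain.blur_sigma, 0))

    return LabeledImage(
        pixels=img.clip(0, 1).astype(np.float32),
        crop=class_spec.crop,
        disease=class_spec.name,
        domain=domain.name,
    )


def _disk_center(mask: np.ndarray, r_px: float, rng: np.random.Generator) -> tuple[int, int]:
    inner = ndimage.binary_erosion(mask, iterations=max(1, int(r_px)))
    ys, xs = np.nonzero(inner if inner.any() else mask)
    i = rng.integers(len(ys))
    return int(ys[i]), int(xs[i])


def _paste(shape: tuple[int, ...], sub: np.ndarray, cy: int, cx: int) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    h, w = sub.shape
    y0, x0 = cy - h // 2, cx - w // 2
    ys0, xs0 = max(y0, 0), max(x0, 0)
    ys1, xs1 = min(y0 + h, shape[0]), min(x0 + w, shape[1])
    if ys1 > ys0 and xs1 > xs0:
        out[ys0:ys1, xs0:xs1] = sub[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
    return out


def generate_dataset(
    class_specs: Sequence[DiseaseClassSpec],
    n_per_class: int | Mapping[str, int],
    domain: DomainSpec,
    train_fraction: float = 0.8,
    seed: int = 0,
    size: int = 64,
) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate a labeled dataset plus its manifest table.

    Per-class counts are honored exactly and the train/test assignment is a
    deterministic function of ``seed``.  The manifest has one row per image
    with columns ``path,crop,disease,domain,split`` (paths are the names the
    images would be written under; see :func:`write_dataset`).
    """
    names = [s.name for s in class_specs]
    if len(set(names)) != len(names):
        raise ValueError("class_specs: duplicate class names")
    if not class_specs:
        raise ValueError("class_specs: need at least one class")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction: must lie in (0, 1)")

    counts = {
        s.name: (n_per_class if isinstance(n_per_class, int) else int(n_per_class[s.name]))
        for s in class_specs
    }
    if any(c < 1 for c in counts.values()):
        raise ValueError("n_per_class: need at least one image per class")

    images: list[LabeledImage] = []
    rows = []
    for ci, spec in enumerate(class_specs):
        n = counts[spec.name]
        n_train = int(round(n * train_fraction))
        split_rng = _rng_for(seed, 1, ci)
        order = split_rng.permutation(n)
        splits = np.empty(n, dtype=object)
        splits[order[:n_train]] = "train"
        splits[order[n_train:]] = "test"
        for ii in range(n):
            child = int(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 2, ci, ii]).generate_state(1)[0]
                % 2**31
            )
            img = generate_leaf_image(spec, domain, seed=child, size=size)
            img.split = str(splits[ii])
            images.append(img)
            rows.append(
                {
                    "path": f"{spec.name.replace(' ', '_')}_{ii:04d}.png",
                    "crop": img.crop,
                    "disease": img.disease,
                    "domain": img.domain,
                    "split": img.split,
                }
            )
    return images, pd.DataFrame(rows)


def write_dataset(
    images: Sequence[LabeledImage],
    manifest: pd.DataFrame,
    outdir: str | Path,
    descriptor: dict | None = None,
) -> None:
    """Write PNGs, ``manifest.csv`` and an optional JSON regeneration descriptor."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for img, path in zip(images, manifest["path"]):
        arr = (img.pixels * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(outdir / path)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    if descriptor is not None:
        (outdir / "descriptor.json").write_text(json.dumps(descriptor, indent=2))


def read_dataset(outdir: str | Path) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Load a dataset previously written by :func:`write_dataset`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    images = []
    for _, row in manifest.iterrows():
        arr = np.asarray(Image.open(outdir / row["path"]), dtype=np.float32) / 255.0
        images.append(
            LabeledImage(arr, row["crop"], row["disease"], row["domain"], row["split"])
        )
    return images, manifest


def dataset_descriptor(
    class_specs: Sequence[DiseaseClassSpec],
    n_per_class: int | Mapping[str, int],
    domain: DomainSpec,
    train_fraction: float,
    seed: int,
    size: int,
) -> dict:
    return {
        "class_specs": [dataclasses.asdict(s) for s in class_specs],
        "n_per_class": n_per_class if isinstance(n_per_class, int) else dict(n_per_class),
        "domain": dataclasses.asdict(domain),
        "train_fraction": train_fraction,
        "seed": seed,
        "size": size,
    }


def benchmark_class_specs() -> list[DiseaseClassSpec]:
    """Eight well-separated disease recipes used by the synthetic benchmark.

    The first five act as the source label space, the last three as novel
    target classes; lesion kinds and colors are chosen to be distinguishable
    so that the class-conditional signal, not rendering noise, dominates.
    """
    return [
        DiseaseClassSpec("brown spot", "spots", (5, 8), (0.03, 0.05), (0.45, 0.28, 0.08)),
        DiseaseClassSpec("rust", "pustules", (25, 45), (0.015, 0.025), (0.75, 0.40, 0.05)),
        DiseaseClassSpec("gray blotch", "blotch", (1, 2), (0.10, 0.16), (0.55, 0.55, 0.50)),
        DiseaseClassSpec("mosaic virus", "mosaic", (1, 1), (0.05, 0.10), (0.75, 0.78, 0.30)),
        DiseaseClassSpec("healthy", "none", (0, 0), (0.01, 0.02), (0.0, 0.0, 0.0)),
        DiseaseClassSpec("leaf scorch", "scorch", (1, 1), (0.05, 0.10), (0.50, 0.20, 0.08)),
        DiseaseClassSpec("black rot", "spots", (2, 3), (0.06, 0.08), (0.12, 0.08, 0.05)),
        DiseaseClassSpec("powdery mildew", "mosaic", (1, 1), (0.05, 0.10), (0.92, 0.92, 0.90)),
    ]
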