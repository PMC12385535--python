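"""Synthetic dermatoscopy-like fixtures: masked lesion images on transparent
background, with controllable class imbalance.

Each image is an RGBA array whose alpha plane is a lesion mask: outside the
lesion every channel is exactly (0, 0, 0, 0) (pre-masked skin background),
inside alpha = 255 and the color is the class base color plus a per-image
jitter and per-pixel texture noise.  Lesion geometry is an ellipse whose
radius is perturbed by low-order harmonics, giving ABCD-like border
irregularity; the centroid stays near the image center.

The generator is deterministic: each image's RNG stream is derived from
(dataset seed, class id, image index), so adding a class or images never
reshuffles existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class ClassSpec:
    """Appearance parameters of one synthetic lesion class."""

    class_id: int
    base_color: tuple[int, int, int]
    color_jitter: float = 0.0     # std of per-image color shift (intensity)
    shape: str = "ellipse"        # 'ellipse' or 'blob'
    irregularity: float = 0.0     # boundary perturbation amplitude in [0, 1]
    texture_noise: float = 0.0    # per-pixel noise std (intensity)
    name: str = ""

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")
        if len(self.base_color) != 3 or any(not 0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color components must lie in [0, 255]")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must lie in [0, 1]")
        if self.texture_noise < 0 or self.color_jitter < 0:
            raise ValueError("noise levels must be non-negative")
        if self.shape not in ("ellipse", "blob"):
            raise ValueError("shape must be 'ellipse' or 'blob'")
        if not self.name:
            object.__setattr__(self, "name", f"class{self.class_id}")


@dataclass(frozen=True)
class DatasetManifest:
    """Counts, geometry and split fractions of a generated dataset."""

    counts: tuple[int, ...]
    seed: int = 0
    image_height: int = 64
    image_width: int = 96
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f):
            raise ValueError("split_fractions must be three non-negative numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("images must be at least 16x16")


@dataclass
class LesionDataset:
    """In-memory labelled image collection with split assignment."""

    images: list[np.ndarray]
    labels: np.ndarray
    splits: dict[str, np.ndarray]          # split name -> indices into images
    class_names: list[str]
    manifest: DatasetManifest

    def subset(self, split: str) -> tuple[list[np.ndarray], np.ndarray]:
        idx = self.splits[split]
        return [self.images[i] for i in idx], self.labels[idx]

    def class_counts(self, split: str) -> np.ndarray:
        _, labels = self.subset(split)
        return np.bincount(labels, minlength=len(self.class_names))


def _image_seed(seed: int, class_id: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(class_id), int(index)]))


def generate_lesion_image(spec: ClassSpec, height: int, width: int, seed) -> np.ndarray:
    """One (height, width, 4) RGBA lesion image; deterministic in its arguments.

    `seed` is an integer or a Generator (internal use).
    """
    if height < 16 or width < 16:
        raise ValueError("height and width must be at least 16 pixels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))

    # geometry: center jitter <= 5% so the centroid stays within 10% of center
    cy = height / 2.0 + rng.uniform(-0.05, 0.05) * height
    cx = width / 2.0 + rng.uniform(-0.05, 0.05) * width
    semi_b = rng.uniform(0.22, 0.34) * height
    semi_a = rng.uniform(0.22, 0.34) * width

    # radial boundary perturbation by low-order harmonics
    max_harmonic = 8 if spec.shape == "blob" else 5
    ks = np.arange(2, max_harmonic + 1)
    amps = rng.normal(0.0, 1.0 / ks)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=ks.size)
    norm = np.abs(amps).sum()
    if norm > 0:
        amps = amps / norm

    yy, xx = np.mgrid[0:height, 0:width]
    u = (xx - cx) / semi_a
    v = (yy - cy) / semi_b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    pert = spec.irregularity * 0.3 * sum(
        a * np.cos(k * theta + ph) for a, k, ph in zip(amps, ks, phases)
    )
    mask = rho <= 1.0 + pert

    img = np.zeros((height, width, 4), dtype=np.uint8)
    color = np.asarray(spec.base_color, dtype=np.float64)
    if spec.color_jitter > 0:
        color = color + rng.normal(0.0, spec.color_jitter, size=3)
    pixels = np.broadcast_to(color, (int(mask.sum()), 3)).copy()
    if spec.texture_noise > 0:
        pixels += rng.normal(0.0, spec.texture_noise, size=pixels.shape)
    img[mask, :3] = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    img[mask, 3] = 255
    return img


def _stratified_split(n: int, fractions, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Shuffle n indices and cut at cumulative-rounded boundaries."""
    order = rng.permutation(n)
    b1 = int(round(n * fractions[0]))
    b2 = int(round(n * (fractions[0] + fractions[1])))
    return {
        "train": np.sort(order[:b1]),
        "validation": np.sort(order[b1:b2]),
        "test": np.sort(order[b2:]),
    }


def generate_dataset(specs: list[ClassSpec], manifest: DatasetManifest) -> LesionDataset:
    """Generate the full labelled collection with stratified splits."""
    if len(specs) != len(manifest.counts):
        raise ValueError(
            f"got {len(specs)} class specs but {len(manifest.counts)} class counts"
        )
    images: list[np.ndarray] = []
    labels: list[int] = []
    split_members: dict[str, list[int]] = {s: [] for s in SPLITS}
    for spec, count in zip(specs, manifest.counts):
        base = len(images)
        for idx in range(count):
            rng = _image_seed(manifest.seed, spec.class_id, idx)
            images.append(
                generate_lesion_image(spec, manifest.image_height, manifest.image_width, rng)
            )
            labels.append(spec.class_id)
        split_rng = np.random.default_rng(
            np.random.SeedSequence([int(manifest.seed), int(spec.class_id), 982451653])
        )
        for split, idx in _stratified_split(count, manifest.split_fractions, split_rng).items():
            split_members[split].extend((base + idx).tolist())
    return LesionDataset(
        images=images,
        labels=np.asarray(labels, dtype=int),
        splits={s: np.asarray(v, dtype=int) for s, v in split_members.items()},
        class_names=[spec.name for spec in specs],
        manifest=manifest,
    )


def save_dataset(ds: LesionDataset, root: str | Path) -> Path:
    """Write PNGs as <root>/<split>/<class_name>/img_<idx>.png plus manifest.json."""
    root = Path(root)
    membership = {}
    for split in SPLITS:
        for i in ds.splits[split]:
            cls = ds.class_names[ds.labels[i]]
            d = root / split / cls
            d.mkdir(parents=True, exist_ok=True)
            Image.fromarray(ds.images[i], mode="RGBA").save(d / f"img_{i}.png")
            membership[str(i)] = split
    meta = {
        "counts": list(ds.manifest.counts),
        "seed": ds.manifest.seed,
        "image_height": ds.manifest.image_height,
        "image_width": ds.manifest.image_width,
        "split_fractions": list(ds.manifest.split_fractions),
        "class_names": ds.class_names,
        "membership": membership,
    }
    (root / "manifest.json").write_text(json.dumps(meta, indent=1))
    return root


def load_dataset(root: str | Path) -> LesionDataset:
    """Inverse of :func:`save_dataset`."""
    root = Path(root)
    meta = json.loads((root / "manifest.json").read_text())
    class_names = meta["class_names"]
    images: list[np.ndarray] = []
    labels: list[int] = []
    splits: dict[str, list[int]] = {s: [] for s in SPLITS}
    for split in SPLITS:
        split_dir = root / split
        if not split_dir.is_dir():
            continue
        for cls_dir in sorted(split_dir.iterdir()):
            cls_id = class_names.index(cls_dir.name)
            for png in sorted(cls_dir.glob("img_*.png"), key=lambda p: int(p.stem.split("_")[1])):
                splits[split].append(len(images))
                images.append(np.asarray(Image.open(png).convert("RGBA")))
                labels.append(cls_id)
    manifest = DatasetManifest(
        counts=tuple(meta["counts"]),
        seed=meta["seed"],
        image_height=meta["image_height"],
        image_width=meta["image_width"],
        split_fractions=tuple(meta["split_fractions"]),
    )
    return LesionDataset(
        images=images,
        labels=np.asarray(labels, dtype=int),
        splits={s: np.asarray(v, dtype=int) for s, v in splits.items()},
        class_names=class_names,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Shipped fixtures
# ---------------------------------------------------------------------------

#: per-class counts of the default imbalanced fixture (majority:minority 60:1,
#: mirroring the long-tailed distribution of public dermatoscopy archives)
DEFAULT_COUNTS = (600, 300, 150, 80, 60, 40, 30, 20, 10)

_CLASS_NAMES = ("MEL", "NV", "BCC", "AK", "BKL", "DF", "VASC", "SCC", "UNK")
_BASE_COLORS = (
    (60, 35, 30),     # MEL: very dark brown/black
    (140, 90, 60),    # NV: mid brown
    (210, 150, 150),  # BCC: pearly pink
    (190, 120, 100),  # AK: reddish tan
    (170, 130, 80),   # BKL: light brown
    (150, 110, 90),   # DF: tan nodule
    (170, 60, 80),    # VASC: red-purple
    (200, 140, 120),  # SCC: pink keratotic
    (128, 128, 128),  # UNK: gray
)


def default_specs(noisy: bool = True) -> list[ClassSpec]:
    """Nine lesion-like class specs; `noisy=False` gives the separable,
    zero-noise variant used for smoke-convergence checks."""
    specs = []
    for i, (name, color) in enumerate(zip(_CLASS_NAMES, _BASE_COLORS)):
        specs.append(
            ClassSpec(
                class_id=i,
                base_color=color,
                color_jitter=8.0 if noisy else 0.0,
                shape="blob" if name in ("MEL", "SCC") else "ellipse",
                irregularity=0.6 if name in ("MEL", "SCC") else 0.25,
                texture_noise=20.0 if noisy else 0.0,
                name=name,
            )
        )
    return specs


def default_manifest(seed: int = 0, counts=DEFAULT_COUNTS) -> DatasetManifest:
    return DatasetManifest(counts=tuple(counts), seed=seed)


def separable_fixture(seed: int = 0, counts=DEFAULT_COUNTS) -> LesionDataset:
    """Noise-free, perfectly color-separable nine-class fixture."""
    return generate_dataset(default_specs(noisy=False), default_manifest(seed, counts))


#: 100:1 majority:minority fixture for imbalance-mitigation experiments
IMBALANCE_COUNTS = (400, 4)


def imbalance_specs() -> list[ClassSpec]:
    """Two moderately-noisy classes: a brown majority and a red minority."""
    return [
        ClassSpec(0, (150, 100, 80), color_jitter=12.0, irregularity=0.3,
                  texture_noise=30.0, name="majority"),
        ClassSpec(1, (170, 60, 60), color_jitter=12.0, irregularity=0.3,
                  texture_noise=30.0, name="minority"),
    ]


def imbalance_fixture(seed: int = 0) -> LesionDataset:
    return generate_dataset(imbalance_specs(), DatasetManifest(counts=IMBALANCE_COUNTS, seed=seed))


def balanced_probe(specs: list[ClassSpec], per_class: int, height: int, width: int,
                   seed: int) -> tuple[list[np.ndarray], np.ndarray]:
    """A balanced evaluation set drawn from a stream disjoint from any
    training fixture (distinct seed component)."""
    images, labels = [], []
    for spec in specs:
        for idx in range(per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(spec.class_id), int(idx), 777])
            )
            images.append(generate_lesion_image(spec, height, width, rng))
            labels.append(spec.class_id)
    return images, np.asarray(labels, dtype=int)
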