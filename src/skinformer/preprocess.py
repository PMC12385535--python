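"""Image standardization, augmentation, and five-channel aggregation.

Images are (H, W, C) uint8 arrays with C = 3 (RGB) or 4 (RGBA); the alpha
plane is a background mask (0 = masked skin background) and is never
modified by any augmentation.  The network consumes a (5, H, W) stack of
(r, g, b, alpha, gray) planes, where gray is the ITU-R 601 luminance.

Augmentations (training only):
  * brightness: g = gamma * f, clipped to [0, L] — a multiplicative
    brightness scale (gamma > 1 brightens, gamma < 1 darkens);
  * contrast: three-segment piecewise-linear stretching with breakpoints
    (r1, s1), (r2, s2) and slopes z1 = s1/r1, z2 = (s2-s1)/(r2-r1),
    z3 = (L-s2)/(L-r2);
  * random horizontal/vertical flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

L_MAX = 255

#: default sampling ranges for training-time augmentation, as fractions of L
GAMMA_RANGE = (0.7, 1.3)
CONTRAST_R1_RANGE = (0.15, 0.35)
CONTRAST_R2_RANGE = (0.65, 0.85)
CONTRAST_S_OFFSET = 0.1
FLIP_P = 0.5


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise ValueError(f"expected (H, W, 3|4) image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image has zero-sized dimension")
    return img


def standardize_resolution(image: np.ndarray, height: int = 784, width: int = 1216) -> np.ndarray:
    """Bilinear resize to a fixed (height, width); uint8 in, uint8 out."""
    img = _check_image(image)
    if height < 1 or width < 1:
        raise ValueError("target dimensions must be positive")
    if img.shape[:2] == (height, width):
        return img.copy()
    mode = "RGBA" if img.shape[2] == 4 else "RGB"
    pil = Image.fromarray(img.astype(np.uint8), mode=mode)
    return np.asarray(pil.resize((width, height), Image.BILINEAR))


def luminance(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma with floor rounding: floor(.299 r + .587 g + .114 b)."""
    r = rgb[..., 0].astype(np.uint32)
    g = rgb[..., 1].astype(np.uint32)
    b = rgb[..., 2].astype(np.uint32)
    return ((299 * r + 587 * g + 114 * b) // 1000).astype(np.uint8)


def to_five_channel(image: np.ndarray) -> np.ndarray:
    """(H, W, 4) RGBA -> (5, H, W) planes (r, g, b, alpha, gray)."""
    img = _check_image(image)
    if img.shape[2] != 4:
        raise ValueError("five-channel aggregation requires an RGBA image (4 planes)")
    gray = luminance(img)
    return np.concatenate([img.transpose(2, 0, 1), gray[None]], axis=0)


def adjust_brightness(image: np.ndarray, gamma: float, l_max: int = L_MAX) -> np.ndarray:
    """Multiplicative brightness g = gamma*f, clipped to [0, l_max]; alpha untouched."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = _check_image(image).astype(np.float64)
    out = img.copy()
    out[..., :3] = np.clip(gamma * img[..., :3], 0, l_max)
    return np.rint(out).astype(np.uint8)


@dataclass(frozen=True)
class ContrastParams:
    """Breakpoints of the piecewise-linear contrast stretch."""

    r1: float
    s1: float
    r2: float
    s2: float
    l_max: float = L_MAX

    def __post_init__(self):
        if not (0 < self.r1 < self.r2 < self.l_max):
            raise ValueError("require 0 < r1 < r2 < L")
        if not (0 <= self.s1 <= self.s2 <= self.l_max):
            raise ValueError("require 0 <= s1 <= s2 <= L")

    @property
    def z1(self) -> float:
        return self.s1 / self.r1

    @property
    def z2(self) -> float:
        return (self.s2 - self.s1) / (self.r2 - self.r1)

    @property
    def z3(self) -> float:
        return (self.l_max - self.s2) / (self.l_max - self.r2)


def stretch_contrast_values(f: np.ndarray, params: ContrastParams) -> np.ndarray:
    """Apply the three-branch stretch to raw intensity values (float out)."""
    f = np.asarray(f, dtype=np.float64)
    p = params
    return np.where(
        f < p.r1,
        p.z1 * f,
        np.where(f < p.r2, p.z2 * (f - p.r1) + p.s1, p.z3 * (f - p.r2) + p.s2),
    )


def stretch_contrast(image: np.ndarray, params: ContrastParams) -> np.ndarray:
    """Contrast stretch on the color planes; alpha untouched."""
    img = _check_image(image)
    out = img.astype(np.float64).copy()
    out[..., :3] = np.clip(stretch_contrast_values(img[..., :3], params), 0, params.l_max)
    return np.rint(out).astype(np.uint8)


def random_flip(
    image: np.ndarray,
    seed: int | np.random.Generator,
    p_horizontal: float = FLIP_P,
    p_vertical: float = FLIP_P,
) -> np.ndarray:
    """Independently flip left-right / up-down with the given probabilities."""
    if not (0 <= p_horizontal <= 1 and 0 <= p_vertical <= 1):
        raise ValueError("flip probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = _check_image(image)
    if rng.random() < p_horizontal:
        img = img[:, ::-1]
    if rng.random() < p_vertical:
        img = img[::-1]
    return np.ascontiguousarray(img)


class Augmenter:
    """Seeded training-time augmentation pipeline.

    Samples gamma ~ U(0.7, 1.3); contrast breakpoints r1 ~ U(.15L, .35L),
    r2 ~ U(.65L, .85L) with s1 pulled below r1 and s2 pushed above r2 by
    U(0, .1L); flips at p = 0.5 each.  Alpha is never modified.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        gamma_range: tuple[float, float] = GAMMA_RANGE,
        flip_p: float = FLIP_P,
        enabled: bool = True,
    ):
        self.rng = rng
        self.gamma_range = gamma_range
        self.flip_p = flip_p
        self.enabled = enabled

    def sample_contrast(self) -> ContrastParams:
        L = float(L_MAX)
        r1 = self.rng.uniform(*CONTRAST_R1_RANGE) * L
        r2 = self.rng.uniform(*CONTRAST_R2_RANGE) * L
        s1 = max(0.0, r1 - self.rng.uniform(0, CONTRAST_S_OFFSET) * L)
        s2 = min(L, r2 + self.rng.uniform(0, CONTRAST_S_OFFSET) * L)
        return ContrastParams(r1=r1, s1=s1, r2=r2, s2=s2, l_max=L)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return image
        img = adjust_brightness(image, self.rng.uniform(*self.gamma_range))
        img = stretch_contrast(img, self.sample_contrast())
        return random_flip(img, self.rng, self.flip_p, self.flip_p)


def to_network_input(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Stack RGBA images into a float32 (batch, 5, H, W) tensor in [0, 1]."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    planes = [to_five_channel(img) for img in images]
    return np.stack(planes).astype(np.float32) / float(L_MAX)
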