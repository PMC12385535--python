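"""Grad-CAM saliency maps for the convolutional stem.

For a target class c and a target conv layer with activations A_k, the
channel weights are the spatial means of dScore_c/dA_k (Score_c is the
pre-softmax class score); the saliency map is ReLU(sum_k w_k A_k),
bilinearly upsampled to the input size and min-max normalized to [0, 1].

The attention stack operates on tokens and sits outside standard
Grad-CAM's scope; the third (last) conv layer is the default target as the
final spatially-resolved representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .model import HybridSkinFormer
from .preprocess import standardize_resolution, to_network_input


@dataclass
class SaliencyMap:
    heatmap: np.ndarray      # (H, W) floats in [0, 1], aligned to the input
    target_class: int
    target_layer: int

    def to_png(self, path, cmap: str = "jet") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(path, self.heatmap, cmap=cmap, vmin=0.0, vmax=1.0)


def grad_cam(
    model: HybridSkinFormer,
    image: np.ndarray,
    target_class: int,
    target_layer: int = 3,
) -> SaliencyMap:
    """Saliency for one RGBA image; `target_layer` is 1, 2 or 3 (conv index)."""
    if not 1 <= target_layer <= len(model.convs):
        raise ValueError(f"target_layer must be in 1..{len(model.convs)}")
    if not 0 <= target_class < model.config.classes_num:
        raise ValueError(f"target_class must be in 0..{model.config.classes_num - 1}")

    h, w = model.config.input_height, model.config.input_width
    if image.shape[:2] != (h, w):
        image = standardize_resolution(image, h, w)
    x = to_network_input([image])

    model.forward(x)
    onehot = np.zeros((1, model.config.classes_num), dtype=np.float32)
    onehot[0, target_class] = 1.0
    model.zero_grad()
    model.backward_from_logits(onehot)

    acts = model.conv_activations[target_layer - 1][0]    # (C, h', w')
    grads = model.conv_gradients[target_layer - 1][0]
    weights = grads.mean(axis=(1, 2))                      # channel importance
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)

    pil = Image.fromarray(cam.astype(np.float32), mode="F")
    cam_up = np.asarray(pil.resize((w, h), Image.BILINEAR), dtype=np.float64)
    lo, hi = cam_up.min(), cam_up.max()
    if hi > lo:
        cam_up = (cam_up - lo) / (hi - lo)
    else:
        cam_up = np.zeros_like(cam_up)
    return SaliencyMap(heatmap=cam_up, target_class=target_class, target_layer=target_layer)


def lesion_focus(sal: SaliencyMap, image: np.ndarray) -> tuple[float, float]:
    """(fraction of saliency mass inside the alpha>0 lesion mask,
    lesion area fraction) — mass above area indicates on-lesion focus."""
    mask = np.asarray(image)[..., 3] > 0
    total = sal.heatmap.sum()
    inside = float(sal.heatmap[mask].sum() / total) if total > 0 else 0.0
    return inside, float(mask.mean())
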