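"""Walk one image through the preprocessing and augmentation pipeline.

Pipeline: bilinear resolution standardization -> (training only) random
brightness scaling, piecewise-linear contrast stretching and seeded flips
-> five-channel aggregation (r, g, b, alpha, floor-luminance gray)
-> float32 network input scaled to [0, 1].
"""

import numpy as np

from skinformer.preprocess import (
    Augmenter,
    ContrastParams,
    adjust_brightness,
    standardize_resolution,
    stretch_contrast,
    to_five_channel,
    to_network_input,
)
from skinformer.synthetic import default_specs, generate_lesion_image

img = generate_lesion_image(default_specs()[1], 48, 72, seed=7)   # an NV lesion
img = standardize_resolution(img, 64, 96)
print("standardized:", img.shape, img.dtype)

bright = adjust_brightness(img, 1.2)                      # multiplicative, clipped
stretched = stretch_contrast(bright, ContrastParams(r1=60, s1=30, r2=200, s2=225))
print("lesion mean intensity before/after:",
      img[img[..., 3] > 0, :3].mean().round(1),
      stretched[stretched[..., 3] > 0, :3].mean().round(1))

planes = to_five_channel(stretched)                       # (5, H, W) uint8
print("five channels (r,g,b,alpha,gray), gray plane mean:",
      planes.shape, planes[4].mean().round(1))

# the Augmenter samples all transform parameters from one seeded stream
aug = Augmenter(np.random.default_rng(0))
x = to_network_input([aug(img), aug(img)])
print("network input:", x.shape, x.dtype, "range",
      (float(x.min()), round(float(x.max()), 3)))
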