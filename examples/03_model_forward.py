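"""Build the classifier and inspect a forward pass and the parameter census.

Architecture: three valid convolutions (kernel/stride 6/2, 6/3, 9/6) map the
five-channel image to an embed_dim feature map; its positions are flattened
into tokens, given an additive learnable positional tensor, and passed
through pre-normalized multi-head attention layers whose residuals are
learnable convex mixes out = alpha*x + (1-alpha)*branch.  A per-token
classifier head is summed over tokens and softmaxed.

At the full scale (784x1216 input, embed 180, 30 heads, 6 layers) the census
contradicts the published 310.599 K total: the third convolution alone holds
~1.31 M weights.  The reduced test-scale preset keeps every code path while
running on a laptop CPU.
"""

import numpy as np

from skinformer.model import (
    REFERENCE_TOTAL_K,
    HybridSkinFormer,
    ModelConfig,
    conv_output_dims,
    format_parameter_report,
    test_scale_config,
)
from skinformer.preprocess import to_network_input
from skinformer.synthetic import default_specs, generate_lesion_image

print("full-scale feature map for 784x1216 input:",
      conv_output_dims(ModelConfig().conv_schedule(), 784, 1216))

model = HybridSkinFormer(test_scale_config(), seed=0)
images = [generate_lesion_image(default_specs()[i], 64, 96, seed=i) for i in range(3)]
probs = model.forward(to_network_input(images))
print("probabilities:", probs.shape, "row sums:", probs.sum(axis=1).round(6))
print("argmax classes:", probs.argmax(axis=1))

print("\nfull-scale parameter census vs the published figure:")
print(format_parameter_report(HybridSkinFormer(ModelConfig(), seed=0),
                              reference_k=REFERENCE_TOTAL_K))
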