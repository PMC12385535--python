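"""Explain a trained model's prediction with Grad-CAM.

The saliency map back-propagates the one-hot pre-softmax class score to a
conv-stem layer, weights each channel by the spatial mean of its gradient,
ReLUs the weighted sum and upsamples it to the input.  At the test scale the
third conv layer collapses to a single spatial position, so the first layer
(still 30x46) is the informative target; `lesion_focus` quantifies how much
saliency mass falls inside the lesion mask relative to its area.
"""

from skinformer.gradcam import grad_cam, lesion_focus
from skinformer.model import test_scale_config
from skinformer.synthetic import DatasetManifest, default_specs, generate_dataset
from skinformer.train import TrainConfig, train

manifest = DatasetManifest(counts=(30, 30, 30, 30), seed=3,
                           split_fractions=(0.7, 0.15, 0.15))
dataset = generate_dataset(default_specs(noisy=False)[:4], manifest)
result = train(test_scale_config(classes_num=4), dataset,
               TrainConfig(epochs=4, batch_size=10, seed=7, preset="full",
                           augment=False))

images, labels = dataset.subset("test")
image, label = images[0], int(labels[0])
sal = grad_cam(result.model, image, target_class=label, target_layer=1)
inside, area = lesion_focus(sal, image)
print(f"class {label}: saliency mass on lesion {inside:.1%} "
      f"(lesion covers {area:.1%} of the image)")
sal.to_png("cam.png")
print("heatmap written to cam.png")
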