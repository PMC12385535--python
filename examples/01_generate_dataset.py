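"""Generate a synthetic lesion dataset and save it as a PNG directory tree.

The generator draws RGBA images whose alpha plane is a lesion mask:
background pixels are exactly (0, 0, 0, 0), lesion pixels carry the class
base color plus per-image jitter and per-pixel texture noise, and the
boundary is an ellipse perturbed by low-order harmonics.  Splits are
stratified per class and every image is deterministic in
(seed, class_id, index), so regenerating never reshuffles existing images.
"""

from skinformer.synthetic import (
    DatasetManifest,
    default_specs,
    generate_dataset,
    save_dataset,
)

# a scaled-down version of the long-tailed default (600...10) for a quick run
manifest = DatasetManifest(counts=(60, 30, 15, 8, 6, 4, 3, 2, 2), seed=0)
dataset = generate_dataset(default_specs(noisy=True), manifest)

print(f"{len(dataset.images)} images, classes: {dataset.class_names}")
for split in ("train", "validation", "test"):
    print(f"{split:<12}{dataset.class_counts(split)}")

out = save_dataset(dataset, "example_data")
print(f"saved under {out}/<split>/<class>/img_<idx>.png with manifest.json")
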