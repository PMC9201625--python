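"""Generate a small synthetic segmentation dataset and describe it.

Each image holds 1-3 non-overlapping shapes (ellipse / rectangle / annulus,
one kind per class) over a noisy background; masks are pixel-exact and the
per-image classification label is the class of the largest shape.  The same
seed always reproduces the same pixels.
"""

import numpy as np

from onet.synth import SynthSpec, generate_dataset, write_dataset

spec = SynthSpec(n_images=8, image_size=96, n_classes=4, seed=11)
ds = generate_dataset(spec)
write_dataset(ds, "scratch/example_dataset")

print(f"images: {ds.images.shape} uint8, masks: {ds.masks.shape}")
for i in range(len(ds)):
    mask = ds.masks[i]
    classes = [int(c) for c in np.unique(mask) if c]
    areas = {c: int((mask == c).sum()) for c in classes}
    print(f"  image {i}: classes {classes}, areas {areas}, "
          f"label {int(ds.labels['label'].iloc[i])}")
# The label column is the identity of the largest shape, which is what the
# classification head is later trained to recover from the image alone.
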