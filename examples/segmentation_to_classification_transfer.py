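"""Warm-start a classifier from a trained segmentation encoder.

The classifier shares the segmentation network's encoders; copying the
trained encoder weights and fine-tuning only a pooled fully connected head
reaches perfect accuracy on the separable largest-shape labels in a few
dozen AdamW steps.  Run ``train_tiny_segmentation.py`` first to produce the
segmentation checkpoint.
"""

from pathlib import Path

from onet.pipeline import TrainConfig, train_classification_with_transfer
from onet.synth import SynthSpec, generate_dataset

ckpt = Path("scratch/example_seg/best.npz")
if not ckpt.exists():
    raise SystemExit("run examples/train_tiny_segmentation.py first")

ds = generate_dataset(SynthSpec(n_images=8, image_size=64, n_classes=4,
                                seed=123))
labels = ds.labels["label"].to_numpy() - 1   # 3 classes: 0..2

cfg = TrainConfig(task="classification", out_dir="scratch/example_cls",
                  batch_size=8, optimizer="adamw", lr=1e-3, weight_decay=1e-4,
                  max_steps=200, eval_every=10, val_fraction=0.0,
                  augment=False, seed=7, target_metric=1.0)
result = train_classification_with_transfer(ckpt, cfg,
                                            data=(ds.images, labels),
                                            verbose=True)
print(f"stopped after {result.steps_run} steps, "
      f"train accuracy {result.final_metric:.4f}")
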