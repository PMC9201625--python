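"""Overfit the tiny dual-branch model on 8 synthetic images.

Desk-scale sanity check of the whole training loop: a C=24, depth-(1,1)
configuration with both encoders and both decoders memorises 8 images of
64x64 within a few dozen SGD steps.  Foreground Dice >= 0.95 on the
training images means every piece — patch embedding, window attention,
MBConv pyramid, skip fusion, both decoders, the CE + soft-Dice loss and
the optimizer — is wired correctly.
"""

from onet import nn
from onet.model import ONet, tiny_config
from onet.pipeline import TrainConfig, predict, train
from onet.metrics import evaluate_case
from onet.synth import SynthSpec, generate_dataset

ds = generate_dataset(SynthSpec(n_images=8, image_size=64, n_classes=4,
                                seed=123))
nn.manual_seed(7)
model = ONet(tiny_config())
cfg = TrainConfig(task="segmentation", out_dir="scratch/example_seg",
                  batch_size=8, optimizer="sgd", lr=5e-2, max_steps=500,
                  eval_every=25, val_fraction=0.0, augment=False, seed=7,
                  target_metric=0.97)
result = train(model, cfg, tiny_config(), data=(ds.images, ds.masks),
               verbose=True)
print(f"stopped after {result.steps_run} steps, "
      f"train Dice {result.final_metric:.4f}")

masks = predict(result.checkpoint, ds.images)
res = evaluate_case(masks[0], ds.masks[0])
print(f"image 0 per-class Dice: "
      f"{ {c: round(v['dice'], 3) for c, v in res['per_class'].items()} }")
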