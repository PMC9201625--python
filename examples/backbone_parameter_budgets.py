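"""Parameter budgets of candidate CNN encoders.

Prints the trainable-parameter totals of the standard 1000-class
configurations.  The EfficientNet numbers come from instantiating the real
network in this package; the others from analytic layer ledgers.  These are
the budgets one weighs against segmentation accuracy when picking the CNN
branch's encoder (the dual-branch model uses EfficientNet-b3 by default:
roughly half the parameters of ResNet-50 or Inception v3).
"""

from onet.backbones import backbone_parameter_count

for name in ("mobilenetv3", "efficientnet-b0", "efficientnet-b3",
             "densenet201", "inception_v3", "resnet50"):
    n = backbone_parameter_count(name)
    print(f"{name:16s} {n:>11,d} parameters = {n / 1e6:6.2f} M")
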