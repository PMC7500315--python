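# Paper-scale training profile: resnet50 backbone, fast bilinear head.
# Requires a framework-backed backbone adapter and ImageNet weights;
# not exercised by the desk-scale test suite.
backbone: resnet50
optimizer: sgd
initial_lr: 0.1
batch_size: 16
lr_factor: 0.1
lr_patience_epochs: 10
max_epochs: 100
min_lr: 1.0e-05
momentum: 0.0
seed: 0
pretrained: true
image_size: 224
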