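# Desk-scale profile: tiny random-init backbone on 64x64 synthetic images.
backbone: tiny
optimizer: sgd
initial_lr: 0.1
batch_size: 16
lr_factor: 0.1
lr_patience_epochs: 10
max_epochs: 10
min_lr: 1.0e-05
momentum: 0.9
seed: 0
pretrained: false
image_size: 64
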