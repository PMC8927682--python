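# Desk-scale reference experiment: 10 synthetic classes, 64px patches,
# 1/8-width upgraded model, 3-way 3-shot episodes.
seed: 1
data:
  synthetic:
    n_classes: 10
    image_size: 160
    seed: 0
  template: 64
  stride: 48
split:
  n_train: 3
model:
  channel_scale: 0.125
  variant: upgraded
train:
  learning_rate: 0.003
  epochs: 10
  iterations_per_epoch: 20
  C: 3
  K: 3
out: runs/desk
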