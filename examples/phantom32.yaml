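# Desk-scale phantom pipeline: search 50 epochs, extract at 70/70/60, retrain 50.
model:
  image_size: 32
  patch_size: 8
  n_classes: 4
  stem_channels: [8, 16]
  decoder_channels: [32, 16]
  feature_channels: 64
  df_enabled: true
  df_iters: 5
  field_loss_weight: 1.0
  search:
    L: 2
    H: 2
    d: 10
    D: 20
    M: 40
    N: 16
    w_mhsa: 2.0e-4
    w_mlp: 4.0e-4
    w_patch: 1.0e-4
optimizer:
  algorithm: adamw
  lr: 1.0e-3
  weight_decay: 1.0e-2
  batch_size: 14
budget:
  mhsa: 0.7
  mlp: 0.7
  patch: 0.6
search_epochs: 50
retrain_epochs: 50
seed: 1
n_phantoms: 60
phantom_size: 32
noise_sigma: 0.08
blur_sigma: 1.0
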