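# Scaled-down CPU profile: trains the dual-attention 2.5D network on
# synthetic phantoms in minutes.  Keeps the 5:1 slice anisotropy and the
# full five-stage architecture, with reduced patch, channels and
# transformer width.
seed: 11
network:
  variant: transresseunet25d
  stage_channels: [8, 16, 32, 64, 128]
  input_patch: [16, 64, 64]
transformer:
  M: 2
  H: 4
  h: 256
  C3: 128
train:
  batch_size: 4
  epochs: 30
phantom:
  shape_voxels: [32, 96, 96]
  spacing_mm: [5.0, 1.0, 1.0]
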