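# Full-size training profile: patch 32x256x256, stage channels
# (16,32,64,128,256), transformer M=4 / H=8 / h=4096 / C3=512, Adam
# lr 1e-3 with weight decay 1e-4, polynomial decay power 0.9, batch 4,
# 500 epochs.  Sized for clinical thick-slice CT cohorts on GPU-class
# hardware; not intended for the CPU-scale phantom bench.
seed: 0
network:
  variant: transresseunet25d
  stage_channels: [16, 32, 64, 128, 256]
  input_patch: [32, 256, 256]
transformer:
  M: 4
  H: 8
  h: 4096
  C3: 512
train:
  batch_size: 4
  lr0: 1.0e-3
  weight_decay: 1.0e-4
  poly_power: 0.9
  epochs: 500
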