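# Desk-scale end-to-end run: 12 synthetic recordings, 2D and 2D+t models.
out_dir: run
seed: 0
n_individuals: 6
recordings_per_individual: 2
fractions: [0.667, 0.167, 0.166]
kinematics:
  image_size: [128, 128]
  n_frames: 12
  total_rom_deg: 40.0
  vertebra_height_px: 12.0
  spacing_px: 15.0
ks: [1, 3]
n_levels: 4
base_filters: 8
learning_rate: 0.002
batch_size: 8
max_epochs: 45
patience: 8
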