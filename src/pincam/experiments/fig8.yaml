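# Real-time acquisition with background: 3-sphere 1 cm Derenzo at z=5 cm,
# 8:1 target-to-background concentration, 4 s (2 s per position), linear.
name: fig8
preset: linear_no_overlap
seed: 8
duration: 4.0
phantom:
  builder: derenzo
  n_spheres: 3
  diameter: 10.0
  spacing: 20.0
  z: 50.0
  activity_per_sphere: 1.0e+5
  background_ratio: 8.0
recon:
  iterations: 2
  subsets: 2
metrics:
  - {kind: profile, axis: x, through: [0, 0, 50], half_width: 2}
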