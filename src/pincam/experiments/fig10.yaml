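# Real-time acquisition, circular no-overlap: 1.8 s (half a rotation),
# 3-sphere 1 cm Derenzo at z=5 cm with 8:1 background.
name: fig10
preset: circular_no_overlap
seed: 10
duration: 1.8
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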