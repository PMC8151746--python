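# Real-time acquisition, circular WITH overlap (o=4 mm): 1.8 s, 3-sphere
# 1 cm Derenzo at z=5 cm, 0.05 MBq per sphere, 8:1 background.
name: fig12
preset: circular_overlap
seed: 12
duration: 1.8
phantom:
  builder: derenzo
  n_spheres: 3
  diameter: 10.0
  spacing: 20.0
  z: 50.0
  activity_per_sphere: 5.0e+4
  background_ratio: 8.0
recon:
  iterations: 2
  subsets: 2
metrics:
  - {kind: profile, axis: x, through: [0, 0, 50], half_width: 2}
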