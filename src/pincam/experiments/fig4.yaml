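# Multiplexing-artifact demonstration: linear motion WITH overlap (o=4 mm),
# three 10 mm spheres at z=40 mm, 0.1 MBq each, 2 min acquisition.
name: fig4
preset: linear_overlap
seed: 4
duration: 120.0
phantom:
  builder: derenzo
  n_spheres: 3
  diameter: 10.0
  spacing: 20.0
  z: 40.0
  activity_per_sphere: 1.0e+5
recon:
  iterations: 2
  subsets: 2
metrics:
  - {kind: profile, axis: x, through: [0, 0, 40], half_width: 2}
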