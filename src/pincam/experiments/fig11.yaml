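# Truncation demonstration: the circular no-overlap plate held STATIC,
# 6-sphere 5 mm Derenzo at z=4 cm, 1 min.
name: fig11
preset: static_no_overlap
seed: 11
duration: 60.0
phantom:
  builder: derenzo
  n_spheres: 6
  diameter: 5.0
  spacing: 10.0
  z: 40.0
  activity_per_sphere: 1.0e+5
recon:
  iterations: 2
  subsets: 2
metrics:
  - {kind: profile, axis: x, through: [0, 0, 40], half_width: 2}
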