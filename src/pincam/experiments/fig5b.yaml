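# Transverse resolution at depth: 3-sphere 1 cm Derenzo near z=10 cm
# (centers at z=95 mm so the spheres stay inside the FOV cube), 1 min.
name: fig5b
preset: linear_no_overlap
seed: 5
duration: 60.0
phantom:
  builder: derenzo
  n_spheres: 3
  diameter: 10.0
  spacing: 20.0
  z: 95.0
  activity_per_sphere: 1.0e+5
recon:
  iterations: 2
  subsets: 2
metrics:
  - {kind: profile, axis: x, through: [0, 0, 95], half_width: 2}
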