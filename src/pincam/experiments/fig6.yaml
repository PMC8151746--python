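# Depth resolution: two 1.5 cm spheres 3 cm apart on the axis, linear preset.
name: fig6
preset: linear_no_overlap
seed: 6
duration: 60.0
phantom:
  builder: two_sphere_depth
  diameter: 15.0
  dz: 30.0
  z0: 40.0
  activity: 1.0e+5
recon:
  iterations: 5
  subsets: 3
metrics:
  - {kind: peaks, axis: z, through: [0, 0, 55], half_width: 2, expected: 2}
  - {kind: profile, axis: z, through: [0, 0, 55], half_width: 2}
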