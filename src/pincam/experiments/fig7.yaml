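# Uniformity: 5 cm diameter, 1 cm tall cylinder at z=6 cm, 3 min, with the
# exponential axial compensation (kappa = 1 per cm).
name: fig7
preset: linear_no_overlap
seed: 7
duration: 180.0
phantom:
  builder: uniformity_cylinder
recon:
  iterations: 5
  subsets: 3
  axial_kappa: 1.0
metrics:
  - {kind: uniformity, region: [[30, 70], [30, 70], [56, 64]]}
  - {kind: profile, axis: z, through: [0, 0, 60], half_width: 5}
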