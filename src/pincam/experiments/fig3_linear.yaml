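# Sensitivity scan: x-line at z=15 mm plus on-axis z-line, linear preset.
name: fig3_linear
preset: linear_no_overlap
seed: 3
scan:
  n_decays: 200000
  points:
    - [-40, 0, 15]
    - [-30, 0, 15]
    - [-20, 0, 15]
    - [-10, 0, 15]
    - [0, 0, 15]
    - [10, 0, 15]
    - [20, 0, 15]
    - [30, 0, 15]
    - [40, 0, 15]
    - [0, 0, 20]
    - [0, 0, 30]
    - [0, 0, 40]
    - [0, 0, 50]
    - [0, 0, 60]
    - [0, 0, 70]
    - [0, 0, 80]
    - [0, 0, 90]
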