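# Shipped camera configurations.
#
# All share the 100x100x3 mm scintillator at a 10 mm standoff behind a 3 mm
# tungsten plate with 35-degree double-cone pinholes (footprint cone radius
# L = 10 tan 35 ~ 7 mm).  mu_crystal is GAGG at 140.5 keV (1/mm).
#
# linear_no_overlap : d=1 mm, D=2L+d=15 mm, two-position motion on the cell
#                     diagonal (D/2, D/2) with 2 s dwell per position.
# linear_overlap    : same but D=2L+d-o with o=4 mm (D=11 mm); used to
#                     demonstrate multiplexing artifacts under linear motion.
# circular_no_overlap: d=2 mm, D=2L+d=16 mm, continuous rotation, T=3.6 s,
#                     rotation axis a quarter pitch from the nearest node
#                     (lattice offset (D/4, D/4)).
# circular_overlap  : d=2 mm, D=2L+d-o=12 mm with o=4 mm, rotation as above.
# static_no_overlap : the circular_no_overlap plate held still (truncation
#                     comparison case).

linear_no_overlap:
  lattice:
    pitch: 15.0
    waist_diameter: 1.0
    half_angle_deg: 35.0
    extent: [100.0, 100.0]
    thickness: 3.0
    lattice_offset: [0.0, 0.0]
    focal_length: 10.0
  panel: &panel
    size: [100.0, 100.0]
    crystal_thickness: 3.0
    standoff: 10.0
    intrinsic_fwhm_xy: 1.0
    energy_resolution_fwhm_frac: 0.10
    mu_crystal: 0.40
  motion:
    kind: linear_two_position
    displacement: [7.5, 7.5]
    dwell_cycle: 4.0

linear_overlap:
  lattice:
    pitch: 11.0
    waist_diameter: 1.0
    half_angle_deg: 35.0
    extent: [100.0, 100.0]
    thickness: 3.0
    lattice_offset: [0.0, 0.0]
    focal_length: 10.0
  panel: *panel
  motion:
    kind: linear_two_position
    displacement: [5.5, 5.5]
    dwell_cycle: 4.0

circular_no_overlap:
  lattice:
    pitch: 16.0
    waist_diameter: 2.0
    half_angle_deg: 35.0
    extent: [100.0, 100.0]
    thickness: 3.0
    lattice_offset: [4.0, 4.0]
    focal_length: 10.0
  panel: *panel
  motion:
    kind: circular
    period: 3.6
    axis_offset: 4.0

circular_overlap:
  lattice:
    pitch: 12.0
    waist_diameter: 2.0
    half_angle_deg: 35.0
    extent: [100.0, 100.0]
    thickness: 3.0
    lattice_offset: [3.0, 3.0]
    focal_length: 10.0
  panel: *panel
  motion:
    kind: circular
    period: 3.6
    axis_offset: 3.0

static_no_overlap:
  lattice:
    pitch: 16.0
    waist_diameter: 2.0
    half_angle_deg: 35.0
    extent: [100.0, 100.0]
    thickness: 3.0
    lattice_offset: [4.0, 4.0]
    focal_length: 10.0
  panel: *panel
  motion:
    kind: static
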