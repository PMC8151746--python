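# Methods

This note documents the physical model, the numerical choices and the known
limitations of `pincam`, in the order the pipeline runs: geometry →
transport → system model → reconstruction → metrics.

## Geometry and coordinate conventions

All modules share one frame: origin at the center of the collimator
mid-plane, +z toward the object. The detection plane is the crystal
entrance face at z = −standoff (no depth-of-interaction information is
modelled, so the 3 mm crystal is collapsed onto its entrance face for
positioning). The field of view is the half-open cube
[−50, 50) × [−50, 50) × [0, 100) mm, reconstructed on 1 mm voxels by
default; `VoxelGrid.coarse(spacing)` provides coarser grids for
sensitivity-image estimation and fast studies.

The pinhole plate is a square lattice aligned with the detector edges.
Every pinhole is a knife-edge double cone, axis normal to the plate (no
tilting or focusing), waist diameter *d*, semi-aperture α = 35°. The
footprint of a pinhole on the detector is a disc of radius
L + d/2 with L = standoff · tan α ≈ 7 mm. Three motion models exist:

* **static** — identity pose at all times;
* **linear_two_position** — identity for the first half of each dwell
  cycle (default 4 s, i.e. 2 s per position), displaced for the second.
  The displacement is the cell diagonal (D/2, D/2): this is the unique
  translation that puts the second-pose footprints into the gaps of the
  first pose, so the two poses jointly tile the detector (verified in the
  test suite: full coverage away from a one-radius border).
* **circular** — continuous rotation about the detector normal through the
  origin, θ = 2πt/T with T = 3.6 s. The design calls for the rotation axis
  to pass a quarter pitch from the nearest pinhole; this is realised by
  offsetting the whole lattice by (D/4, D/4), so the nearest node orbits at
  D√2/4 from the axis. The quarter-pitch choice breaks the 90°
  self-similarity a half-pitch offset would have (asserted in the tests);
  whether the offset is axial or diagonal is not fixed by the design, so
  the diagonal convention is ours and is configurable.

## Photon transport

Decay count over an acquisition is Poisson(activity × duration); times are
uniform, positions uniform within each analytic primitive
(activity-weighted across primitives), directions isotropic. Sources emit
in air: no object attenuation or scatter, matching the phantom setup the
design studies use.

**Aperture acceptance (binary model, default).** A ray passes iff it
crosses the waist disc within d/2 of a pinhole center *and* its obliquity
is at most α. For rays within α this is exactly the condition of never
touching tungsten in the double-cone solid (at the mid-plane the open
region is the waist disc itself), which is how the brute-force sampled
oracle in the tests checks it. Rays steeper than α can in reality sneak
through the waist without touching tungsten (for d = 2 mm and a 3 mm
plate, up to ≈53°); the binary model deliberately excludes this halo
because the multiplexing-free footprint tiling — the premise of the whole
moving-collimator design — holds only for the design aperture. The
**exponential model** (off by default) restores the physical behaviour:
every binary-rejected ray is weighted by exp(−μ_W × tungsten path), with
the path integrated numerically along the ray (17 samples across the
plate); steep waist-crossers have zero path and survive.

**Detection.** Interaction probability 1 − exp(−μ·t/cos θ) with t = 3 mm
and μ = 0.40 mm⁻¹ for GAGG at 140.5 keV. The isotope is not part of the
design; Tc-99m (140.5 keV), the standard gamma-camera tracer, is the
default. μ was derived once from elemental mass-attenuation mixtures for
Gd₃Al₂Ga₃O₁₂ (ρ = 6.63 g/cm³) at 140.5 keV and recorded in the default
configuration; it is the single most uncertain constant in the model
(±10% moves all absolute sensitivities by the same factor). Impacts get
independent 1 mm FWHM Gaussian blur per axis (blurred impacts are clipped
to the panel, as a real readout would report an in-panel position), the
energy gets 10% FWHM fractional blur, and a ±20% photopeak window is
applied — with no scatter modelled it only trims far Gaussian tails.

## System model

**Pinhole assignment.** Candidates are the pinholes whose footprint at the
event-time pose contains the impact; since footprints are equal discs, the
nearest lattice node is the unique candidate, found by rounding in the
collimator frame. Events outside every footprint (blur migrants in
no-overlap presets) are dropped and counted. In the o = 4 mm overlap
preset, ambiguous events are resolved by the same nearest-center rule
rather than split: the design's own argument is that collimator motion
keeps mis-assignment noise from accumulating anywhere, so a simple rule
suffices; the mis-assignment rate is measured in the tests (~10% of
assigned events for a mid-FOV extended source).

**LORs and p_ij.** The LOR runs from the impact point (lifted to the
detection plane) through the assigned pinhole center at the event time,
extended into the FOV. The system response p_ij is the chord length of the
LOR in voxel j, computed by an exact incremental plane-crossing traversal
(segment midpoints own the voxels; half-open boundaries; chord lengths sum
to the in-box path). Solid-angle and efficiency weighting are *not* put
into p_ij; they are absorbed into the Monte-Carlo sensitivity image. This
is the simplest response consistent with the update formula, and its main
consequence is documented under Limitations.

**Sensitivity image.** Σ_i p_ij per voxel is estimated by simulating a
uniform source filling the FOV over one motion cycle and accumulating
traversal lengths of every detected event's LOR, normalised per decay.
For moving collimators the event poses are discretised to 64 equally
spaced poses per cycle (angular sampling well below the footprint scale at
the plate edge, at 64× less pose bookkeeping than per-event poses); the
result is the cycle-summed *effective* sensitivity, not any instantaneous
pose. Per-event reconstruction poses remain continuous.

## Reconstruction

LM-OSEM with round-robin subsets of the time-ordered event list; one
"iteration" is a pass over all subsets. Initialisation is all-ones
(positive, uninformative); non-negativity is preserved by the
multiplicative update; voxels with zero sensitivity are frozen at zero;
events whose forward projection vanishes are skipped for that pass and
counted. With one subset and uniform sensitivity the update reduces to
classical list-mode MLEM (checked against an independent dense
implementation).

The uniform-sensitivity option (Σ_i p_ij ≡ 1) is the default below 10⁵
events: per-voxel geometric normalisation needs per-voxel statistics that
short, low-activity acquisitions cannot support. The threshold is
configurable. The exponential axial compensation multiplies the voxel at
depth z (cm) by e^{+κ(z−z0)}, κ = 1 cm⁻¹ by default, countering an
e^{−z} falloff of reconstructed intensity with depth.

## Metrics

FWHM uses linear interpolation of the half-maximum crossings.
Resolvability smooths lightly, finds prominent local maxima, and flags a
pair resolved when valley/lower-peak < 0.75 (Rayleigh-like; the threshold
is configurable because the underlying judgment in the design studies is
visual). Two measurement recipes deserve explanation:

* **Transverse resolution of a compact source** is the FWHM of the
  smoothed transverse profile of a 1 cm depth slab through the source, not
  of a raw profile through the brightest voxel: converged list-mode MLEM
  point images carry voxel-scale speckle, and a raw peak profile measures
  the speckle (one voxel), not the system response. Resolution
  reconstructions use 2 iterations × 2 subsets, before speckle growth.
* **Axial two-peak resolution** measures each depth peak's half-width on
  its *outer* side and doubles it (the inner sides may never fall below
  half maximum when peaks partially merge), then removes the source size
  in quadrature — a uniform sphere of diameter D has a summed-profile FWHM
  of D/√2. Frozen at transverse averaging half-width 10 voxels and
  smoothing σ = 2 samples after an 8-seed robustness sweep.

## Study conditions and problem sizes

Phantoms, activities and durations follow the design studies: 0.05–0.1 MBq
per sphere, 8:1 target-to-background concentration with an FOV-filling
background cube, acquisitions of 1.8 s (half a rotation) to 5 min.
Derenzo layouts are centered triangular clusters (rows of 1/2/3) with the
stated center spacing, since only counts, diameters and spacings are fixed
by the design; coordinates are emitted with the phantom so runs are
deterministic. Sphere clusters nominally "at z = 10 cm" are placed so the
spheres fit inside the FOV cube (centers at 95 mm, or 99.5 mm for the 1 mm
point-like source).

The test suite runs the same pipelines at reduced Monte-Carlo sizes chosen
for statistical sufficiency: 0.3–1×10⁶ decays per sensitivity point,
60–120 s acquisitions for resolution studies, 1.6–2.4×10⁷-decay floods on
2–4 mm grids for sensitivity images. The acceptance script uses the full
stated durations (up to 300 s / 3×10⁷ decays).

## Limitations

* **No object physics**: attenuation, Compton/Rayleigh scatter,
  fluorescence, dead time and pile-up are all absent. Absolute
  sensitivities are geometric × crystal absorption only, so they sit
  somewhat below a full GEANT4 treatment (which also gains from septal
  penetration); relative comparisons between presets are the robust
  output.
* **Chord-length p_ij** has no distance weighting. For compact sources
  this is benign, but for extended sources LM-MLEM with *uniform*
  sensitivity then provably prefers piling activity onto the voxels at the
  pinhole pivots (activity concentrated at z ≈ 0 under each pinhole
  reproduces any event set, and the uniform expected-count penalty cannot
  break the tie). The Monte-Carlo sensitivity image suppresses but does
  not eliminate this, and division by small noisy far-z sensitivities
  biases deep voxels upward. Consequently the reconstructed uniformity
  cylinder does not show the clean e^{−z} axial falloff the exponential
  compensation targets, and applying the compensation does not improve its
  flatness in this implementation — the relevant acceptance checks fail
  and are documented as model limitations rather than adjusted.
* **Synthetic data only**: the generator emulates the idealised bench
  conditions above. Passing tests demonstrate internal consistency of
  geometry, transport and reconstruction and reproduction of the design's
  relative performance claims at desk scale; they do not validate against
  measured data or full physics.
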