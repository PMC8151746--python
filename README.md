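# pincam

Monte-Carlo simulation and list-mode OSEM reconstruction for gamma cameras
with **moving multi-pinhole collimators** — the intraoperative imaging
design in which a tungsten pinhole plate translates or rotates in front of a
static scintillator so that the pinhole projections sweep the detector,
removing the classic trade-off between multiplexing artifacts (overlapping
projections) and image truncation (blind regions).

The package is aimed at detector physicists and image-reconstruction
researchers who want a desk-scale, fully scriptable stand-in for a
GATE/GEANT4 study of this geometry: every phantom, acquisition and
reconstruction in the package is generated and analysed in code, with no
external data.

## The model

**Camera.** A 100×100×3 mm³ GAGG scintillator sits 10 mm behind a 3 mm
tungsten plate drilled with a square lattice of knife-edge (double-cone)
pinholes of waist diameter *d* and semi-aperture α = 35°, so each footprint
cone has radius L = 10 tan 35° ≈ 7 mm on the detector. Adjacent pinholes are
a pitch *D* apart; with D = 2L + d the footprints tile without overlap, and
D = 2L + d − o leaves an overlap *o*. Three shipped presets reproduce the
standard configurations: `linear_no_overlap` (d = 1 mm, D = 15 mm,
two-position diagonal motion), `circular_no_overlap` (d = 2 mm, D = 16 mm,
continuous rotation, T = 3.6 s, axis a quarter pitch from the nearest
pinhole) and `circular_overlap` (d = 2 mm, D = 12 mm, o = 4 mm).

**Transport.** Decays are Poisson in time, uniform in each analytic source
primitive, isotropic in direction. A ray is accepted by the collimator iff
it crosses a pinhole waist within d/2 and is inclined less than α to the
plate normal (an optional exponential model adds tungsten penetration).
Detection applies an interaction probability
1 − exp(−μ·t/cos θ), 1 mm FWHM intrinsic blur, 10% FWHM energy blur and a
±20% photopeak window.

**Reconstruction.** Each event defines a line of response (LOR) through its
impact point and the center of the pinhole it is assigned to at the event
time. LM-OSEM updates the voxel image λ per event subset S_l:

    λ_j ← λ_j / Σ_i p_ij · Σ_{k∈S_l} p_{i_k j} / Σ_b p_{i_k b} λ_b

with p_ij the chord length of LOR *i* in voxel *j* and Σ_i p_ij the
per-voxel sensitivity, estimated by a flood-source Monte Carlo summed over
one motion cycle (or set to 1 for low-count acquisitions). The analytic
single-pinhole resolution predictor

    R = √[(φ(h+d)/d)² + (R_i h/d)²]

and FWHM/uniformity/resolvability metrics complete the evaluation chain.

## Worked example

```python
import numpy as np
import pincam as pc
from pincam.reconstruction import ListModeOSEM, ReconOptions
from pincam.metrics import transverse_resolution

camera = pc.load_preset("circular_no_overlap")

# 0.1 MBq point-like source 10 cm from the collimator, 60 s acquisition
phantom = pc.Phantom([pc.phantoms.Sphere((0, 0, 99.5), 1.0, 1e5)], "pt")
events = pc.simulate(phantom, camera, pc.AcquisitionConfig(duration=60, seed=7))
print(f"{len(events)} events from {events.n_emitted} decays "
      f"({len(events)/events.n_emitted:.2e} cps/Bq)")

result = ListModeOSEM(events, camera,
                      options=ReconOptions(iterations=2, subsets=2)).fit()
rep = transverse_resolution(result.image, (90.0, 100.0))
print(f"transverse FWHM at z=10 cm: {rep.fwhm_mm:.1f} mm")
```

Output:

```
2818 events from 6001249 decays (4.70e-04 cps/Bq)
transverse FWHM at z=10 cm: 13.7 mm
```

That is: the rotating no-overlap camera detects about 4.7·10⁻⁴ of the
emitted photons from a source 11 cm from the crystal, and reconstructs it
with ≈1.4 cm transverse resolution — the sensitivity/resolution operating
point of this design at its largest working distance.

The same pipeline is scriptable from the shell:

```bash
pincam run fig9  --out out/fig9     # two-sphere depth study, rotating camera
pincam run fig12 --out out/fig12    # 1.8 s real-time acquisition, 8:1 background
pincam simulate --preset circular_overlap --phantom my_phantom.yaml \
       --duration 60 --seed 1 --out events.csv
pincam recon --events events.csv --preset circular_overlap --iters 2 \
       --subsets 2 --out volume.mhd
```

The shipped `fig*` experiment specs (under `pincam/experiments/`) cover the
sensitivity scans, resolution studies, uniformity test, truncation
demonstration and background studies; each emits events, a MetaImage
volume, a metrics report and a provenance record.

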