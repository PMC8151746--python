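"""Geometric Monte-Carlo photon transport.

Turns phantom decays into list-mode events: decays are sampled from the
analytic phantom (Poisson statistics, isotropic emission), each ray is tested
against the double-cone pinhole apertures at the collimator pose of its
emission time, surviving rays are intersected with the detection plane,
and the crystal response applies an interaction probability, Gaussian
position blur (1 mm FWHM per axis), Gaussian energy blur (10% FWHM) and an
energy window.

The default (binary) aperture model realises the design aperture: a ray is
accepted iff it crosses the waist disc (diameter ``d`` at the plate
mid-plane) and makes an angle of at most ``alpha`` with the pinhole axis.
For such rays this is exactly equivalent to never touching tungsten in the
double-cone solid.  Rays steeper than ``alpha`` are treated as blocked even
when a path through the waist exists; the optional exponential model instead
weighs every rejected ray by ``exp(-mu_W * tungsten path length)``, which
re-admits the steep waist-crossing halo (zero path) and adds knife-edge
penetration.

No scatter, fluorescence or attenuation in the object is modelled; sources
emit in air.  Everything is vectorised over chunks of emissions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .geometry import CameraSystem, PinholeLattice, poses_at_times
from .phantoms import Phantom

__all__ = [
    "AcquisitionConfig",
    "EmissionBatch",
    "ListModeEvents",
    "sample_decays",
    "trace_aperture",
    "detect",
    "simulate",
    "sensitivity",
]

_CHUNK = 2_000_000


@dataclass
class AcquisitionConfig:
    """Acquisition settings.

    duration : s.  photopeak : keV (default Tc-99m, 140.5 keV).
    energy_window : (lo, hi) keV; default photopeak +/- 20%.
    penetration_model : 'binary' (knife-edge, default) or 'exponential'
    (tungsten penetration for near-miss rays, ``mu_tungsten`` in 1/mm at the
    photopeak energy).
    """

    duration: float
    photopeak: float = 140.5
    energy_window: tuple[float, float] | None = None
    seed: int = 0
    penetration_model: str = "binary"
    mu_tungsten: float = 3.46

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.energy_window is None:
            self.energy_window = (0.8 * self.photopeak, 1.2 * self.photopeak)
        lo, hi = self.energy_window
        if not lo < self.photopeak < hi:
            raise ValueError("energy window must bracket the photopeak")
        if self.penetration_model not in ("binary", "exponential"):
            raise ValueError("penetration_model must be 'binary' or 'exponential'")


@dataclass
class EmissionBatch:
    """A chunk of primary decays: positions, unit directions, times (sorted)."""

    origin: np.ndarray     # (n, 3) mm
    direction: np.ndarray  # (n, 3) unit vectors
    time: np.ndarray       # (n,) s
    energy: float          # keV, monoenergetic

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ListModeEvents:
    """Columnar list-mode data with simulation provenance.

    ``x, y`` are blurred impact coordinates in the detection-plane frame
    (which coincides laterally with the global frame); ``truth_pinhole`` and
    ``truth_origin`` are filled by the simulator (-1 / NaN when absent).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    energy: np.ndarray
    truth_pinhole: np.ndarray
    truth_origin: np.ndarray
    n_emitted: int = 0
    duration: float = 0.0
    seed: int | None = None
    system_name: str = ""
    geometry_hash: str = ""

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, sel: np.ndarray) -> "ListModeEvents":
        return ListModeEvents(
            self.time[sel], self.x[sel], self.y[sel], self.energy[sel],
            self.truth_pinhole[sel], self.truth_origin[sel],
            n_emitted=self.n_emitted, duration=self.duration, seed=self.seed,
            system_name=self.system_name, geometry_hash=self.geometry_hash,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "x_mm": self.x,
                "y_mm": self.y,
                "energy_keV": self.energy,
                "truth_pinhole": self.truth_pinhole,
                "truth_x_mm": self.truth_origin[:, 0],
                "truth_y_mm": self.truth_origin[:, 1],
                "truth_z_mm": self.truth_origin[:, 2],
            }
        )

    @classmethod
    def empty(cls) -> "ListModeEvents":
        return cls(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0),
            np.full(0, -1, dtype=np.int64), np.empty((0, 3)),
        )


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def sample_decays(
    phantom: Phantom,
    duration: float,
    rng: np.random.Generator,
    energy: float = 140.5,
    chunk_size: int = _CHUNK,
) -> Iterator[EmissionBatch]:
    """Stream Poisson decays over ``[0, duration)`` in time-ordered chunks.

    The total decay count is Poisson(total activity x duration); times are
    uniform, positions activity-weighted uniform within each primitive,
    directions isotropic.  Chunks partition the acquisition into equal time
    slices so concatenated chunks are globally time-ordered.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    activity = phantom.total_activity
    if activity <= 0:
        return
    mean_total = activity * duration
    n_chunks = max(1, int(math.ceil(mean_total / chunk_size)))
    dt = duration / n_chunks
    for c in range(n_chunks):
        n = int(rng.poisson(activity * dt))
        if n == 0:
            continue
        t = np.sort(rng.uniform(c * dt, (c + 1) * dt, size=n))
        origin = phantom.sample(n, rng)
        direction = _isotropic_directions(n, rng)
        yield EmissionBatch(origin=origin, direction=direction, time=t, energy=energy)


def _to_collimator_frame(
    xy: np.ndarray, theta: np.ndarray, trans: np.ndarray
) -> np.ndarray:
    """Inverse-pose map of global lateral coordinates, per-row angles."""
    q = xy - trans
    c, s = np.cos(theta), np.sin(theta)
    return np.column_stack([c * q[:, 0] + s * q[:, 1], -s * q[:, 0] + c * q[:, 1]])


def _rotate(xy: np.ndarray, theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.column_stack([c * xy[:, 0] - s * xy[:, 1], s * xy[:, 0] + c * xy[:, 1]])


def trace_aperture(
    origin: np.ndarray,
    direction: np.ndarray,
    lattice: PinholeLattice,
    theta: np.ndarray | float = 0.0,
    translation: np.ndarray | None = None,
    penetration_model: str = "binary",
    mu_tungsten: float = 3.46,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Test rays against the posed pinhole plate.

    Parameters are arrays over rays (single rays broadcast); ``theta`` /
    ``translation`` give the collimator pose per ray.  Returns
    ``(passed, pinhole_index, obliquity_rad)``; the index refers to the
    nearest pinhole (valid whether or not the ray passed) and the obliquity
    is the angle between the ray and the plate normal.
    """
    origin = np.atleast_2d(np.asarray(origin, float))
    direction = np.atleast_2d(np.asarray(direction, float))
    n = len(origin)
    theta = np.broadcast_to(np.asarray(theta, float), (n,))
    if translation is None:
        trans = np.zeros((n, 2))
    else:
        trans = np.broadcast_to(np.asarray(translation, float), (n, 2))

    uz = direction[:, 2]
    down = uz < -1e-12
    passed = np.zeros(n, bool)
    pinhole = np.full(n, -1, dtype=np.int64)
    obliquity = np.arccos(np.clip(np.abs(uz), 0.0, 1.0))
    if not np.any(down):
        return passed, pinhole, obliquity

    o = origin[down]
    u = direction[down]
    th = theta[down]
    tr = trans[down]
    o_c = _to_collimator_frame(o[:, :2], th, tr)
    u_c = _rotate(u[:, :2], -th)
    uz_d = u[:, 2]

    d = lattice.waist_diameter
    half_t = lattice.thickness / 2.0
    tan_a = math.tan(math.radians(lattice.half_angle_deg))

    t0 = -o[:, 2] / uz_d
    p0 = o_c + t0[:, None] * u_c
    idx = lattice.nearest_index(p0)
    node = lattice.centers[idx]
    dr = p0 - node
    cos_alpha_sq = 1.0 / (1.0 + tan_a**2)
    ok = (dr[:, 0] ** 2 + dr[:, 1] ** 2 <= (d / 2.0) ** 2) & (
        uz_d**2 >= cos_alpha_sq - 1e-12
    )

    if penetration_model == "exponential":
        if rng is None:
            raise ValueError("exponential penetration needs an rng")
        miss = ~ok
        if np.any(miss):
            zs = np.linspace(half_t, -half_t, 17)
            frac = np.zeros(miss.sum())
            om, um, nodem, ozm, uzm = (
                o_c[miss], u_c[miss], node[miss], o[miss, 2], uz_d[miss]
            )
            for z in zs:
                tz = (z - ozm) / uzm
                pz = om + tz[:, None] * um
                rz = np.linalg.norm(pz - nodem, axis=1)
                frac += (rz > d / 2.0 + abs(z) * tan_a).astype(float)
            frac /= len(zs)
            path = lattice.thickness / np.abs(uzm) * frac
            survive = rng.uniform(size=miss.sum()) < np.exp(-mu_tungsten * path)
            ok[miss] = survive

    passed[down] = ok
    pinhole[down] = idx
    return passed, pinhole, obliquity


def _interaction_probability(
    obliquity: np.ndarray, mu_crystal: float, thickness: float
) -> np.ndarray:
    """Probability that a photon interacts in the crystal slab.

    ``1 - exp(-mu * thickness / cos(obliquity))`` -- the path through the
    slab grows with incidence angle.
    """
    cos_t = np.clip(np.cos(obliquity), 1e-6, 1.0)
    return 1.0 - np.exp(-mu_crystal * thickness / cos_t)


def detect(
    origin: np.ndarray,
    direction: np.ndarray,
    panel,
    config: AcquisitionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Crystal response for rays that already passed the aperture.

    Returns ``(kept, x, y, energy)`` where ``kept`` masks the input rays and
    the coordinate/energy arrays are aligned with the kept rays.  The impact
    is the geometric intersection with the detection plane, blurred by the
    panel's intrinsic resolution; the energy is the photopeak with fractional
    Gaussian blur, cut to the energy window; interaction happens with
    probability ``1 - exp(-mu * t / cos(theta))``.
    """
    origin = np.atleast_2d(np.asarray(origin, float))
    direction = np.atleast_2d(np.asarray(direction, float))
    uz = direction[:, 2]
    n = len(origin)
    kept = np.zeros(n, bool)
    t_hit = (-panel.standoff - origin[:, 2]) / uz
    impact = origin[:, :2] + t_hit[:, None] * direction[:, :2]
    hx, hy = panel.size[0] / 2.0, panel.size[1] / 2.0
    on_panel = (
        (np.abs(impact[:, 0]) <= hx) & (np.abs(impact[:, 1]) <= hy) & (t_hit > 0)
    )

    obliquity = np.arccos(np.clip(np.abs(uz), 0.0, 1.0))
    p_int = _interaction_probability(
        obliquity, panel.mu_crystal, panel.crystal_thickness
    )
    interacts = rng.uniform(size=n) < p_int
    kept = on_panel & interacts

    m = int(kept.sum())
    sigma_xy = panel.intrinsic_fwhm_xy / 2.3548200450309493
    xy = impact[kept].copy()
    if sigma_xy > 0:
        xy += rng.normal(scale=sigma_xy, size=(m, 2))
    # keep blurred impacts on the panel (events are positioned by the readout)
    xy[:, 0] = np.clip(xy[:, 0], -hx + 1e-9, hx - 1e-9)
    xy[:, 1] = np.clip(xy[:, 1], -hy + 1e-9, hy - 1e-9)

    sigma_e = config.photopeak * panel.energy_resolution_fwhm_frac / 2.3548200450309493
    energy = config.photopeak + rng.normal(scale=sigma_e, size=m)
    lo, hi = config.energy_window
    in_window = (energy >= lo) & (energy <= hi)

    out = np.zeros(n, bool)
    out[np.flatnonzero(kept)[in_window]] = True
    return out, xy[in_window, 0], xy[in_window, 1], energy[in_window]


def simulate(
    phantom: Phantom,
    system: CameraSystem,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> ListModeEvents:
    """Full acquisition: decays -> aperture at the emission-time pose ->
    crystal response.  Events come out time-ordered with truth provenance."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cols: dict[str, list[np.ndarray]] = {k: [] for k in
                                         ("t", "x", "y", "e", "ph", "org")}
    n_emitted = 0
    for batch in sample_decays(phantom, config.duration, rng, energy=config.photopeak):
        n_emitted += len(batch)
        down = batch.direction[:, 2] < -1e-12
        if not np.any(down):
            continue
        o, u, t = batch.origin[down], batch.direction[down], batch.time[down]
        theta, trans = poses_at_times(system.motion, t)
        passed, pinhole, _ = trace_aperture(
            o, u, system.lattice, theta, trans,
            penetration_model=config.penetration_model,
            mu_tungsten=config.mu_tungsten, rng=rng,
        )
        if not np.any(passed):
            continue
        o, u, t, pinhole = o[passed], u[passed], t[passed], pinhole[passed]
        kept, x, y, e = detect(o, u, system.panel, config, rng)
        if not np.any(kept):
            continue
        cols["t"].append(t[kept])
        cols["x"].append(x)
        cols["y"].append(y)
        cols["e"].append(e)
        cols["ph"].append(pinhole[kept])
        cols["org"].append(o[kept])
    if cols["t"]:
        events = ListModeEvents(
            np.concatenate(cols["t"]),
            np.concatenate(cols["x"]),
            np.concatenate(cols["y"]),
            np.concatenate(cols["e"]),
            np.concatenate(cols["ph"]),
            np.concatenate(cols["org"], axis=0),
        )
    else:
        events = ListModeEvents.empty()
    events.n_emitted = n_emitted
    events.duration = config.duration
    events.seed = config.seed
    events.system_name = system.name
    events.geometry_hash = system.geometry_hash()
    return events


def sensitivity(
    point: np.ndarray,
    system: CameraSystem,
    n_decays: int,
    rng: np.random.Generator,
    duration: float | None = None,
    config: AcquisitionConfig | None = None,
) -> float:
    """Point-source sensitivity in cps/Bq (= detected / emitted).

    An isotropic point source at ``point`` emits ``n_decays`` photons with
    emission times spread uniformly over one motion cycle (``duration``
    overrides; static collimators use an arbitrary 1 s window).
    """
    if n_decays < 1:
        raise ValueError("n_decays must be >= 1")
    point = np.asarray(point, float)
    if duration is None:
        duration = system.motion.cycle or 1.0
    if config is None:
        config = AcquisitionConfig(duration=duration)
    detected = 0
    remaining = n_decays
    while remaining > 0:
        n = min(remaining, _CHUNK)
        remaining -= n
        u = _isotropic_directions(n, rng)
        down = u[:, 2] < -1e-12
        if not np.any(down):
            continue
        u = u[down]
        o = np.broadcast_to(point, (len(u), 3))
        t = rng.uniform(0.0, duration, size=len(u))
        theta, trans = poses_at_times(system.motion, t)
        passed, _, _ = trace_aperture(
            o, u, system.lattice, theta, trans,
            penetration_model=config.penetration_model,
            mu_tungsten=config.mu_tungsten, rng=rng,
        )
        if not np.any(passed):
            continue
        kept, _, _, _ = detect(o[passed], u[passed], system.panel, config, rng)
        detected += int(kept.sum())
    return detected / n_decays
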