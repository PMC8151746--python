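"""Collimator, detector and motion geometry.

Global coordinate convention (used by every module in the package):

* origin at the center of the collimator mid-plane, +z toward the object;
* the detection plane (crystal entrance face) sits at ``z = -standoff``;
* the field of view is the half-open box ``[-50, 50) x [-50, 50) x [0, 100)``
  mm with 1 mm voxels, voxel ``(0, 0, 0)`` at the ``(-50, -50, 0)`` corner.

"Distance from the collimator" always means the z coordinate; the
source-to-detector distance is ``z + standoff``.

The collimator is a square lattice of knife-edge (double-cone) pinholes in a
tungsten plate.  Adjacent pinhole centers are a pitch ``D`` apart; each
pinhole has a waist diameter ``d`` and a semi-aperture angle ``alpha``.  The
projection of one acceptance cone onto the detector has radius
``standoff * tan(alpha) + d/2``; with ``L = standoff * tan(alpha)`` the
footprints of adjacent pinholes overlap by ``o = 2L + d - D`` (negative
``o`` is a gap).

The collimator may move relative to the (static) detector: either jumping
between two positions with equal dwell (linear motion), or rotating
continuously about the detector normal through the origin.  For the circular
presets the rotation axis passes a quarter pitch from the nearest lattice
node, realised by offsetting the whole lattice by ``(D/4, D/4)``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
import numpy as np
import yaml

__all__ = [
    "FOV_MIN",
    "FOV_SIZE",
    "GeometryError",
    "Pinhole",
    "PinholeLattice",
    "DetectorPanel",
    "MotionModel",
    "RigidPose",
    "CameraSystem",
    "build_lattice",
    "pose_at_time",
    "poses_at_times",
    "footprint",
    "overlap_of",
    "load_preset",
    "preset_names",
]

#: Lower corner of the field of view (mm).
FOV_MIN = np.array([-50.0, -50.0, 0.0])
#: Edge length of the cubic field of view (mm).
FOV_SIZE = 100.0


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate geometry parameters."""


@dataclass(frozen=True)
class Pinhole:
    """A single double-cone pinhole.

    Parameters
    ----------
    center : (float, float)
        Position in the collimator frame (mm), mid-plane coordinates.
    waist_diameter : float
        Inner diameter ``d`` of the waist (mm).
    half_angle_deg : float
        Semi-aperture angle ``alpha`` of the two cones (degrees).
    index : int
        Integer id, unique within a lattice.
    """

    center: tuple[float, float]
    waist_diameter: float
    half_angle_deg: float
    index: int

    def __post_init__(self) -> None:
        if self.waist_diameter <= 0:
            raise GeometryError("pinhole waist diameter must be > 0")
        if not 0.0 < self.half_angle_deg < 90.0:
            raise GeometryError("pinhole half angle must be in (0, 90) degrees")


@dataclass
class PinholeLattice:
    """Square grid of identical pinholes in a tungsten plate.

    ``overlap`` is the derived footprint overlap ``o = 2L + d - D`` with
    ``L = focal_length * tan(alpha)``; a negative value means the footprints
    leave a gap on the detector.
    """

    pitch: float
    pinholes: list[Pinhole]
    extent: tuple[float, float] = (100.0, 100.0)
    thickness: float = 3.0
    lattice_offset: tuple[float, float] = (0.0, 0.0)
    focal_length: float = 10.0

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise GeometryError("lattice pitch must be > 0")
        if self.thickness <= 0 or min(self.extent) <= 0:
            raise GeometryError("lattice extent and thickness must be > 0")
        idx = [p.index for p in self.pinholes]
        if len(set(idx)) != len(idx):
            raise GeometryError("pinhole indices must be unique")
        d = self.waist_diameter
        for p in self.pinholes:
            for c, e in zip(p.center, self.extent):
                if abs(c) > e / 2 - d / 2 + 1e-9:
                    raise GeometryError(
                        f"pinhole {p.index} at {p.center} falls outside the plate"
                    )
        # cache arrays and the k-index bookkeeping used by vectorised lookups
        self._centers = np.array([p.center for p in self.pinholes], float)
        off = np.asarray(self.lattice_offset, float)
        k = np.rint((self._centers - off) / self.pitch).astype(np.int64)
        if not np.allclose(k * self.pitch + off, self._centers, atol=1e-6):
            raise GeometryError("pinhole centers do not lie on the stated lattice")
        self._kmin = k.min(axis=0)
        self._kmax = k.max(axis=0)
        shape = self._kmax - self._kmin + 1
        lookup = np.full(shape, -1, dtype=np.int64)
        rel = k - self._kmin
        lookup[rel[:, 0], rel[:, 1]] = np.array(idx, dtype=np.int64)
        self._lookup = lookup

    @property
    def centers(self) -> np.ndarray:
        """``(n, 2)`` array of pinhole centers in the collimator frame."""
        return self._centers

    @property
    def waist_diameter(self) -> float:
        return self.pinholes[0].waist_diameter

    @property
    def half_angle_deg(self) -> float:
        return self.pinholes[0].half_angle_deg

    @property
    def acceptance_length(self) -> float:
        """``L = focal_length * tan(alpha)`` (mm), the footprint cone radius."""
        return self.focal_length * math.tan(math.radians(self.half_angle_deg))

    @property
    def overlap(self) -> float:
        """Footprint overlap ``o = 2L + d - D`` (mm); negative means a gap."""
        return overlap_of(self.pitch, self.acceptance_length, self.waist_diameter)

    def nearest_index(self, points: np.ndarray) -> np.ndarray:
        """Index of the lattice pinhole nearest to each 2-D point.

        Points are expected in the collimator frame.  Returns ``(n,)`` int
        indices; always a valid pinhole (the grid is clipped at its edges).
        """
        points = np.atleast_2d(points)
        off = np.asarray(self.lattice_offset, float)
        k = np.rint((points - off) / self.pitch).astype(np.int64)
        k = np.clip(k, self._kmin, self._kmax)
        idx = self._lookup[k[:, 0] - self._kmin[0], k[:, 1] - self._kmin[1]]
        # rectangular builds have no holes, but guard against -1 anyway
        return idx


@dataclass
class DetectorPanel:
    """Monolithic scintillator panel behind the collimator.

    Defaults model a 100x100x3 mm GAGG crystal read out with 1 mm FWHM
    intrinsic spatial resolution and 10% FWHM energy resolution, placed with
    its entrance face ``standoff`` mm behind the collimator mid-plane.
    ``mu_crystal`` is the linear attenuation coefficient of the crystal at
    the photopeak energy (1/mm); the default is GAGG at 140.5 keV.
    """

    size: tuple[float, float] = (100.0, 100.0)
    crystal_thickness: float = 3.0
    standoff: float = 10.0
    intrinsic_fwhm_xy: float = 1.0
    energy_resolution_fwhm_frac: float = 0.10
    mu_crystal: float = 0.40

    def __post_init__(self) -> None:
        if min(self.size) <= 0 or self.crystal_thickness <= 0 or self.standoff <= 0:
            raise GeometryError("panel dimensions must be > 0")
        if not 0.0 < self.energy_resolution_fwhm_frac < 1.0:
            raise GeometryError("fractional energy resolution must be in (0, 1)")
        if self.intrinsic_fwhm_xy < 0 or self.mu_crystal < 0:
            raise GeometryError("panel blur and attenuation must be >= 0")


@dataclass
class MotionModel:
    """Relative motion of the collimator with respect to the detector.

    kind
        ``static``, ``linear_two_position`` or ``circular``.
    period
        Rotation period T (s) for circular motion.
    displacement
        Second-position offset (mm) for linear motion; the first position is
        the identity.  Equal dwell at each position over ``dwell_cycle``.
    axis_offset
        Distance (mm) of the nearest lattice node from the rotation axis,
        informational; the geometry realises it through the lattice offset.
    """

    kind: str = "static"
    period: float = 3.6
    displacement: tuple[float, float] = (0.0, 0.0)
    dwell_cycle: float = 4.0
    axis_offset: float = 0.0

    _KINDS = ("static", "linear_two_position", "circular")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise GeometryError(f"unknown motion kind {self.kind!r}")
        if self.kind == "circular" and self.period <= 0:
            raise GeometryError("circular motion requires period > 0")
        if self.kind == "linear_two_position" and self.dwell_cycle <= 0:
            raise GeometryError("linear motion requires dwell_cycle > 0")

    @property
    def cycle(self) -> float:
        """Duration of one full motion cycle (s); 0 for static."""
        if self.kind == "circular":
            return self.period
        if self.kind == "linear_two_position":
            return self.dwell_cycle
        return 0.0


@dataclass
class RigidPose:
    """In-plane rigid transform: rotation ``theta`` about the detector normal
    (through the global origin) followed by a 2-D translation."""

    theta: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` collimator-frame points into the global frame."""
        points = np.atleast_2d(np.asarray(points, float))
        c, s = math.cos(self.theta), math.sin(self.theta)
        out = np.empty_like(points)
        out[:, 0] = c * points[:, 0] - s * points[:, 1] + self.translation[0]
        out[:, 1] = s * points[:, 0] + c * points[:, 1] + self.translation[1]
        return out

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        """Map global-frame points back into the collimator frame."""
        points = np.atleast_2d(np.asarray(points, float))
        q = points - np.asarray(self.translation, float)
        c, s = math.cos(-self.theta), math.sin(-self.theta)
        out = np.empty_like(q)
        out[:, 0] = c * q[:, 0] - s * q[:, 1]
        out[:, 1] = s * q[:, 0] + c * q[:, 1]
        return out

    def inverse(self) -> "RigidPose":
        c, s = math.cos(-self.theta), math.sin(-self.theta)
        tx, ty = self.translation
        return RigidPose(-self.theta, (-(c * tx - s * ty), -(s * tx + c * ty)))

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        moved = self.apply(np.array([other.translation], float))[0]
        return RigidPose(self.theta + other.theta, (moved[0], moved[1]))


def build_lattice(
    D: float,
    d: float,
    extent: tuple[float, float] = (100.0, 100.0),
    lattice_offset: tuple[float, float] = (0.0, 0.0),
    half_angle_deg: float = 35.0,
    thickness: float = 3.0,
    focal_length: float = 10.0,
) -> PinholeLattice:
    """Build the square pinhole grid that fits on the plate.

    Every node ``k * D + lattice_offset`` (per axis) whose center lies within
    ``extent/2 - d/2`` of the plate center becomes a pinhole.  Indices run
    row-major with x fastest, sorted by (y, x).
    """
    if D <= 0:
        raise GeometryError("pitch D must be > 0")
    if not D > d >= 0:
        raise GeometryError("require D > d >= 0")
    if d == 0:
        # allow the degenerate limit only for analytic checks
        d_eff = 0.0
    else:
        d_eff = d
    axes = []
    for a in range(2):
        half = extent[a] / 2.0 - d_eff / 2.0
        off = lattice_offset[a]
        kmin = math.ceil((-half - off) / D - 1e-9)
        kmax = math.floor((half - off) / D + 1e-9)
        axes.append(np.arange(kmin, kmax + 1) * D + off)
    xs, ys = axes
    pinholes = []
    idx = 0
    for y in ys:
        for x in xs:
            pinholes.append(
                Pinhole((float(x), float(y)), max(d, 1e-12), half_angle_deg, idx)
            )
            idx += 1
    if not pinholes:
        raise GeometryError("no pinhole fits on the plate")
    return PinholeLattice(
        pitch=D,
        pinholes=pinholes,
        extent=tuple(extent),
        thickness=thickness,
        lattice_offset=tuple(lattice_offset),
        focal_length=focal_length,
    )


def pose_at_time(motion: MotionModel, t: float) -> RigidPose:
    """Collimator pose at time ``t`` (s).

    Circular motion rotates continuously, ``theta = 2 pi t / T``, about the
    global z axis with no translation (the off-axis placement of the lattice
    is part of the lattice offset).  Linear motion sits at the identity for
    the first half of each dwell cycle and at ``displacement`` for the
    second.  Static motion is the identity for all t.
    """
    theta, trans = poses_at_times(motion, np.array([t], float))
    return RigidPose(float(theta[0]), (float(trans[0, 0]), float(trans[0, 1])))


def poses_at_times(motion: MotionModel, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`pose_at_time`: returns ``(theta, translation)`` arrays."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise GeometryError("time must be >= 0")
    theta = np.zeros_like(t)
    trans = np.zeros(t.shape + (2,), float)
    if motion.kind == "circular":
        theta = 2.0 * np.pi * t / motion.period
    elif motion.kind == "linear_two_position":
        second = np.mod(t, motion.dwell_cycle) >= motion.dwell_cycle / 2.0
        trans[second] = np.asarray(motion.displacement, float)
    return theta, trans


def footprint(
    pinhole: Pinhole, panel: DetectorPanel, pose: RigidPose | None = None
) -> tuple[np.ndarray, float]:
    """Detector-plane footprint of one pinhole at a pose.

    The center is the posed pinhole center projected straight down to the
    detection plane; the radius is ``standoff * tan(alpha) + d/2``.
    """
    pose = pose or RigidPose()
    center = pose.apply(np.array([pinhole.center], float))[0]
    radius = (
        panel.standoff * math.tan(math.radians(pinhole.half_angle_deg))
        + pinhole.waist_diameter / 2.0
    )
    return center, radius


def overlap_of(D: float, L: float, d: float) -> float:
    """Footprint overlap ``o = 2L + d - D`` (mm); negative values are gaps."""
    if min(D, L, d) < 0:
        raise GeometryError("overlap_of arguments must be >= 0")
    return 2.0 * L + d - D


@dataclass
class CameraSystem:
    """Complete camera: pinhole lattice + detector panel + motion model."""

    lattice: PinholeLattice
    panel: DetectorPanel
    motion: MotionModel
    name: str = ""

    @property
    def footprint_radius(self) -> float:
        return (
            self.panel.standoff
            * math.tan(math.radians(self.lattice.half_angle_deg))
            + self.lattice.waist_diameter / 2.0
        )

    def config_dict(self) -> dict:
        return {
            "name": self.name,
            "lattice": {
                "pitch": self.lattice.pitch,
                "waist_diameter": self.lattice.waist_diameter,
                "half_angle_deg": self.lattice.half_angle_deg,
                "extent": list(self.lattice.extent),
                "thickness": self.lattice.thickness,
                "lattice_offset": list(self.lattice.lattice_offset),
                "focal_length": self.lattice.focal_length,
            },
            "panel": {
                "size": list(self.panel.size),
                "crystal_thickness": self.panel.crystal_thickness,
                "standoff": self.panel.standoff,
                "intrinsic_fwhm_xy": self.panel.intrinsic_fwhm_xy,
                "energy_resolution_fwhm_frac": self.panel.energy_resolution_fwhm_frac,
                "mu_crystal": self.panel.mu_crystal,
            },
            "motion": {
                "kind": self.motion.kind,
                "period": self.motion.period,
                "displacement": list(self.motion.displacement),
                "dwell_cycle": self.motion.dwell_cycle,
                "axis_offset": self.motion.axis_offset,
            },
        }

    def geometry_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_config(cls, cfg: dict, name: str = "") -> "CameraSystem":
        lat = dict(cfg["lattice"])
        panel = DetectorPanel(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.get("panel", {}).items()}
        )
        mot_cfg = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.get("motion", {"kind": "static"}).items()
        }
        motion = MotionModel(**mot_cfg)
        lattice = build_lattice(
            D=lat["pitch"],
            d=lat["waist_diameter"],
            extent=tuple(lat.get("extent", (100.0, 100.0))),
            lattice_offset=tuple(lat.get("lattice_offset", (0.0, 0.0))),
            half_angle_deg=lat.get("half_angle_deg", 35.0),
            thickness=lat.get("thickness", 3.0),
            focal_length=lat.get("focal_length", panel.standoff),
        )
        return cls(lattice=lattice, panel=panel, motion=motion, name=name or cfg.get("name", ""))


def _preset_table() -> dict:
    text = resources.files("pincam").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_names() -> list[str]:
    """Names of the shipped camera configurations."""
    return sorted(_preset_table())


def load_preset(name: str) -> CameraSystem:
    """Load one of the shipped camera configurations by name."""
    table = _preset_table()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(table)}")
    return CameraSystem.from_config(table[name], name=name)
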