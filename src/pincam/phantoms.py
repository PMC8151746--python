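"""Analytic emission phantoms.

Sources are voxel-free geometric primitives (spheres, a z-axis cylinder, an
axis-aligned box) carrying a total activity in Bq.  Decay positions are drawn
uniformly within each primitive, so a phantom is fully described by shapes
and activities; no voxelisation or attenuation is modelled (sources in air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import FOV_MIN, FOV_SIZE

__all__ = [
    "PhantomError",
    "Sphere",
    "Cylinder",
    "Box",
    "Phantom",
    "derenzo",
    "two_sphere_depth",
    "uniformity_cylinder",
    "with_background",
]

_FOV_MAX = FOV_MIN + FOV_SIZE


class PhantomError(ValueError):
    """Raised for invalid phantom definitions."""


def _check_inside_fov(lo: np.ndarray, hi: np.ndarray, what: str) -> None:
    if np.any(lo < FOV_MIN - 1e-9) or np.any(hi > _FOV_MAX + 1e-9):
        raise PhantomError(f"{what} extends outside the field of view")


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    diameter: float
    activity: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise PhantomError("sphere diameter must be > 0")
        if self.activity < 0:
            raise PhantomError("activity must be >= 0")
        c = np.asarray(self.center, float)
        r = self.diameter / 2.0
        _check_inside_fov(c - r, c + r, "sphere")

    @property
    def volume(self) -> float:
        return math.pi * self.diameter**3 / 6.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.sqrt(np.einsum("ij,ij->i", v, v))[:, None]
        r = self.diameter / 2.0 * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
        return np.asarray(self.center, float) + v * r

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - np.asarray(self.center, float)
        return np.einsum("ij,ij->i", d, d) <= (self.diameter / 2.0) ** 2


@dataclass(frozen=True)
class Cylinder:
    """Right circular cylinder with its axis along z."""

    center: tuple[float, float, float]
    diameter: float
    height: float
    activity: float

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise PhantomError("cylinder dimensions must be > 0")
        if self.activity < 0:
            raise PhantomError("activity must be >= 0")
        c = np.asarray(self.center, float)
        r = self.diameter / 2.0
        lo = c - [r, r, self.height / 2.0]
        hi = c + [r, r, self.height / 2.0]
        _check_inside_fov(lo, hi, "cylinder")

    @property
    def volume(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2 * self.height

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.diameter / 2.0 * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        z = rng.uniform(-self.height / 2.0, self.height / 2.0, size=n)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        return np.asarray(self.center, float) + pts

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - np.asarray(self.center, float)
        in_r = d[:, 0] ** 2 + d[:, 1] ** 2 <= (self.diameter / 2.0) ** 2
        return in_r & (np.abs(d[:, 2]) <= self.height / 2.0)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box given by its lower corner and edge lengths."""

    corner: tuple[float, float, float]
    size: tuple[float, float, float]
    activity: float

    def __post_init__(self) -> None:
        if min(self.size) <= 0:
            raise PhantomError("box size must be > 0")
        if self.activity < 0:
            raise PhantomError("activity must be >= 0")
        lo = np.asarray(self.corner, float)
        _check_inside_fov(lo, lo + np.asarray(self.size, float), "box")

    @property
    def volume(self) -> float:
        return float(np.prod(self.size))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(size=(n, 3))
        return np.asarray(self.corner, float) + u * np.asarray(self.size, float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.corner, float)
        hi = lo + np.asarray(self.size, float)
        return np.all((points >= lo) & (points <= hi), axis=1)


Primitive = Sphere | Cylinder | Box


@dataclass
class Phantom:
    primitives: list[Primitive]
    name: str = ""

    @property
    def total_activity(self) -> float:
        return float(sum(p.activity for p in self.primitives))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` decay positions, activity-weighted across primitives."""
        if not self.primitives or self.total_activity <= 0 or n == 0:
            return np.empty((0, 3))
        if len(self.primitives) == 1:
            return self.primitives[0].sample(n, rng)
        weights = np.array([p.activity for p in self.primitives], float)
        counts = rng.multinomial(n, weights / weights.sum())
        parts = [
            p.sample(int(k), rng) for p, k in zip(self.primitives, counts) if k > 0
        ]
        pts = np.concatenate(parts, axis=0)
        # decouple position from (sorted) emission time downstream
        return pts[rng.permutation(len(pts))]

    def to_dict(self) -> dict:
        out = []
        for p in self.primitives:
            if isinstance(p, Sphere):
                out.append(
                    {"shape": "sphere", "center": list(p.center),
                     "diameter": p.diameter, "activity": p.activity}
                )
            elif isinstance(p, Cylinder):
                out.append(
                    {"shape": "cylinder", "center": list(p.center),
                     "diameter": p.diameter, "height": p.height,
                     "activity": p.activity}
                )
            else:
                out.append(
                    {"shape": "box", "corner": list(p.corner),
                     "size": list(p.size), "activity": p.activity}
                )
        return {"name": self.name, "primitives": out}

    @classmethod
    def from_dict(cls, cfg: dict) -> "Phantom":
        prims: list[Primitive] = []
        for p in cfg.get("primitives", []):
            shape = p.get("shape")
            if shape == "sphere":
                prims.append(Sphere(tuple(p["center"]), p["diameter"], p["activity"]))
            elif shape == "cylinder":
                prims.append(
                    Cylinder(tuple(p["center"]), p["diameter"], p["height"], p["activity"])
                )
            elif shape == "box":
                prims.append(Box(tuple(p["corner"]), tuple(p["size"]), p["activity"]))
            else:
                raise PhantomError(f"unknown primitive shape {shape!r}")
        return cls(primitives=prims, name=cfg.get("name", ""))


def _triangular_layout(n: int, spacing: float) -> np.ndarray:
    """Centers of a compact triangular cluster of ``n`` spheres (2-D, mm).

    Rows of 1, 2, 3, ... spheres with the stated center spacing; the cluster
    centroid is returned at the origin.  For n=3 this is an equilateral
    triangle of side ``spacing``.
    """
    pts: list[tuple[float, float]] = []
    row = 0
    while len(pts) < n:
        row += 1
        y = -(row - 1) * spacing * math.sqrt(3.0) / 2.0
        for i in range(row):
            if len(pts) >= n:
                break
            x = (i - (row - 1) / 2.0) * spacing
            pts.append((x, y))
    arr = np.array(pts, float)
    return arr - arr.mean(axis=0)


def derenzo(
    n_spheres: int,
    diameter: float,
    spacing: float,
    z: float,
    activity_per_sphere: float,
) -> Phantom:
    """Derenzo-like cluster of equal spheres in a transverse plane.

    Sphere centers lie at depth ``z`` on a centered triangular layout (rows of
    1/2/3... spheres) with the stated center-to-center ``spacing``; the
    cluster centroid sits on the FOV axis.
    """
    if n_spheres < 1:
        raise PhantomError("need at least one sphere")
    if spacing < diameter:
        raise PhantomError("spacing must be >= sphere diameter")
    layout = _triangular_layout(n_spheres, spacing) if n_spheres > 1 else np.zeros((1, 2))
    prims = [
        Sphere((float(x), float(y), float(z)), diameter, activity_per_sphere)
        for x, y in layout
    ]
    return Phantom(prims, name=f"derenzo{n_spheres}_{diameter:g}mm_z{z:g}")


def two_sphere_depth(
    diameter: float, dz: float, z0: float, activity: float
) -> Phantom:
    """Two spheres on the FOV axis at depths ``z0`` and ``z0 + dz``."""
    if dz < diameter:
        raise PhantomError("spheres overlap: dz < diameter")
    prims = [
        Sphere((0.0, 0.0, float(z0)), diameter, activity),
        Sphere((0.0, 0.0, float(z0 + dz)), diameter, activity),
    ]
    return Phantom(prims, name=f"two_sphere_{diameter:g}mm_dz{dz:g}")


def uniformity_cylinder() -> Phantom:
    """Uniformity phantom: 5 cm diameter, 1 cm tall cylinder at z = 6 cm,
    0.1 MBq, bases parallel to the collimator plane."""
    return Phantom(
        [Cylinder((0.0, 0.0, 60.0), diameter=50.0, height=10.0, activity=1e5)],
        name="uniformity_cylinder",
    )


def with_background(phantom: Phantom, ratio: float) -> Phantom:
    """Append an FOV-filling background cube at a target:background
    concentration ratio.

    The background concentration is the sphere activity concentration divided
    by ``ratio``; spheres are assumed equal so the first one sets the
    concentration.
    """
    if ratio <= 0:
        raise PhantomError("ratio must be > 0")
    spheres = [p for p in phantom.primitives if isinstance(p, Sphere)]
    if not spheres:
        raise PhantomError("phantom has no sphere to define the target concentration")
    conc = spheres[0].activity / spheres[0].volume
    bg_activity = conc / ratio * FOV_SIZE**3
    bg = Box(tuple(FOV_MIN), (FOV_SIZE, FOV_SIZE, FOV_SIZE), bg_activity)
    return Phantom(
        phantom.primitives + [bg], name=(phantom.name + f"_bg{ratio:g}to1")
    )
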