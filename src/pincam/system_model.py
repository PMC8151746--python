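"""System model: pinhole assignment, LORs, voxel traversal, sensitivity image.

A detected event is turned into a line of response (LOR): the straight line
through the impact point on the detection plane and the center of the pinhole
the event is assigned to, taken at the collimator pose of the event time.
The per-voxel system response ``p_ij`` along a LOR is modelled as the
voxel-intersection chord length (solid-angle and efficiency effects are
absorbed into the Monte-Carlo sensitivity image); the total per-voxel
sensitivity ``sum_i p_ij`` is estimated by simulating a uniform source that
fills the field of view over one full motion cycle, with the rotation
discretised to a fixed number of poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .geometry import CameraSystem, FOV_MIN, FOV_SIZE, poses_at_times
from .phantoms import Box, Phantom
from .transport import AcquisitionConfig, ListModeEvents, simulate

__all__ = [
    "VoxelGrid",
    "ImageVolume",
    "SensitivityImage",
    "LORBundle",
    "assign_pinhole",
    "lors_from_events",
    "traverse",
    "ProjectionData",
    "build_projection",
    "estimate_sensitivity_image",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid over the field of view.

    The default is the reconstruction grid: 100^3 voxels of 1 mm over the
    10x10x10 cm FOV cube.  Voxel ownership is half-open per axis:
    voxel ``i`` owns ``[origin + i*spacing, origin + (i+1)*spacing)``.
    """

    shape: tuple[int, int, int] = (100, 100, 100)
    spacing: float = 1.0
    origin: tuple[float, float, float] = (-50.0, -50.0, 0.0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape, float) * self.spacing

    def centers(self, axis: int) -> np.ndarray:
        return (
            self.origin[axis]
            + (np.arange(self.shape[axis]) + 0.5) * self.spacing
        )

    @classmethod
    def default(cls) -> "VoxelGrid":
        return cls()

    @classmethod
    def coarse(cls, spacing: float) -> "VoxelGrid":
        """FOV-covering grid at a different isotropic spacing."""
        n = int(round(FOV_SIZE / spacing))
        return cls(shape=(n, n, n), spacing=spacing, origin=tuple(FOV_MIN))


@dataclass
class ImageVolume:
    """Non-negative activity estimate on a voxel grid (arbitrary units)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("image values must be >= 0")

    @classmethod
    def zeros(cls, grid: VoxelGrid | None = None) -> "ImageVolume":
        grid = grid or VoxelGrid.default()
        return cls(grid, np.zeros(grid.shape))

    @classmethod
    def full(cls, value: float, grid: VoxelGrid | None = None) -> "ImageVolume":
        grid = grid or VoxelGrid.default()
        return cls(grid, np.full(grid.shape, float(value)))


class SensitivityImage(ImageVolume):
    """Per-voxel total system response ``sum_i p_ij`` on the image grid."""

    @classmethod
    def uniform(cls, grid: VoxelGrid | None = None) -> "SensitivityImage":
        """The low-count option: unit sensitivity everywhere."""
        grid = grid or VoxelGrid.default()
        return cls(grid, np.ones(grid.shape))


def assign_pinhole(
    x: np.ndarray, y: np.ndarray, time: np.ndarray, system: CameraSystem
) -> np.ndarray:
    """Assign each detected impact to a pinhole, or -1.

    Candidates are the pinholes whose detector footprint at the event-time
    pose contains the impact; the nearest footprint center wins (footprints
    are concentric discs of one radius, so the nearest lattice node is the
    unique candidate to check).  Events outside every footprint get -1.
    """
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    time = np.broadcast_to(np.asarray(time, float), x.shape)
    theta, trans = poses_at_times(system.motion, time)
    pts = np.column_stack([x, y])
    q = pts - trans
    c, s = np.cos(theta), np.sin(theta)
    pc = np.column_stack([c * q[:, 0] + s * q[:, 1], -s * q[:, 0] + c * q[:, 1]])
    idx = system.lattice.nearest_index(pc)
    dist = np.linalg.norm(pc - system.lattice.centers[idx], axis=1)
    out = np.where(dist <= system.footprint_radius, idx, -1)
    return out.astype(np.int64)


@dataclass
class LORBundle:
    """Oriented lines of response for a set of events.

    ``entry`` is the impact point lifted to 3-D (detection plane), ``pivot``
    the assigned pinhole center at event time on the collimator mid-plane;
    the line is followed from the pivot into the FOV.  ``valid`` flags LORs
    with an assigned pinhole whose line crosses the FOV box.
    """

    entry: np.ndarray      # (n, 3)
    pivot: np.ndarray      # (n, 3)
    direction: np.ndarray  # (n, 3) unit, +z
    pinhole: np.ndarray    # (n,)
    valid: np.ndarray      # (n,) bool


def lors_from_events(
    events: ListModeEvents,
    system: CameraSystem,
    times: np.ndarray | None = None,
    pinhole: np.ndarray | None = None,
) -> LORBundle:
    """Build LORs from events; pinholes are re-assigned from the blurred
    impacts unless explicit assignments are given.

    ``times`` optionally overrides the pose times (used for the discretised
    sensitivity-image poses)."""
    t = events.time if times is None else np.asarray(times, float)
    if pinhole is None:
        pinhole = assign_pinhole(events.x, events.y, t, system)
    theta, trans = poses_at_times(system.motion, t)
    safe = np.maximum(pinhole, 0)
    node = system.lattice.centers[safe]
    c, s = np.cos(theta), np.sin(theta)
    gx = c * node[:, 0] - s * node[:, 1] + trans[:, 0]
    gy = s * node[:, 0] + c * node[:, 1] + trans[:, 1]
    pivot = np.column_stack([gx, gy, np.zeros_like(gx)])
    entry = np.column_stack(
        [events.x, events.y, np.full(len(events.x), -system.panel.standoff)]
    )
    direction = pivot - entry
    norm = np.linalg.norm(direction, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    direction = direction / norm
    valid = (pinhole >= 0) & (direction[:, 2] > 1e-9)
    return LORBundle(entry, pivot, direction, pinhole, valid)


def _clip_to_box(p0, u, lo, hi):
    """Slab-clip a ray p0 + t u to an axis-aligned box; returns (t0, t1)."""
    t0, t1 = 0.0, np.inf
    for a in range(3):
        if abs(u[a]) < 1e-12:
            if not (lo[a] <= p0[a] <= hi[a]):
                return 0.0, -1.0
            continue
        ta = (lo[a] - p0[a]) / u[a]
        tb = (hi[a] - p0[a]) / u[a]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
    return t0, t1


def traverse(
    p0: np.ndarray, direction: np.ndarray, grid: VoxelGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Voxels visited by a ray and the chord length in each (mm).

    Incremental plane-crossing traversal (Siddon-style): the ray
    ``p0 + t * direction`` (``direction`` unit) is clipped to the grid box;
    every voxel-boundary crossing splits it into segments whose midpoints
    identify the owning voxel.  Chord lengths sum to the in-box path length.
    Returns ``(flat voxel indices, lengths)``; empty arrays if the ray
    misses the grid.
    """
    p0 = np.asarray(p0, float)
    u = np.asarray(direction, float)
    lo = np.asarray(grid.origin, float)
    hi = lo + grid.extent
    t0, t1 = _clip_to_box(p0, u, lo, hi)
    if t1 <= t0:
        return np.empty(0, np.int64), np.empty(0)
    ts = [np.array([t0, t1])]
    for a in range(3):
        if abs(u[a]) < 1e-12:
            continue
        # plane indices strictly inside (t0, t1)
        xa0 = p0[a] + t0 * u[a]
        xa1 = p0[a] + t1 * u[a]
        i_lo = int(math.ceil((min(xa0, xa1) - lo[a]) / grid.spacing - 1e-9))
        i_hi = int(math.floor((max(xa0, xa1) - lo[a]) / grid.spacing + 1e-9))
        i_lo = max(i_lo, 1)
        i_hi = min(i_hi, grid.shape[a] - 1)
        if i_hi < i_lo:
            continue
        planes = lo[a] + np.arange(i_lo, i_hi + 1) * grid.spacing
        ts.append((planes - p0[a]) / u[a])
    t = np.unique(np.concatenate(ts))
    t = t[(t >= t0 - 1e-12) & (t <= t1 + 1e-12)]
    if len(t) < 2:
        return np.empty(0, np.int64), np.empty(0)
    lengths = np.diff(t)
    keep = lengths > 1e-12
    mids = p0[None, :] + (0.5 * (t[:-1] + t[1:]))[keep, None] * u[None, :]
    lengths = lengths[keep]
    ijk = np.floor((mids - lo) / grid.spacing).astype(np.int64)
    np.clip(ijk, 0, np.asarray(grid.shape) - 1, out=ijk)
    flat = np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), grid.shape)
    return flat, lengths


@dataclass
class ProjectionData:
    """Sparse per-event system rows ``p_{i_k j}`` on a voxel grid."""

    matrix: sparse.csr_matrix       # (n_used, n_voxels)
    used: np.ndarray                # indices into the original event list
    pinhole: np.ndarray             # assignment per original event (-1 none)
    log: dict


def build_projection(
    events: ListModeEvents,
    system: CameraSystem,
    grid: VoxelGrid | None = None,
    times: np.ndarray | None = None,
) -> ProjectionData:
    """Assign pinholes, build LORs and traverse them into CSR rows.

    Events without a pinhole or whose LOR misses the FOV are dropped and
    counted in the log.
    """
    grid = grid or VoxelGrid.default()
    lors = lors_from_events(events, system, times=times)
    n = len(events)
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    used = []
    n_no_pinhole = int(np.sum(lors.pinhole < 0))
    n_out_fov = 0
    for i in range(n):
        if not lors.valid[i]:
            continue
        flat, lengths = traverse(lors.pivot[i], lors.direction[i], grid)
        if len(flat) == 0:
            n_out_fov += 1
            continue
        used.append(i)
        indices.append(flat)
        data.append(lengths)
        indptr.append(indptr[-1] + len(flat))
    if used:
        matrix = sparse.csr_matrix(
            (np.concatenate(data), np.concatenate(indices), np.array(indptr)),
            shape=(len(used), grid.n_voxels),
        )
    else:
        matrix = sparse.csr_matrix((0, grid.n_voxels))
    log = {
        "n_events": n,
        "n_used": len(used),
        "n_no_pinhole": n_no_pinhole,
        "n_out_of_fov": n_out_fov,
    }
    return ProjectionData(matrix, np.array(used, np.int64), lors.pinhole, log)


def estimate_sensitivity_image(
    system: CameraSystem,
    n_decays: int,
    rng: np.random.Generator,
    grid: VoxelGrid | None = None,
    n_poses: int = 64,
) -> SensitivityImage:
    """Monte-Carlo effective sensitivity image by flood-source simulation.

    A uniform source filling the FOV emits ``n_decays`` photons over one
    full motion cycle; each detected event's LOR is traversed and the chord
    lengths accumulated per voxel, then normalised per decay.  For moving
    collimators the event poses are discretised to ``n_poses`` equally
    spaced poses per cycle, which makes this the rotation-summed (effective)
    sensitivity of the whole cycle rather than any instantaneous pose.
    """
    grid = grid or VoxelGrid.default()
    duration = system.motion.cycle or 1.0
    flood = Phantom(
        [Box(tuple(FOV_MIN), (FOV_SIZE, FOV_SIZE, FOV_SIZE), n_decays / duration)],
        name="flood",
    )
    config = AcquisitionConfig(duration=duration)
    events = simulate(flood, system, config, rng)
    if len(events) == 0:
        return SensitivityImage.zeros(grid)
    t = events.time
    if system.motion.kind != "static" and n_poses > 0:
        cycle = system.motion.cycle
        t = (np.floor(t / cycle * n_poses) + 0.5) * cycle / n_poses
    proj = build_projection(events, system, grid, times=t)
    acc = np.zeros(grid.n_voxels)
    m = proj.matrix.tocoo()
    np.add.at(acc, m.col, m.data)
    acc /= max(events.n_emitted, 1)
    return SensitivityImage(grid, acc.reshape(grid.shape))
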