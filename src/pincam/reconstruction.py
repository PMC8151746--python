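"""List-mode OSEM reconstruction.

The image update for subset ``S_l`` at iteration ``m`` is the multiplicative
EM step

    lambda_j  <-  lambda_j / (sum_i p_ij)  *
                  sum_{k in S_l}  p_{i_k j} / (sum_b p_{i_k b} lambda_b)

where ``i_k`` is the LOR of event ``k``, ``p_ij`` the chord length of LOR
``i`` in voxel ``j`` and ``sum_i p_ij`` the per-voxel sensitivity.  One
"iteration" is a full pass over all ``L`` subsets; subsets partition the
time-ordered event list round-robin.  For short, low-count acquisitions the
sensitivity is set to one everywhere (the geometric normalisation only helps
once per-voxel statistics support it); voxels with zero sensitivity are
frozen at zero to avoid division by zero.

The module exposes both a functional surface (:func:`lm_osem`,
:func:`partition`, :func:`axial_correct`) and a model/results pair
(:class:`ListModeOSEM` / :class:`OSEMResults`) that carries diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CameraSystem
from .system_model import (
    ImageVolume,
    ProjectionData,
    SensitivityImage,
    VoxelGrid,
    build_projection,
)
from .transport import ListModeEvents

__all__ = [
    "SubsetPartition",
    "ReconOptions",
    "partition",
    "lm_osem",
    "axial_correct",
    "ListModeOSEM",
    "OSEMResults",
]

#: Below this many events the sensitivity normalisation defaults to uniform.
LOW_COUNT_THRESHOLD = 100_000


@dataclass
class SubsetPartition:
    """Disjoint round-robin subsets covering all events."""

    n_subsets: int
    subsets: list[np.ndarray]

    @property
    def assignment(self) -> np.ndarray:
        n = sum(len(s) for s in self.subsets)
        out = np.empty(n, np.int64)
        for l, s in enumerate(self.subsets):
            out[s] = l
        return out


def partition(n_events: int, n_subsets: int) -> SubsetPartition:
    """Interleave time-ordered events round-robin: event k -> subset k mod L.

    Subset sizes differ by at most one; with fewer events than subsets some
    subsets are empty (they are skipped during updates).
    """
    if n_subsets < 1:
        raise ValueError("need at least one subset")
    idx = np.arange(n_events)
    return SubsetPartition(
        n_subsets, [idx[l::n_subsets] for l in range(n_subsets)]
    )


@dataclass
class ReconOptions:
    """LM-OSEM settings.

    ``uniform_sensitivity=None`` resolves automatically: uniform below
    ``LOW_COUNT_THRESHOLD`` events, the supplied Monte-Carlo image above.
    ``axial_kappa`` (1/cm) and ``axial_z0`` (cm) configure the optional
    exponential depth compensation applied after reconstruction.
    """

    iterations: int = 2
    subsets: int = 2
    uniform_sensitivity: bool | None = None
    init_value: float = 1.0
    axial_kappa: float = 0.0
    axial_z0: float = 0.0

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if self.init_value <= 0:
            raise ValueError("initial value must be > 0")
        if self.axial_kappa < 0:
            raise ValueError("axial correction coefficient must be >= 0")


def _osem_core(
    P, part: SubsetPartition, sens_flat: np.ndarray, iterations: int,
    init_value: float, init_image: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    n_vox = P.shape[1]
    active = sens_flat > 0
    if init_image is not None:
        lam = np.asarray(init_image, float).ravel().copy()
    else:
        lam = np.full(n_vox, float(init_value))
    lam[~active] = 0.0
    inv_sens = np.zeros(n_vox)
    inv_sens[active] = 1.0 / sens_flat[active]
    skipped: list[int] = []
    for _ in range(iterations):
        for sub in part.subsets:
            if len(sub) == 0:
                continue
            Psub = P[sub]
            fwd = Psub @ lam
            good = fwd > 0
            skipped.append(int(np.sum(~good)))
            w = np.zeros(len(sub))
            w[good] = 1.0 / fwd[good]
            back = Psub.T @ w
            lam = lam * inv_sens * back
    return lam, skipped


def lm_osem(
    events: ListModeEvents,
    system: CameraSystem,
    sensitivity: SensitivityImage | None = None,
    options: ReconOptions | None = None,
    grid: VoxelGrid | None = None,
) -> ImageVolume:
    """Reconstruct an activity image from list-mode events (functional form).

    See :class:`ListModeOSEM` for the object interface with diagnostics.
    """
    model = ListModeOSEM(events, system, sensitivity=sensitivity,
                         options=options, grid=grid)
    return model.fit().image


def axial_correct(
    image: ImageVolume, kappa: float = 1.0, z0: float = 0.0
) -> ImageVolume:
    """Exponential depth compensation: voxel at depth z (cm) is multiplied by
    ``exp(+kappa * (z - z0))``, countering the e^{-z} falloff of projections
    with distance from the collimator.  ``kappa`` in 1/cm, ``z0`` in cm."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    z_cm = image.grid.centers(2) / 10.0
    gain = np.exp(kappa * (z_cm - z0))
    return ImageVolume(image.grid, image.values * gain[None, None, :])


class ListModeOSEM:
    """LM-OSEM reconstruction model for one acquisition.

    Builds the per-event system rows once (pinhole assignment, LOR, voxel
    traversal); :meth:`fit` then runs the multiplicative updates and returns
    an :class:`OSEMResults`.

    Parameters
    ----------
    events : ListModeEvents
    system : CameraSystem
    sensitivity : SensitivityImage, optional
        Monte-Carlo sensitivity image; ignored when the uniform option is
        in force.
    options : ReconOptions, optional
    grid : VoxelGrid, optional
        Reconstruction grid (default 100^3 at 1 mm).
    """

    def __init__(
        self,
        events: ListModeEvents,
        system: CameraSystem,
        sensitivity: SensitivityImage | None = None,
        options: ReconOptions | None = None,
        grid: VoxelGrid | None = None,
    ) -> None:
        self.events = events
        self.system = system
        self.options = options or ReconOptions()
        self.grid = grid or VoxelGrid.default()
        self.projection: ProjectionData = build_projection(events, system, self.grid)
        uniform = self.options.uniform_sensitivity
        if uniform is None:
            uniform = len(events) < LOW_COUNT_THRESHOLD
        if uniform or sensitivity is None:
            self.sensitivity = SensitivityImage.uniform(self.grid)
            self.uniform_sensitivity = True
        else:
            if sensitivity.grid != self.grid:
                raise ValueError("sensitivity image grid does not match")
            self.sensitivity = sensitivity
            self.uniform_sensitivity = False

    def fit(
        self,
        iterations: int | None = None,
        subsets: int | None = None,
        init_image: ImageVolume | None = None,
    ) -> "OSEMResults":
        it = iterations if iterations is not None else self.options.iterations
        L = subsets if subsets is not None else self.options.subsets
        init = None if init_image is None else init_image.values
        n_used = self.projection.matrix.shape[0]
        part = partition(n_used, L)
        if n_used == 0:
            lam = (np.full(self.grid.n_voxels, self.options.init_value)
                   if init is None else np.asarray(init, float).ravel().copy())
            lam[self.sensitivity.values.ravel() == 0] = 0.0
            skipped: list[int] = []
        else:
            lam, skipped = _osem_core(
                self.projection.matrix, part,
                self.sensitivity.values.ravel(), it, self.options.init_value,
                init_image=init,
            )
        image = ImageVolume(self.grid, lam.reshape(self.grid.shape))
        if self.options.axial_kappa > 0:
            image = axial_correct(
                image, self.options.axial_kappa, self.options.axial_z0
            )
        return OSEMResults(
            image=image, model=self, iterations=it, subsets=L,
            skipped_per_pass=skipped,
        )


@dataclass
class OSEMResults:
    """Reconstruction output with diagnostics."""

    image: ImageVolume
    model: ListModeOSEM
    iterations: int
    subsets: int
    skipped_per_pass: list[int]

    @property
    def n_events_used(self) -> int:
        return self.model.projection.matrix.shape[0]

    @property
    def drop_log(self) -> dict:
        return self.model.projection.log

    def axial_corrected(self, kappa: float = 1.0, z0: float = 0.0) -> ImageVolume:
        return axial_correct(self.image, kappa, z0)

    def profile(self, axis: str, through, half_width: int = 0):
        from .metrics import profile

        return profile(self.image, axis, through, half_width)

    def peak_position(self) -> np.ndarray:
        """Center (mm) of the brightest voxel."""
        ijk = np.unravel_index(int(np.argmax(self.image.values)), self.image.grid.shape)
        g = self.image.grid
        return np.asarray(g.origin) + (np.asarray(ijk) + 0.5) * g.spacing

    def summary(self) -> str:
        log = self.drop_log
        v = self.image.values
        peak = self.peak_position()
        lines = [
            "List-mode OSEM reconstruction",
            "=" * 34,
            f"system            : {self.system_name}",
            f"grid              : {self.image.grid.shape}, "
            f"{self.image.grid.spacing:g} mm voxels",
            f"events (detected) : {log['n_events']}",
            f"events (used)     : {log['n_used']}  "
            f"[no pinhole: {log['n_no_pinhole']}, out of FOV: {log['n_out_of_fov']}]",
            f"iterations x subsets : {self.iterations} x {self.subsets}",
            f"sensitivity       : "
            f"{'uniform' if self.model.uniform_sensitivity else 'Monte-Carlo'}",
            f"skipped per pass  : {self.skipped_per_pass}",
            f"image total       : {v.sum():.6g}",
            f"image max         : {v.max():.6g} at "
            f"({peak[0]:.1f}, {peak[1]:.1f}, {peak[2]:.1f}) mm",
        ]
        return "\n".join(lines)

    @property
    def system_name(self) -> str:
        return self.model.system.name or "<unnamed>"
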