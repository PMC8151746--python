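"""File formats, experiment specs and experiment execution.

List-mode events are stored as CSV with a commented header carrying
provenance (geometry hash, seed, duration, preset).  Volumes are written as
MetaImage (.mhd/.raw, float32, mm spacing) or as raw float32 with a JSON
sidecar.  An :class:`ExperimentSpec` bundles preset + phantom + acquisition
+ reconstruction + metric requests; the specs shipped under
``pincam/experiments`` reproduce the package's standard studies end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantoms as ph
from .geometry import CameraSystem, load_preset
from .metrics import fwhm as metric_fwhm
from .metrics import profile as metric_profile
from .metrics import resolvable_peaks, sensitivity_curve, uniformity_metrics
from .reconstruction import ListModeOSEM, ReconOptions
from .system_model import ImageVolume, VoxelGrid
from .transport import AcquisitionConfig, ListModeEvents, simulate

__all__ = [
    "EventFileError",
    "write_events",
    "read_events",
    "write_volume",
    "read_volume",
    "ExperimentError",
    "ExperimentSpec",
    "experiment_names",
    "load_experiment",
    "build_phantom",
    "run_experiment",
]

_EVENT_COLUMNS = [
    "time_s", "x_mm", "y_mm", "energy_keV",
    "truth_pinhole", "truth_x_mm", "truth_y_mm", "truth_z_mm",
]
_FORMAT_VERSION = 1


class EventFileError(ValueError):
    """Raised for malformed list-mode files."""


def write_events(events: ListModeEvents, path) -> None:
    path = Path(path)
    header = {
        "format_version": _FORMAT_VERSION,
        "system": events.system_name,
        "geometry_hash": events.geometry_hash,
        "seed": events.seed,
        "duration_s": events.duration,
        "n_emitted": events.n_emitted,
        "n_events": len(events),
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(",".join(_EVENT_COLUMNS) + "\n")
        df = events.to_dataframe()
        df.to_csv(fh, index=False, header=False, float_format="%.6f")


def read_events(path) -> ListModeEvents:
    """Read a list-mode CSV; raises :class:`EventFileError` with the line
    number for truncated or malformed rows."""
    path = Path(path)
    header: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if body_start >= len(lines):
        raise EventFileError(f"{path}: missing column header line")
    columns = lines[body_start].strip().split(",")
    if columns != _EVENT_COLUMNS:
        raise EventFileError(
            f"{path}: line {body_start + 1}: unexpected columns {columns}"
        )
    rows = []
    for ln, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != len(_EVENT_COLUMNS):
            raise EventFileError(
                f"{path}: line {ln}: expected {len(_EVENT_COLUMNS)} fields, "
                f"got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise EventFileError(f"{path}: line {ln}: {exc}") from None
    n_declared = header.get("n_events")
    if n_declared is not None and int(n_declared) != len(rows):
        raise EventFileError(
            f"{path}: truncated file: header declares {n_declared} events, "
            f"found {len(rows)}"
        )
    arr = np.array(rows, float).reshape(len(rows), len(_EVENT_COLUMNS))
    events = ListModeEvents(
        time=arr[:, 0], x=arr[:, 1], y=arr[:, 2], energy=arr[:, 3],
        truth_pinhole=arr[:, 4].astype(np.int64), truth_origin=arr[:, 5:8],
        n_emitted=int(header.get("n_emitted", 0) or 0),
        duration=float(header.get("duration_s", 0) or 0),
        seed=int(header["seed"]) if header.get("seed", "None") != "None" else None,
        system_name=header.get("system", ""),
        geometry_hash=header.get("geometry_hash", ""),
    )
    return events


def write_volume(image: ImageVolume, path) -> None:
    """Write a volume as MetaImage (.mhd/.raw) or raw float32 + JSON sidecar."""
    path = Path(path)
    if path.suffix == ".mhd":
        import SimpleITK as sitk

        # SimpleITK indexes (z, y, x); transpose so x is the fastest axis
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(image.values.T.astype(np.float32))
        )
        img.SetSpacing([image.grid.spacing] * 3)
        img.SetOrigin(list(image.grid.origin))
        sitk.WriteImage(img, str(path))
    elif path.suffix == ".raw":
        image.values.astype(np.float32).tofile(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "dtype": "float32",
            "shape": list(image.grid.shape),
            "order": "C (x, y, z)",
            "spacing_mm": image.grid.spacing,
            "origin_mm": list(image.grid.origin),
        }, indent=2))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if path.suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T.astype(float)
        grid = VoxelGrid(
            shape=tuple(values.shape),
            spacing=float(img.GetSpacing()[0]),
            origin=tuple(img.GetOrigin()),
        )
        return ImageVolume(grid, values)
    if path.suffix == ".raw":
        meta = json.loads(path.with_suffix(".json").read_text())
        values = np.fromfile(path, dtype=np.float32).reshape(meta["shape"])
        grid = VoxelGrid(
            shape=tuple(meta["shape"]), spacing=meta["spacing_mm"],
            origin=tuple(meta["origin_mm"]),
        )
        return ImageVolume(grid, values.astype(float))
    raise ValueError(f"unsupported volume format: {path.suffix}")


class ExperimentError(ValueError):
    """Raised for invalid experiment specs; message lists the bad fields."""


_PHANTOM_BUILDERS = {"derenzo", "two_sphere_depth", "uniformity_cylinder", "explicit"}


def build_phantom(cfg: dict) -> ph.Phantom:
    """Build a phantom from its spec dict (builder name + parameters)."""
    cfg = dict(cfg)
    builder = cfg.pop("builder", "explicit")
    background_ratio = cfg.pop("background_ratio", None)
    if builder == "derenzo":
        phantom = ph.derenzo(**cfg)
    elif builder == "two_sphere_depth":
        phantom = ph.two_sphere_depth(**cfg)
    elif builder == "uniformity_cylinder":
        phantom = ph.uniformity_cylinder()
    elif builder == "explicit":
        phantom = ph.Phantom.from_dict(cfg)
    else:
        raise ExperimentError(f"unknown phantom builder {builder!r}")
    if background_ratio is not None:
        phantom = ph.with_background(phantom, background_ratio)
    return phantom


@dataclass
class ExperimentSpec:
    """One reproducible study: preset + phantom (or sensitivity scan) +
    acquisition + reconstruction + metric requests."""

    name: str
    preset: str
    seed: int = 0
    duration: float | None = None
    phantom: dict | None = None
    scan: dict | None = None
    recon: dict = field(default_factory=dict)
    metrics: list = field(default_factory=list)

    def validate(self) -> None:
        problems = []
        try:
            load_preset(self.preset)
        except KeyError as exc:
            problems.append(f"preset: {exc}")
        if self.phantom is None and self.scan is None:
            problems.append("phantom/scan: exactly one required, neither given")
        if self.phantom is not None and self.scan is not None:
            problems.append("phantom/scan: exactly one required, both given")
        if self.phantom is not None:
            if self.duration is None or self.duration <= 0:
                problems.append("duration: must be > 0 for phantom acquisitions")
            try:
                build_phantom(self.phantom)
            except Exception as exc:
                problems.append(f"phantom: {exc}")
            try:
                ReconOptions(**self.recon)
            except Exception as exc:
                problems.append(f"recon: {exc}")
        if self.scan is not None:
            if "points" not in self.scan or "n_decays" not in self.scan:
                problems.append("scan: needs 'points' and 'n_decays'")
        if problems:
            raise ExperimentError(
                f"invalid experiment {self.name!r}: " + "; ".join(problems)
            )

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentSpec":
        known = {"name", "preset", "seed", "duration", "phantom", "scan",
                 "recon", "metrics"}
        unknown = set(cfg) - known
        if unknown:
            raise ExperimentError(f"unknown experiment fields: {sorted(unknown)}")
        return cls(**cfg)

    def to_dict(self) -> dict:
        out = {"name": self.name, "preset": self.preset, "seed": self.seed}
        if self.duration is not None:
            out["duration"] = self.duration
        if self.phantom is not None:
            out["phantom"] = self.phantom
        if self.scan is not None:
            out["scan"] = self.scan
        if self.recon:
            out["recon"] = self.recon
        if self.metrics:
            out["metrics"] = self.metrics
        return out


def experiment_names() -> list[str]:
    files = resources.files("pincam").joinpath("experiments")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_experiment(name_or_path) -> ExperimentSpec:
    """Load a shipped experiment by name, or any spec from a YAML path."""
    p = Path(str(name_or_path))
    if p.suffix == ".yaml" and p.exists():
        cfg = yaml.safe_load(p.read_text())
    else:
        res = resources.files("pincam").joinpath(f"experiments/{name_or_path}.yaml")
        if not res.is_file():
            raise ExperimentError(
                f"unknown experiment {name_or_path!r}; shipped: {experiment_names()}"
            )
        cfg = yaml.safe_load(res.read_text())
    spec = ExperimentSpec.from_dict(cfg)
    spec.validate()
    return spec


def _run_metric(request: dict, image: ImageVolume) -> dict:
    kind = request.get("kind")
    out = {"kind": kind}
    if kind == "profile" or kind == "fwhm":
        prof = metric_profile(
            image, request["axis"], request["through"],
            request.get("half_width", 0),
        )
        if kind == "fwhm":
            out["fwhm_mm"] = metric_fwhm(prof)
        else:
            out["coordinates_mm"] = prof.coordinates.tolist()
            out["values"] = prof.values.tolist()
        out["axis"] = request["axis"]
    elif kind == "peaks":
        prof = metric_profile(
            image, request["axis"], request["through"],
            request.get("half_width", 0),
        )
        n, ratio, pos = resolvable_peaks(prof, request.get("expected", 2))
        out.update(
            n_peaks=n,
            peak_to_valley=ratio,
            positions_mm=pos.tolist(),
        )
    elif kind == "uniformity":
        region = request.get("region")
        region_slices = (
            tuple(slice(a, b) for a, b in region) if region is not None else None
        )
        iu, cv = uniformity_metrics(image, region_slices)
        out.update(integral_uniformity=iu, coefficient_of_variation=cv)
    else:
        raise ExperimentError(f"unknown metric kind {kind!r}")
    return out


def run_experiment(spec: ExperimentSpec, outdir) -> dict:
    """Execute a spec end to end; returns the result bundle as a dict.

    Deterministic given the spec seed.  Writes events, the reconstructed
    volume, a metrics report and a provenance record into ``outdir``.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system = load_preset(spec.preset)
    rng = np.random.default_rng(spec.seed)
    bundle: dict = {"name": spec.name, "preset": spec.preset, "seed": spec.seed}

    if spec.scan is not None:
        points = np.asarray(spec.scan["points"], float)
        df = sensitivity_curve(system, points, int(spec.scan["n_decays"]), rng)
        scan_path = outdir / "sensitivity.csv"
        df.to_csv(scan_path, index=False, float_format="%.6g")
        bundle["sensitivity_csv"] = str(scan_path)
        bundle["sensitivity"] = df.to_dict(orient="records")
    else:
        phantom = build_phantom(spec.phantom)
        config = AcquisitionConfig(duration=spec.duration, seed=spec.seed)
        events = simulate(phantom, system, config, rng)
        ev_path = outdir / "events.csv"
        write_events(events, ev_path)
        model = ListModeOSEM(events, system, options=ReconOptions(**spec.recon))
        result = model.fit()
        vol_path = outdir / "volume.mhd"
        write_volume(result.image, vol_path)
        reports = [_run_metric(m, result.image) for m in spec.metrics]
        (outdir / "metrics.json").write_text(json.dumps(reports, indent=2))
        bundle.update(
            events_csv=str(ev_path),
            volume=str(vol_path),
            n_events=len(events),
            n_events_used=result.n_events_used,
            metrics=reports,
            summary=result.summary(),
        )

    provenance = {
        "experiment": spec.to_dict(),
        "geometry_hash": system.geometry_hash(),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return bundle
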