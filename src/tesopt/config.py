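"""YAML run configuration: one file drives the whole CLI pipeline.

A config describes the head model, the target, the constraint set, and the
optimizer/sweep settings.  Lengths in the file are millimetres and currents
milliamps (the natural units at this scale); everything is converted to SI
on load.

Example
-------
```yaml
head:
  kind: sphere
  radii_mm: [80, 81, 86, 92]
  target_edge_length_mm: 14
  n_electrodes: 64
  seed: 0
target:
  roi_center_mm: [0, 0, 70]
  roi_radius_mm: 8
  orientation: normal
constraints:
  i_max_mA: 2.0
optimize:
  method: dirmax
  nonroi_mode: integral
  alpha: 1.0e-9
sweep:
  nonroi_mode: integral
  n_points: 25
workdir: out
```
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fem import FEMSystem, TransferMatrix, assemble_fem, build_transfer_matrix
from .mesh import (
    BRAIN,
    ConductivityMap,
    ElectrodeSet,
    HeadMesh,
    TISSUE_NAMES,
    generate_sphere_head,
    read_electrodes_csv,
    read_gmsh,
    read_mesh_text,
)
from .problem import (
    ConstraintSet,
    TargetSpec,
    VolumeWeights,
    build_volume_weights,
    define_roi_orientation,
)

__all__ = ["RunConfig", "load_config", "build_head", "build_forward", "build_problem"]

_METHODS = (
    "wls",
    "scaled-wls",
    "constrained-wls",
    "dirmax",
    "reciprocity",
    "reciprocity-limited",
)


@dataclass
class HeadConfig:
    kind: str = "sphere"
    radii_mm: tuple[float, ...] = (80.0, 81.0, 86.0, 92.0)
    conductivities: dict[str, float] | None = None
    target_edge_length_mm: float = 12.0
    n_electrodes: int = 64
    seed: int = 0
    mesh_file: str | None = None
    electrodes_file: str | None = None


@dataclass
class TargetConfig:
    roi_center_mm: tuple[float, float, float] = (0.0, 0.0, 70.0)
    roi_radius_mm: float = 8.0
    orientation: str | tuple[float, float, float] = "normal"
    weight_mode: str = "exact"


@dataclass
class ConstraintConfig:
    i_max_mA: float = 2.0
    per_electrode_mA: float | None = None


@dataclass
class OptimizeConfig:
    method: str = "dirmax"
    nonroi_mode: str = "integral"
    alpha: float | None = None
    k: float | None = None
    source_limit_mA: float | None = None
    sink_limit_mA: float | None = None


@dataclass
class SweepConfig:
    nonroi_mode: str = "integral"
    n_points: int = 25
    alpha_min: float | None = None
    alpha_max: float | None = None


@dataclass
class RunConfig:
    head: HeadConfig = field(default_factory=HeadConfig)
    target: TargetConfig = field(default_factory=TargetConfig)
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    optimize: OptimizeConfig = field(default_factory=OptimizeConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    workdir: str = "out"

    def __post_init__(self) -> None:
        if self.optimize.method not in _METHODS:
            raise ValueError(
                f"unknown method {self.optimize.method!r}; choose from {_METHODS}"
            )
        for mode in (self.optimize.nonroi_mode, self.sweep.nonroi_mode):
            if mode not in ("integral", "elementwise"):
                raise ValueError(f"nonroi_mode must be integral/elementwise, got {mode!r}")
        if not self.constraints.i_max_mA > 0:
            raise ValueError("constraints.i_max_mA must be positive")

    def constraint_set(self, alpha: float | None = None) -> ConstraintSet:
        i_max = self.constraints.i_max_mA * 1e-3
        box = self.constraints.per_electrode_mA
        kwargs: dict = {}
        if box is not None:
            kwargs["i_min_vec"] = np.full(self.head.n_electrodes, -box * 1e-3)
            kwargs["i_max_vec"] = np.full(self.head.n_electrodes, box * 1e-3)
        if alpha is None:
            alpha = self.optimize.alpha
        if alpha is not None:
            if self.optimize.nonroi_mode == "integral":
                kwargs["alpha_I"] = alpha
            else:
                kwargs["alpha_E"] = alpha
        return ConstraintSet(i_max=i_max, **kwargs)


def _as_dataclass(cls, data: dict | None):
    if data is None:
        return cls()
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = dict(data)
    for key in ("radii_mm", "roi_center_mm"):
        if key in coerced and coerced[key] is not None:
            coerced[key] = tuple(float(v) for v in coerced[key])
    if isinstance(coerced.get("orientation"), (list, tuple)):
        coerced["orientation"] = tuple(float(v) for v in coerced["orientation"])
    return cls(**coerced)


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = {"head", "target", "constraints", "optimize", "sweep", "workdir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        head=_as_dataclass(HeadConfig, raw.get("head")),
        target=_as_dataclass(TargetConfig, raw.get("target")),
        constraints=_as_dataclass(ConstraintConfig, raw.get("constraints")),
        optimize=_as_dataclass(OptimizeConfig, raw.get("optimize")),
        sweep=_as_dataclass(SweepConfig, raw.get("sweep")),
        workdir=str(raw.get("workdir", "out")),
    )


def _conductivity_map(cfg: HeadConfig) -> ConductivityMap:
    if not cfg.conductivities:
        return ConductivityMap()
    by_name = {name.lower(): label for label, name in TISSUE_NAMES.items()}
    values = {}
    for name, sigma in cfg.conductivities.items():
        if name.lower() not in by_name:
            raise ValueError(f"unknown tissue {name!r}; expected {sorted(by_name)}")
        values[by_name[name.lower()]] = float(sigma)
    base = ConductivityMap()
    base.values.update(values)
    return base


def build_head(cfg: RunConfig, base_dir=".") -> tuple[HeadMesh, ElectrodeSet, ConductivityMap]:
    """Generate (kind: sphere) or load (kind: files) the head model."""
    h = cfg.head
    sigma = _conductivity_map(h)
    if h.kind == "sphere":
        mesh, electrodes = generate_sphere_head(
            radii=tuple(r * 1e-3 for r in h.radii_mm),
            target_edge_length=h.target_edge_length_mm * 1e-3,
            n_electrodes=h.n_electrodes,
            seed=h.seed,
        )
        return mesh, electrodes, sigma
    if h.kind == "files":
        if not h.mesh_file or not h.electrodes_file:
            raise ValueError("head.kind 'files' needs mesh_file and electrodes_file")
        mesh_path = Path(base_dir) / h.mesh_file
        if mesh_path.suffix == ".msh":
            mesh = read_gmsh(mesh_path)
        else:
            mesh = read_mesh_text(mesh_path)
        electrodes = read_electrodes_csv(Path(base_dir) / h.electrodes_file, mesh)
        return mesh, electrodes, sigma
    raise ValueError(f"head.kind must be 'sphere' or 'files', got {h.kind!r}")


def build_forward(
    mesh: HeadMesh, electrodes: ElectrodeSet, sigma: ConductivityMap
) -> tuple[FEMSystem, TransferMatrix]:
    system = assemble_fem(mesh, sigma)
    brain_elements = mesh.elements_with_label(BRAIN)
    return system, build_transfer_matrix(system, electrodes, brain_elements)


def build_problem(
    cfg: RunConfig, mesh: HeadMesh, T: TransferMatrix
) -> tuple[TargetSpec, VolumeWeights]:
    """ROI = brain elements whose centroid lies in the configured ball."""
    t = cfg.target
    center = np.asarray(t.roi_center_mm, dtype=float) * 1e-3
    radius = t.roi_radius_mm * 1e-3
    centroids = mesh.centroids()[T.element_index]
    inside = np.linalg.norm(centroids - center, axis=1) <= radius
    roi_elements = T.element_index[inside]
    if roi_elements.size == 0:
        raise ValueError("ROI ball contains no brain elements; enlarge roi_radius_mm")
    d_user = None
    if t.orientation != "normal":
        d_user = np.asarray(t.orientation, dtype=float)
    target = define_roi_orientation(mesh, T, roi_elements, d_user=d_user)
    weights = build_volume_weights(mesh, T, target.roi_local, mode=t.weight_mode)
    return target, weights
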