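"""Regular-grid containers: greyscale voxel volumes and tissue/implant label maps.

Conventions
-----------
* Units are mm throughout; greyvalues are HU-like scalars.
* Arrays are indexed ``values[ix, iy, iz]``; the voxel center of index
  ``(ix, iy, iz)`` sits at ``origin + (index + 0.5) * spacing``.
* The bone axis is +z with the distal end at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical region labels shared across the pipeline.
BACKGROUND = 0
CORTICAL = 1
TRABECULAR = 2
CALLUS = 3
NAIL = 4
PLATE = 5
SCREW = 6

REGION_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    CORTICAL: "cortical",
    TRABECULAR: "trabecular",
    CALLUS: "callus",
    NAIL: "nail",
    PLATE: "plate",
    SCREW: "screw",
}

#: Regions treated as metallic implant components.
IMPLANT_REGIONS = frozenset({"nail", "plate", "screw"})
#: Regions whose stiffness is mapped from greyvalues rather than fixed.
BONE_REGIONS = frozenset({"cortical", "trabecular"})


def _as_triple(x) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    return arr


@dataclass
class VoxelVolume:
    """A scalar greyvalue field on a regular grid."""

    values: np.ndarray  # (nx, ny, nz) float
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if min(self.values.shape) < 1:
            raise ValueError("dims must be >= 1 per axis")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("greyvalues must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinate vectors."""
        return tuple(
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def same_grid(self, other: "VoxelVolume | LabelMap") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMap:
    """Integer region labels on a regular grid, congruent with a VoxelVolume."""

    labels: np.ndarray  # (nx, ny, nz) int
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    legend: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def same_grid(self, other: "VoxelVolume | LabelMap") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def region_id(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(f"region {name!r} not in legend")

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.labels == self.region_id(name)))

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))
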