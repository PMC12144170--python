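"""Greyvalue-to-stiffness mapping and per-element material assignment.

Bone elements get their Young's modulus from the CT greyvalue of their
source voxel through a density calibration (rho = a + b*HU, clamped below)
and an apparent-density power law (E = c * rho**d). Implant and callus
elements get fixed region properties: early soft callus is orders of
magnitude softer than bone, metallic implants orders of magnitude stiffer.

Units: mm-N-MPa; density in g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .grids import BONE_REGIONS
from .meshing import TetMesh
from .grids import VoxelVolume, LabelMap


@dataclass
class DensityCalibration:
    """HU -> apparent density -> Young's modulus calibration.

    rho = max(a + b * HU, rho_min)   [g/cm^3]
    E   = c * rho ** d               [MPa]
    """

    a: float = 1.0  # g/cm^3 at 0 HU (water-equivalent)
    b: float = 0.001  # g/cm^3 per HU
    c: float = 6850.0  # MPa * (g/cm^3)^-d
    d: float = 1.49
    rho_min: float = 0.05  # clamp floor, g/cm^3

    def validate(self) -> None:
        if not (self.b > 0 and self.c > 0 and self.d > 0 and self.rho_min > 0):
            raise ValueError("calibration requires b, c, d, rho_min > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegionMaterial:
    E: float | None  # MPa; None = CT-derived via the calibration
    nu: float


#: Default fixed region properties. Callus stiffness follows the soft-callus
#: convention of the tissue-differentiation literature; implants are a
#: Ti-6Al-4V-class alloy. Bone regions are CT-derived (E is None).
DEFAULT_REGION_TABLE: dict[str, RegionMaterial] = {
    "cortical": RegionMaterial(None, 0.3),
    "trabecular": RegionMaterial(None, 0.3),
    "callus": RegionMaterial(3.0, 0.4),
    "nail": RegionMaterial(110_000.0, 0.3),
    "plate": RegionMaterial(110_000.0, 0.3),
    "screw": RegionMaterial(110_000.0, 0.3),
}

#: Optional stainless-steel implant alternative.
STEEL = RegionMaterial(200_000.0, 0.3)


@dataclass
class MaterialTable:
    """Per-element isotropic elastic constants with provenance."""

    E: np.ndarray  # (ne,) MPa
    nu: np.ndarray  # (ne,)
    provenance: np.ndarray  # (ne,) "ct" | "fixed"
    calibration: DensityCalibration | None = None
    region_table: dict[str, RegionMaterial] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.E <= 0):
            raise ValueError("every element needs E > 0")
        if np.any(self.nu <= -1) or np.any(self.nu >= 0.5):
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")


def hu_to_modulus(hu, calib: DensityCalibration | None = None):
    """Map greyvalue(s) to Young's modulus in MPa (nondecreasing in HU)."""
    calib = calib or DensityCalibration()
    calib.validate()
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("greyvalue must be finite")
    rho = np.maximum(calib.a + calib.b * hu, calib.rho_min)
    E = calib.c * rho**calib.d
    return E if E.ndim else float(E)


def assign_materials(
    mesh: TetMesh,
    volume: VoxelVolume,
    labels: LabelMap,
    region_table: dict[str, RegionMaterial] | None = None,
    calib: DensityCalibration | None = None,
) -> MaterialTable:
    """Assign (E, nu) to every element exactly once.

    Bone regions map the source voxel's greyvalue through the calibration;
    all other regions use the fixed values from ``region_table``. On the
    6-tet voxel mesh every element of one voxel shares the same source
    voxel, hence identical properties.
    """
    region_table = region_table if region_table is not None else DEFAULT_REGION_TABLE
    calib = calib or DensityCalibration()
    calib.validate()
    if mesh.element_voxel is None:
        raise ValueError("mesh lacks source-voxel provenance; cannot map greyvalues")
    if not volume.same_grid(labels):
        raise ValueError("volume and label map are on different grids")

    names = mesh.element_region_names()
    ne = mesh.n_elements
    E = np.zeros(ne)
    nu = np.zeros(ne)
    prov = np.empty(ne, dtype=object)
    hu_flat = volume.values.ravel()

    for name in np.unique(names):
        sel = names == name
        if name not in region_table:
            raise ValueError(f"region {name!r} missing from the material table")
        mat = region_table[name]
        nu[sel] = mat.nu
        if name in BONE_REGIONS and mat.E is None:
            E[sel] = hu_to_modulus(hu_flat[mesh.element_voxel[sel]], calib)
            prov[sel] = "ct"
        else:
            if mat.E is None:
                raise ValueError(f"region {name!r} has no fixed modulus")
            E[sel] = mat.E
            prov[sel] = "fixed"
    return MaterialTable(E=E, nu=nu, provenance=prov,
                         calibration=calib, region_table=dict(region_table))
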