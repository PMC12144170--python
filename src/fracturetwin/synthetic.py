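"""Parametric synthetic bone-implant constructs and wrist scenes.

These stand in for patient CT data and surgical variants: an idealized long
bone (cortical shell, trabecular interior, transverse fracture gap filled
with soft callus) instrumented with an intramedullary nail of configurable
diameter, an optional lateral augmentative plate and optional transverse
screws. Geometry is evaluated analytically at voxel centers (no
anti-aliasing), so every construct carries exact ground-truth labels.

Greyvalues are HU-like: each region has a nominal level plus i.i.d. Gaussian
noise with an explicit seed, so identical spec + seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh

from .grids import (
    BACKGROUND,
    CALLUS,
    CORTICAL,
    NAIL,
    PLATE,
    REGION_NAMES,
    SCREW,
    TRABECULAR,
    LabelMap,
    VoxelVolume,
)

#: Default HU-like greyvalue per region: well separated so that threshold
#: segmentation can recover the ground truth; ordering mimics clinical CT.
DEFAULT_GREYVALUES: dict[str, float] = {
    "background": -1000.0,
    "callus": 50.0,
    "trabecular": 300.0,
    "cortical": 1500.0,
    "nail": 3000.0,
    "plate": 3000.0,
    "screw": 3000.0,
}


@dataclass
class ScrewSpec:
    """A transverse screw: a cylinder through the bone axis."""

    axial_position: float  # mm along the bone axis (z)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    radius: float = 2.0  # mm
    length: float = 30.0  # mm


@dataclass
class PlateSpec:
    """A partial cylindrical shell flush with the periosteal surface."""

    length: float = 80.0  # mm, centered on the fracture gap
    width: float = 12.0  # mm of arc along the circumference
    thickness: float = 4.0  # mm radial
    angular_position: float = 0.0  # deg, 0 = +x direction
    plate_screws: list[ScrewSpec] = field(default_factory=list)


@dataclass
class ConstructSpec:
    """Parametric description of one bone-implant treatment variant.

    All lengths in mm. ``nail_radius = 0`` means no nail. The bone axis is
    +z with the distal end at z = 0; the fracture gap is a transverse slab
    of width ``gap_width`` centered at ``gap_position`` and filled with
    soft callus.
    """

    bone_length: float = 200.0
    outer_radius: float = 12.0
    cortical_thickness: float = 4.0
    canal_radius: float = 6.0
    gap_position: float = 100.0
    gap_width: float = 4.0
    nail_radius: float = 4.0
    nail_length: float = 180.0
    screws: list[ScrewSpec] = field(default_factory=list)
    plate: PlateSpec | None = None
    tissue_greyvalues: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GREYVALUES)
    )
    noise_sd: float = 0.0
    voxel_spacing: float = 1.0
    seed: int = 0
    margin: float = 2.0  # empty border around the construct, mm

    def validate(self) -> None:
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.gap_width < self.bone_length):
            raise ValueError("gap_width must satisfy 0 < gap_width < bone_length")
        if self.canal_radius > self.outer_radius - self.cortical_thickness:
            raise ValueError(
                "canal_radius must satisfy canal_radius <= outer_radius - cortical_thickness"
            )
        if not (0 <= self.nail_radius <= self.canal_radius):
            raise ValueError("nail_radius must satisfy 0 <= nail_radius <= canal_radius")
        if self.cortical_thickness <= 0 or self.cortical_thickness >= self.outer_radius:
            raise ValueError("cortical_thickness must lie in (0, outer_radius)")
        missing = [
            name
            for name in ("background", "cortical", "trabecular", "callus")
            if name not in self.tissue_greyvalues
        ]
        if missing:
            raise ValueError(f"tissue_greyvalues missing regions {missing}")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_construct(spec: ConstructSpec) -> tuple[VoxelVolume, LabelMap]:
    """Rasterize a construct spec into a greyscale volume and ground-truth labels.

    Labels are geometric memberships of voxel centers with precedence
    implant > callus > cortical > trabecular > background. Greyvalue =
    tissue level of the label + Gaussian(0, noise_sd) drawn from the spec's
    seed, so the output is a deterministic function of the spec.
    """
    spec.validate()
    h = spec.voxel_spacing
    half_xy = spec.outer_radius + (spec.plate.thickness if spec.plate else 0.0) + spec.margin
    # Screws may protrude beyond the cortex.
    for s in _all_screws(spec):
        half_xy = max(half_xy, s.length / 2.0 + spec.margin)
    nx = ny = int(math.ceil(2 * half_xy / h))
    nz = int(math.ceil((spec.bone_length + 2 * spec.margin) / h))
    origin = np.array([-nx * h / 2.0, -ny * h / 2.0, -spec.margin])

    xs = origin[0] + (np.arange(nx) + 0.5) * h
    ys = origin[1] + (np.arange(ny) + 0.5) * h
    zs = origin[2] + (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    R = np.hypot(X, Y)

    labels = np.full((nx, ny, nz), BACKGROUND, dtype=np.int16)

    in_shaft = (Z >= 0.0) & (Z < spec.bone_length)
    inner_cortex = spec.outer_radius - spec.cortical_thickness
    labels[in_shaft & (R <= inner_cortex)] = TRABECULAR
    labels[in_shaft & (R > inner_cortex) & (R <= spec.outer_radius)] = CORTICAL

    gap_lo = spec.gap_position - spec.gap_width / 2.0
    gap_hi = spec.gap_position + spec.gap_width / 2.0
    in_gap = (Z >= gap_lo) & (Z < gap_hi) & (R <= spec.outer_radius)
    labels[in_gap] = CALLUS

    if spec.nail_radius > 0:
        nail_lo = (spec.bone_length - spec.nail_length) / 2.0
        nail_hi = (spec.bone_length + spec.nail_length) / 2.0
        in_nail = (R <= spec.nail_radius) & (Z >= nail_lo) & (Z < nail_hi)
        labels[in_nail] = NAIL

    if spec.plate is not None:
        p = spec.plate
        ang0 = math.radians(p.angular_position)
        # Width measured as arc length on the periosteal surface.
        half_ang = p.width / (2.0 * spec.outer_radius)
        ang = np.arctan2(Y, X)
        dang = np.abs((ang - ang0 + np.pi) % (2 * np.pi) - np.pi)
        in_plate = (
            (R > spec.outer_radius)
            & (R <= spec.outer_radius + p.thickness)
            & (dang <= half_ang)
            & (Z >= spec.gap_position - p.length / 2.0)
            & (Z < spec.gap_position + p.length / 2.0)
        )
        labels[in_plate] = PLATE
        for s in p.plate_screws:
            labels[_screw_mask(s, X, Y, Z)] = SCREW

    for s in spec.screws:
        labels[_screw_mask(s, X, Y, Z)] = SCREW

    grey = np.empty(labels.shape, dtype=float)
    for rid, name in REGION_NAMES.items():
        mask = labels == rid
        if np.any(mask):
            if name not in spec.tissue_greyvalues:
                raise ValueError(f"tissue_greyvalues missing region {name!r}")
            grey[mask] = spec.tissue_greyvalues[name]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)

    volume = VoxelVolume(values=grey, spacing=h, origin=origin)
    label_map = LabelMap(labels=labels, spacing=h, origin=origin)
    return volume, label_map


def _all_screws(spec: ConstructSpec) -> list[ScrewSpec]:
    screws = list(spec.screws)
    if spec.plate is not None:
        screws.extend(spec.plate.plate_screws)
    return screws


def _screw_mask(s: ScrewSpec, X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    axis = np.asarray(s.axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("screw axis must be nonzero")
    axis = axis / nrm
    px, py, pz = X, Y, Z - s.axial_position
    t = px * axis[0] + py * axis[1] + pz * axis[2]
    d2 = (px - t * axis[0]) ** 2 + (py - t * axis[1]) ** 2 + (pz - t * axis[2]) ** 2
    return (d2 <= s.radius**2) & (np.abs(t) <= s.length / 2.0)


# ---------------------------------------------------------------------------
# Wrist range-of-motion scene (radius/ulna analogue + rigid carpal unit)
# ---------------------------------------------------------------------------


@dataclass
class ProminenceSpec:
    """A bony prominence on the articular cup, modeled as an inward bump."""

    angular_position: float = 25.0  # deg in the deviation (x-z) plane
    angular_half_width: float = 5.0  # deg
    height: float = 2.0  # mm, inward radial protrusion


@dataclass
class WristParams:
    """Geometry of the idealized wrist scene.

    The distal radius articular surface is a concave spherical cup of radius
    ``cup_radius`` centered at the rotation center; the proximal carpal row
    (scaphoid + lunate + triquetrum as one rigid unit) is a sphere of radius
    ``carpal_radius`` whose center sits ``center_offset`` mm from the
    rotation center along -z. The radial clearance at neutral is
    ``cup_radius - center_offset - carpal_radius``.
    """

    cup_radius: float = 15.0
    carpal_radius: float = 6.0
    center_offset: float = 8.0
    cup_extent_deg: float = 70.0  # polar extent of the cup patch from -z
    prominence: ProminenceSpec | None = None
    cup_resolution: int = 64  # azimuthal facets; polar rings scale with extent
    carpal_subdivisions: int = 3
    ulna_offset: tuple[float, float, float] = (-30.0, 0.0, 0.0)

    @property
    def clearance(self) -> float:
        return self.cup_radius - self.center_offset - self.carpal_radius

    def validate(self) -> None:
        if self.carpal_radius + self.center_offset >= self.cup_radius:
            raise ValueError(
                "carpal sphere does not clear the cup: require "
                "carpal_radius + center_offset < cup_radius"
            )
        if self.prominence is not None and self.prominence.height < 0:
            raise ValueError("prominence height must be >= 0")


@dataclass
class RomScene:
    """Triangulated surfaces and rotation geometry for a ROM sweep."""

    radius_mesh: trimesh.Trimesh
    ulna_mesh: trimesh.Trimesh
    carpal_mesh: trimesh.Trimesh
    rotation_center: np.ndarray
    rotation_axis: np.ndarray
    radius_anatomical_axis: np.ndarray
    prominence: ProminenceSpec | None = None
    watertight: dict[str, bool] = field(default_factory=dict)


def _cup_mesh(params: WristParams) -> trimesh.Trimesh:
    """Spherical cup patch opening toward -z, with optional inward prominence."""
    n_az = params.cup_resolution
    extent = math.radians(params.cup_extent_deg)
    n_pol = max(8, int(round(n_az * extent / (2 * math.pi) * 2)))
    pol = np.linspace(0.0, extent, n_pol + 1)  # polar angle from -z
    az = np.linspace(0.0, 2 * math.pi, n_az, endpoint=False)

    P, A = np.meshgrid(pol[1:], az, indexing="ij")
    # Direction on the unit sphere: polar from -z, azimuth from +x.
    dirs = np.stack(
        [np.sin(P) * np.cos(A), np.sin(P) * np.sin(A), -np.cos(P)], axis=-1
    )
    radii = np.full(P.shape, params.cup_radius)
    if params.prominence is not None:
        pr = params.prominence
        bump_dir = np.array(
            [
                math.sin(math.radians(pr.angular_position)),
                0.0,
                -math.cos(math.radians(pr.angular_position)),
            ]
        )
        gc = np.arccos(np.clip(dirs @ bump_dir, -1.0, 1.0))  # great-circle dist
        half = math.radians(pr.angular_half_width)
        w = np.clip(1.0 - (gc / half) ** 2, 0.0, None)  # quadratic bump profile
        radii = radii - pr.height * w
    ring_verts = (radii[..., None] * dirs).reshape(-1, 3)
    pole = np.array([[0.0, 0.0, -(params.cup_radius - _pole_bump(params))]])
    vertices = np.vstack([pole, ring_verts])

    faces = []
    # pole fan to first ring
    for j in range(n_az):
        faces.append([0, 1 + j, 1 + (j + 1) % n_az])
    # quad strips between rings
    for i in range(n_pol - 1):
        base0 = 1 + i * n_az
        base1 = 1 + (i + 1) * n_az
        for j in range(n_az):
            jn = (j + 1) % n_az
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    return mesh


def _pole_bump(params: WristParams) -> float:
    if params.prominence is None:
        return 0.0
    pr = params.prominence
    gc = math.radians(pr.angular_position)
    half = math.radians(pr.angular_half_width)
    return pr.height * max(0.0, 1.0 - (gc / half) ** 2)


def generate_wrist_scene(params: WristParams | None = None) -> RomScene:
    """Build the synthetic wrist scene for impingement analysis.

    Without a prominence the carpal sphere clears the cup at every rotation
    angle (the neutral clearance is rotation-invariant by construction);
    with a prominence taller than the clearance, contact occurs near the
    prominence's angular position.
    """
    params = params or WristParams()
    params.validate()
    cup = _cup_mesh(params)
    carpal = trimesh.creation.icosphere(
        subdivisions=params.carpal_subdivisions, radius=params.carpal_radius
    )
    carpal.apply_translation([0.0, 0.0, -params.center_offset])
    ulna = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    ulna.apply_translation(np.asarray(params.ulna_offset, dtype=float))
    return RomScene(
        radius_mesh=cup,
        ulna_mesh=ulna,
        carpal_mesh=carpal,
        rotation_center=np.zeros(3),
        # -y axis: positive sweep angles move the carpal unit toward +x,
        # the direction in which the prominence (if any) sits.
        rotation_axis=np.array([0.0, -1.0, 0.0]),
        radius_anatomical_axis=np.array([0.0, 0.0, 1.0]),
        prominence=params.prominence,
        watertight={
            "radius": bool(cup.is_watertight),
            "ulna": bool(ulna.is_watertight),
            "carpal": bool(carpal.is_watertight),
        },
    )
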