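"""End-to-end treatment-comparison cases.

Each case pairs a baseline construct with a revision that differs only in
the intended treatment parameter(s), runs the full chain
generate -> segment -> mesh -> materials -> solve -> evaluate, and emits a
:class:`~fracturetwin.reporting.ComparisonReport`:

* ``usecase1_nail_diameter`` — exchange an 8 mm intramedullary nail for an
  11 mm one (tibia analogue, bending-dominant peak load);
* ``usecase2_plate_humerus_analogue`` — add an augmentative plate to a
  nailed humerus analogue;
* ``usecase3_plate_femur_analogue`` — add an augmentative plate to a
  nailed femur analogue;
* ``usecase4_screw_torsion`` — add a strain-reduction screw under a
  torsion-dominant load (an equilibrated force couple);
* ``usecase5_wrist`` — rigid range-of-motion sweep of a malaligned wrist
  (prominence impinging) vs. a realigned one.

Meshing uses the construct's label map directly (the pipeline's label-map
entry point): thresholding alone cannot tell metallic components apart, so
the segmentation stage is run and its agreement with the merged ground
truth recorded in provenance, mirroring how clinical masks separate
implant components manually.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import LabelMap, VoxelVolume
from .kinematics import RomResult, sweep_contact
from .materials import (
    DEFAULT_REGION_TABLE,
    DensityCalibration,
    assign_materials,
)
from .mechanobiology import (
    HealingZoneConfig,
    HealingWindowResult,
    evaluate_healing_window,
)
from .meshing import TetMesh, define_cuboid_nodeset, voxels_to_tetmesh
from .reporting import ComparisonReport, compare_treatments
from .segmentation import ThresholdTable, misclassified_fraction, threshold_segment
from .solver import DirichletBC, FESolution, LoadCase, NeumannBC, assemble_and_solve
from .synthetic import (
    ConstructSpec,
    PlateSpec,
    ProminenceSpec,
    ScrewSpec,
    WristParams,
    generate_construct,
    generate_wrist_scene,
)

CASE_NAMES = (
    "usecase1_nail_diameter",
    "usecase2_plate_humerus_analogue",
    "usecase3_plate_femur_analogue",
    "usecase4_screw_torsion",
    "usecase5_wrist",
)

logger = logging.getLogger("fracturetwin")

#: Thickness of the distal/proximal cuboid reference regions, mm.
END_SLAB = 5.0


@dataclass
class LoadSpec:
    """Static peak-load stand-in for musculoskeletal-simulation output."""

    axial_N: float = -1500.0  # compressive along -z, applied proximally
    transverse_N: float = 150.0  # +x shear producing bending at the gap
    torsion_couple_N: float = 0.0  # force couple magnitude about the bone axis

    def to_dict(self) -> dict:
        return {
            "axial_N": self.axial_N,
            "transverse_N": self.transverse_N,
            "torsion_couple_N": self.torsion_couple_N,
        }


@dataclass
class CaseDefinition:
    name: str
    baseline: ConstructSpec | WristParams
    revision: ConstructSpec | WristParams
    load: LoadSpec = field(default_factory=LoadSpec)
    zones: HealingZoneConfig = field(default_factory=HealingZoneConfig)
    calibration: DensityCalibration = field(default_factory=DensityCalibration)
    seed: int = 0
    element_order: int = 1
    rom_range: tuple[float, float] = (-40.0, 40.0)
    rom_step: float = 0.5


@dataclass
class VariantArtifacts:
    volume: VoxelVolume
    labels: LabelMap
    mesh: TetMesh
    solution: FESolution
    healing: HealingWindowResult
    segmentation_mismatch: float


@dataclass
class CaseResult:
    definition: CaseDefinition
    report: ComparisonReport | None = None
    baseline: VariantArtifacts | None = None
    revised: VariantArtifacts | None = None
    rom_baseline: RomResult | None = None
    rom_revised: RomResult | None = None


# ---------------------------------------------------------------------------
# Shipped case definitions
# ---------------------------------------------------------------------------


def build_case(name: str, seed: int = 0, desk_scale: bool = True) -> CaseDefinition:
    """Construct a shipped case definition.

    ``desk_scale=True`` gives the default construct scale (bone length
    200 mm at 1 mm voxels, tens of thousands of elements, minutes on one
    CPU). ``desk_scale=False`` gives a geometrically similar miniature
    (bone length 60 mm) that runs in seconds, used by the test suite.
    """
    if name not in CASE_NAMES:
        raise ValueError(f"unknown case {name!r}; choose one of {CASE_NAMES}")
    if name == "usecase5_wrist":
        prominent = WristParams(prominence=ProminenceSpec())
        realigned = WristParams(prominence=None)
        return CaseDefinition(name=name, baseline=prominent, revision=realigned,
                              seed=seed)

    if desk_scale:
        base = ConstructSpec(seed=seed)
        load = LoadSpec()
    else:
        base = ConstructSpec(
            bone_length=60.0, outer_radius=6.0, cortical_thickness=2.0,
            canal_radius=3.0, gap_position=30.0, gap_width=3.0,
            nail_radius=2.0, nail_length=50.0, seed=seed,
        )
        load = LoadSpec(axial_N=-400.0, transverse_N=150.0)

    if name == "usecase1_nail_diameter":
        baseline = base
        revision = copy.deepcopy(base)
        # 8 mm -> 11 mm nail at desk scale; same diameter ratio in miniature
        revision.nail_radius = base.nail_radius * 11.0 / 8.0
    elif name in ("usecase2_plate_humerus_analogue", "usecase3_plate_femur_analogue"):
        if desk_scale and name == "usecase2_plate_humerus_analogue":
            base = ConstructSpec(
                bone_length=180.0, outer_radius=10.0, cortical_thickness=3.5,
                canal_radius=5.0, gap_position=90.0, gap_width=4.0,
                nail_radius=3.5, nail_length=160.0, seed=seed,
            )
        elif desk_scale:
            base = ConstructSpec(
                bone_length=220.0, outer_radius=14.0, cortical_thickness=5.0,
                canal_radius=7.0, gap_position=110.0, gap_width=4.0,
                nail_radius=4.5, nail_length=200.0, seed=seed,
            )
        baseline = base
        revision = copy.deepcopy(base)
        plate_len = min(0.5 * base.bone_length, 80.0)
        revision.plate = PlateSpec(
            length=plate_len,
            width=max(4.0, base.outer_radius),
            thickness=max(2.0, base.outer_radius / 3.0),
            angular_position=0.0,
        )
    elif name == "usecase4_screw_torsion":
        baseline = base
        revision = copy.deepcopy(base)
        screw_len = 2.0 * base.outer_radius + 4.0
        revision.screws = [
            ScrewSpec(
                axial_position=base.gap_position + base.gap_width / 2.0 + 3.0,
                axis=(1.0, 0.0, 0.0),
                radius=max(1.0, base.outer_radius / 8.0),
                length=screw_len,
            )
        ]
        load = LoadSpec(
            axial_N=load.axial_N / 10.0,
            transverse_N=0.0,
            torsion_couple_N=2000.0 if desk_scale else 400.0,
        )
    return CaseDefinition(name=name, baseline=baseline, revision=revision,
                          load=load, seed=seed)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def make_load_case(spec: ConstructSpec, load: LoadSpec) -> LoadCase:
    dirichlet = [DirichletBC("DISTAL_FIX", 0.0, 0.0, 0.0)]
    neumann = []
    if load.axial_N or load.transverse_N:
        neumann.append(
            NeumannBC("PROXIMAL_LOAD", (load.transverse_N, 0.0, load.axial_N))
        )
    if load.torsion_couple_N:
        neumann.append(NeumannBC("PROXIMAL_XPOS", (0.0, load.torsion_couple_N, 0.0)))
        neumann.append(NeumannBC("PROXIMAL_XNEG", (0.0, -load.torsion_couple_N, 0.0)))
    return LoadCase(name="static_peak", dirichlet=dirichlet, neumann=neumann)


def add_end_nodesets(mesh: TetMesh, spec: ConstructSpec,
                     torsion: bool = False) -> TetMesh:
    big = 10.0 * (spec.outer_radius + 10.0)
    L = spec.bone_length
    define_cuboid_nodeset(
        mesh, "DISTAL_FIX", ((-big, big), (-big, big), (-big, END_SLAB))
    )
    define_cuboid_nodeset(
        mesh, "PROXIMAL_LOAD", ((-big, big), (-big, big), (L - END_SLAB, L + big))
    )
    if torsion:
        h = float(mesh.spacing[0]) if mesh.spacing is not None else 1.0
        define_cuboid_nodeset(
            mesh, "PROXIMAL_XPOS", ((h / 4.0, big), (-big, big), (L - END_SLAB, L + big))
        )
        define_cuboid_nodeset(
            mesh, "PROXIMAL_XNEG", ((-big, -h / 4.0), (-big, big), (L - END_SLAB, L + big))
        )
    return mesh


def run_variant(spec: ConstructSpec, load: LoadSpec,
                zones: HealingZoneConfig, calib: DensityCalibration,
                element_order: int = 1) -> VariantArtifacts:
    t0 = time.time()
    volume, labels = generate_construct(spec)
    logger.info("generate: %d voxels in %.2f s",
                int(np.prod(volume.dims)), time.time() - t0)

    t0 = time.time()
    table = ThresholdTable.from_greyvalues(spec.tissue_greyvalues)
    segmented = threshold_segment(volume, table)
    mismatch = misclassified_fraction(
        segmented, labels, table.merge_names(spec.tissue_greyvalues)
    )
    logger.info("segment: mismatch vs merged ground truth %.2e in %.2f s",
                mismatch, time.time() - t0)

    t0 = time.time()
    mesh = voxels_to_tetmesh(labels, element_order=element_order)
    mesh = add_end_nodesets(mesh, spec, torsion=bool(load.torsion_couple_N))
    logger.info("mesh: %d nodes, %d elements in %.2f s",
                mesh.n_nodes, mesh.n_elements, time.time() - t0)

    materials = assign_materials(mesh, volume, labels, calib=calib)
    load_case = make_load_case(spec, load)
    t0 = time.time()
    solution = assemble_and_solve(mesh, materials, load_case)
    logger.info("solve: %s in %.2f s", solution.solver_info, time.time() - t0)
    healing = evaluate_healing_window(solution, region="callus", config=zones)
    return VariantArtifacts(
        volume=volume, labels=labels, mesh=mesh, solution=solution,
        healing=healing, segmentation_mismatch=mismatch,
    )


def run_case(case: CaseDefinition, out_dir: str | Path | None = None) -> CaseResult:
    """Execute a case end-to-end, deterministically for a given seed."""
    if case.name == "usecase5_wrist":
        rom_b = sweep_contact(generate_wrist_scene(case.baseline),
                              case.rom_range, case.rom_step)
        rom_r = sweep_contact(generate_wrist_scene(case.revision),
                              case.rom_range, case.rom_step)
        result = CaseResult(definition=case, rom_baseline=rom_b, rom_revised=rom_r)
        if out_dir is not None:
            _write_rom(result, Path(out_dir))
        return result

    try:
        art_b = run_variant(case.baseline, case.load, case.zones,
                            case.calibration, case.element_order)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"{case.name}: baseline variant failed: {exc}") from exc
    try:
        art_r = run_variant(case.revision, case.load, case.zones,
                            case.calibration, case.element_order)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"{case.name}: revision variant failed: {exc}") from exc

    # paired metrics only over regions present in both variants
    common = set(np.unique(art_b.mesh.element_region_names())) & set(
        np.unique(art_r.mesh.element_region_names())
    )
    regions = [r for r in ("nail", "plate", "screw") if r in common]
    provenance = {
        "case": case.name,
        "seed": case.seed,
        "element_order": case.element_order,
        "load": case.load.to_dict(),
        "zone_config": case.zones.to_dict(),
        "calibration": case.calibration.to_dict(),
        "region_table": {
            k: {"E_MPa": v.E, "nu": v.nu} for k, v in DEFAULT_REGION_TABLE.items()
        },
        "baseline_spec": case.baseline.to_dict(),
        "revision_spec": case.revision.to_dict(),
        "baseline_mesh": {"nodes": art_b.mesh.n_nodes, "elements": art_b.mesh.n_elements},
        "revision_mesh": {"nodes": art_r.mesh.n_nodes, "elements": art_r.mesh.n_elements},
        "segmentation_mismatch": {
            "baseline": art_b.segmentation_mismatch,
            "revision": art_r.segmentation_mismatch,
        },
    }
    report = compare_treatments(
        case.name,
        (art_b.solution, art_b.healing),
        (art_r.solution, art_r.healing),
        regions=regions,
        provenance=provenance,
    )
    result = CaseResult(definition=case, report=report,
                        baseline=art_b, revised=art_r)
    if out_dir is not None:
        _write_case(result, Path(out_dir))
    return result


def _write_case(result: CaseResult, out: Path) -> None:
    from .fileio import write_vtu
    from .mechanobiology import strain_invariants, von_mises

    out.mkdir(parents=True, exist_ok=True)
    result.report.to_json(out / "report.json")
    result.report.to_csv(out / "report.csv")
    from .mechanobiology import ZONES

    for tag, art in (("baseline", result.baseline), ("revised", result.revised)):
        sol = art.solution
        gamma, eps_vol = strain_invariants(sol.strain)
        # healing zone per element: callus elements get their zone index,
        # everything else -1
        zone_field = np.full(art.mesh.n_elements, -1, dtype=np.int64)
        zone_index = {z: i for i, z in enumerate(ZONES)}
        zone_field[art.healing.element_ids] = [
            zone_index[z] for z in art.healing.zone_labels
        ]
        fields = {
            "von_mises_MPa": von_mises(sol.stress),
            "gamma_oct": gamma,
            "eps_vol": eps_vol,
            "healing_zone": zone_field,
        }
        write_vtu(out / f"{tag}.vtu", art.mesh, cell_fields=fields,
                  point_fields={"displacement_mm": sol.displacements})


def _write_rom(result: CaseResult, out: Path) -> None:
    import json

    import pandas as pd

    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "case": result.definition.name,
        "baseline": result.rom_baseline.to_dict(),
        "revised": result.rom_revised.to_dict(),
    }
    (out / "rom.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    for tag, rom in (("baseline", result.rom_baseline), ("revised", result.rom_revised)):
        pd.DataFrame(
            {"angle_deg": rom.angles_deg, "contact": rom.contact.astype(int)}
        ).to_csv(out / f"rom_{tag}.csv", index=False)
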