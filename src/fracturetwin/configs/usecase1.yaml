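# Use case 1: exchange nailing — replace the 8 mm intramedullary nail of an
# idealized tibial construct with an 11 mm nail, without altering its position.
case: usecase1_nail_diameter
desk_scale: true
seed: 0
element_order: 1
baseline:
  bone_length: 200.0        # mm, distal end at z = 0
  outer_radius: 12.0        # mm periosteal radius
  cortical_thickness: 4.0   # mm
  canal_radius: 6.0         # mm medullary canal
  gap_position: 100.0       # mm, mid-shaft transverse fracture
  gap_width: 4.0            # mm soft-callus gap
  nail_radius: 4.0          # 8 mm nail
  nail_length: 180.0
  voxel_spacing: 1.0        # mm
  noise_sd: 0.0             # HU
revision:
  nail_radius: 5.5          # 11 mm nail; everything else unchanged
load:
  axial_N: -1500.0          # compressive peak joint load (walking stand-in)
  transverse_N: 150.0       # shear producing bending at the gap
  torsion_couple_N: 0.0
zones:
  gamma_low: 0.0025
  eps_low: 0.0025
  gamma_im: 0.05
  eps_im: 0.05
  gamma_ec: 0.15
  eps_ec_compressive: -0.15
  eps_ec_tensile: 0.05
calibration:
  a: 1.0          # g/cm^3 at 0 HU
  b: 0.001        # g/cm^3 per HU
  c: 6850.0       # MPa (g/cm^3)^-d
  d: 1.49
  rho_min: 0.05
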