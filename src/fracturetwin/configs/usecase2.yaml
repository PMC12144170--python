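# Use case 2: augmentative plate added to a nailed humerus analogue.
case: usecase2_plate_humerus_analogue
desk_scale: true
seed: 0
element_order: 1
# baseline/revision geometry defaults are built by the case; any field of
# the construct spec may be overridden here, e.g.:
# revision:
#   plate: {length: 80.0, width: 10.0, thickness: 3.0, angular_position: 0.0}
load:
  axial_N: -1500.0
  transverse_N: 150.0
  torsion_couple_N: 0.0
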