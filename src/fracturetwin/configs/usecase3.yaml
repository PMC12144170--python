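# Use case 3: augmentative plate added to a nailed femur analogue.
case: usecase3_plate_femur_analogue
desk_scale: true
seed: 0
element_order: 1
load:
  axial_N: -1500.0
  transverse_N: 150.0
  torsion_couple_N: 0.0
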