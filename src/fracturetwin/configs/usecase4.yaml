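# Use case 4: strain-reduction screw under a torsion-dominant load
# (equilibrated force couple over the proximal reference region).
case: usecase4_screw_torsion
desk_scale: true
seed: 0
element_order: 1
load:
  axial_N: -150.0
  transverse_N: 0.0
  torsion_couple_N: 2000.0
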