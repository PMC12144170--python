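# Use case 5: wrist range-of-motion sweep. Baseline: malaligned distal
# radius with a bony prominence impinging against the proximal carpal row;
# revision: realigned joint without the prominence.
case: usecase5_wrist
seed: 0
baseline:
  cup_radius: 15.0          # mm articular cup
  carpal_radius: 6.0        # mm rigid proximal carpal unit
  center_offset: 8.0        # mm carpal center below rotation center
  prominence:
    angular_position: 25.0  # deg toward radial deviation
    angular_half_width: 5.0 # deg
    height: 2.0             # mm (> 1 mm neutral clearance)
revision: {}
rom:
  range: [-40.0, 40.0]      # deg; ulnar negative, radial positive
  step: 0.5                 # deg
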