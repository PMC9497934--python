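# Fixed acquisition constants: IEC 62220-1-1 beam qualities and the detector
# specification sheet. Numbers are editable; user files with the same schema
# can be loaded via dqekit.protocols.load_registry(path).
#
# Beam qualities carry both the IEC 62220-1-1:2015 values (default) and the
# superseded IEC 62220-1:2003 values, selectable by protocol version.
# snr2_per_kerma is the squared SNR per air kerma in 1/(mm^2 uGy), which is
# numerically the photon fluence per air kerma ratio used by the DQE.
beam_qualities:
  RQA3:
    tube_voltage_kv: 50.0
    added_filtration_mm_al: 10.0
    iec_2015:
      half_value_layer_mm_al: 3.8
      snr2_per_kerma: 21759.0
    iec_2003:
      half_value_layer_mm_al: 4.0
      snr2_per_kerma: 30174.0
  RQA5:
    tube_voltage_kv: 70.0
    added_filtration_mm_al: 21.0
    iec_2015:
      half_value_layer_mm_al: 6.8
      snr2_per_kerma: 20673.0
    iec_2003:
      half_value_layer_mm_al: 7.1
      snr2_per_kerma: 29653.0

# Detector specification sheet. pixel_pitch in micrometres;
# scintillator_thickness_factor is the CsI(Tl) thickness as a multiple of the
# standard (FXRD-4343VAW) layer.
detectors:
  FXRD-4343VAW:
    scintillator_thickness_factor: 1.0
    pixel_pitch_um: 140.0
    matrix: [3072, 3072]
    detection_area: [3048, 3048]
    weight_kg: 3.45
  FXRD-4343VAW Plus:
    scintillator_thickness_factor: 1.5
    pixel_pitch_um: 140.0
    matrix: [3072, 3072]
    detection_area: [3048, 3048]
    weight_kg: 3.7
  FXRD-4343FAW:
    scintillator_thickness_factor: 1.6
    pixel_pitch_um: 99.0
    matrix: [4316, 4316]
    detection_area: [4276, 4276]
    weight_kg: 2.95
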