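# Study-emulation preset: 3 sites (5, 3, 5 transects of five 4 m x 0.8 m
# sections), 2 observers, 2 readings per observer. Detection and
# misclassification probabilities reproduce the validation study's recovery
# and confusion-matrix anchors.
design:
  n_sites: 3
  transects_per_site: [5, 3, 5]
  sections_per_transect: 5
  observers: 2
  readings_per_observer: 2
  section_length: 4.0
  section_width: 0.8
generator:
  mode: mechanistic
  grand_mean: 4.0
  site_effects: [0.0, 0.0, 0.0]
  vc:
    s_tr2: 1.1
    s_se2: 26.2
  dead_grand_mean: 3.7
  p_detect_living: 0.8
  p_detect_dead: 0.5
  p_live_classified_dead: 0.18
  p_dead_classified_living: 0.20
  p_probably_given_detected_living: 0.5
  seed: 0
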