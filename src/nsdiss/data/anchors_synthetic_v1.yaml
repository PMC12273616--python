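# Synthetic reconstruction of NSD-ISS staging anchors, version 1.
#
# These thresholds are NOT the operational staging anchors used on real
# cohort data (those are published separately as supplementary material to
# the staging-system literature and must be supplied by the user).  They are
# a self-consistent synthetic rulebook with the same structure, used by the
# cohort simulator and the test suite.
#
# Bands are half-open [lo, hi): a score equal to a threshold falls in the
# higher band.  Scores are "higher = worse".  A null threshold marks a band
# the domain cannot anchor; other_nonmotor has no "slight" band, so stage 3
# is reachable through the cognitive and motor domains only.
version: anchors_synthetic_v1
domains:
  cognitive:
    score_field: cognitive_score
    sign_field: cognitive_signs
    bands:
      slight: 2
      mild: 6
      moderate: 12
      severe: 20
  motor:
    score_field: motor_score
    sign_field: motor_signs
    bands:
      slight: 3
      mild: 13
      moderate: 27
      severe: 40
  other_nonmotor:
    score_field: nonmotor_score
    sign_field: nonmotor_signs
    bands:
      slight: null
      mild: 13
      moderate: 27
      severe: 40
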