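# Example criteria configuration for ranking athletes on their
# stroke-cycle angles.  The knee joint angle and finger-spread angle are
# treated as larger-is-better; the thigh and calf link angles (measured
# against the vertical, negative by convention) as smaller-magnitude-is-
# better via the subtract-from-max transform.  Weights are equal; no
# authoritative weighting is published, so adjust to taste.
criteria:
  right_knee: {direction: maximize, weight: 0.25}
  right_thigh: {direction: minimize_subtract, weight: 0.25}
  right_calf: {direction: minimize_subtract, weight: 0.25}
  finger_spread: {direction: maximize, weight: 0.25}
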