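# Synthetic reconstruction of a Kaiser-style flowchart (NOT a transcription
# of the published instrument, which is not redistributed here). The leaf
# placement is constrained so the published worked examples hold:
#   * no root sign, persistent enhancement, irregular margin, homogeneous -> 3
#   * no root sign, plateau enhancement, irregular margin -> 5
#   * root sign present, no edema -> 7
#   * no root sign, persistent, irregular margin, inhomogeneous -> 6
# Total, deterministic, all 11 scores reachable. For clinical scoring,
# substitute a faithful transcription of the published flowchart.
name: kaiser_reconstructed
version: "0.1-synthetic"
paths:
  - {root_sign: "yes", curve_type: "*", margin: "*", internal_enhancement: "*", edema: "yes", score: 11}
  - {root_sign: "yes", curve_type: "*", margin: "*", internal_enhancement: "*", edema: "no", score: 7}
  - {root_sign: "no", curve_type: washout, margin: not_circumscribed, internal_enhancement: "*", edema: "yes", score: 10}
  - {root_sign: "no", curve_type: washout, margin: not_circumscribed, internal_enhancement: "*", edema: "no", score: 9}
  - {root_sign: "no", curve_type: washout, margin: circumscribed, internal_enhancement: inhomogeneous, edema: "*", score: 8}
  - {root_sign: "no", curve_type: washout, margin: circumscribed, internal_enhancement: homogeneous, edema: "*", score: 6}
  - {root_sign: "no", curve_type: plateau, margin: not_circumscribed, internal_enhancement: "*", edema: "*", score: 5}
  - {root_sign: "no", curve_type: plateau, margin: circumscribed, internal_enhancement: inhomogeneous, edema: "*", score: 4}
  - {root_sign: "no", curve_type: plateau, margin: circumscribed, internal_enhancement: homogeneous, edema: "*", score: 2}
  - {root_sign: "no", curve_type: persistent, margin: not_circumscribed, internal_enhancement: inhomogeneous, edema: "*", score: 6}
  - {root_sign: "no", curve_type: persistent, margin: not_circumscribed, internal_enhancement: homogeneous, edema: "*", score: 3}
  - {root_sign: "no", curve_type: persistent, margin: circumscribed, internal_enhancement: inhomogeneous, edema: "*", score: 2}
  - {root_sign: "no", curve_type: persistent, margin: circumscribed, internal_enhancement: homogeneous, edema: "*", score: 1}
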