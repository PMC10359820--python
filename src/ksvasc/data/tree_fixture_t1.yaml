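# Fixture score tree T1: a compact, fully specified flowchart used by the
# test suite. Total and deterministic over the 48 feature combinations;
# every score 1..11 is reachable. Not a clinical instrument.
name: fixture_T1
version: "1.0"
paths:
  - {root_sign: "yes", curve_type: "*", margin: "*", internal_enhancement: "*", edema: "yes", score: 11}
  - {root_sign: "yes", curve_type: "*", margin: "*", internal_enhancement: "*", edema: "no", score: 8}
  - {root_sign: "no", curve_type: washout, margin: not_circumscribed, internal_enhancement: "*", edema: "yes", score: 10}
  - {root_sign: "no", curve_type: washout, margin: not_circumscribed, internal_enhancement: "*", edema: "no", score: 9}
  - {root_sign: "no", curve_type: washout, margin: circumscribed, internal_enhancement: inhomogeneous, edema: "*", score: 7}
  - {root_sign: "no", curve_type: washout, margin: circumscribed, internal_enhancement: homogeneous, edema: "*", score: 5}
  - {root_sign: "no", curve_type: plateau, margin: not_circumscribed, internal_enhancement: "*", edema: "*", score: 6}
  - {root_sign: "no", curve_type: plateau, margin: circumscribed, internal_enhancement: inhomogeneous, edema: "*", score: 4}
  - {root_sign: "no", curve_type: plateau, margin: circumscribed, internal_enhancement: homogeneous, edema: "*", score: 3}
  - {root_sign: "no", curve_type: persistent, margin: not_circumscribed, internal_enhancement: "*", edema: "*", score: 2}
  - {root_sign: "no", curve_type: persistent, margin: circumscribed, internal_enhancement: "*", edema: "*", score: 1}
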