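# Methods

## The scoring model

A lesion is described by five flowchart features — root sign (present /
absent), delayed-phase kinetics (persistent / plateau / washout), margin
(circumscribed / not circumscribed, with "irregular" and "spiculated"
accepted as ingest aliases), internal enhancement (homogeneous /
inhomogeneous) and perifocal edema (present / absent) — giving 48 legal
combinations. A **score tree** maps every combination to a Kaiser score in
1–11. Trees are data, not code: YAML path lists with wildcards, expanded
and validated at load time for totality (every combination covered),
determinism (no combination covered twice) and leaf range.

Two trees ship with the package:

* `tree_fixture_t1.yaml` — a compact fixture tree, fully specified,
  total, deterministic, with all 11 scores reachable. Every unit test
  binds to it, so test expectations are independent of any external
  flowchart.
* `tree_kaiser_reconstructed.yaml` — a synthetic Kaiser-style flowchart
  used as the pipeline default. It is **not** a transcription of the
  published clinical instrument; it is constrained to reproduce the four
  published worked examples (irregular margin + persistent enhancement
  → 3, irregular margin + plateau → 5, root sign without edema → 7, and a
  persistent-enhancement path reaching 6) and to keep the usual coarse
  structure (root sign dominates; washout > plateau > persistent;
  non-circumscribed > circumscribed). Two of those worked examples fix
  only part of the feature vector; the reconstruction resolves the
  freedom by letting internal enhancement split the persistent/irregular
  branch (homogeneous → 3, inhomogeneous → 6), which is the smallest
  change that satisfies both examples at once. Anyone scoring real
  patients must substitute a faithful transcription of the published
  flowchart; everything downstream is tree-agnostic.

The **vascular assessment** is two binary criteria: increased ipsilateral
vascularity (ipsilateral minus contralateral qualifying-vessel count ≥ 2,
where a vessel qualifies when length ≥ 30 mm and diameter ≥ 2 mm, both
thresholds inclusive) and the adjacent-vessel sign. The composite score is

KS\* = KS + 3 if KS ≤ 7 **and** both criteria are positive; otherwise
KS\* = KS.

All eligibility is decided by the conjunction: one positive sign alone
never changes the score, and scores ≥ 8 are never changed (they already
map to BI-RADS 5, so extra points could not alter management). The +3 was
chosen by the rule's authors so that an upgraded lesion moves up exactly
one BI-RADS band (1–4 → 2/3, 5–7 → 4, 8–11 → 5). A consequence worth
stating: KS\* is *not* monotone in KS at the eligibility boundary — with
both signs positive, KS 7 maps to 10 while KS 8 stays 8. That is a genuine
property of the rule, not an implementation artefact, and the property
tests assert it explicitly.

## The synthetic cohort generator

No patient-level data are distributed with the study, so the package
ships a generative model of the cohort's published structure. Per lesion:

1. lesion type ~ Bernoulli(p_mass), default 164/223;
2. truth given type: P(malignant | mass) = 85/164,
   P(malignant | non-mass) = 19/59 (implying the printed overall
   prevalence 104/223);
3. the sign pair (vascularity, AVS) from a class-conditional joint
   parameterised by the two marginals and the conjunction — malignant
   (72/104, 86/104, 64/104), benign (28/119, 28/119, 16/119) — validated
   against the Fréchet bounds max(0, p_v + p_a − 1) ≤ p_both ≤ min(p_v, p_a);
4. KS from a class-conditional pmf over 1–11 (below); features drawn
   uniformly from the active tree's preimage of that score, so re-scoring
   the features always reproduces the drawn KS;
5. vessel counts: contralateral from a small-integer pmf
   (default (0.15, 0.30, 0.25, 0.15, 0.08, 0.05, 0.02) over 0–6, a
   right-skewed shape typical of MIP vessel counts); ipsilateral =
   contralateral + 2 + extra (extra in 0–3, mean ≈ 0.6) when the
   vascularity flag is positive, otherwise contralateral + δ with
   δ ∈ {−2…1} floored at zero — so the count pair always reproduces the
   flag through the ≥ 2 criterion;
6. optional second reading: each assessment (vascularity flag, AVS flag,
   each feature field) independently disagrees with reading 1 with a
   configured probability. Defaults (inter-reader: vascularity 0.049,
   AVS 0.018; intra-reader: 0.022 / 0.0135) were solved analytically from
   κ ≈ 1 − f/(1 − p_e) at the published sign prevalences so the simulated
   kappas concentrate near the reported 0.900/0.964 (inter) and
   0.955/0.973 (intra).

The KS pmfs are not published (the study prints no score histogram); the
package commits one fixed pair chosen so that the printed operating point
at cutoff >4 holds exactly in expectation — P(KS > 4 | malignant) = 0.942,
P(KS ≤ 4 | benign) = 0.588 — and the population AUC is ≈ 0.86, matching
the reported whole-cohort discrimination:

* benign: (.150, .170, .133, .135, .145, .110, .070, .042, .025, .013, .007)
* malignant: (.008, .014, .016, .020, .110, .130, .125, .160, .170, .140, .107)

These give analytic AUC(KS) = 0.864 and, with the sign joints above and
conditional independence, AUC(KS\*) = 0.896. They are a calibration
device, not an estimate of the study's true score distributions.

**Dependence structure.** By default KS and the vascular signs are
conditionally independent given the truth class. The study's own upgrade
audit (18 upgraded lesions, 14 malignant) suggests the real data couple
the signs to severity more tightly than that — conditional independence
upgrades every double-positive KS ≤ 7 lesion, ≈ 41 per 223-lesion cohort —
so absolute upgrade counts from the generator overshoot the study's. The
direction and approximate size of the AUC gain, the malignancy enrichment
among upgraded lesions, and every marginal rate are preserved, and those
are the quantities the evaluation pipeline tests. A single
`severity_coupling` knob (0–1, default 0) tilts the sign probabilities
with the drawn score for sensitivity analyses. This is the main respect in
which passing tests say less about real data than about the generator.

**Reproducibility.** One root seed in the spec; all draws derive from a
single `numpy` Generator; replicate k of a simulation study uses seed + k;
the second reader and the intra-reader re-read use seed + 1 and seed + 2.
Identical spec ⇒ byte-identical cohorts and report bundles.

## Evaluation statistics

* **2×2 metrics** are kept as exact rationals (`fractions.Fraction`)
  alongside a display value: percent rounded half-up to one decimal
  (floor(x + ½) at the first decimal). Zero-denominator metrics are
  reported as undefined, never as 0.
* **ROC/AUC**: operating points are "score > c" for every distinct c,
  malignant positive; AUC is the Mann–Whitney statistic with midrank tie
  handling (ψ = ½ on ties), computed from pooled ranks; it equals the
  trapezoidal area of the operating points by construction, and a test
  asserts the two code paths agree to 1e-12.
* **DeLong**: variance from the structural components V10, V01 with
  sample variances (ddof = 1); the paired test uses the paired component
  covariances; degenerate zero-denominator comparisons with equal AUCs
  return z = 0, p = 1. Single-AUC 95% CIs are normal intervals on the
  DeLong SE truncated to [0, 1] — the study's own CI construction is not
  stated, so its printed CI digits are not a reproduction target.
* **Cohen's kappa** (two categories): point estimate from observed vs
  chance agreement; SE from the Fleiss–Cohen–Everitt large-sample
  variance of the estimate (cross-checked against statsmodels to 1e-10);
  bands < 0.4 bad, 0.4–0.7 good, > 0.7 excellent. Two constant identical
  readings are κ = 1 by convention.
* **Chi-square**: Pearson, df = 1, continuity correction off by default —
  the published mass vs non-mass specificity comparison (65/79 vs 26/40,
  P = 0.036) is reproduced by the uncorrected statistic (χ² ≈ 4.41) and
  not by the Yates-corrected one; a flag enables the correction. No
  multiple-testing adjustment anywhere, mirroring the source analysis.

## Problem sizes used by the test suite

Distributional checks use the smallest sizes at which the tolerances are
comfortably stable: parameter recovery at n = 10,000 (±0.02 on sign
rates and pmf categories, ±0.03 on the operating point), the conjunction
rate at n = 50,000 (±0.01), the AUC direction-of-effect over 200
replicates of n = 223, the DeLong-vs-bootstrap comparison at n = 200 with
2,000 resamples, the permutation cross-check with 5,000 swaps, and the
type-I-error calibration over 500 null replicates (empirical α required
in [0.03, 0.08]).

## Known limitations

* The default flowchart is a constrained reconstruction, not the
  published clinical instrument (see above).
* Conditional independence of KS and the vascular signs given truth
  overstates the number of upgraded lesions (direction and enrichment are
  unaffected; see the dependence note).
* Per-lesion-type sign conjunctions are not published; the pooled
  dependence structure is reused within mass and non-mass subgroups.
* Kappa is implemented for binary assessments only — the reliability of
  the 11-point score itself is not evaluated (the source reports kappas
  only for the two vascular signs).
* The generator does not model pathology subtypes, lesion size, or
  reader-specific bias (the simulated second reader disagrees
  symmetrically).
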