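"""Seeded synthetic lesion cohorts.

The generator emulates the statistical structure of a single-centre breast-MRI
diagnostic-accuracy cohort: 223 suspicious lesions, about 53% benign, 73.5%
mass-type, with the two vascular signs (increased ipsilateral vascularity and
the adjacent-vessel sign) drawn from class-conditional joint distributions
taken from the study's printed counts, and class-conditional ordinal Kaiser
score distributions calibrated to the printed operating point at cutoff >4
(sensitivity 94.2%, specificity 58.8%).

What it deliberately does NOT model: images, pathology subtypes, lesion
sizes, or any dependence between the Kaiser score and the vascular signs
beyond the shared truth class (conditional independence by default; a single
latent-severity coupling knob is available for sensitivity analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .scoring import (
    CURVE_TYPES,
    KaiserFeatures,
    ScoreTree,
    assess_increased_vascularity,
)

__all__ = [
    "SignJoint",
    "Reading",
    "LesionRecord",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "sample_features_for_score",
    "materialize_vessel_counts",
    "simulate_second_reader",
]

TRUTH_CLASSES = ("benign", "malignant")
LESION_TYPES = ("mass", "non_mass")


@dataclass(frozen=True)
class SignJoint:
    """Joint law of (increased vascularity V, adjacent-vessel sign A) given a
    truth class, parameterised by the two marginals and the conjunction."""

    p_vascularity: float
    p_avs: float
    p_both: float

    def validate(self) -> None:
        for name, p in (
            ("p_vascularity", self.p_vascularity),
            ("p_avs", self.p_avs),
            ("p_both", self.p_both),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        lo = max(0.0, self.p_vascularity + self.p_avs - 1.0)
        hi = min(self.p_vascularity, self.p_avs)
        if not (lo - 1e-12 <= self.p_both <= hi + 1e-12):
            raise ValueError(
                f"infeasible sign joint: Frechet bounds require "
                f"{lo:.6f} <= p_both <= {hi:.6f}, got {self.p_both:.6f}"
            )

    def cell_probabilities(self) -> np.ndarray:
        """Probabilities of (V&A, V only, A only, neither)."""
        both = self.p_both
        v_only = self.p_vascularity - both
        a_only = self.p_avs - both
        return np.array([both, v_only, a_only, 1.0 - both - v_only - a_only])


@dataclass(frozen=True)
class Reading:
    """One reader's three assessments of a lesion."""

    increased_vascularity: bool
    avs_present: bool
    features: KaiserFeatures


@dataclass(frozen=True)
class LesionRecord:
    id: str
    truth: str  # benign | malignant
    lesion_type: str  # mass | non_mass
    features: KaiserFeatures
    ipsi_vessels: int
    contra_vessels: int
    avs_present: bool
    ks_drawn: int | None = None  # generator-internal truth of the drawn score
    reader2: Reading | None = None

    @property
    def increased_vascularity(self) -> bool:
        return assess_increased_vascularity(self.ipsi_vessels, self.contra_vessels)


@dataclass(frozen=True)
class CohortSpec:
    """Full generative parameterisation of a synthetic cohort.

    ``ks_pmf`` vectors index scores 1..11. ``reader_flip`` gives per-assessment
    probabilities that the simulated second reading disagrees with the first
    (keys: vascularity, avs, features). ``severity_coupling`` in [0, 1] mixes
    in a shared latent severity that raises sign probabilities for high-score
    lesions; 0 (default) is conditional independence given truth.
    """

    n: int = 223
    p_mass: float = 164 / 223
    p_malignant_given_mass: float = 85 / 164
    p_malignant_given_nonmass: float = 19 / 59
    sign_joint: Mapping[str, SignJoint] = field(
        default_factory=lambda: {
            "malignant": SignJoint(72 / 104, 86 / 104, 64 / 104),
            "benign": SignJoint(28 / 119, 28 / 119, 16 / 119),
        }
    )
    ks_pmf: Mapping[str, tuple] = field(
        default_factory=lambda: {
            # calibrated so that P(KS > 4 | malignant) = 0.942 and
            # P(KS <= 4 | benign) = 0.588 exactly
            "benign": (0.150, 0.170, 0.133, 0.135, 0.145, 0.110, 0.070, 0.042, 0.025, 0.013, 0.007),
            "malignant": (0.008, 0.014, 0.016, 0.020, 0.110, 0.130, 0.125, 0.160, 0.170, 0.140, 0.107),
        }
    )
    contralateral_count_pmf: tuple = (0.15, 0.30, 0.25, 0.15, 0.08, 0.05, 0.02)
    reader_flip: Mapping[str, float] = field(
        default_factory=lambda: {"vascularity": 0.049, "avs": 0.018, "features": 0.02}
    )
    reader_flip_intra: Mapping[str, float] = field(
        default_factory=lambda: {"vascularity": 0.022, "avs": 0.0135, "features": 0.01}
    )
    severity_coupling: float = 0.0
    seed: int = 20230706

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("p_mass", "p_malignant_given_mass", "p_malignant_given_nonmass"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for cls in TRUTH_CLASSES:
            self.sign_joint[cls].validate()
            pmf = np.asarray(self.ks_pmf[cls], dtype=float)
            if pmf.shape != (11,) or (pmf < 0).any():
                raise ValueError(f"ks_pmf[{cls!r}] must be 11 non-negative probabilities")
            if not math.isclose(pmf.sum(), 1.0, abs_tol=1e-12):
                raise ValueError(f"ks_pmf[{cls!r}] sums to {pmf.sum()!r}, not 1")
        cpmf = np.asarray(self.contralateral_count_pmf, dtype=float)
        if (cpmf < 0).any() or not math.isclose(cpmf.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("contralateral_count_pmf must be a probability vector")
        for flips in (self.reader_flip, self.reader_flip_intra):
            for key, p in flips.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"reader flip probability {key}={p} outside [0, 1]")
        if not 0.0 <= self.severity_coupling <= 1.0:
            raise ValueError("severity_coupling outside [0, 1]")


def default_spec(seed: int | None = None, **overrides) -> CohortSpec:
    """The study-calibrated default cohort specification."""
    spec = CohortSpec(**overrides)
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    spec.validate()
    return spec


def sample_features_for_score(
    score: int, tree: ScoreTree, rng: np.random.Generator
) -> KaiserFeatures:
    """Draw a feature combination uniformly from the tree preimage of a score."""
    pre = tree.preimage(int(score))
    if not pre:
        raise ValueError(f"score {score} is unreachable in tree {tree.name!r}")
    return pre[int(rng.integers(len(pre)))]


# extra vessels beyond the minimum excess of 2 when vascularity is increased,
# and the (ipsi - contra) offset when it is not
_EXTRA_VALUES = np.array([0, 1, 2, 3])
_EXTRA_PROBS = np.array([0.60, 0.25, 0.10, 0.05])
_EXTRA_CUM = np.cumsum(_EXTRA_PROBS)
_DELTA_VALUES = np.array([-2, -1, 0, 1])
_DELTA_PROBS = np.array([0.20, 0.30, 0.30, 0.20])
_DELTA_CUM = np.cumsum(_DELTA_PROBS)


def materialize_vessel_counts(
    increased: bool, pmf: Sequence[float], rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (ipsilateral, contralateral) qualifying-vessel counts consistent
    with the vascularity flag: difference >= 2 iff ``increased``."""
    cum = np.cumsum(np.asarray(pmf, dtype=float))
    contra = int(np.searchsorted(cum, rng.random(), side="right"))
    if increased:
        extra = int(_EXTRA_VALUES[np.searchsorted(_EXTRA_CUM, rng.random(), side="right")])
        ipsi = contra + 2 + extra
    else:
        delta = int(_DELTA_VALUES[np.searchsorted(_DELTA_CUM, rng.random(), side="right")])
        ipsi = max(0, contra + delta)
    return ipsi, contra


def _draw_sign_cell(joint: SignJoint, rng: np.random.Generator) -> tuple[bool, bool]:
    cell = int(np.searchsorted(np.cumsum(joint.cell_probabilities()), rng.random(), side="right"))
    cell = min(cell, 3)  # guard against fp round-off at the upper edge
    return cell in (0, 1), cell in (0, 2)  # (vascularity, avs)


def generate_cohort(spec: CohortSpec, tree: ScoreTree) -> list[LesionRecord]:
    """Generate ``spec.n`` lesion records, fully reproducible from ``spec.seed``.

    Per record: lesion type ~ Bernoulli(p_mass); truth given type; the sign
    pair from the class sign joint; KS from the class pmf; features drawn
    uniformly from the tree preimage of the drawn KS; vessel counts
    materialised consistently with the vascularity flag.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ks_cum = {
        cls: np.cumsum(np.asarray(spec.ks_pmf[cls], dtype=float)) for cls in TRUTH_CLASSES
    }
    preimages = {s: tree.preimage(s) for s in range(1, 12)}
    width = max(4, len(str(max(spec.n, 1))))
    records: list[LesionRecord] = []
    for i in range(spec.n):
        is_mass = rng.random() < spec.p_mass
        p_mal = spec.p_malignant_given_mass if is_mass else spec.p_malignant_given_nonmass
        truth = "malignant" if rng.random() < p_mal else "benign"
        ks = 1 + int(np.searchsorted(ks_cum[truth], rng.random(), side="right"))
        ks = min(ks, 11)  # guard against fp round-off at the upper edge
        joint = spec.sign_joint[truth]
        if spec.severity_coupling > 0:
            joint = _couple_to_severity(joint, ks, spec.severity_coupling)
        vasc, avs = _draw_sign_cell(joint, rng)
        pre = preimages.get(ks)
        if not pre:
            raise ValueError(f"score {ks} is unreachable in tree {tree.name!r}")
        features = pre[int(rng.integers(len(pre)))]
        ipsi, contra = materialize_vessel_counts(vasc, spec.contralateral_count_pmf, rng)
        records.append(
            LesionRecord(
                id=f"L{i + 1:0{width}d}",
                truth=truth,
                lesion_type="mass" if is_mass else "non_mass",
                features=features,
                ipsi_vessels=ipsi,
                contra_vessels=contra,
                avs_present=avs,
                ks_drawn=ks,
            )
        )
    return records


def _couple_to_severity(joint: SignJoint, ks: int, coupling: float) -> SignJoint:
    """Optional latent-severity coupling: tilt both sign marginals toward 1
    for high scores and toward 0 for low scores, preserving feasibility."""
    tilt = coupling * (ks - 6) / 5.0  # in [-coupling, +coupling]
    def clamp(p):
        return min(1.0, max(0.0, p + tilt * min(p, 1 - p)))
    pv, pa = clamp(joint.p_vascularity), clamp(joint.p_avs)
    lo, hi = max(0.0, pv + pa - 1.0), min(pv, pa)
    pb = min(hi, max(lo, joint.p_both + tilt * min(joint.p_both, 1 - joint.p_both)))
    return SignJoint(pv, pa, pb)


def _flip_features(f: KaiserFeatures, p: float, rng: np.random.Generator) -> KaiserFeatures:
    root = f.root_sign ^ (rng.random() < p)
    edema = f.edema ^ (rng.random() < p)
    curve = f.curve_type
    if rng.random() < p:
        curve = [c for c in CURVE_TYPES if c != curve][int(rng.integers(2))]
    margin = f.margin
    if rng.random() < p:
        margin = "circumscribed" if margin == "not_circumscribed" else "not_circumscribed"
    internal = f.internal_enhancement
    if rng.random() < p:
        internal = "homogeneous" if internal == "inhomogeneous" else "inhomogeneous"
    return KaiserFeatures(root, curve, margin, internal, edema)


def simulate_second_reader(
    cohort: Sequence[LesionRecord],
    reader_flip: Mapping[str, float],
    rng: np.random.Generator | int,
) -> list[LesionRecord]:
    """Fill ``reader2`` on every record: each assessment independently
    disagrees with reading 1 with its configured probability."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_v = float(reader_flip.get("vascularity", 0.0))
    p_a = float(reader_flip.get("avs", 0.0))
    p_f = float(reader_flip.get("features", 0.0))
    out = []
    for rec in cohort:
        reading = Reading(
            increased_vascularity=rec.increased_vascularity ^ (rng.random() < p_v),
            avs_present=rec.avs_present ^ (rng.random() < p_a),
            features=_flip_features(rec.features, p_f, rng),
        )
        out.append(replace(rec, reader2=reading))
    return out
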