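"""Kaiser-score engine with breast-vascular adjustment (KS*).

The Kaiser score (KS) is an 11-level ordinal decision score for breast MRI
lesions (1 = almost certainly benign, 11 = almost certainly malignant),
obtained by walking a published flowchart over five lesion features:
root sign (spiculations), delayed-phase enhancement kinetics, margin,
internal enhancement pattern, and perifocal edema.

The adjusted score KS* additionally looks at the breast vasculature on
MIP / subtraction images: if a lesion scoring <= 7 shows *both* increased
ipsilateral breast vascularity (>= 2 more qualifying vessels than the
contralateral breast) and a positive adjacent-vessel sign (AVS), the score
is raised by 3. Scores >= 8 are already in the highest BI-RADS band, so no
adjustment is applied there and the result always stays within 1..11.

The flowchart itself is configuration data (:class:`ScoreTree`), not code:
trees are YAML files mapping feature combinations to leaf scores, validated
for totality and determinism before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

__all__ = [
    "CURVE_TYPES",
    "MARGINS",
    "INTERNAL_PATTERNS",
    "KaiserFeatures",
    "VesselObservation",
    "VascularAssessment",
    "ScoreTree",
    "ScoreResult",
    "TreeValidationError",
    "qualify_vessel",
    "count_qualifying_vessels",
    "assess_increased_vascularity",
    "assign_kaiser_score",
    "adjust_score",
    "translate_to_birads",
    "validate_tree",
    "all_feature_combinations",
]

CURVE_TYPES = ("persistent", "plateau", "washout")
MARGINS = ("circumscribed", "not_circumscribed")
INTERNAL_PATTERNS = ("homogeneous", "inhomogeneous")

#: Synonyms accepted on ingest (case-insensitive); canonical value on the right.
_MARGIN_ALIASES = {
    "circumscribed": "circumscribed",
    "not_circumscribed": "not_circumscribed",
    "irregular": "not_circumscribed",
    "spiculated": "not_circumscribed",
}

MIN_SCORE = 1
MAX_SCORE = 11
UPGRADE_POINTS = 3
UPGRADE_MAX_KS = 7  # only lesions scoring <= 7 are eligible for the upgrade

VESSEL_MIN_LENGTH_MM = 30.0  # ">= 3 cm"
VESSEL_MIN_DIAMETER_MM = 2.0  # ">= 2 mm"
VASCULARITY_MIN_EXCESS = 2  # ipsilateral minus contralateral count


def _norm_bool(value, field: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("yes", "true", "present", "1"):
            return True
        if v in ("no", "false", "absent", "0"):
            return False
    raise ValueError(f"cannot interpret {value!r} as yes/no for field {field!r}")


def _norm_enum(value: str, allowed: tuple, field: str, aliases: Mapping[str, str] | None = None) -> str:
    v = str(value).strip().lower()
    if aliases is not None:
        v = aliases.get(v, v)
    if v not in allowed:
        raise ValueError(f"illegal value {value!r} for field {field!r}; allowed: {allowed}")
    return v


@dataclass(frozen=True)
class KaiserFeatures:
    """The five flowchart features of a lesion.

    All fields must be set; scoring never tolerates missing states.
    """

    root_sign: bool
    curve_type: str  # persistent | plateau | washout
    margin: str  # circumscribed | not_circumscribed
    internal_enhancement: str  # homogeneous | inhomogeneous
    edema: bool

    def __post_init__(self):
        object.__setattr__(self, "root_sign", _norm_bool(self.root_sign, "root_sign"))
        object.__setattr__(self, "edema", _norm_bool(self.edema, "edema"))
        object.__setattr__(
            self, "curve_type", _norm_enum(self.curve_type, CURVE_TYPES, "curve_type")
        )
        object.__setattr__(
            self, "margin", _norm_enum(self.margin, MARGINS, "margin", _MARGIN_ALIASES)
        )
        object.__setattr__(
            self,
            "internal_enhancement",
            _norm_enum(self.internal_enhancement, INTERNAL_PATTERNS, "internal_enhancement"),
        )

    def key(self) -> tuple:
        return (
            self.root_sign,
            self.curve_type,
            self.margin,
            self.internal_enhancement,
            self.edema,
        )


def all_feature_combinations() -> list[KaiserFeatures]:
    """All 48 legal feature combinations (2 x 3 x 2 x 2 x 2)."""
    return [
        KaiserFeatures(r, c, mg, ie, e)
        for r, c, mg, ie, e in product(
            (False, True), CURVE_TYPES, MARGINS, INTERNAL_PATTERNS, (False, True)
        )
    ]


@dataclass(frozen=True)
class VesselObservation:
    """One vessel measured on the MIP image, in millimetres."""

    length: float
    diameter: float

    def __post_init__(self):
        if not (self.length > 0 and self.diameter > 0):
            raise ValueError(
                f"vessel dimensions must be positive, got length={self.length}, "
                f"diameter={self.diameter}"
            )


@dataclass(frozen=True)
class VascularAssessment:
    """Per-lesion vascular reading: qualifying-vessel counts and the AVS flag."""

    ipsilateral_count: int
    contralateral_count: int
    avs_present: bool

    def __post_init__(self):
        if self.ipsilateral_count < 0 or self.contralateral_count < 0:
            raise ValueError("vessel counts must be non-negative")

    @property
    def increased_vascularity(self) -> bool:
        return assess_increased_vascularity(self.ipsilateral_count, self.contralateral_count)


class TreeValidationError(ValueError):
    """A score tree failed totality / determinism / range validation."""


@dataclass(frozen=True)
class ScoreTree:
    """A total, deterministic map from feature combinations to scores 1..11.

    Internally the tree is stored in path-expanded form: one entry per legal
    feature combination. This makes totality and determinism trivially
    checkable and keeps lookup O(1); the YAML on-disk form (with wildcards)
    is expanded into this representation by :mod:`ksvasc.trees`.
    """

    name: str
    version: str
    leaves: Mapping[tuple, int]  # KaiserFeatures.key() -> score

    def score(self, features: KaiserFeatures) -> int:
        return assign_kaiser_score(features, self)

    def preimage(self, score: int) -> list[KaiserFeatures]:
        """All feature combinations mapped to ``score``."""
        return [f for f in all_feature_combinations() if self.leaves.get(f.key()) == score]

    def reachable_scores(self) -> set[int]:
        return set(self.leaves.values())


@dataclass(frozen=True)
class ScoreResult:
    """Scored lesion: raw KS, adjusted KS*, and the BI-RADS band of KS*."""

    ks: int
    ks_star: int
    increased_vascularity: bool
    avs_present: bool
    birads_band: str

    def __post_init__(self):
        if not (self.ks_star >= self.ks and self.ks_star - self.ks in (0, UPGRADE_POINTS)):
            raise ValueError("ks_star must equal ks or ks + 3")
        if self.ks_star > MAX_SCORE:
            raise ValueError("ks_star out of range")


def qualify_vessel(v: VesselObservation) -> bool:
    """Whether a vessel counts toward breast vascularity.

    Both thresholds are inclusive: length >= 3 cm and diameter >= 2 mm.
    """
    return v.length >= VESSEL_MIN_LENGTH_MM and v.diameter >= VESSEL_MIN_DIAMETER_MM


def count_qualifying_vessels(vessels: Iterable[VesselObservation]) -> int:
    return sum(1 for v in vessels if qualify_vessel(v))


def assess_increased_vascularity(ipsilateral_count: int, contralateral_count: int) -> bool:
    """Increased ipsilateral breast vascularity: >= 2 more qualifying vessels
    on the lesion side than contralaterally (difference of exactly 2 counts)."""
    if ipsilateral_count < 0 or contralateral_count < 0:
        raise ValueError("vessel counts must be non-negative")
    return ipsilateral_count - contralateral_count >= VASCULARITY_MIN_EXCESS


def assign_kaiser_score(f: KaiserFeatures, tree: ScoreTree) -> int:
    """Look up the Kaiser score of a feature combination in a validated tree."""
    try:
        return tree.leaves[f.key()]
    except KeyError:
        raise TreeValidationError(
            f"tree {tree.name!r} does not cover feature combination {f.key()}"
        ) from None


def adjust_score(ks: int, increased_vascularity: bool, avs_present: bool) -> int:
    """Apply the KS* rule.

    KS <= 7 lesions showing increased ipsilateral vascularity *and* a positive
    AVS simultaneously gain 3 points; anything else is unchanged. 7 + 3 = 10,
    so the result never needs clipping.
    """
    if not (MIN_SCORE <= ks <= MAX_SCORE):
        raise ValueError(f"Kaiser score must be in [{MIN_SCORE}, {MAX_SCORE}], got {ks}")
    if ks <= UPGRADE_MAX_KS and increased_vascularity and avs_present:
        return ks + UPGRADE_POINTS
    return ks


def translate_to_birads(score: int) -> str:
    """KS band -> BI-RADS category: 1-4 -> "2/3", 5-7 -> "4", 8-11 -> "5"."""
    if not (MIN_SCORE <= score <= MAX_SCORE):
        raise ValueError(f"score must be in [{MIN_SCORE}, {MAX_SCORE}], got {score}")
    if score <= 4:
        return "2/3"
    if score <= 7:
        return "4"
    return "5"


def score_lesion(
    features: KaiserFeatures, vascular: VascularAssessment, tree: ScoreTree
) -> ScoreResult:
    """Full per-lesion scoring: KS from the tree, then the vascular adjustment."""
    ks = assign_kaiser_score(features, tree)
    inc = vascular.increased_vascularity
    ks_star = adjust_score(ks, inc, vascular.avs_present)
    return ScoreResult(
        ks=ks,
        ks_star=ks_star,
        increased_vascularity=inc,
        avs_present=vascular.avs_present,
        birads_band=translate_to_birads(ks_star),
    )


def validate_tree(tree: ScoreTree) -> list[str]:
    """Validation report: empty list iff the tree is total, deterministic and
    every leaf score is inside [1, 11].

    Determinism of the expanded form is structural (one dict entry per
    combination); duplicate paths are caught at load time, but stray keys
    that are not legal combinations are still reported here.
    """
    findings: list[str] = []
    legal = {f.key() for f in all_feature_combinations()}
    for key in sorted(legal - set(tree.leaves), key=repr):
        findings.append(f"uncovered combination: {key}")
    for key in sorted(set(tree.leaves) - legal, key=repr):
        findings.append(f"unknown combination: {key}")
    for key, score in tree.leaves.items():
        if key in legal and not (MIN_SCORE <= score <= MAX_SCORE):
            findings.append(f"out-of-range leaf score {score} at {key}")
    return findings
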