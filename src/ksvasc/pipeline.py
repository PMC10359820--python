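"""End-to-end orchestration: cohort in, report bundle out.

The pipeline reads (or simulates) a lesion cohort, scores every lesion
(KS from the active flowchart, the vascular adjustment to KS*, the BI-RADS
band), and evaluates both scores the way a diagnostic-accuracy study
reports them:

* reader-agreement kappas for the two vascular signs (intra / inter);
* per-sign, per-subgroup sensitivity / specificity / accuracy / PPV / NPV
  with exact fractions and mass vs non-mass chi-square comparisons;
* per-subgroup AUC (with DeLong CI) for KS and KS*, and the paired DeLong
  test between them;
* an audit of the lesions whose score was upgraded.

Any inconsistency detected on the way (single-class subgroup, undefined
test) is logged at WARNING and reported as missing, never silently fixed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortSpec,
    LesionRecord,
    Reading,
    generate_cohort,
    simulate_second_reader,
)
from .scoring import (
    KaiserFeatures,
    ScoreTree,
    adjust_score,
    assign_kaiser_score,
    translate_to_birads,
)
from .stats import (
    auc_with_ci,
    build_confusion,
    chi2_2x2,
    cohen_kappa,
    confusion_metrics,
    delong_paired_test,
)
from .trees import DEFAULT_TREE_NAME, load_builtin_tree, load_tree

logger = logging.getLogger("ksvasc")

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "REQUIRED_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "score_cohort",
    "dichotomize",
    "upgrade_audit",
    "evaluate_cohort",
    "run_pipeline",
    "bundle_to_json",
]

REQUIRED_COLUMNS = [
    "id",
    "truth",
    "lesion_type",
    "root_sign",
    "curve_type",
    "margin",
    "internal_enhancement",
    "edema",
    "ipsi_vessels",
    "contra_vessels",
    "avs_present",
]
_READER2_COLUMNS = [
    "reader2_increased_vascularity",
    "reader2_avs_present",
    "reader2_root_sign",
    "reader2_curve_type",
    "reader2_margin",
    "reader2_internal_enhancement",
    "reader2_edema",
]
SUBGROUPS = ("all", "mass", "non_mass")


class SchemaError(ValueError):
    """A cohort file does not match the expected schema."""


@dataclass(frozen=True)
class PipelineConfig:
    """What to run: either a cohort CSV path or a simulation spec."""

    cohort_path: str | None = None
    spec: CohortSpec | None = None
    tree: str = DEFAULT_TREE_NAME  # builtin tree name or a YAML/JSON path
    cutoff: int = 4  # "score > cutoff" is called positive
    subgroups: tuple = SUBGROUPS
    simulate_readers: bool = True

    def __post_init__(self):
        if (self.cohort_path is None) == (self.spec is None):
            raise ValueError("exactly one of cohort_path / spec must be given")
        if not 0 <= self.cutoff <= 11:
            raise ValueError("cutoff must be in [0, 11]")
        unknown = set(self.subgroups) - set(SUBGROUPS)
        if unknown:
            raise ValueError(f"unknown subgroups: {sorted(unknown)}")


def resolve_tree(tree: str | ScoreTree) -> ScoreTree:
    if isinstance(tree, ScoreTree):
        return tree
    if tree in ("fixture_t1", "kaiser_reconstructed"):
        return load_builtin_tree(tree)
    return load_tree(tree)


# ---------------------------------------------------------------------------
# cohort CSV I/O

def _yn(flag: bool) -> str:
    return "yes" if flag else "no"


def cohort_to_frame(records: Sequence[LesionRecord]) -> pd.DataFrame:
    rows = []
    has_reader2 = any(r.reader2 is not None for r in records)
    has_ks_drawn = any(r.ks_drawn is not None for r in records)
    for r in records:
        row = {
            "id": r.id,
            "truth": r.truth,
            "lesion_type": r.lesion_type,
            "root_sign": _yn(r.features.root_sign),
            "curve_type": r.features.curve_type,
            "margin": r.features.margin,
            "internal_enhancement": r.features.internal_enhancement,
            "edema": _yn(r.features.edema),
            "ipsi_vessels": r.ipsi_vessels,
            "contra_vessels": r.contra_vessels,
            "avs_present": _yn(r.avs_present),
        }
        if has_ks_drawn:
            row["ks_drawn"] = r.ks_drawn
        if has_reader2:
            r2 = r.reader2
            if r2 is None:
                raise ValueError(f"record {r.id}: reader2 present on some records only")
            row.update(
                {
                    "reader2_increased_vascularity": _yn(r2.increased_vascularity),
                    "reader2_avs_present": _yn(r2.avs_present),
                    "reader2_root_sign": _yn(r2.features.root_sign),
                    "reader2_curve_type": r2.features.curve_type,
                    "reader2_margin": r2.features.margin,
                    "reader2_internal_enhancement": r2.features.internal_enhancement,
                    "reader2_edema": _yn(r2.features.edema),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[LesionRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def _parse_bool(value, column: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in ("yes", "true", "1"):
        return True
    if v in ("no", "false", "0"):
        return False
    raise SchemaError(f"row {row}: cannot interpret {value!r} in column {column!r}")


def _parse_enum(value, allowed, column: str, row: int) -> str:
    v = str(value).strip().lower()
    if column == "margin" and v in ("irregular", "spiculated"):
        v = "not_circumscribed"
    if column == "lesion_type" and v in ("nonmass", "non-mass"):
        v = "non_mass"
    if v not in allowed:
        raise SchemaError(f"row {row}: unknown value {value!r} in column {column!r}")
    return v


def read_cohort_csv(path: str | Path) -> list[LesionRecord]:
    """Read and validate a cohort CSV (schema documented in the README)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise SchemaError(f"duplicate lesion ids: {dupes[:5]}")
    has_reader2 = all(c in df.columns for c in _READER2_COLUMNS)
    records = []
    for i, raw in enumerate(df.to_dict("records")):
        row = i + 2  # 1-based with header line
        features = KaiserFeatures(
            root_sign=_parse_bool(raw["root_sign"], "root_sign", row),
            curve_type=_parse_enum(
                raw["curve_type"], ("persistent", "plateau", "washout"), "curve_type", row
            ),
            margin=_parse_enum(
                raw["margin"], ("circumscribed", "not_circumscribed"), "margin", row
            ),
            internal_enhancement=_parse_enum(
                raw["internal_enhancement"],
                ("homogeneous", "inhomogeneous"),
                "internal_enhancement",
                row,
            ),
            edema=_parse_bool(raw["edema"], "edema", row),
        )
        reader2 = None
        if has_reader2:
            reader2 = Reading(
                increased_vascularity=_parse_bool(
                    raw["reader2_increased_vascularity"], "reader2_increased_vascularity", row
                ),
                avs_present=_parse_bool(raw["reader2_avs_present"], "reader2_avs_present", row),
                features=KaiserFeatures(
                    root_sign=_parse_bool(raw["reader2_root_sign"], "reader2_root_sign", row),
                    curve_type=_parse_enum(
                        raw["reader2_curve_type"],
                        ("persistent", "plateau", "washout"),
                        "reader2_curve_type",
                        row,
                    ),
                    margin=_parse_enum(
                        raw["reader2_margin"],
                        ("circumscribed", "not_circumscribed"),
                        "reader2_margin",
                        row,
                    ),
                    internal_enhancement=_parse_enum(
                        raw["reader2_internal_enhancement"],
                        ("homogeneous", "inhomogeneous"),
                        "reader2_internal_enhancement",
                        row,
                    ),
                    edema=_parse_bool(raw["reader2_edema"], "reader2_edema", row),
                ),
            )
        try:
            ipsi = int(raw["ipsi_vessels"])
            contra = int(raw["contra_vessels"])
        except (TypeError, ValueError):
            raise SchemaError(f"row {row}: vessel counts must be integers") from None
        ks_drawn = raw.get("ks_drawn")
        records.append(
            LesionRecord(
                id=str(raw["id"]),
                truth=_parse_enum(raw["truth"], ("benign", "malignant"), "truth", row),
                lesion_type=_parse_enum(raw["lesion_type"], ("mass", "non_mass"), "lesion_type", row),
                features=features,
                ipsi_vessels=ipsi,
                contra_vessels=contra,
                avs_present=_parse_bool(raw["avs_present"], "avs_present", row),
                ks_drawn=int(ks_drawn) if ks_drawn is not None and str(ks_drawn) != "nan" else None,
                reader2=reader2,
            )
        )
    return records


# ---------------------------------------------------------------------------
# scoring and evaluation

def score_cohort(records: Sequence[LesionRecord], tree: ScoreTree) -> pd.DataFrame:
    """One row per lesion with truth, subgroup, signs, ks, ks_star, birads."""
    rows = []
    for r in records:
        ks = assign_kaiser_score(r.features, tree)
        inc = r.increased_vascularity
        ks_star = adjust_score(ks, inc, r.avs_present)
        rows.append(
            {
                "id": r.id,
                "truth": r.truth,
                "lesion_type": r.lesion_type,
                "increased_vascularity": inc,
                "avs_present": r.avs_present,
                "ks": ks,
                "ks_star": ks_star,
                "birads": translate_to_birads(ks_star),
            }
        )
    return pd.DataFrame(rows)


def dichotomize(scores, cutoff: int) -> np.ndarray:
    """Positive iff score > cutoff (strict, the study's ">4" convention)."""
    return np.asarray(scores) > cutoff


def _subgroup_mask(df: pd.DataFrame, subgroup: str) -> np.ndarray:
    if subgroup == "all":
        return np.ones(len(df), dtype=bool)
    return (df["lesion_type"] == subgroup).to_numpy()


def upgrade_audit(scored: pd.DataFrame, cutoff: int) -> dict:
    """Cross-tab of lesions whose score was upgraded, by truth and lesion
    type, plus the subset whose dichotomous call crossed the cutoff."""
    up = scored[scored["ks_star"] != scored["ks"]]
    audit = {
        "n_upgraded": int(len(up)),
        "by_truth_and_type": {
            truth: {
                ltype: int(((up["truth"] == truth) & (up["lesion_type"] == ltype)).sum())
                for ltype in ("mass", "non_mass")
            }
            for truth in ("malignant", "benign")
        },
        "crossed_cutoff": {
            truth: int(
                (
                    (up["truth"] == truth)
                    & (up["ks"] <= cutoff)
                    & (up["ks_star"] > cutoff)
                ).sum()
            )
            for truth in ("malignant", "benign")
        },
    }
    return audit


_SIGN_COLUMNS = {
    "increased_vascularity": "increased_vascularity",
    "avs": "avs_present",
    "both_signs": None,  # conjunction, filled below
}


def _sign_vector(df: pd.DataFrame, sign: str) -> np.ndarray:
    if sign == "both_signs":
        return (df["increased_vascularity"] & df["avs_present"]).to_numpy()
    return df[_SIGN_COLUMNS[sign]].to_numpy()


def _metric_tables(metrics_by_group: dict, metric: str) -> np.ndarray | None:
    """2x2 table (mass row, non_mass row) x (hits, misses) for one metric."""
    rows = []
    for grp in ("mass", "non_mass"):
        m = metrics_by_group.get(grp)
        if m is None:
            return None
        met = getattr(m, metric)
        if not met.defined:
            return None
        rows.append([met.numerator, met.denominator - met.numerator])
    return np.array(rows)


def evaluate_cohort(
    records: Sequence[LesionRecord],
    tree: ScoreTree,
    cutoff: int = 4,
    subgroups: Sequence[str] = SUBGROUPS,
    intra_readings: Sequence[Reading] | None = None,
) -> dict:
    """Score a cohort and assemble the full report bundle (a plain dict)."""
    scored = score_cohort(records, tree)
    truth = (scored["truth"] == "malignant").to_numpy()
    bundle: dict = {
        "meta": {
            "n": int(len(scored)),
            "tree": {"name": tree.name, "version": tree.version},
            "cutoff": cutoff,
            "positive_rule": f"score > {cutoff}",
        }
    }

    # --- reader agreement (kappa) -------------------------------------
    kappas: dict = {}
    inter = {}
    if all(r.reader2 is not None for r in records) and len(records) >= 2:
        r1v = [r.increased_vascularity for r in records]
        r2v = [r.reader2.increased_vascularity for r in records]
        r1a = [r.avs_present for r in records]
        r2a = [r.reader2.avs_present for r in records]
        inter = {
            "increased_vascularity": _kappa_dict(cohen_kappa(r1v, r2v)),
            "avs": _kappa_dict(cohen_kappa(r1a, r2a)),
        }
    elif any(r.reader2 is not None for r in records):
        logger.warning("reader2 present on only some records; inter-reader kappa skipped")
    if inter:
        kappas["inter"] = inter
    if intra_readings is not None and len(records) >= 2:
        kappas["intra"] = {
            "increased_vascularity": _kappa_dict(
                cohen_kappa(
                    [r.increased_vascularity for r in records],
                    [rd.increased_vascularity for rd in intra_readings],
                )
            ),
            "avs": _kappa_dict(
                cohen_kappa(
                    [r.avs_present for r in records],
                    [rd.avs_present for rd in intra_readings],
                )
            ),
        }
    bundle["reader_agreement"] = kappas

    # --- per-sign diagnostic metrics ------------------------------------
    signs_out: dict = {}
    for sign in ("increased_vascularity", "avs", "both_signs"):
        pred = _sign_vector(scored, sign)
        per_group: dict = {}
        metric_objs: dict = {}
        for grp in subgroups:
            mask = _subgroup_mask(scored, grp)
            if truth[mask].all() or (~truth[mask]).all():
                logger.warning("subgroup %r has a single truth class; metrics skipped", grp)
                continue
            mset = confusion_metrics(build_confusion(pred[mask], truth[mask]))
            metric_objs[grp] = mset
            per_group[grp] = mset.as_dict()
        comparisons = {}
        for metric in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            table = _metric_tables(metric_objs, metric)
            if table is None:
                continue
            try:
                cmp_res = chi2_2x2(table)
                comparisons[metric] = {"chi2": cmp_res.chi2, "p": cmp_res.p}
            except ValueError as exc:
                logger.warning("chi-square undefined for %s/%s: %s", sign, metric, exc)
        signs_out[sign] = {"metrics": per_group, "mass_vs_non_mass": comparisons}
    bundle["sign_metrics"] = signs_out

    # --- AUC comparison KS vs KS* ---------------------------------------
    auc_out: dict = {}
    for grp in subgroups:
        mask = _subgroup_mask(scored, grp)
        t = truth[mask]
        if t.sum() < 2 or (~t).sum() < 2:
            logger.warning("subgroup %r lacks two cases per class; AUC row skipped", grp)
            continue
        ks = scored.loc[mask, "ks"].to_numpy()
        ks_star = scored.loc[mask, "ks_star"].to_numpy()
        est_ks = auc_with_ci(ks, t)
        est_star = auc_with_ci(ks_star, t)
        paired = delong_paired_test(ks_star, ks, t)
        auc_out[grp] = {
            "ks": _auc_dict(est_ks),
            "ks_star": _auc_dict(est_star),
            "delong": {"z": paired.z, "p": paired.p},
        }
    bundle["auc_comparison"] = auc_out

    bundle["upgrade_audit"] = upgrade_audit(scored, cutoff)

    # operating point of both scores at the active cutoff
    op = {}
    for name, col in (("ks", "ks"), ("ks_star", "ks_star")):
        mset = confusion_metrics(
            build_confusion(dichotomize(scored[col].to_numpy(), cutoff), truth)
        )
        op[name] = mset.as_dict()
    bundle["operating_point"] = op
    return bundle


def _kappa_dict(k) -> dict:
    return {"kappa": k.kappa, "se": k.se, "ci95": list(k.ci95), "band": k.band}


def _auc_dict(est) -> dict:
    return {"auc": est.auc, "se": est.se, "ci95": list(est.ci95)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Resolve the input, score, evaluate; deterministic under a fixed seed."""
    tree = resolve_tree(config.tree)
    intra = None
    if config.spec is not None:
        records = generate_cohort(config.spec, tree)
        if config.simulate_readers:
            # independent streams for the second reader and the re-read,
            # both derived from the cohort seed
            records = simulate_second_reader(
                records, config.spec.reader_flip, np.random.default_rng(config.spec.seed + 1)
            )
            intra = [
                r.reader2
                for r in simulate_second_reader(
                    records,
                    config.spec.reader_flip_intra,
                    np.random.default_rng(config.spec.seed + 2),
                )
            ]
    else:
        records = read_cohort_csv(config.cohort_path)
    bundle = evaluate_cohort(
        records, tree, cutoff=config.cutoff, subgroups=config.subgroups, intra_readings=intra
    )
    if config.spec is not None:
        bundle["meta"]["seed"] = config.spec.seed
    else:
        bundle["meta"]["source"] = str(config.cohort_path)
    return bundle


def replicate_study(
    spec: CohortSpec,
    tree: str | ScoreTree = DEFAULT_TREE_NAME,
    n_replicates: int = 200,
) -> pd.DataFrame:
    """Simulation study: regenerate the cohort ``n_replicates`` times
    (replicate k uses seed ``spec.seed + k``) and collect, per replicate,
    AUC(KS), AUC(KS*), the paired DeLong p and the upgrade audit.

    Replicates where a class has fewer than two members are skipped with a
    warning (cannot happen at the default sizes)."""
    from dataclasses import replace as _replace

    tree = resolve_tree(tree)
    rows = []
    for k in range(n_replicates):
        rep_spec = _replace(spec, seed=spec.seed + k)
        records = generate_cohort(rep_spec, tree)
        scored = score_cohort(records, tree)
        t = (scored["truth"] == "malignant").to_numpy()
        if t.sum() < 2 or (~t).sum() < 2:
            logger.warning("replicate %d skipped: single-class cohort", k)
            continue
        ks = scored["ks"].to_numpy()
        ks_star = scored["ks_star"].to_numpy()
        paired = delong_paired_test(ks_star, ks, t)
        up = scored[scored["ks_star"] != scored["ks"]]
        rows.append(
            {
                "replicate": k,
                "seed": rep_spec.seed,
                "auc_ks": paired.auc2,
                "auc_ks_star": paired.auc1,
                "delong_p": paired.p,
                "n_upgraded": int(len(up)),
                "n_upgraded_malignant": int((up["truth"] == "malignant").sum()),
                "n_malignant": int(t.sum()),
            }
        )
    return pd.DataFrame(rows)


def bundle_to_json(bundle: dict) -> str:
    """Canonical JSON serialisation (sorted keys) — byte-stable for a fixed
    config and seed."""
    return json.dumps(bundle, sort_keys=True, indent=2) + "\n"
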