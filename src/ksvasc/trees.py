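"""Loading and serialising score trees.

On disk a tree is YAML (or JSON — a subset of YAML): a ``name``, a
``version`` and a list of ``paths``. Each path fixes some of the five
features and may leave others as the wildcard ``"*"``; the loader expands
wildcards into explicit feature combinations, rejects combinations claimed
by two paths (non-determinism) and re-validates the expanded tree.

Two trees ship with the package::

    tree_fixture_t1.yaml           fixture tree bound by the unit tests
    tree_kaiser_reconstructed.yaml synthetic Kaiser-style default flowchart
"""

from __future__ import annotations

from importlib import resources
from itertools import product
from pathlib import Path

import yaml

from .scoring import (
    CURVE_TYPES,
    INTERNAL_PATTERNS,
    MARGINS,
    ScoreTree,
    TreeValidationError,
    validate_tree,
)

__all__ = [
    "load_tree",
    "load_builtin_tree",
    "dump_tree",
    "BUILTIN_TREES",
    "DEFAULT_TREE_NAME",
    "FIXTURE_TREE_NAME",
]

BUILTIN_TREES = {
    "fixture_t1": "tree_fixture_t1.yaml",
    "kaiser_reconstructed": "tree_kaiser_reconstructed.yaml",
}
FIXTURE_TREE_NAME = "fixture_t1"
DEFAULT_TREE_NAME = "kaiser_reconstructed"

_WILDCARD = "*"

_FIELD_VALUES = {
    "root_sign": (False, True),
    "curve_type": CURVE_TYPES,
    "margin": MARGINS,
    "internal_enhancement": INTERNAL_PATTERNS,
    "edema": (False, True),
}
_BOOL_MAP = {
    "yes": True, "no": False, "true": True, "false": False,
    True: True, False: False,
}


def _path_values(field: str, raw) -> tuple:
    """Concrete values a path entry stands for (singleton unless wildcard)."""
    if isinstance(raw, str) and raw.strip() == _WILDCARD:
        return _FIELD_VALUES[field]
    if field in ("root_sign", "edema"):
        key = raw.strip().lower() if isinstance(raw, str) else raw
        if key not in _BOOL_MAP:
            raise TreeValidationError(f"bad value {raw!r} for {field}")
        return (_BOOL_MAP[key],)
    value = str(raw).strip().lower()
    if value == "irregular" or value == "spiculated":
        value = "not_circumscribed"
    if value not in _FIELD_VALUES[field]:
        raise TreeValidationError(f"bad value {raw!r} for {field}")
    return (value,)


def _expand_paths(paths: list[dict]) -> dict[tuple, int]:
    leaves: dict[tuple, int] = {}
    fields = ("root_sign", "curve_type", "margin", "internal_enhancement", "edema")
    for i, path in enumerate(paths):
        missing = [f for f in fields if f not in path]
        if missing or "score" not in path:
            raise TreeValidationError(
                f"path {i} missing fields: {missing + (['score'] if 'score' not in path else [])}"
            )
        score = int(path["score"])
        for combo in product(*(_path_values(f, path[f]) for f in fields)):
            if combo in leaves:
                raise TreeValidationError(
                    f"non-deterministic tree: combination {combo} reached by "
                    f"two paths (scores {leaves[combo]} and {score})"
                )
            leaves[combo] = score
    return leaves


def load_tree(source: str | Path | dict) -> ScoreTree:
    """Load, expand and validate a score tree from YAML/JSON or a dict."""
    if isinstance(source, dict):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, dict) or "paths" not in doc:
        raise TreeValidationError("tree document must be a mapping with a 'paths' list")
    tree = ScoreTree(
        name=str(doc.get("name", "unnamed")),
        version=str(doc.get("version", "0")),
        leaves=_expand_paths(doc["paths"]),
    )
    findings = validate_tree(tree)
    if findings:
        raise TreeValidationError(
            f"tree {tree.name!r} invalid: " + "; ".join(findings[:5])
            + ("" if len(findings) <= 5 else f" (+{len(findings) - 5} more)")
        )
    return tree


def load_builtin_tree(name: str = DEFAULT_TREE_NAME) -> ScoreTree:
    try:
        filename = BUILTIN_TREES[name]
    except KeyError:
        raise KeyError(f"unknown builtin tree {name!r}; available: {sorted(BUILTIN_TREES)}")
    ref = resources.files("ksvasc.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return load_tree(path)


def dump_tree(tree: ScoreTree, path: str | Path) -> None:
    """Serialise a tree in fully expanded path form (no wildcards)."""
    paths = []
    for key in sorted(tree.leaves, key=repr):
        root, curve, margin, internal, edema = key
        paths.append(
            {
                "root_sign": "yes" if root else "no",
                "curve_type": curve,
                "margin": margin,
                "internal_enhancement": internal,
                "edema": "yes" if edema else "no",
                "score": int(tree.leaves[key]),
            }
        )
    doc = {"name": tree.name, "version": tree.version, "paths": paths}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
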