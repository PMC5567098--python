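"""Tree serialization (JSON) and indented Y/N text reports.

The text format mirrors the published tree figures: each internal node
prints its rule as a question, the ``Y`` branch is the affirmative (left)
answer, and leaves print the payload — a hazard ratio to two decimals for
survival trees, a graft-failure percentage to one decimal for classification
trees.
"""

from __future__ import annotations

import json

from .._split import SplitCandidate
from .classification import ClassNode, GiniTreeClassifier
from .survival import SurvivalNode, SurvivalTree

__all__ = ["tree_to_dict", "tree_from_dict", "tree_to_json", "tree_from_json", "render_text"]

_SURV_FIELDS = ("n", "event_sum", "time_sum", "rate", "deviance", "hr", "hr_smooth")
_CLASS_FIELDS = ("n", "weight", "fraction", "gini")


def _split_to_dict(split: SplitCandidate | None, names):
    if split is None:
        return None
    return {
        "feature": names[split.feature],
        "feature_index": split.feature,
        "threshold": split.threshold,
        "left_categories": (sorted(split.left_categories, key=str)
                            if split.left_categories is not None else None),
        "gain": split.gain,
    }


def _split_from_dict(d):
    if d is None:
        return None
    cats = d["left_categories"]
    return SplitCandidate(d["feature_index"], d["threshold"],
                          frozenset(cats) if cats is not None else None, d["gain"])


def _node_to_dict(node, fields, names):
    out = {f: getattr(node, f) for f in fields}
    out.update(depth=node.depth, improvement=node.improvement,
               majority_left=node.majority_left,
               split=_split_to_dict(node.split, names))
    if not node.is_leaf:
        out["left"] = _node_to_dict(node.left, fields, names)
        out["right"] = _node_to_dict(node.right, fields, names)
    return out


def _node_from_dict(d, cls, fields):
    node = cls(**{f: d[f] for f in fields})
    node.depth = d["depth"]
    node.improvement = d["improvement"]
    node.majority_left = d["majority_left"]
    node.split = _split_from_dict(d["split"])
    if "left" in d:
        node.left = _node_from_dict(d["left"], cls, fields)
        node.right = _node_from_dict(d["right"], cls, fields)
    return node


def tree_to_dict(tree) -> dict:
    if isinstance(tree, SurvivalTree):
        kind, fields = "survival", _SURV_FIELDS
    elif isinstance(tree, GiniTreeClassifier):
        kind, fields = "classification", _CLASS_FIELDS
    else:
        raise TypeError(f"unsupported tree type {type(tree).__name__}")
    return {
        "kind": kind,
        "params": tree.get_params(),
        "feature_names": list(tree.feature_names_in_),
        "root": _node_to_dict(tree.root_, fields, tree.feature_names_in_),
    }


def tree_from_dict(d: dict):
    params = {k: v for k, v in d["params"].items() if k != "random_state"}
    if d["kind"] == "survival":
        est = SurvivalTree(**params)
        est.root_ = _node_from_dict(d["root"], SurvivalNode, _SURV_FIELDS)
        est.warnings_ = []
    elif d["kind"] == "classification":
        est = GiniTreeClassifier(**params)
        est.root_ = _node_from_dict(d["root"], ClassNode, _CLASS_FIELDS)
    else:
        raise ValueError(f"unknown tree kind {d['kind']!r}")
    est.feature_names_in_ = list(d["feature_names"])
    est.n_features_in_ = len(est.feature_names_in_)
    return est


def tree_to_json(tree, path=None) -> str:
    text = json.dumps(tree_to_dict(tree), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def tree_from_json(source):
    try:
        d = json.loads(source)
    except (TypeError, ValueError):
        with open(source) as fh:
            d = json.load(fh)
    return tree_from_dict(d)


def _leaf_label(node):
    if isinstance(node, SurvivalNode):
        return f"HR = {node.hr:.2f}"
    return f"GF = {100.0 * node.fraction:.1f}%"


def _question(split, names):
    name = names[split.feature]
    if split.is_categorical:
        cats = sorted(split.left_categories, key=str)
        inside = cats[0] if len(cats) == 1 else "{" + ", ".join(map(str, cats)) + "}"
        return f"{name} in {inside}?" if len(cats) > 1 else f"{name} = {inside}?"
    return f"{name} <= {split.threshold:.6g}?"


def _render(node, names, indent, lines):
    pad = "  " * indent
    if node.is_leaf:
        lines.append(f"{pad}{_leaf_label(node)} (n = {node.n})")
        return
    lines.append(f"{pad}{_question(node.split, names)}")
    lines.append(f"{pad}Y:")
    _render(node.left, names, indent + 1, lines)
    lines.append(f"{pad}N:")
    _render(node.right, names, indent + 1, lines)


def render_text(tree) -> str:
    """Indented Y/N rule listing of a fitted tree."""
    lines: list[str] = []
    _render(tree.root_, tree.feature_names_in_, 0, lines)
    return "\n".join(lines)
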