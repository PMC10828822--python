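"""Empirical peptide classes of homogeneous fragmentation efficiency.

Reporter-ion yield per unit of precursor ion current varies strongly across
peptides; much of that variance is explained by a handful of physicochemical
properties (charge state, number of TMT labels, presence of H/R/K/E/D, an
unexplained extra positive charge).  A greedy binary decision tree groups
PSMs into classes that minimize within-class variance of the log
fragmentation-efficiency response, subject to a minimum leaf occupancy.
The classes are refit for every dataset; they are not portable between
instruments or gradients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io import PsmRecord

MIN_LEAF = 100
#: a split must remove at least this fraction of the root sum of squares
MIN_GAIN = 0.01

#: fixed variable order used for tie-breaking among equal-variance splits
BASE_VARIABLES = ("Charge", "Labels", "H", "R", "K", "E", "D", "Extra")
ORDINAL_VARIABLES = {"Charge", "Labels"}


@dataclass(frozen=True)
class PeptideFeatures:
    charge_cat: int  # 1, 2, or 3; charges above 3 collapse to 3
    n_labels: int
    has_H: bool
    has_R: bool
    has_K: bool
    has_E: bool
    has_D: bool
    extra_charge: bool
    mod_flags: tuple[tuple[str, bool], ...] = ()

    def as_dict(self) -> dict[str, float | bool]:
        d: dict[str, float | bool] = {
            "Charge": self.charge_cat,
            "Labels": self.n_labels,
            "H": self.has_H,
            "R": self.has_R,
            "K": self.has_K,
            "E": self.has_E,
            "D": self.has_D,
            "Extra": self.extra_charge,
        }
        d.update(self.mod_flags)
        return d


def featurize(psm: PsmRecord, mod_features: Sequence[str] = ()) -> PeptideFeatures:
    """Map one PSM to the tree's feature vector.

    TMT labels are counted from the modification list (any token containing
    "TMT"); the extra-charge flag fires when the charge exceeds the
    allowance of one N-terminal proton plus one per arginine and histidine.
    ``mod_features`` lists variable-modification names to expose as
    additional boolean features.
    """
    if psm.charge < 1:
        raise ConfigurationError(f"PSM {psm.ms2_scan}: charge must be >= 1")
    seq = psm.sequence.upper()
    if not seq.isalpha():
        raise ConfigurationError(f"unparseable sequence {psm.sequence!r}")
    mod_names = [name for _, name in psm.modifications]
    n_labels = sum("tmt" in name.lower() for name in mod_names)
    allowance = seq.count("R") + seq.count("H") + 1
    flags = tuple(
        (f"mod:{m}", any(name == m for name in mod_names)) for m in mod_features
    )
    return PeptideFeatures(
        charge_cat=min(psm.charge, 3),
        n_labels=n_labels,
        has_H="H" in seq,
        has_R="R" in seq,
        has_K="K" in seq,
        has_E="E" in seq,
        has_D="D" in seq,
        extra_charge=psm.charge > allowance,
        mod_flags=flags,
    )


def fragmentation_response(total_reporter: float, pic: float, ppf: float) -> float | None:
    """log of reporter yield per precursor ion current, the tree's response."""
    denom = pic * ppf
    if total_reporter <= 0 or denom <= 0:
        return None
    return math.log(total_reporter / denom)


# ---------------------------------------------------------------------------
@dataclass
class TreeNode:
    n: int
    ss: float
    variable: str | None = None
    threshold: float | None = None  # ordinal split: value <= threshold goes left
    level: bool | None = None  # boolean split: value == level goes left
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass
class ClassTree:
    root: TreeNode
    min_leaf: int
    variables: tuple[str, ...]

    @property
    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])  # type: ignore[list-item]
        return out

    def to_dict(self) -> dict:
        def encode(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"label": node.label, "n": node.n}
            return {
                "variable": node.variable,
                "threshold": node.threshold,
                "level": node.level,
                "n": node.n,
                "left": encode(node.left),  # type: ignore[arg-type]
                "right": encode(node.right),  # type: ignore[arg-type]
            }

        return {"min_leaf": self.min_leaf, "variables": list(self.variables), "tree": encode(self.root)}


def _ss(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    return float(np.sum((y - y.mean()) ** 2))


def _split_description(variable: str, threshold, level) -> tuple[str, str]:
    if threshold is not None:
        return f"{variable}<={threshold:g}", f"{variable}>{threshold:g}"
    return (f"{variable}+", f"{variable}-") if level else (f"{variable}-", f"{variable}+")


def fit_class_tree(
    responses: Sequence[float],
    features: Sequence[PeptideFeatures],
    min_leaf: int = MIN_LEAF,
    min_gain: float = MIN_GAIN,
) -> ClassTree:
    """Grow the greedy variance-minimizing tree.

    At each node every admissible binary split over every feature variable
    is evaluated; the split minimizing the summed within-child sum of
    squares wins, with ties broken by the fixed variable order and then the
    smaller threshold.  Splits leaving a child with <= ``min_leaf`` PSMs
    are rejected, as are splits removing less than ``min_gain`` of the root
    sum of squares (which keeps sampling noise from growing spurious
    leaves).  Growth stops when no admissible split remains.
    """
    y = np.asarray(responses, dtype=float)
    if len(y) != len(features):
        raise ConfigurationError("responses and features must align")
    ok = np.isfinite(y)
    if not ok.all():
        raise ConfigurationError("responses must be finite; filter beforehand")
    feature_dicts = [f.as_dict() for f in features]
    variables = tuple(BASE_VARIABLES) + tuple(
        sorted(k for k in feature_dicts[0] if k.startswith("mod:"))
    )
    cols = {v: np.asarray([d[v] for d in feature_dicts]) for v in variables}

    if len(y) < 2 * min_leaf:
        warnings.warn(
            f"only {len(y)} PSMs (< {2 * min_leaf}); fitting a single-class tree"
        )
        root = TreeNode(n=len(y), ss=_ss(y), label="all")
        return ClassTree(root=root, min_leaf=min_leaf, variables=variables)

    root_ss = _ss(y)
    gain_floor = min_gain * root_ss

    def grow(idx: np.ndarray, path: str) -> TreeNode:
        node_y = y[idx]
        node = TreeNode(n=len(idx), ss=_ss(node_y))
        best = None  # (child_ss_sum, var_order, threshold_order, descr, mask)
        for order, var in enumerate(variables):
            col = cols[var][idx]
            if var in ORDINAL_VARIABLES:
                candidates = [(float(t), None) for t in np.unique(col)[:-1]]
            else:
                candidates = [(None, True)] if len(np.unique(col)) > 1 else []
            for threshold, level in candidates:
                mask = (col <= threshold) if threshold is not None else (col == level)
                n_left = int(mask.sum())
                if n_left <= min_leaf or len(idx) - n_left <= min_leaf:
                    continue
                child_ss = _ss(node_y[mask]) + _ss(node_y[~mask])
                if node.ss - child_ss <= gain_floor:
                    continue
                key = (child_ss, order, threshold if threshold is not None else 0.0)
                if best is None or key < best[0]:
                    best = (key, var, threshold, level, mask)
        if best is None:
            node.label = path or "all"
            return node
        _, var, threshold, level, mask = best
        left_desc, right_desc = _split_description(var, threshold, level)
        node.variable, node.threshold, node.level = var, threshold, level
        prefix = f"{path}/" if path else ""
        node.left = grow(idx[mask], f"{prefix}{left_desc}")
        node.right = grow(idx[~mask], f"{prefix}{right_desc}")
        return node

    root = grow(np.arange(len(y)), "")
    return ClassTree(root=root, min_leaf=min_leaf, variables=variables)


def assign_class(tree: ClassTree, features: PeptideFeatures) -> str:
    """Deterministically route a feature vector to its leaf label."""
    d = features.as_dict()
    node = tree.root
    while not node.is_leaf:
        value = d.get(node.variable, False)
        goes_left = (
            value <= node.threshold if node.threshold is not None else value == node.level
        )
        node = node.left if goes_left else node.right  # type: ignore[assignment]
    return node.label  # type: ignore[return-value]
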