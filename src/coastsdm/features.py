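"""MaxEnt-style feature expansions of environmental variables.

Variables are rescaled to [0, 1] by their training range, then expanded
into linear, quadratic, product, threshold and hinge features.  Feature
metadata records which underlying variable(s) each column derives from so
that jackknife and contribution analyses can attribute model structure
back to the predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = ["FeatureSpec", "Feature", "build_features", "CLASS_COMBOS"]

FEATURE_CLASSES = ("linear", "quadratic", "product", "threshold", "hinge")

#: the tuning grid's feature-class combinations, in the conventional
#: shorthand (l = linear, q = quadratic, h = hinge, p = product,
#: t = threshold)
CLASS_COMBOS = {
    "l": ("linear",),
    "lq": ("linear", "quadratic"),
    "lqh": ("linear", "quadratic", "hinge"),
    "lqhp": ("linear", "quadratic", "hinge", "product"),
    "lqpt": ("linear", "quadratic", "product", "threshold"),
    "lqhpt": ("linear", "quadratic", "hinge", "product", "threshold"),
}


@dataclass
class FeatureSpec:
    """Feature classes, knot counts and per-variable training ranges."""

    classes: tuple[str, ...] = ("linear", "quadratic")
    hinge_knots: int = 50
    threshold_knots: int = 50
    variable_ranges: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.classes, str):
            self.classes = CLASS_COMBOS[self.classes]
        self.classes = tuple(self.classes)
        if not self.classes:
            raise ValueError("at least one feature class is required")
        unknown = set(self.classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "hinge" in self.classes and self.hinge_knots < 2:
            raise ValueError("hinge_knots must be >= 2")
        if "threshold" in self.classes and self.threshold_knots < 2:
            raise ValueError("threshold_knots must be >= 2")

    def set_ranges(self, variables: Sequence[int], env: np.ndarray) -> None:
        """Record per-variable (min, max) from the training matrix."""
        env = np.asarray(env, dtype=float)
        for j, v in enumerate(variables):
            self.variable_ranges[v] = (float(env[:, j].min()), float(env[:, j].max()))


@dataclass(frozen=True)
class Feature:
    """One design-matrix column: its class, variables, and knot if any."""

    cls: str
    variables: tuple[int, ...]
    knot: float | None = None
    direction: str | None = None  # hinge: "forward" | "reverse"

    @property
    def name(self) -> str:
        v = "x".join(f"bio{i}" for i in self.variables)
        if self.cls == "linear":
            return v
        if self.cls == "quadratic":
            return f"{v}^2"
        if self.cls == "product":
            return v
        if self.cls == "threshold":
            return f"thr({v},{self.knot:.4g})"
        return f"hinge_{self.direction[0]}({v},{self.knot:.4g})"


def rescale(
    env: np.ndarray,
    variables: Sequence[int],
    ranges: dict[int, tuple[float, float]],
    clamp: bool = False,
) -> np.ndarray:
    """Map raw variables onto [0, 1] by their training range.

    With ``clamp``, values beyond the training range are pinned to it
    before scaling, so projected features never extrapolate.
    Constant variables map to 0.
    """
    env = np.asarray(env, dtype=float)
    out = np.empty_like(env)
    for j, v in enumerate(variables):
        lo, hi = ranges[v]
        if hi == lo:
            out[:, j] = 0.0
            continue
        x = env[:, j]
        if clamp:
            x = np.clip(x, lo, hi)
        out[:, j] = (x - lo) / (hi - lo)
    return out


def feature_list(variables: Sequence[int], spec: FeatureSpec) -> list[Feature]:
    """Enumerate the design-matrix columns for a variable set and spec.

    Nonlinear features of constant variables (training max == min) are
    skipped with a warning; their linear column is kept (it is identically
    zero after rescaling and attracts no coefficient).
    """
    constant = {
        v
        for v in variables
        if v in spec.variable_ranges
        and spec.variable_ranges[v][0] == spec.variable_ranges[v][1]
    }
    if constant:
        warnings.warn(
            f"variables {sorted(constant)} are constant in training; "
            "their nonlinear features are skipped",
            stacklevel=2,
        )
    feats: list[Feature] = []
    if "linear" in spec.classes:
        feats += [Feature("linear", (v,)) for v in variables]
    if "quadratic" in spec.classes:
        feats += [Feature("quadratic", (v,)) for v in variables if v not in constant]
    if "product" in spec.classes:
        feats += [
            Feature("product", (a, b))
            for a, b in combinations(variables, 2)
            if a not in constant and b not in constant
        ]
    if "threshold" in spec.classes:
        knots = np.linspace(0.0, 1.0, spec.threshold_knots + 2)[1:-1]
        feats += [
            Feature("threshold", (v,), knot=float(k))
            for v in variables
            if v not in constant
            for k in knots
        ]
    if "hinge" in spec.classes:
        knots = np.linspace(0.0, 1.0, spec.hinge_knots)
        feats += [
            Feature("hinge", (v,), knot=float(k), direction="forward")
            for v in variables
            if v not in constant
            for k in knots[:-1]
        ]
        feats += [
            Feature("hinge", (v,), knot=float(k), direction="reverse")
            for v in variables
            if v not in constant
            for k in knots[1:]
        ]
    return feats


def build_features(
    env: np.ndarray,
    variables: Sequence[int],
    spec: FeatureSpec,
    clamp: bool = False,
    feats: list[Feature] | None = None,
) -> tuple[np.ndarray, list[Feature]]:
    """Evaluate the feature expansion on an (n, n_vars) environment matrix.

    Returns the (n, n_features) design matrix and the feature metadata.
    ``variables`` names the columns of ``env`` (BIO indices); the training
    ranges must already be present in ``spec.variable_ranges``.
    """
    missing = [v for v in variables if v not in spec.variable_ranges]
    if missing:
        raise ValueError(f"no training range recorded for variables {missing}")
    z = rescale(env, variables, spec.variable_ranges, clamp=clamp)
    col = {v: z[:, j] for j, v in enumerate(variables)}
    if feats is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = feature_list(variables, spec)
    cols = np.empty((z.shape[0], len(feats)))
    for i, f in enumerate(feats):
        if f.cls == "linear":
            cols[:, i] = col[f.variables[0]]
        elif f.cls == "quadratic":
            cols[:, i] = col[f.variables[0]] ** 2
        elif f.cls == "product":
            cols[:, i] = col[f.variables[0]] * col[f.variables[1]]
        elif f.cls == "threshold":
            cols[:, i] = (col[f.variables[0]] > f.knot).astype(float)
        elif f.cls == "hinge":
            x = col[f.variables[0]]
            k = f.knot
            if f.direction == "forward":
                cols[:, i] = np.maximum(0.0, (x - k) / (1.0 - k))
            else:
                cols[:, i] = np.maximum(0.0, (k - x) / k)
    return cols, feats
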