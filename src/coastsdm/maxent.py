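"""Presence-only maximum-entropy species distribution model.

The model is the Gibbs distribution over landscape cells

    q_beta(z) ∝ exp(eta(z)),    eta(z) = sum_j beta_j f_j(z),

whose coefficients maximize the L1-penalized presence log-likelihood

    J(beta) = mean_presences eta(x)
              - log( mean_background exp(eta(z)) )
              - sum_j reg_j |beta_j|,

a concave objective solved here by monotone proximal-gradient ascent with
soft thresholding and backtracking line search.  Per-feature penalties
reg_j follow the MaxEnt default schedule: a feature-class base level
interpolated by presence count, scaled by the feature's spread over the
presences and shrunk as 1/sqrt(m), all inflated by a user-chosen
regularization multiplier.

Output follows the cloglog convention: with H the entropy of the fitted
background distribution and raw(z) = exp(eta(z) - alpha) normalized so the
background raw values sum to one, suitability is

    p(z) = 1 - exp( -exp(H) * raw(z) ),

a value in [0, 1] read as probability of presence.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .bioclim import BioclimStack
from .features import Feature, FeatureSpec, build_features, feature_list
from .grids import RasterGrid

__all__ = [
    "MaxentModel",
    "FitTrace",
    "sample_background",
    "fit",
    "predict",
    "min_training_presence",
]

log = logging.getLogger(__name__)

# presence-count breakpoints -> base penalty, per feature class
_REG_SCHEDULE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "product": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "threshold": ([0, 100], [2.0, 1.0]),
}
_MIN_FEATURE_SD = 1e-3


@dataclass
class FitTrace:
    """Optimizer history: objective per iteration and per-variable credit."""

    objective: list[float] = field(default_factory=list)
    variable_credit: dict[int, float] = field(default_factory=dict)
    converged: bool = False
    n_iter: int = 0


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model, sufficient to reproduce projections."""

    variables: list[int]
    feature_spec: FeatureSpec
    features: list[Feature]
    beta: np.ndarray
    reg: np.ndarray
    multiplier: float
    alpha: float
    entropy_H: float
    n_presences: int
    n_background: int
    trace: FitTrace = field(default_factory=FitTrace)

    @property
    def n_parameters(self) -> int:
        """Count of nonzero coefficients (the AICc ``k``)."""
        return int(np.count_nonzero(self.beta))

    def linear_predictor(self, env: np.ndarray, clamp: bool = True) -> np.ndarray:
        F, _ = build_features(
            env, self.variables, self.feature_spec, clamp=clamp, feats=self.features
        )
        return F @ self.beta

    def raw(self, env: np.ndarray, clamp: bool = True) -> np.ndarray:
        """exp(eta - alpha); sums to 1 over the training background."""
        return np.exp(self.linear_predictor(env, clamp=clamp) - self.alpha)

    def cloglog(self, env: np.ndarray, clamp: bool = True) -> np.ndarray:
        p = 1.0 - np.exp(-np.exp(self.entropy_H) * self.raw(env, clamp=clamp))
        return np.clip(p, 0.0, 1.0)

    # -- plain-text serialization so projections are reproducible ----------
    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "classes": list(self.feature_spec.classes),
            "hinge_knots": self.feature_spec.hinge_knots,
            "threshold_knots": self.feature_spec.threshold_knots,
            "variable_ranges": {str(k): v for k, v in self.feature_spec.variable_ranges.items()},
            "features": [
                {"cls": f.cls, "variables": list(f.variables), "knot": f.knot,
                 "direction": f.direction}
                for f in self.features
            ],
            "beta": self.beta.tolist(),
            "reg": self.reg.tolist(),
            "multiplier": self.multiplier,
            "alpha": self.alpha,
            "entropy_H": self.entropy_H,
            "n_presences": self.n_presences,
            "n_background": self.n_background,
            "trace": {
                "final_objective": self.trace.objective[-1] if self.trace.objective else None,
                "variable_credit": {str(v): c for v, c in self.trace.variable_credit.items()},
                "converged": self.trace.converged,
                "n_iter": self.trace.n_iter,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        spec = FeatureSpec(
            classes=tuple(d["classes"]),
            hinge_knots=d["hinge_knots"],
            threshold_knots=d["threshold_knots"],
            variable_ranges={int(k): tuple(v) for k, v in d["variable_ranges"].items()},
        )
        feats = [
            Feature(f["cls"], tuple(f["variables"]), f["knot"], f["direction"])
            for f in d["features"]
        ]
        trace = FitTrace()
        if "trace" in d:
            t = d["trace"]
            if t.get("final_objective") is not None:
                trace.objective = [t["final_objective"]]
            trace.variable_credit = {
                int(v): c for v, c in t.get("variable_credit", {}).items()
            }
            trace.converged = t.get("converged", False)
            trace.n_iter = t.get("n_iter", 0)
        return cls(
            variables=list(d["variables"]),
            feature_spec=spec,
            features=feats,
            beta=np.asarray(d["beta"], dtype=float),
            reg=np.asarray(d["reg"], dtype=float),
            multiplier=d["multiplier"],
            alpha=d["alpha"],
            entropy_H=d["entropy_H"],
            n_presences=d["n_presences"],
            n_background=d["n_background"],
            trace=trace,
        )

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sample_background(
    stack: BioclimStack,
    n: int = 10_000,
    seed: int | np.random.Generator = 0,
    variables: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of valid-cell centers, without replacement.

    Returns ``(lonlat, cells)``: an (n, 2) array of cell-center coordinates
    and the flat indices of the sampled cells.  If fewer than ``n`` cells
    are valid, all of them are returned with a warning.  The same seed
    always yields the same sample, so one background can serve every
    species.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = stack.valid_mask(variables)
    flat = np.nonzero(mask.ravel())[0]
    if flat.size == 0:
        raise ValueError("no valid cells to sample background from")
    if flat.size < n:
        warnings.warn(
            f"only {flat.size} valid cells for {n} background points; using all",
            stacklevel=2,
        )
        chosen = flat
    else:
        chosen = rng.choice(flat, size=n, replace=False)
    spec = stack.spec
    rows, cols = np.unravel_index(chosen, spec.shape)
    lon = spec.lon_centers()[cols]
    lat = spec.lat_centers()[rows]
    return np.column_stack([lon, lat]), chosen


def default_regularization(
    F_presence: np.ndarray, features: list[Feature], multiplier: float
) -> np.ndarray:
    """MaxEnt-style default L1 penalties, scaled by the multiplier."""
    m = F_presence.shape[0]
    reg = np.empty(len(features))
    sd = F_presence.std(axis=0, ddof=1) if m > 1 else np.zeros(len(features))
    for j, f in enumerate(features):
        xs, ys = _REG_SCHEDULE[f.cls]
        base = float(np.interp(m, xs, ys))
        reg[j] = multiplier * base * max(sd[j], _MIN_FEATURE_SD) / np.sqrt(m)
    return reg


def _objective(beta, Fp, Fb, reg):
    eta_p = Fp @ beta
    eta_b = Fb @ beta
    return float(eta_p.mean() - (logsumexp(eta_b) - np.log(Fb.shape[0]))
                 - np.sum(reg * np.abs(beta)))


def fit(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Sequence[int],
    feature_spec: FeatureSpec | str = "lq",
    multiplier: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    raise_on_nonconvergence: bool = False,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``presence_env`` (m, n_vars) and ``background_env`` (n, n_vars) hold the
    raw environmental values at presences and background points; columns
    are named by ``variables`` (BIO indices).  Training ranges for feature
    rescaling and clamping are taken over presences and background jointly.
    The fit is deterministic given its inputs.
    """
    presence_env = np.atleast_2d(np.asarray(presence_env, dtype=float))
    background_env = np.atleast_2d(np.asarray(background_env, dtype=float))
    m, n = presence_env.shape[0], background_env.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presences with valid environment")
    if isinstance(feature_spec, (str, tuple)):
        feature_spec = FeatureSpec(classes=feature_spec)
    if not feature_spec.variable_ranges:
        feature_spec.set_ranges(
            variables, np.vstack([presence_env, background_env])
        )

    feats = feature_list(variables, feature_spec)
    Fp, _ = build_features(presence_env, variables, feature_spec, feats=feats)
    Fb, _ = build_features(background_env, variables, feature_spec, feats=feats)
    reg = default_regularization(Fp, feats, multiplier)

    beta = np.zeros(len(feats))
    fbar_p = Fp.mean(axis=0)
    trace = FitTrace()
    obj = _objective(beta, Fp, Fb, reg)
    trace.objective.append(obj)
    step = 1.0
    credit: dict[int, float] = {v: 0.0 for v in variables}

    for it in range(max_iter):
        eta_b = Fb @ beta
        w = np.exp(eta_b - logsumexp(eta_b))
        grad = fbar_p - w @ Fb  # gradient of the smooth (concave) part
        smooth = float((Fp @ beta).mean() - (logsumexp(eta_b) - np.log(n)))
        # backtracking proximal step on the concave smooth part
        accepted = False
        for _ in range(60):
            cand = beta + step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * reg, 0.0)
            delta = cand - beta
            eta_b_c = Fb @ cand
            smooth_c = float((Fp @ cand).mean() - (logsumexp(eta_b_c) - np.log(n)))
            if smooth_c >= smooth + grad @ delta - (delta @ delta) / (2 * step) - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        new_obj = smooth_c - float(np.sum(reg * np.abs(cand)))
        if new_obj < obj - 1e-12:
            # proximal theory guarantees ascent; numerical slack only
            break
        gain = max(new_obj - obj, 0.0)
        if gain > 0:
            weight = np.abs(delta) * np.abs(grad)
            total = weight.sum()
            if total > 0:
                for j, f in enumerate(feats):
                    if weight[j] == 0:
                        continue
                    share = gain * weight[j] / total
                    for v in f.variables:
                        credit[v] += share / len(f.variables)
        beta = cand
        obj = new_obj
        trace.objective.append(obj)
        step = min(step * 2.0, 1e6)  # allow the step to grow back
        if it > 0 and abs(trace.objective[-1] - trace.objective[-2]) < tol:
            trace.converged = True
            break
    trace.n_iter = len(trace.objective) - 1
    trace.variable_credit = credit
    if not trace.converged:
        msg = (f"maxent fit did not converge in {max_iter} iterations "
               f"(last objective {obj:.6g})")
        if raise_on_nonconvergence:
            raise RuntimeError(msg + f"; trace={trace.objective[-5:]}")
        log.warning(msg)

    eta_b = Fb @ beta
    alpha = float(logsumexp(eta_b))
    p_bg = np.exp(eta_b - alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-np.sum(p_bg * np.where(p_bg > 0, np.log(p_bg), 0.0)))
    return MaxentModel(
        variables=list(variables),
        feature_spec=feature_spec,
        features=feats,
        beta=beta,
        reg=reg,
        multiplier=multiplier,
        alpha=alpha,
        entropy_H=H,
        n_presences=m,
        n_background=n,
        trace=trace,
    )


def predict(
    model: MaxentModel, stack: BioclimStack, clamp: bool = True
) -> RasterGrid:
    """Project a fitted model onto a bioclim stack as a cloglog grid.

    With ``clamp`` (the default) each variable is pinned to its training
    range before feature evaluation, so projections never extrapolate
    feature values beyond conditions seen in training.
    """
    missing = [v for v in model.variables if v not in stack.bio]
    if missing:
        raise ValueError(f"projection stack lacks variables {missing}")
    mask = stack.valid_mask(model.variables)
    env = stack.env_matrix(model.variables, mask)
    p = model.cloglog(env, clamp=clamp)
    spec = stack.spec
    out = np.full(spec.shape, spec.nodata)
    out[mask] = p
    return RasterGrid(spec, out)


def min_training_presence(model: MaxentModel, presence_env: np.ndarray) -> float:
    """Zero-training-omission threshold: the lowest presence suitability."""
    return float(model.cloglog(np.atleast_2d(presence_env)).min())
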