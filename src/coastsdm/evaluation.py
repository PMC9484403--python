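"""Model tuning and evaluation.

Candidate models (feature-class combination x regularization multiplier)
are ranked by small-sample-corrected AIC; spatial structure in the data is
respected through two-scale checkerboard partitions; the selected model is
evaluated by k-fold cross-validation and partial ROC; variable importance
comes from jackknife tests of regularized training gain and from the
optimizer's per-variable contribution credits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bioclim import BioclimStack
from .features import CLASS_COMBOS, FeatureSpec
from .grids import GridSpec
from .maxent import MaxentModel, fit, min_training_presence

__all__ = [
    "TuningCandidate",
    "TuningResult",
    "EvalReport",
    "checkerboard2_partition",
    "aicc",
    "aicc_formula",
    "kfold_cv",
    "partial_roc",
    "jackknife_gain",
    "percent_contribution",
    "tune",
    "DEFAULT_MULTIPLIERS",
    "DEFAULT_COMBOS",
]

log = logging.getLogger(__name__)

DEFAULT_MULTIPLIERS = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_COMBOS = ("l", "lq", "lqh", "lqhp", "lqpt", "lqhpt")


def checkerboard2_partition(
    lons: np.ndarray,
    lats: np.ndarray,
    spec: GridSpec,
    aggregation_factors: tuple[int, int] = (2, 2),
    seed: int | None = None,
) -> np.ndarray:
    """Assign points to 4 spatial bins by two nested checkerboards.

    A fine checkerboard aggregates raster cells by ``factors[0]`` and a
    coarse one by ``factors[0] * factors[1]``; a point's bin in {1..4}
    combines the parities of its fine and coarse checkerboard cells.  The
    partition is deterministic (``seed`` is accepted for interface
    symmetry and ignored).  Background points are partitioned by the same
    rule, so presence and background share spatial structure per bin.
    """
    f1, f2 = aggregation_factors
    if f1 < 1 or f2 < 1:
        raise ValueError("aggregation factors must be >= 1")
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    rows = np.floor((spec.north - lats) / spec.cell_size).astype(int)
    cols = np.floor((lons - spec.west) / spec.cell_size).astype(int)
    rows = np.clip(rows, 0, spec.n_rows - 1)
    cols = np.clip(cols, 0, spec.n_cols - 1)
    fine = ((rows // f1) + (cols // f1)) % 2
    coarse = ((rows // (f1 * f2)) + (cols // (f1 * f2))) % 2
    return (1 + fine + 2 * coarse).astype(int)


@dataclass
class TuningCandidate:
    combo: str
    multiplier: float
    aicc: float
    delta_aicc: float
    k: int
    mean_cv_omission: float
    valid: bool


@dataclass
class TuningResult:
    candidates: list[TuningCandidate]
    selected: TuningCandidate
    selected_model: MaxentModel


@dataclass
class EvalReport:
    proc_ratio: float
    proc_p: float
    jackknife: dict[int, tuple[float, float]]  # var -> (gain_alone, gain_without)
    percent_contribution: dict[int, float]
    cv_omission: float = float("nan")
    cv_proc_ratio: float = float("nan")


def aicc(model: MaxentModel, presence_env: np.ndarray, landscape_env: np.ndarray) -> float:
    """Small-sample-corrected AIC of a fitted model.

    The likelihood is the raw model density normalized to sum to one over
    the landscape cells; ``k`` counts nonzero coefficients.  Undefined
    (returned as ``inf``) when m <= k + 1, in which case the candidate is
    not comparable.
    """
    m = np.atleast_2d(presence_env).shape[0]
    k = model.n_parameters
    if m <= k + 1:
        return float("inf")
    raw_land = model.raw(landscape_env, clamp=False)
    raw_pres = model.raw(np.atleast_2d(presence_env), clamp=False)
    dens = raw_pres / raw_land.sum()
    if np.any(dens <= 0):
        return float("inf")
    lnL = float(np.log(dens).sum())
    return aicc_formula(k, lnL, m)


def aicc_formula(k: int, lnL: float, m: int) -> float:
    """AICc = 2k - 2 lnL + 2k(k+1)/(m-k-1); inf when m <= k + 1."""
    if m <= k + 1:
        return float("inf")
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (m - k - 1)


def kfold_folds(m: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Random partition of range(m) into k folds differing by <= 1 in size."""
    if m < k:
        raise ValueError(f"cannot make {k} folds from {m} presences")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(m)
    return [np.sort(part) for part in np.array_split(idx, k)]


def kfold_cv(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Sequence[int],
    combo: str,
    multiplier: float,
    landscape_env: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    proc_kwargs: dict | None = None,
) -> dict:
    """Fivefold cross-validation of one configuration.

    Each fold's model is trained on the remaining folds; held-out presences
    are scored for omission at the fold's minimum-training-presence
    threshold and (if a landscape is given) partial ROC.
    """
    presence_env = np.atleast_2d(presence_env)
    folds = kfold_folds(presence_env.shape[0], k=k, seed=seed)
    omission, ratios = [], []
    for fold in folds:
        test_mask = np.zeros(presence_env.shape[0], dtype=bool)
        test_mask[fold] = True
        model = fit(
            presence_env[~test_mask], background_env, variables, combo, multiplier
        )
        thr = min_training_presence(model, presence_env[~test_mask])
        test_pred = model.cloglog(presence_env[test_mask])
        omission.append(float((test_pred < thr).mean()))
        if landscape_env is not None and test_pred.size >= 10:
            land_pred = model.cloglog(landscape_env)
            ratio, _ = partial_roc(test_pred, land_pred, **(proc_kwargs or {}))
            ratios.append(ratio)
    return {
        "fold_omission": omission,
        "mean_omission": float(np.mean(omission)),
        "fold_proc_ratio": ratios,
        "mean_proc_ratio": float(np.mean(ratios)) if ratios else float("nan"),
    }


def partial_roc(
    test_pred: np.ndarray,
    landscape_pred: np.ndarray,
    E: float = 0.05,
    n_boot: int = 1000,
    boot_frac: float = 0.5,
    seed: int = 0,
    n_thresholds: int = 500,
) -> tuple[float, float]:
    """Partial-ROC AUC ratio with bootstrap, after Peterson's formulation.

    The ROC curve plots sensitivity (1 - omission of test points) against
    the proportion of the landscape predicted suitable, over a descending
    sweep of suitability thresholds.  Only the low-omission region
    (sensitivity >= 1 - E) contributes.  The statistic is the partial AUC
    divided by the area expected of a random predictor on that region; each
    bootstrap resamples ``boot_frac`` of the test points with replacement.
    Returns (mean ratio, proportion of bootstrap ratios <= 1).
    """
    test_pred = np.asarray(test_pred, dtype=float)
    landscape_pred = np.asarray(landscape_pred, dtype=float)
    if test_pred.size < 10:
        raise ValueError("partial ROC needs at least 10 test points")
    if np.ptp(landscape_pred) == 0:
        raise ValueError("degenerate constant landscape predictions")
    lo, hi = landscape_pred.min(), landscape_pred.max()
    thresholds = np.linspace(lo, hi, n_thresholds)
    land_sorted = np.sort(landscape_pred)
    # fraction of landscape at or above each threshold (descending curve)
    area = 1.0 - np.searchsorted(land_sorted, thresholds, side="left") / land_sorted.size

    rng = np.random.default_rng(seed)
    n_take = max(1, int(round(boot_frac * test_pred.size)))
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = test_pred[rng.integers(0, test_pred.size, n_take)]
        ratios[b] = _proc_ratio(sample, thresholds, area, E)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ValueError("partial ROC undefined for every bootstrap sample")
    return float(ratios.mean()), float((ratios <= 1.0).mean())


def _proc_ratio(
    test_pred: np.ndarray, thresholds: np.ndarray, area: np.ndarray, E: float
) -> float:
    test_sorted = np.sort(test_pred)
    sens = 1.0 - np.searchsorted(test_sorted, thresholds, side="left") / test_sorted.size
    keep = sens >= 1.0 - E
    if keep.sum() < 2:
        return float("nan")
    x = area[keep][::-1]  # ascending in landscape fraction
    y = sens[keep][::-1]
    auc_model = float(np.trapezoid(y, x))
    auc_random = float(np.trapezoid(x, x))
    if auc_random == 0:
        return float("nan")
    return auc_model / auc_random


def jackknife_gain(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Sequence[int],
    combo: str | FeatureSpec = "lq",
    multiplier: float = 1.0,
) -> dict[int, tuple[float, float]]:
    """Jackknife of regularized training gain, per variable.

    Training gain is the unpenalized part of the fitted objective relative
    to the uniform null (which has gain zero).  For each variable v the
    model is refit with only v and with all variables but v.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    presence_env = np.atleast_2d(presence_env)
    out: dict[int, tuple[float, float]] = {}
    for i, v in enumerate(variables):
        rest = [u for u in variables if u != v]
        rest_cols = [j for j, u in enumerate(variables) if u != v]
        try:
            alone = fit(
                presence_env[:, [i]], background_env[:, [i]], [v], combo, multiplier
            )
            without = fit(
                presence_env[:, rest_cols], background_env[:, rest_cols],
                rest, combo, multiplier,
            )
        except Exception as exc:  # refit failure flags the variable
            log.warning("jackknife refit failed for BIO%s: %s", v, exc)
            out[v] = (float("nan"), float("nan"))
            continue
        out[v] = (training_gain(alone), training_gain(without))
    return out


def training_gain(model: MaxentModel) -> float:
    """Unpenalized objective value of the fit (gain over the uniform null)."""
    obj = model.trace.objective[-1]
    return float(obj + np.sum(model.reg * np.abs(model.beta)))


def percent_contribution(model: MaxentModel) -> dict[int, float]:
    """Share of optimizer gain credited to each variable, normalized to 100.

    Each accepted optimizer step's objective improvement is credited to the
    moved features' underlying variables (product features split equally).
    """
    credit = model.trace.variable_credit
    total = sum(credit.values())
    if total <= 0:
        raise ValueError("zero total gain; contributions undefined")
    return {v: 100.0 * c / total for v, c in credit.items()}


def tune(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Sequence[int],
    presence_lonlat: np.ndarray | None = None,
    background_lonlat: np.ndarray | None = None,
    spec: GridSpec | None = None,
    combos: Sequence[str] = DEFAULT_COMBOS,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    landscape_env: np.ndarray | None = None,
    aggregation_factors: tuple[int, int] = (2, 2),
    cv_omission: bool = True,
    **fit_kwargs,
) -> TuningResult:
    """Grid-search feature combos x multipliers, ranked by AICc.

    Each candidate is fit on all presences; candidates whose presence count
    cannot support their parameter count are flagged invalid and excluded
    from ranking.  When point coordinates and a grid are supplied, the
    checkerboard2 partition drives a 4-bin spatial cross-validation whose
    mean omission rate is reported per candidate (informational; selection
    is by delta-AICc alone).
    """
    presence_env = np.atleast_2d(presence_env)
    land = landscape_env if landscape_env is not None else background_env
    bins = None
    if cv_omission and presence_lonlat is not None and spec is not None:
        bins = checkerboard2_partition(
            presence_lonlat[:, 0], presence_lonlat[:, 1], spec, aggregation_factors
        )
        for b in range(1, 5):
            if not np.any(bins == b):
                warnings.warn(f"checkerboard bin {b} holds no presences", stacklevel=2)

    candidates: list[TuningCandidate] = []
    best: tuple[float, TuningCandidate, MaxentModel] | None = None
    for combo in combos:
        for mult in multipliers:
            model = fit(presence_env, background_env, variables, combo, float(mult),
                        **fit_kwargs)
            a = aicc(model, presence_env, land)
            omission = float("nan")
            if bins is not None:
                omission = _checkerboard_omission(
                    presence_env, background_env, variables, combo, float(mult),
                    bins, **fit_kwargs
                )
            cand = TuningCandidate(
                combo=combo,
                multiplier=float(mult),
                aicc=a,
                delta_aicc=float("nan"),
                k=model.n_parameters,
                mean_cv_omission=omission,
                valid=np.isfinite(a),
            )
            candidates.append(cand)
            if cand.valid and (best is None or a < best[0]):
                best = (a, cand, model)
    if best is None:
        raise ValueError("no tuning candidate produced a finite AICc")
    for cand in candidates:
        if cand.valid:
            cand.delta_aicc = cand.aicc - best[0]
    return TuningResult(candidates=candidates, selected=best[1], selected_model=best[2])


def _checkerboard_omission(
    presence_env, background_env, variables, combo, mult, bins, **fit_kwargs
) -> float:
    rates = []
    for b in np.unique(bins):
        test = bins == b
        if test.all() or not test.any() or (~test).sum() < 2:
            continue
        model = fit(presence_env[~test], background_env, variables, combo, mult,
                    **fit_kwargs)
        thr = min_training_presence(model, presence_env[~test])
        rates.append(float((model.cloglog(presence_env[test]) < thr).mean()))
    return float(np.mean(rates)) if rates else float("nan")
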