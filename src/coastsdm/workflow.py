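"""High-level orchestration: from climate series to validated projections.

These functions compose the pipeline stages in the order of the study
design: window-average the monthly series, derive bioclim stacks, mask by
elevation, prune predictors on the present window, fit one
maximum-entropy model per species on the present, hindcast into the past
dominance windows, validate the group-level orderings, and project the
timeline.  The config-file CLI wraps these same calls.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bioclim import (
    BioclimStack,
    MonthlyClimateNormals,
    PredictorSet,
    compute_bioclim,
    correlation_prune,
    window_average,
)
from .grids import RasterGrid
from .maxent import MaxentModel, fit, predict, sample_background
from .projection import (
    PeriodSummary,
    RegionBox,
    ValidationReport,
    hindcast_validate,
    project_timeline,
    summarize_period,
)
from .spatial_io import OccurrenceSet, clean_occurrences, elevation_mask, min_occurrence_filter
from .synthetic import (
    DEFAULT_GROUPS,
    ClimateScenario,
    default_scenario,
    default_truths,
    generate_climate,
    generate_elevation,
    generate_occurrences,
)

__all__ = [
    "build_stacks",
    "fit_present_models",
    "project_all",
    "HindcastExperiment",
    "run_hindcast_experiment",
]

log = logging.getLogger(__name__)

#: period roles of the named windows used by the validation rule
PAST_ROLES = {"saltmarsh_dom": "1984-1989", "mangrove_dom": "2001-2006"}
PRESENT_WINDOW = "2013-2018"


def build_stacks(
    monthly_series: Mapping[tuple[int, int], dict[str, RasterGrid]],
    windows: Mapping[str, tuple[int, int]],
    elevation: RasterGrid | None = None,
    elevation_cutoff_m: float = 10.0,
) -> dict[str, BioclimStack]:
    """Window-average the series and derive a bioclim stack per window."""
    stacks: dict[str, BioclimStack] = {}
    for name, window in windows.items():
        normals = window_average(monthly_series, window)
        stack = compute_bioclim(normals)
        if elevation is not None:
            stack = BioclimStack(
                window=stack.window,
                bio={
                    i: elevation_mask(g, elevation, elevation_cutoff_m)
                    for i, g in stack.bio.items()
                },
            )
        stacks[name] = stack
    return stacks


def occurrences_to_env(
    occ: OccurrenceSet, stack: BioclimStack, variables: Sequence[int]
) -> np.ndarray:
    """Environmental values at occurrence cells; rows with nodata dropped."""
    mask = stack.valid_mask(variables)
    spec = stack.spec
    rows, cols = [], []
    for lon, lat in occ.records:
        try:
            r, c = spec.cell_index(lon, lat)
        except ValueError:
            continue
        if mask[r, c]:
            rows.append(r)
            cols.append(c)
    if not rows:
        raise ValueError(f"no occurrence of {occ.species} falls on a valid cell")
    return np.column_stack(
        [stack.bio[v].values[rows, cols] for v in variables]
    )


def fit_present_models(
    present: BioclimStack,
    occurrences: Mapping[str, OccurrenceSet],
    variables: Sequence[int],
    n_background: int = 10_000,
    seed: int = 0,
    feature_classes: str = "lq",
    multiplier: float = 1.0,
    n_min: int = 50,
) -> tuple[dict[str, MaxentModel], np.ndarray]:
    """Fit one model per species on the present stack.

    The same background sample serves every species.  Species failing the
    minimum-occurrence gate are skipped with a warning.  Returns the
    models and the shared background environment matrix.
    """
    _, bg_cells = sample_background(present, n_background, seed, variables)
    mask = present.valid_mask(variables)
    rows, cols = np.unravel_index(bg_cells, present.spec.shape)
    bg_env = np.column_stack([present.bio[v].values[rows, cols] for v in variables])
    assert mask[rows, cols].all()

    models: dict[str, MaxentModel] = {}
    for sp, occ in occurrences.items():
        if not min_occurrence_filter(occ, n_min):
            log.warning(
                "%s has %d cleaned occurrences (< %d); skipped", sp, len(occ), n_min
            )
            continue
        env = occurrences_to_env(occ, present, variables)
        models[sp] = fit(env, bg_env, variables, feature_classes, multiplier)
    return models, bg_env


def project_all(
    models: Mapping[str, MaxentModel],
    stacks: Mapping[str, BioclimStack],
    clamp: bool = True,
) -> dict[str, dict[str, RasterGrid]]:
    """Suitability map per window per species (window -> species -> grid)."""
    return {
        w: {sp: predict(m, stack, clamp=clamp) for sp, m in models.items()}
        for w, stack in stacks.items()
    }


@dataclass
class HindcastExperiment:
    """Everything the end-to-end synthetic run produces."""

    stacks: dict[str, BioclimStack]
    predictors: PredictorSet
    models: dict[str, MaxentModel]
    suitability: dict[str, dict[str, RasterGrid]]
    summaries: dict[str, PeriodSummary]
    validation: ValidationReport
    tables: dict = field(default_factory=dict)


def run_hindcast_experiment(
    seed: int = 0,
    invert_past: bool = False,
    scenario: ClimateScenario | None = None,
    truths: Mapping | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    region: RegionBox | None = None,
    windows: Mapping[str, tuple[int, int]] | None = None,
    m_occurrences: int = 600,
    n_background: int = 5000,
    maskable_fraction: float = 0.3,
    feature_classes: str = "lq",
    multiplier: float = 1.0,
    include_futures: bool = False,
    make_tables: bool = False,
) -> HindcastExperiment:
    """Run the whole study design on synthetic data.

    Generates an oscillating two-group climate (cold/wet salt-marsh
    dominance period, warm/dry mangrove dominance period), fits per-species
    models on the present window only, hindcasts them into the two past
    windows, and applies the validation rule.  With ``invert_past`` the
    past offsets are swapped — the negative control that a discriminating
    pipeline must fail to validate.
    """
    scenario = scenario or default_scenario(seed, invert_past)
    if scenario.period_offsets == {}:
        scenario.period_offsets.update(default_scenario(seed, invert_past).period_offsets)
    truths = truths or default_truths()
    groups = groups or DEFAULT_GROUPS
    windows = dict(windows) if windows is not None else None
    if windows is None:
        from .synthetic import DEFAULT_WINDOWS

        windows = {
            k: v
            for k, v in DEFAULT_WINDOWS.items()
            if include_futures or v[1] <= 2020
        }
    years = sorted({y for w in windows.values() for y in range(w[0], w[1] + 1)})
    series = generate_climate(scenario, years)
    elevation = generate_elevation(
        scenario.grid, maskable_fraction=maskable_fraction, seed=scenario.seed
    )
    stacks = build_stacks(series, windows, elevation)
    present = stacks[PRESENT_WINDOW]

    predictors = correlation_prune(present)
    variables = sorted(predictors.retained)

    occurrences = {}
    for sp, truth in truths.items():
        raw = generate_occurrences(
            truth, present, m=m_occurrences,
            seed=seed + zlib.crc32(sp.encode()) % 10_000, species=sp,
        )
        occurrences[sp], _ = clean_occurrences(raw.records, species=sp)

    models, _ = fit_present_models(
        present,
        occurrences,
        variables,
        n_background=n_background,
        seed=seed,
        feature_classes=feature_classes,
        multiplier=multiplier,
    )
    suitability = project_all(models, stacks)

    if region is None:
        g = scenario.grid
        region = RegionBox("synthetic domain", g.west, g.east, g.south, g.north)
    summaries = {
        role: summarize_period(region, w, suitability[w], groups)
        for role, w in PAST_ROLES.items()
    }
    summaries["present"] = summarize_period(
        region, PRESENT_WINDOW, suitability[PRESENT_WINDOW], groups
    )
    validation = hindcast_validate(summaries)

    tables = {}
    if make_tables:
        tables = project_timeline(
            suitability, [region], groups, PRESENT_WINDOW
        )
    return HindcastExperiment(
        stacks=stacks,
        predictors=predictors,
        models=models,
        suitability=suitability,
        summaries=summaries,
        validation=validation,
        tables=tables,
    )


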