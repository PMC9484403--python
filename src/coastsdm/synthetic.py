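"""Synthetic climate, elevation and occurrence generators.

These emulate the shape of the real inputs — monthly gridded climate
normals with a latitudinal temperature gradient and seasonal cycle, a
longitudinal precipitation gradient, inter-period offsets standing in for
documented warm/cold and wet/dry spells, a coastal elevation surface, and
presence records sampled from a known suitability truth — so every stage
of the pipeline can be exercised and ground-truthed without any download.

All generators are fully deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bioclim import BioclimStack
from .grids import GridSpec, RasterGrid
from .spatial_io import OccurrenceSet

__all__ = [
    "ClimateScenario",
    "TruthModel",
    "generate_climate",
    "generate_elevation",
    "generate_occurrences",
    "default_scenario",
    "DEFAULT_WINDOWS",
]

#: named study windows: the present, the two documented-dominance periods
#: in the past, and three future windows
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "1984-1989": (1984, 1989),
    "2001-2006": (2001, 2006),
    "2013-2018": (2013, 2018),
    "2021-2040": (2021, 2040),
    "2041-2060": (2041, 2060),
    "2061-2080": (2061, 2080),
}

DEFAULT_GRID = GridSpec(n_rows=100, n_cols=120, west=-95.0, south=0.0, cell_size=0.3)


@dataclass
class ClimateScenario:
    """Parameters of the synthetic climate.

    Temperature (degC): ``tmean = base_temp - lapse * |lat| +
    seasonal_amplitude * cos(2 pi (month - peak_month) / 12) + offset +
    noise``; tmin/tmax sit half a diurnal range below/above tmean.
    Precipitation (mm/month): a base level plus an eastward gradient, a
    seasonal cycle and noise, floored at zero.  ``period_offsets`` maps
    (start_year, end_year) to (temperature offset degC, precipitation
    offset mm/month) applied to every year in that range — the knob that
    emulates dominance oscillations in the past and warming/drying in the
    future.
    """

    grid: GridSpec = DEFAULT_GRID
    base_temp: float = 27.0
    lapse: float = 0.45
    seasonal_amplitude: float = 6.0
    peak_month: int = 7
    diurnal_range: float = 8.0
    diurnal_lat_gradient: float = 0.05  # degC extra range per degree |lat|
    diurnal_noise_sd: float = 0.3
    base_prec: float = 90.0
    prec_gradient: float = 1.2  # mm/month per degree longitude eastward
    prec_seasonal: float = 35.0
    prec_peak_month: int = 8
    temp_noise_sd: float = 0.8
    prec_noise_sd: float = 12.0
    period_offsets: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def offset_for(self, year: int) -> tuple[float, float]:
        for (y0, y1), off in self.period_offsets.items():
            if y0 <= year <= y1:
                return off
        return (0.0, 0.0)


@dataclass
class TruthModel:
    """Known suitability truth: log-density linear in BIO variables."""

    coefficients: dict[int, float]  # BIO index -> coefficient (raw units)
    intercept: float = 0.0

    def linear_predictor(self, stack: BioclimStack, mask: np.ndarray) -> np.ndarray:
        eta = np.full(int(mask.sum()), self.intercept)
        for v, c in self.coefficients.items():
            eta = eta + c * stack.bio[v].values[mask]
        return eta


def default_offsets(invert_past: bool = False) -> dict[tuple[int, int], tuple[float, float]]:
    """Period offsets of the two-group study design.

    The salt-marsh dominance window is cold and wet, the mangrove
    dominance window warm and dry, the present neutral, and the future
    progressively warmer and drier.  ``invert_past`` swaps the two past
    periods' offsets (the negative control for hindcast validation).
    """
    cold_wet = (-2.5, 30.0)
    warm_dry = (1.2, -35.0)
    off = {
        (1984, 1989): warm_dry if invert_past else cold_wet,
        (2001, 2006): cold_wet if invert_past else warm_dry,
        (2013, 2018): (0.0, 0.0),
        (2021, 2040): (1.0, -15.0),
        (2041, 2060): (2.0, -25.0),
        (2061, 2080): (3.0, -35.0),
    }
    return off


def default_scenario(seed: int = 0, invert_past: bool = False) -> ClimateScenario:
    return ClimateScenario(period_offsets=default_offsets(invert_past), seed=seed)


def generate_climate(
    scenario: ClimateScenario,
    years: Sequence[int],
) -> dict[tuple[int, int], dict[str, RasterGrid]]:
    """Monthly tmin/tmax/prec grids for each requested year.

    Noise is independent per (year, month, cell) but reproducible: the
    stream is seeded from ``scenario.seed`` alone, with each (year, month)
    drawing from its own child generator, so any subset of years yields
    the same fields as a full run.
    """
    spec = scenario.grid
    lat = spec.lat_centers()[:, None]  # (rows, 1)
    lon = spec.lon_centers()[None, :]  # (1, cols)
    lat2 = np.broadcast_to(lat, spec.shape)
    lon2 = np.broadcast_to(lon, spec.shape)

    out: dict[tuple[int, int], dict[str, RasterGrid]] = {}
    for year in years:
        t_off, p_off = scenario.offset_for(year)
        for month in range(1, 13):
            rng = np.random.default_rng([scenario.seed, year, month])
            tmean = (
                scenario.base_temp
                - scenario.lapse * np.abs(lat2)
                + scenario.seasonal_amplitude
                * math.cos(2 * math.pi * (month - scenario.peak_month) / 12.0)
                + t_off
                + rng.normal(0.0, scenario.temp_noise_sd, spec.shape)
            )
            drange = np.maximum(
                scenario.diurnal_range
                + scenario.diurnal_lat_gradient * np.abs(lat2)
                + rng.normal(0.0, scenario.diurnal_noise_sd, spec.shape),
                0.5,
            )
            half = drange / 2.0
            prec = (
                scenario.base_prec
                + scenario.prec_gradient * (lon2 - spec.west)
                + scenario.prec_seasonal
                * math.cos(2 * math.pi * (month - scenario.prec_peak_month) / 12.0)
                + p_off
                + rng.normal(0.0, scenario.prec_noise_sd, spec.shape)
            )
            out[(year, month)] = {
                "tmin": RasterGrid(spec, tmean - half),
                "tmax": RasterGrid(spec, tmean + half),
                "prec": RasterGrid(spec, np.maximum(prec, 0.0)),
            }
    return out


def generate_elevation(
    grid: GridSpec,
    coastal_band_cells: int | None = None,
    maskable_fraction: float | None = None,
    seed: int = 0,
    inland_slope_m: float = 6.0,
) -> RasterGrid:
    """A coastal elevation surface: low near the western coast, rising inland.

    Columns within the coastal band draw elevations in [0, 9] m; inland
    columns climb by ``inland_slope_m`` per column above the 10 m cutoff.
    Give either the band width in cells or the desired fraction of cells
    above 10 m (``maskable_fraction``), from which the band is derived.
    """
    if maskable_fraction is not None:
        if coastal_band_cells is not None:
            raise ValueError("give either coastal_band_cells or maskable_fraction")
        coastal_band_cells = int(round((1.0 - maskable_fraction) * grid.n_cols))
    if coastal_band_cells is None:
        coastal_band_cells = grid.n_cols // 2
    band = int(np.clip(coastal_band_cells, 0, grid.n_cols))
    rng = np.random.default_rng([seed, 7])
    values = np.empty(grid.shape)
    values[:, :band] = rng.uniform(0.0, 9.0, (grid.n_rows, band))
    inland = np.arange(grid.n_cols - band)
    values[:, band:] = (
        11.0
        + inland_slope_m * inland[None, :]
        + rng.uniform(0.0, 2.0, (grid.n_rows, grid.n_cols - band))
    )
    return RasterGrid(grid, values)


def generate_occurrences(
    truth: TruthModel,
    stack: BioclimStack,
    m: int = 600,
    seed: int = 0,
    species: str = "synthetic",
    jitter: bool = True,
    n_duplicates: int = 0,
    n_zero_zero: int = 0,
) -> OccurrenceSet:
    """Sample ``m`` presence points from the truth's Gibbs distribution.

    Cells are drawn (with replacement) with probability proportional to
    ``exp(eta_truth)`` over the stack's valid cells, then jittered
    uniformly within the cell.  Optional contamination appends exact
    duplicates of sampled points and (0, 0) records so that occurrence
    cleaning can be exercised.
    """
    mask = stack.valid_mask(list(truth.coefficients))
    n_cells = int(mask.sum())
    if n_cells == 0:
        raise ValueError("truth model has no valid cells on this stack")
    eta = truth.linear_predictor(stack, mask)
    eta = eta - eta.max()
    p = np.exp(eta)
    p /= p.sum()
    if p.max() > 0.999:
        raise ValueError("degenerate truth: nearly all mass on one cell")
    rng = np.random.default_rng([seed, 11])
    flat = np.nonzero(mask.ravel())[0]
    chosen = rng.choice(flat, size=m, replace=True, p=p)
    spec = stack.spec
    rows, cols = np.unravel_index(chosen, spec.shape)
    lon = spec.lon_centers()[cols]
    lat = spec.lat_centers()[rows]
    if jitter:
        lon = lon + rng.uniform(-0.5, 0.5, m) * spec.cell_size
        lat = lat + rng.uniform(-0.5, 0.5, m) * spec.cell_size
    records = list(zip(lon.tolist(), lat.tolist()))
    if n_duplicates:
        dup_idx = rng.integers(0, m, n_duplicates)
        records += [records[i] for i in dup_idx]
    records += [(0.0, 0.0)] * n_zero_zero
    return OccurrenceSet(species=species, records=records)


#: the two-group truth models of the study design: mangrove-like species
#: limited by cold extremes (positive coefficient on BIO6), salt-marsh-like
#: species tracking annual precipitation (positive coefficient on BIO12)
def default_truths() -> dict[str, TruthModel]:
    return {
        "mangrove_a": TruthModel({6: 0.45}),
        "mangrove_b": TruthModel({6: 0.35, 18: 0.002}),
        "saltmarsh_a": TruthModel({12: 0.010}),
        "saltmarsh_b": TruthModel({12: 0.008, 6: 0.05}),
    }


DEFAULT_GROUPS = {
    "mangrove": ["mangrove_a", "mangrove_b"],
    "saltmarsh": ["saltmarsh_a", "saltmarsh_b"],
}
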