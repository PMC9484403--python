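"""Bioclimatic variables from monthly climate normals.

The pipeline averages monthly minimum temperature, maximum temperature and
precipitation over multi-year windows, derives the 19 standard bioclimatic
variables (BIO1-BIO19) from the 12 monthly normals, and prunes predictors
that are pairwise correlated above a threshold.

Conventions (chosen to match the dominant ``biovars`` implementation):

* standard deviations use the sample (n-1) denominator (BIO4, BIO15);
* BIO15 is the coefficient of variation of monthly precipitation with +1
  in the denominator, ``100 * sd(prec) / (1 + mean(prec))``, which keeps
  arid cells finite;
* "quarters" are the 12 wrapping windows of 3 consecutive months
  (Dec-Jan-Feb wraps); ties between quarters are broken by the earliest
  starting month, January first;
* temperatures are plain degrees Celsius, precipitation millimetres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grids import GridSpec, RasterGrid

__all__ = [
    "MonthlyClimateNormals",
    "BioclimStack",
    "PredictorSet",
    "window_average",
    "compute_bioclim",
    "correlation_prune",
    "BIO_LONG_NAMES",
    "DEFAULT_PRUNE_PRIORITY",
]

log = logging.getLogger(__name__)

BIO_LONG_NAMES = {
    1: "annual mean temperature",
    2: "mean diurnal temperature range",
    3: "isothermality",
    4: "temperature seasonality",
    5: "maximum temperature of warmest month",
    6: "minimum temperature of coldest month",
    7: "temperature annual range",
    8: "mean temperature of wettest quarter",
    9: "mean temperature of driest quarter",
    10: "mean temperature of warmest quarter",
    11: "mean temperature of coldest quarter",
    12: "annual precipitation",
    13: "precipitation of wettest month",
    14: "precipitation of driest month",
    15: "precipitation seasonality",
    16: "precipitation of wettest quarter",
    17: "precipitation of driest quarter",
    18: "precipitation of warmest quarter",
    19: "precipitation of coldest quarter",
}

#: Greedy pruning order: coastal range limits are shaped first by cold
#: extremes and moisture, so those variables are protected first.
DEFAULT_PRUNE_PRIORITY = (6, 12, 2, 5, 15, 18) + tuple(
    i for i in range(1, 20) if i not in (6, 12, 2, 5, 15, 18)
)


@dataclass
class MonthlyClimateNormals:
    """Twelve monthly normals of tmin/tmax (degC) and precipitation (mm)."""

    window: tuple[int, int]
    tmin: list[RasterGrid]
    tmax: list[RasterGrid]
    prec: list[RasterGrid]

    def __post_init__(self) -> None:
        for name, grids in (("tmin", self.tmin), ("tmax", self.tmax), ("prec", self.prec)):
            if len(grids) != 12:
                raise ValueError(f"{name} must have 12 monthly grids, got {len(grids)}")
            for g in grids:
                if not g.spec.same_geometry(self.spec):
                    raise ValueError(f"{name} grids do not share one geometry")

    @property
    def spec(self) -> GridSpec:
        return self.tmin[0].spec

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.spec.shape, dtype=bool)
        for grids in (self.tmin, self.tmax, self.prec):
            for g in grids:
                mask &= g.valid_mask
        return mask


@dataclass
class BioclimStack:
    """BIO1..BIO19 on a shared grid, for one time window."""

    window: tuple[int, int]
    bio: dict[int, RasterGrid]

    def __post_init__(self) -> None:
        if set(self.bio) - set(range(1, 20)):
            raise ValueError("bio keys must be in 1..19")
        spec = self.spec
        for g in self.bio.values():
            if not g.spec.same_geometry(spec):
                raise ValueError("bioclim grids do not share one geometry")

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.bio.values())).spec

    @property
    def variables(self) -> list[int]:
        return sorted(self.bio)

    def valid_mask(self, variables: Sequence[int] | None = None) -> np.ndarray:
        mask = np.ones(self.spec.shape, dtype=bool)
        for i in variables if variables is not None else self.variables:
            mask &= self.bio[i].valid_mask
        return mask

    def subset(self, variables: Sequence[int]) -> "BioclimStack":
        return BioclimStack(self.window, {i: self.bio[i] for i in variables})

    def env_matrix(
        self, variables: Sequence[int], mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Stack variables into an (n_valid_cells, n_vars) matrix."""
        if mask is None:
            mask = self.valid_mask(variables)
        return np.column_stack([self.bio[i].values[mask] for i in variables])


@dataclass
class PredictorSet:
    """Outcome of correlation pruning."""

    retained: list[int]
    dropped: list[tuple[int, int, float]]  # (dropped, kept partner, r)
    threshold: float


def window_average(
    monthly_series: Mapping[tuple[int, int], dict[str, RasterGrid]],
    window: tuple[int, int],
) -> MonthlyClimateNormals:
    """Average per-year monthly grids over a year window (inclusive).

    ``monthly_series`` maps (year, month) to ``{"tmin": g, "tmax": g,
    "prec": g}``.  Every (year, month) in the window must be present.
    """
    start, end = window
    years = list(range(start, end + 1))
    gaps = [
        (y, m) for y in years for m in range(1, 13) if (y, m) not in monthly_series
    ]
    if gaps:
        raise ValueError(f"monthly series has gaps in window {window}: {gaps[:8]}"
                         + ("..." if len(gaps) > 8 else ""))
    out: dict[str, list[RasterGrid]] = {"tmin": [], "tmax": [], "prec": []}
    ref = monthly_series[(years[0], 1)]["tmin"]
    for var in ("tmin", "tmax", "prec"):
        for m in range(1, 13):
            grids = [monthly_series[(y, m)][var] for y in years]
            stack = np.stack([g.values for g in grids])
            valid = np.all(
                np.stack([g.valid_mask for g in grids]), axis=0
            )
            mean = stack.mean(axis=0)
            mean[~valid] = ref.spec.nodata
            out[var].append(RasterGrid(ref.spec, mean))
    return MonthlyClimateNormals(window=window, tmin=out["tmin"], tmax=out["tmax"], prec=out["prec"])


def _quarter_sums(x: np.ndarray) -> np.ndarray:
    """Sums of the 12 wrapping 3-month windows; shape (12, ncells)."""
    return np.stack([x[i] + x[(i + 1) % 12] + x[(i + 2) % 12] for i in range(12)])


def compute_bioclim(normals: MonthlyClimateNormals) -> BioclimStack:
    """Derive BIO1..BIO19 from 12-month normals, cell-wise.

    Cells where any input month is nodata are nodata in every output.
    BIO3 is nodata (with a warning) wherever the annual temperature range
    BIO7 is zero.
    """
    spec = normals.spec
    mask = normals.valid_mask
    nodata = spec.nodata

    tmin = np.stack([g.values for g in normals.tmin])[:, mask]  # (12, ncells)
    tmax = np.stack([g.values for g in normals.tmax])[:, mask]
    prec = np.stack([g.values for g in normals.prec])[:, mask]
    tavg = (tmax + tmin) / 2.0

    out: dict[int, np.ndarray] = {}
    out[1] = tavg.mean(axis=0)
    out[2] = (tmax - tmin).mean(axis=0)
    out[4] = 100.0 * tavg.std(axis=0, ddof=1)
    out[5] = tmax.max(axis=0)
    out[6] = tmin.min(axis=0)
    out[7] = out[5] - out[6]
    with np.errstate(divide="ignore", invalid="ignore"):
        out[3] = 100.0 * out[2] / out[7]
    flat = out[7] == 0
    if flat.any():
        warnings.warn(
            f"BIO3 undefined at {int(flat.sum())} cell(s) with zero annual "
            "temperature range; set to nodata",
            stacklevel=2,
        )
        out[3][flat] = nodata
    out[12] = prec.sum(axis=0)
    out[13] = prec.max(axis=0)
    out[14] = prec.min(axis=0)
    out[15] = 100.0 * prec.std(axis=0, ddof=1) / (1.0 + prec.mean(axis=0))

    pq = _quarter_sums(prec)  # precip total per quarter
    tq = _quarter_sums(tavg) / 3.0  # mean temperature per quarter
    wettest = pq.argmax(axis=0)  # argmax/argmin take the earliest on ties
    driest = pq.argmin(axis=0)
    warmest = tq.argmax(axis=0)
    coldest = tq.argmin(axis=0)
    cells = np.arange(pq.shape[1])
    out[8] = tq[wettest, cells]
    out[9] = tq[driest, cells]
    out[10] = tq[warmest, cells]
    out[11] = tq[coldest, cells]
    out[16] = pq[wettest, cells]
    out[17] = pq[driest, cells]
    out[18] = pq[warmest, cells]
    out[19] = pq[coldest, cells]

    bio: dict[int, RasterGrid] = {}
    for i in range(1, 20):
        full = np.full(spec.shape, nodata)
        full[mask] = out[i]
        bio[i] = RasterGrid(spec, full)
    return BioclimStack(window=normals.window, bio=bio)


def correlation_prune(
    stack: BioclimStack,
    threshold: float = 0.7,
    priority: Sequence[int] = DEFAULT_PRUNE_PRIORITY,
) -> PredictorSet:
    """Greedy correlation pruning over jointly valid cells.

    Scanning in ``priority`` order, a variable is retained iff its absolute
    Pearson correlation with every already-retained variable is <= the
    threshold; otherwise it is dropped and records its blocking partner.
    Zero-variance layers are excluded with a warning.
    """
    variables = [v for v in priority if v in stack.bio]
    mask = stack.valid_mask(variables)
    if int(mask.sum()) < 2:
        raise ValueError("need at least 2 jointly valid cells to correlate")
    data = {v: stack.bio[v].values[mask] for v in variables}

    retained: list[int] = []
    dropped: list[tuple[int, int, float]] = []
    for v in variables:
        x = data[v]
        if np.std(x) == 0:
            warnings.warn(f"BIO{v} has zero variance; excluded from pruning", stacklevel=2)
            continue
        blocker = None
        for kept in retained:
            r = float(np.corrcoef(x, data[kept])[0, 1])
            if abs(r) > threshold:
                blocker = (v, kept, r)
                break
        if blocker is None:
            retained.append(v)
        else:
            dropped.append(blocker)
    return PredictorSet(retained=retained, dropped=dropped, threshold=threshold)
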