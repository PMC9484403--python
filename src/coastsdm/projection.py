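"""Suitability aggregation across regions, periods and species groups.

The region-wise sum of cloglog suitability is the measure of total
suitable habitat.  Group trajectories compare the mangrove and salt-marsh
group means across time windows via ratios and percent changes, and the
hindcast decision rule checks that projections into past windows of
documented dominance reproduce the known group-level ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import RasterGrid

__all__ = [
    "RegionBox",
    "PeriodSummary",
    "ValidationReport",
    "total_suitability",
    "group_average",
    "percent_change",
    "suitability_ratio",
    "hindcast_validate",
    "project_timeline",
    "NE_FLORIDA",
    "FLORIDA",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionBox:
    """A named lat/lon box; membership is by cell center, inclusive."""

    name: str
    west: float
    east: float
    south: float
    north: float

    def __post_init__(self) -> None:
        if not (self.east > self.west and self.north > self.south):
            raise ValueError(f"degenerate region {self.name}")


# The two hindcast-validation regions around the Florida ecotone.
NE_FLORIDA = RegionBox("NE Florida", west=-82.0, east=-80.0, south=28.0, north=31.0)
FLORIDA = RegionBox("Florida", west=-87.0, east=-79.0, south=24.0, north=31.0)


@dataclass
class PeriodSummary:
    """Per-species suitability sums and group means for one region/window."""

    region: str
    window: str
    species_S: dict[str, float]
    group_S: dict[str, float]  # group name -> mean of member species' S


@dataclass
class ValidationReport:
    region: str
    criterion_mangrove: bool  # group-1 mean lowest in the rival's period
    criterion_saltmarsh: bool
    criterion_ratio: bool
    validated: bool
    species_orderings: dict[str, bool] = field(default_factory=dict)


def total_suitability(grid: RasterGrid, region: RegionBox | None = None) -> float:
    """Sum of cloglog values over valid cells with centers in the region."""
    mask = grid.valid_mask
    if region is not None:
        spec = grid.spec
        lon_ok = (spec.lon_centers() >= region.west) & (spec.lon_centers() <= region.east)
        lat_ok = (spec.lat_centers() >= region.south) & (spec.lat_centers() <= region.north)
        box = np.outer(lat_ok, lon_ok)
        if not box.any():
            raise ValueError(f"region {region.name} overlaps no cell center")
        mask = mask & box
    return float(grid.values[mask].sum())


def group_average(species_S: Sequence[float] | Mapping[str, float]) -> float:
    """Arithmetic mean of member species' suitability sums."""
    values = list(species_S.values()) if isinstance(species_S, Mapping) else list(species_S)
    if not values:
        raise ValueError("empty species group")
    return float(np.mean(values))


def percent_change(S_t: float, S_present: float) -> float:
    """100 * (S_t - S_present) / S_present."""
    if S_present <= 0:
        raise ValueError("present-period suitability must be positive")
    return 100.0 * (S_t - S_present) / S_present


def suitability_ratio(S_mangrove: float, S_saltmarsh: float) -> float:
    """Mangrove : salt-marsh suitable-habitat ratio."""
    if S_saltmarsh <= 0:
        raise ValueError("salt-marsh suitability must be positive")
    return S_mangrove / S_saltmarsh


def summarize_period(
    region: RegionBox,
    window: str,
    species_maps: Mapping[str, RasterGrid],
    groups: Mapping[str, Sequence[str]],
) -> PeriodSummary:
    """Sum each species' suitability over the region and average by group."""
    species_S = {
        sp: total_suitability(grid, region) for sp, grid in species_maps.items()
    }
    group_S = {
        g: group_average([species_S[sp] for sp in members])
        for g, members in groups.items()
    }
    return PeriodSummary(region=region.name, window=window,
                         species_S=species_S, group_S=group_S)


def hindcast_validate(
    summaries: Mapping[str, PeriodSummary],
    mangrove_group: str = "mangrove",
    saltmarsh_group: str = "saltmarsh",
) -> ValidationReport:
    """Check the documented-dominance ordering against the hindcasts.

    ``summaries`` maps the period roles ``saltmarsh_dom``, ``mangrove_dom``
    and ``present`` to their summaries for one region.  The model is
    validated when, on unrounded group means:

    * mangrove suitability is lower in the salt-marsh dominance period
      than in the mangrove dominance period,
    * salt-marsh suitability is lower in the mangrove dominance period
      than in the salt-marsh dominance period, and
    * the mangrove:salt-marsh ratio is higher under mangrove dominance
      than under salt-marsh dominance.

    Species-level orderings are reported for information only; individual
    species may deviate without failing the verdict.
    """
    for role in ("saltmarsh_dom", "mangrove_dom", "present"):
        if role not in summaries:
            raise ValueError(f"missing period summary for role {role!r}")
    sm = summaries["saltmarsh_dom"]
    mg = summaries["mangrove_dom"]

    a = sm.group_S[mangrove_group] < mg.group_S[mangrove_group]
    b = mg.group_S[saltmarsh_group] < sm.group_S[saltmarsh_group]
    ratio_mg = suitability_ratio(mg.group_S[mangrove_group], mg.group_S[saltmarsh_group])
    ratio_sm = suitability_ratio(sm.group_S[mangrove_group], sm.group_S[saltmarsh_group])
    c = ratio_mg > ratio_sm

    species_ok: dict[str, bool] = {}
    for sp in sm.species_S:
        if sp in mg.species_S:
            # does the species follow its own group's expected ordering?
            # (membership inferred from which group averages it enters is
            # not tracked here; callers pass orderings onward untouched)
            species_ok[sp] = sm.species_S[sp] < mg.species_S[sp]
    region = sm.region
    return ValidationReport(
        region=region,
        criterion_mangrove=bool(a),
        criterion_saltmarsh=bool(b),
        criterion_ratio=bool(c),
        validated=bool(a and b and c),
        species_orderings=species_ok,
    )


def project_timeline(
    species_maps: Mapping[str, Mapping[str, RasterGrid]],
    regions: Sequence[RegionBox],
    groups: Mapping[str, Sequence[str]],
    present_window: str,
    mangrove_group: str = "mangrove",
    saltmarsh_group: str = "saltmarsh",
) -> dict[str, pd.DataFrame]:
    """Aggregate per-window suitability maps into the reporting tables.

    ``species_maps`` maps window name -> species -> suitability grid.
    Returns four tables: per-species sums with group means (``sums``),
    mangrove:salt-marsh ratios (``ratios``), group percent changes
    (``group_change``) and species percent changes (``species_change``)
    versus the present window.  Sums are reported to 1 decimal, ratios to
    3, percent changes to 1; percent changes of group means are computed
    from the unrounded group-average sums.
    """
    windows = list(species_maps)
    if present_window not in windows:
        raise ValueError(f"present window {present_window!r} has no maps")
    species = list(next(iter(species_maps.values())))

    sums_rows, ratio_rows, gch_rows, sch_rows = [], [], [], []
    for region in regions:
        summaries = {}
        for w in windows:
            if set(species_maps[w]) != set(species):
                log.warning("window %s is missing species; omitted from tables", w)
                continue
            summaries[w] = summarize_period(region, w, species_maps[w], groups)
        present = summaries[present_window]
        for w, summ in summaries.items():
            sums_rows.append(
                {"region": region.name, "window": w}
                | {sp: round(summ.species_S[sp], 1) for sp in species}
                | {f"avg_{g}": round(summ.group_S[g], 1) for g in groups}
            )
            ratio_rows.append(
                {
                    "region": region.name,
                    "window": w,
                    "ratio": round(
                        suitability_ratio(
                            summ.group_S[mangrove_group], summ.group_S[saltmarsh_group]
                        ),
                        3,
                    ),
                }
            )
            gch_rows.append(
                {"region": region.name, "window": w}
                | {
                    g: round(percent_change(summ.group_S[g], present.group_S[g]), 1)
                    for g in groups
                }
            )
            sch_rows.append(
                {"region": region.name, "window": w}
                | {
                    sp: round(percent_change(summ.species_S[sp], present.species_S[sp]), 1)
                    for sp in species
                }
            )
    return {
        "sums": pd.DataFrame(sums_rows),
        "ratios": pd.DataFrame(ratio_rows),
        "group_change": pd.DataFrame(gch_rows),
        "species_change": pd.DataFrame(sch_rows),
    }
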