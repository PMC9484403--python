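"""Config-file-driven pipeline with file artifacts and a run manifest.

Each stage reads its inputs from, and writes its outputs under, the
configured output directory, so stages are idempotent and a rerun with
the same config and seed reproduces the artifacts bit for bit.  The
stages mirror the study design:

``simulate``   synthetic monthly climate, elevation and occurrences
``bioclim``    window averages -> BIO1..BIO19 stacks, elevation-masked
``prune``      correlation pruning of predictors on the present window
``fit``        per-species maximum-entropy models on the present window
``evaluate``   partial ROC, jackknife gain, percent contribution
``project``    suitability maps for every window
``aggregate``  suitability sums, ratios, percent-change tables
``validate``   hindcast decision rule on the past dominance windows
``report``     all of the above plus the machine-readable manifest
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioclim import BioclimStack, correlation_prune
from .evaluation import jackknife_gain, partial_roc, percent_contribution, training_gain
from .grids import GridSpec, RasterGrid
from .maxent import MaxentModel, fit, min_training_presence, predict, sample_background
from .projection import RegionBox, hindcast_validate, project_timeline, summarize_period
from .spatial_io import (
    clean_occurrences,
    elevation_mask,
    min_occurrence_filter,
    read_occurrences,
    read_raster,
    write_occurrences,
    write_raster,
)
from .synthetic import (
    DEFAULT_GRID,
    ClimateScenario,
    TruthModel,
    default_truths,
    generate_climate,
    generate_elevation,
    generate_occurrences,
)
from .workflow import build_stacks, occurrences_to_env

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "bioclim",
    "prune",
    "fit",
    "evaluate",
    "project",
    "aggregate",
    "validate",
    "report",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "coastsdm_out",
    "windows": {
        "saltmarsh_dom": [1984, 1989],
        "mangrove_dom": [2001, 2006],
        "present": [2013, 2018],
        "future1": [2021, 2040],
        "future2": [2041, 2060],
        "future3": [2061, 2080],
    },
    "extent": {"west": -120.0, "east": -32.0, "south": -36.0, "north": 36.0},
    "regions": [
        {"name": "NE Florida", "west": -82.0, "east": -80.0, "south": 28.0, "north": 31.0},
        {"name": "Florida", "west": -87.0, "east": -79.0, "south": 24.0, "north": 31.0},
    ],
    "groups": {
        "mangrove": ["mangrove_a", "mangrove_b"],
        "saltmarsh": ["saltmarsh_a", "saltmarsh_b"],
    },
    "thresholds": {
        "correlation_r": 0.7,
        "elevation_m": 10.0,
        "n_min": 50,
        "n_background": 10000,
    },
    "features": {"classes": "lq", "multiplier": 1.0},
    "evaluation": {"proc_boot": 1000, "proc_E": 0.05},
    "synthetic": {
        "enabled": True,
        "m_occurrences": 600,
        "maskable_fraction": 0.3,
        "invert_past": False,
        "grid": None,  # defaults to the desk-scale synthetic grid
    },
    "raster_format": "ascii_grid",
}


class ConfigError(ValueError):
    """The run configuration violates the schema."""


@dataclass
class RunConfig:
    """Validated run configuration (see DEFAULT_CONFIG for the schema)."""

    data: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = _deep_merge(DEFAULT_CONFIG, self.data)
        _validate_config(merged)
        self.data = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls(data)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def out(self) -> Path:
        return Path(self.data["output_dir"])

    @property
    def windows(self) -> dict[str, tuple[int, int]]:
        return {k: tuple(v) for k, v in self.data["windows"].items()}

    @property
    def regions(self) -> list[RegionBox]:
        return [RegionBox(**r) for r in self.data["regions"]]

    @property
    def suffix(self) -> str:
        return ".asc" if self.data["raster_format"] == "ascii_grid" else ".tif"


#: config sections the user replaces wholesale rather than merging into
#: the defaults (a custom window or group set stands on its own)
_REPLACE_KEYS = {"windows", "groups"}


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        if (
            isinstance(v, dict)
            and isinstance(out.get(k), dict)
            and k not in _REPLACE_KEYS
        ):
            out[k] = _deep_merge(out[k], v, f"{path}{k}.")
        else:
            out[k] = v
    return out


def _validate_config(cfg: dict) -> None:
    for key in ("seed", "output_dir", "windows", "regions", "groups", "thresholds"):
        if key not in cfg:
            raise ConfigError(f"config missing required field {key!r}")
    roles = {"saltmarsh_dom", "mangrove_dom", "present"}
    if not roles <= set(cfg["windows"]):
        raise ConfigError(f"windows must include roles {sorted(roles)}")
    for name, w in cfg["windows"].items():
        if len(w) != 2 or w[0] > w[1]:
            raise ConfigError(f"window {name!r} must be [start_year, end_year]")
    spans = sorted((tuple(w), n) for n, w in cfg["windows"].items())
    for (a, na), (b, nb) in zip(spans, spans[1:]):
        if b[0] <= a[1]:
            raise ConfigError(f"windows {na!r} and {nb!r} overlap")
    seen: dict[str, str] = {}
    for g, members in cfg["groups"].items():
        for sp in members:
            if sp in seen:
                raise ConfigError(f"species {sp!r} in groups {seen[sp]!r} and {g!r}")
            seen[sp] = g
    for r in cfg["regions"]:
        missing = {"name", "west", "east", "south", "north"} - set(r)
        if missing:
            raise ConfigError(f"region missing fields {sorted(missing)}")


class Pipeline:
    """Executes the stages for one configuration."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = config.out
        self.manifest: dict[str, Any] = {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config.data, sort_keys=True).encode()
            ).hexdigest(),
            "stages": {},
        }

    # ---------------------------------------------------------------- utils
    def _windows_years(self) -> list[int]:
        return sorted(
            {y for w in self.cfg.windows.values() for y in range(w[0], w[1] + 1)}
        )

    def _grid(self) -> GridSpec:
        g = self.cfg["synthetic"].get("grid")
        if g:
            return GridSpec(**g)
        return DEFAULT_GRID

    def _species(self) -> list[str]:
        return [sp for members in self.cfg["groups"].values() for sp in members]

    def _raster_path(self, *parts: str) -> Path:
        return self.out.joinpath(*parts).with_suffix(self.cfg.suffix)

    def _stamp(self, stage: str, t0: float, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {
                str(p.relative_to(self.out)): _sha256(p) for p in sorted(outputs)
            },
        }

    # --------------------------------------------------------------- stages
    def simulate(self) -> None:
        t0 = time.perf_counter()
        sy = self.cfg["synthetic"]
        if not sy.get("enabled", True):
            log.info("synthetic input disabled; simulate is a no-op")
            return
        grid = self._grid()
        invert = sy.get("invert_past", False)
        cold_wet, warm_dry = (-2.5, 30.0), (1.2, -35.0)
        if invert:
            cold_wet, warm_dry = warm_dry, cold_wet
        offsets: dict[tuple[int, int], tuple[float, float]] = {
            tuple(self.cfg.windows["saltmarsh_dom"]): cold_wet,
            tuple(self.cfg.windows["mangrove_dom"]): warm_dry,
            tuple(self.cfg.windows["present"]): (0.0, 0.0),
        }
        futures = sorted(
            tuple(w)
            for name, w in self.cfg.windows.items()
            if name not in ("saltmarsh_dom", "mangrove_dom", "present")
        )
        for i, w in enumerate(futures):  # progressive warming and drying
            offsets[w] = (1.0 + i, -15.0 - 10.0 * i)
        scenario = ClimateScenario(
            grid=grid, period_offsets=offsets, seed=self.cfg.seed
        )
        series = generate_climate(scenario, self._windows_years())
        outputs = []
        for (year, month), grids in series.items():
            for var, g in grids.items():
                p = self._raster_path("climate", f"{var}_{year}_{month:02d}")
                write_raster(g, p)
                outputs.append(p)
        elev = generate_elevation(
            grid,
            maskable_fraction=sy.get("maskable_fraction", 0.3),
            seed=self.cfg.seed,
        )
        p = self._raster_path("elevation")
        write_raster(elev, p)
        outputs.append(p)

        truths = self._truths()
        # occurrences need the present bioclim stack
        stacks = build_stacks(
            series, {"present": self.cfg.windows["present"]}, None
        )
        for sp, truth in truths.items():
            occ = generate_occurrences(
                truth,
                stacks["present"],
                m=sy.get("m_occurrences", 600),
                seed=self.cfg.seed + zlib.crc32(sp.encode()) % 10_000,
                species=sp,
                n_duplicates=sy.get("n_duplicates", 0),
                n_zero_zero=sy.get("n_zero_zero", 0),
            )
            path = self.out / "occurrences" / f"{sp}.csv"
            write_occurrences(occ, path)
            outputs.append(path)
        self._stamp("simulate", t0, outputs)

    def _truths(self) -> dict[str, TruthModel]:
        sy = self.cfg["synthetic"]
        if "truths" in sy and sy["truths"]:
            return {
                sp: TruthModel({int(k): v for k, v in coefs.items()})
                for sp, coefs in sy["truths"].items()
            }
        return default_truths()

    def _read_series(self):
        series = {}
        for p in sorted((self.out / "climate").glob(f"*{self.cfg.suffix}")):
            var, year, month = p.stem.rsplit("_", 2)
            series.setdefault((int(year), int(month)), {})[var] = read_raster(p)
        if not series:
            raise FileNotFoundError(
                f"no climate rasters under {self.out / 'climate'}; run simulate "
                "or point the config at real data"
            )
        return series

    def bioclim(self) -> None:
        t0 = time.perf_counter()
        series = self._read_series()
        elev = read_raster(self._raster_path("elevation"))
        stacks = build_stacks(
            series,
            self.cfg.windows,
            elev,
            self.cfg["thresholds"]["elevation_m"],
        )
        outputs = []
        for w, stack in stacks.items():
            for i, g in stack.bio.items():
                p = self._raster_path("bioclim", w, f"bio{i:02d}")
                write_raster(g, p)
                outputs.append(p)
        self._stamp("bioclim", t0, outputs)

    def _read_stack(self, window: str, variables=None) -> BioclimStack:
        bio = {}
        for p in sorted((self.out / "bioclim" / window).glob(f"bio*{self.cfg.suffix}")):
            i = int(p.stem[3:])
            if variables is None or i in variables:
                bio[i] = read_raster(p)
        if not bio:
            raise FileNotFoundError(f"no bioclim rasters for window {window!r}")
        return BioclimStack(window=tuple(self.cfg.windows[window]), bio=bio)

    def prune(self) -> None:
        t0 = time.perf_counter()
        stack = self._read_stack("present")
        predictors = correlation_prune(
            stack, self.cfg["thresholds"]["correlation_r"]
        )
        rows = [
            {"variable": f"BIO{v}", "status": "retained", "partner": "", "r": ""}
            for v in predictors.retained
        ] + [
            {
                "variable": f"BIO{d}",
                "status": "dropped",
                "partner": f"BIO{k}",
                "r": round(r, 4),
            }
            for d, k, r in predictors.dropped
        ]
        p = self.out / "predictors.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        self._stamp("prune", t0, [p])

    def _retained(self) -> list[int]:
        df = pd.read_csv(self.out / "predictors.csv")
        return sorted(
            int(v[3:]) for v in df.loc[df.status == "retained", "variable"]
        )

    def fit(self) -> None:
        t0 = time.perf_counter()
        variables = self._retained()
        present = self._read_stack("present", variables)
        thr = self.cfg["thresholds"]
        _, bg_cells = sample_background(
            present, thr["n_background"], self.cfg.seed, variables
        )
        rows, cols = np.unravel_index(bg_cells, present.spec.shape)
        bg_env = np.column_stack(
            [present.bio[v].values[rows, cols] for v in variables]
        )
        np.savetxt(self.out / "background_env.csv", bg_env, delimiter=",", header=",".join(f"BIO{v}" for v in variables), comments="")
        outputs = [self.out / "background_env.csv"]
        feat = self.cfg["features"]
        ext = self.cfg["extent"]
        for sp in self._species():
            raw = read_occurrences(self.out / "occurrences" / f"{sp}.csv")
            occ, rep = clean_occurrences(
                raw, species=sp,
                extent=(ext["west"], ext["east"], ext["south"], ext["north"]),
            )
            if not min_occurrence_filter(occ, thr["n_min"]):
                log.warning("%s: only %d occurrences after cleaning; skipped",
                            sp, len(occ))
                continue
            env = occurrences_to_env(occ, present, variables)
            model = fit(
                env, bg_env, variables, feat["classes"], feat["multiplier"]
            )
            p = self.out / "models" / f"{sp}.json"
            model.save(p)
            outputs.append(p)
            env_path = self.out / "models" / f"{sp}_presence_env.csv"
            np.savetxt(env_path, env, delimiter=",", header=",".join(f"BIO{v}" for v in variables), comments="")
            outputs.append(env_path)
        self._stamp("fit", t0, outputs)

    def evaluate(self) -> None:
        t0 = time.perf_counter()
        variables = self._retained()
        present = self._read_stack("present", variables)
        bg_env = np.loadtxt(self.out / "background_env.csv", delimiter=",", skiprows=1)
        ev = self.cfg["evaluation"]
        feat = self.cfg["features"]
        rows = []
        outputs = []
        for sp in self._species():
            model_path = self.out / "models" / f"{sp}.json"
            if not model_path.exists():
                continue
            model = MaxentModel.load(model_path)
            env = np.loadtxt(
                self.out / "models" / f"{sp}_presence_env.csv",
                delimiter=",", skiprows=1,
            )
            land_pred = model.cloglog(bg_env)
            pres_pred = model.cloglog(env)
            ratio, pval = partial_roc(
                pres_pred,
                land_pred,
                E=ev["proc_E"],
                n_boot=ev["proc_boot"],
                seed=self.cfg.seed,
            )
            jack = jackknife_gain(
                env, bg_env, variables, feat["classes"], feat["multiplier"]
            )
            contrib = percent_contribution(model)
            rows.append(
                {
                    "species": sp,
                    "proc_ratio": round(ratio, 4),
                    "proc_p": round(pval, 4),
                    "training_gain": round(training_gain(model), 4),
                    "mtp_threshold": round(min_training_presence(model, env), 4),
                }
                | {f"contrib_BIO{v}": round(c, 1) for v, c in sorted(contrib.items())}
                | {f"gain_alone_BIO{v}": round(g[0], 4) for v, g in sorted(jack.items())}
                | {f"gain_without_BIO{v}": round(g[1], 4) for v, g in sorted(jack.items())}
            )
        p = self.out / "evaluation.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs.append(p)
        self._stamp("evaluate", t0, outputs)

    def project(self) -> None:
        t0 = time.perf_counter()
        variables = self._retained()
        outputs = []
        for w in self.cfg.windows:
            stack = self._read_stack(w, variables)
            for sp in self._species():
                model_path = self.out / "models" / f"{sp}.json"
                if not model_path.exists():
                    continue
                model = MaxentModel.load(model_path)
                grid = predict(model, stack, clamp=True)
                p = self._raster_path("suitability", w, sp)
                write_raster(grid, p)
                outputs.append(p)
        self._stamp("project", t0, outputs)

    def _suitability_maps(self) -> dict[str, dict[str, RasterGrid]]:
        maps: dict[str, dict[str, RasterGrid]] = {}
        for w in self.cfg.windows:
            d = {}
            for sp in self._species():
                p = self._raster_path("suitability", w, sp)
                if p.exists():
                    d[sp] = read_raster(p)
            if d:
                maps[w] = d
        if not maps:
            raise FileNotFoundError("no suitability maps; run project first")
        return maps

    def aggregate(self) -> None:
        t0 = time.perf_counter()
        maps = self._suitability_maps()
        regions = self.cfg.regions
        if self.cfg["synthetic"].get("enabled", True):
            g = self._grid()
            regions = [RegionBox("synthetic domain", g.west, g.east, g.south, g.north)] + [
                r for r in regions if _region_on_grid(r, g)
            ]
        tables = project_timeline(
            maps, regions, self.cfg["groups"], "present"
        )
        outputs = []
        for name, df in tables.items():
            p = self.out / "tables" / f"{name}.csv"
            p.parent.mkdir(parents=True, exist_ok=True)
            df.to_csv(p, index=False)
            outputs.append(p)
        self._stamp("aggregate", t0, outputs)

    def validate(self) -> None:
        t0 = time.perf_counter()
        maps = self._suitability_maps()
        if self.cfg["synthetic"].get("enabled", True):
            g = self._grid()
            region = RegionBox("synthetic domain", g.west, g.east, g.south, g.north)
        else:
            region = self.cfg.regions[0]
        summaries = {
            role: summarize_period(region, w, maps[w], self.cfg["groups"])
            for role, w in (
                ("saltmarsh_dom", "saltmarsh_dom"),
                ("mangrove_dom", "mangrove_dom"),
                ("present", "present"),
            )
        }
        report = hindcast_validate(summaries)
        p = self.out / "validation.json"
        p.write_text(
            json.dumps(
                {
                    "region": report.region,
                    "criterion_mangrove": report.criterion_mangrove,
                    "criterion_saltmarsh": report.criterion_saltmarsh,
                    "criterion_ratio": report.criterion_ratio,
                    "validated": report.validated,
                    "group_sums": {
                        role: s.group_S for role, s in summaries.items()
                    },
                },
                indent=1,
            )
        )
        self._stamp("validate", t0, [p])
        if not report.validated:
            log.warning("hindcast validation FAILED for region %s", report.region)

    def report(self) -> None:
        for stage in STAGES[:-1]:
            self.run_stage(stage)
        self.write_manifest()

    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
        self.out.mkdir(parents=True, exist_ok=True)
        getattr(self, stage)()

    def write_manifest(self) -> Path:
        p = self.out / "manifest.json"
        p.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return p


def _region_on_grid(r: RegionBox, g: GridSpec) -> bool:
    """True when at least one cell center falls inside the region."""
    lon = g.lon_centers()
    lat = g.lat_centers()
    return bool(
        ((lon >= r.west) & (lon <= r.east)).any()
        and ((lat >= r.south) & (lat <= r.north)).any()
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
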