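"""Synthetic study system with known ground truth.

Generates everything a real niche-modeling study downloads: spatially
autocorrelated, partially collinear environmental raster stacks; a true
suitability surface with a cloglog link; presence samples drawn from that
surface; and per-scenario shifted stacks inducing known expansion or
contraction.  Every output is deterministic under (config, seed), and the
truth bundle (true areas, centroids, coefficients) is recomputable from
the config alone, so every pipeline stage can be tested offline against
an exact oracle.

Defaults describe the study conditions used throughout the test suite: a
100x100 grid of 0.05-degree cells over a subtropical-China-scale window,
six standardized smoothed fields with one planted r = 0.9 collinear pair
of which only one member is causal, a single dominant coefficient, 200
presences, and two climate-shift scenarios.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter

from .errors import ConfigError, DataError
from .habitat import SuitabilityClassMap, centroid, class_areas, classify
from .occurrences import OccurrenceRecord, OccurrenceSet
from .raster_io import (
    GridSpec,
    Raster,
    RasterStack,
    area_grid_km2,
    cell_center,
    write_ascii_grid,
)

__all__ = [
    "GeneratorConfig",
    "TruthBundle",
    "gen_env_stack",
    "true_suitability",
    "sample_presences",
    "gen_scenario",
    "end_to_end_fixture",
]


def _default_coefficients():
    # env1 dominant; env2 is its r=0.9 twin but carries no effect itself.
    # Magnitudes give a sharp response and, with the -8 intercept, a
    # range-restricted species covering roughly a tenth of the window.
    return {"env1": 5.0, "env2": 0.0, "env3": 1.6, "env4": -1.2, "env5": 0.8, "env6": 0.0}


def _default_scenarios():
    # additive shifts in standardized units: a warming-like degradation of
    # the dominant driver (mild and strong variants)
    return {
        "future_mild": {"env1": -0.15, "env3": 0.05},
        "future_strong": {"env1": -0.4, "env3": 0.1},
    }


@dataclass
class GeneratorConfig:
    nrows: int = 100
    ncols: int = 100
    cellsize: float = 0.05
    origin: tuple[float, float] = (100.0, 20.0)  # (lon, lat) of the ll corner
    n_vars: int = 6
    smoothness: int = 5  # moving-average kernel width in cells
    correlation_plan: tuple = (("env1", "env2", 0.9),)
    coefficients: dict = field(default_factory=_default_coefficients)
    quadratic: dict = field(default_factory=dict)
    intercept: float = -8.0
    n_presences: int = 200
    scenario_shifts: dict = field(default_factory=_default_scenarios)
    seed: int = 0
    species: str = "synthetic_species"

    def __post_init__(self):
        if self.n_vars < 2:
            raise ConfigError("need at least 2 variables")
        if self.n_presences < 10:
            raise ConfigError("need at least 10 presences")
        for a, b, r in self.correlation_plan:
            if not abs(r) < 1:
                raise ConfigError(f"|target r| must be < 1, got {r} for ({a}, {b})")

    @property
    def var_names(self) -> list[str]:
        return [f"env{i + 1}" for i in range(self.n_vars)]

    def spec(self) -> GridSpec:
        return GridSpec(self.ncols, self.nrows, self.origin[0], self.origin[1], self.cellsize)


@dataclass
class TruthBundle:
    config: GeneratorConfig
    suitability: dict[str, Raster]  # per scenario
    class_areas: dict[str, dict[str, float]]  # 1e4 km^2, per scenario
    centroids: dict[str, tuple[float, float]]
    coefficients: dict[str, float]


def _smooth_standard_field(rng, nrows, ncols, width) -> np.ndarray:
    z = rng.standard_normal((nrows, ncols))
    if width and width > 1:
        z = uniform_filter(z, size=width, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def gen_env_stack(cfg: GeneratorConfig) -> RasterStack:
    """Smoothed, standardized noise fields with the planned pairwise
    correlations imposed by linear mixing ``y = r x + sqrt(1 - r^2) z``."""
    targets = [b for _, b, _ in cfg.correlation_plan]
    if len(set(targets)) != len(targets):
        raise ConfigError("correlation plan assigns one variable twice")
    sources = {a for a, _, _ in cfg.correlation_plan}
    if sources & set(targets):
        raise ConfigError("correlation plan has chained/cyclic dependencies")
    for a, b, _ in cfg.correlation_plan:
        if a not in cfg.var_names or b not in cfg.var_names:
            raise ConfigError(f"correlation plan names unknown variable ({a}, {b})")

    rng = np.random.default_rng(cfg.seed)
    spec = cfg.spec()
    fields = {
        name: _smooth_standard_field(rng, cfg.nrows, cfg.ncols, cfg.smoothness)
        for name in cfg.var_names
    }
    for a, b, r in cfg.correlation_plan:
        mixed = r * fields[a] + np.sqrt(1 - r**2) * fields[b]
        mixed = mixed - mixed.mean()
        fields[b] = mixed / mixed.std()
    return RasterStack([Raster(spec, fields[n], n) for n in cfg.var_names])


def true_suitability(stack: RasterStack, cfg: GeneratorConfig) -> Raster:
    """Ground-truth surface: cloglog of a log-linear predictor,
    ``1 - exp(-exp(eta))`` with ``eta = intercept + sum c_v x_v
    (+ optional quadratic terms)``."""
    eta = np.full((stack.spec.nrows, stack.spec.ncols), cfg.intercept, dtype=float)
    for name, c in cfg.coefficients.items():
        if c == 0:
            continue
        eta += c * stack.get(name).values
    for name, c in cfg.quadratic.items():
        if c == 0:
            continue
        eta += c * stack.get(name).values ** 2
    suit = 1.0 - np.exp(-np.exp(eta))
    return Raster(stack.spec, suit, "true_suitability")


def sample_presences(surface: Raster, n: int, seed: int, species: str = "synthetic_species") -> OccurrenceSet:
    """Draw cells without replacement with probability proportional to
    suitability x cell area; records sit at cell centers."""
    suit = surface.values
    finite = ~np.isnan(suit)
    w = np.where(finite, suit, 0.0) * area_grid_km2(surface.spec)
    flat = w.ravel()
    n_candidates = int((flat > 0).sum())
    if n > n_candidates:
        raise DataError(f"requested {n} presences but only {n_candidates} suitable cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    records = []
    for k, i in enumerate(idx):
        row, col = divmod(int(i), surface.spec.ncols)
        lon, lat = cell_center(row, col, surface.spec)
        records.append(OccurrenceRecord(lon, lat, source="synthetic", raw_id=str(k)))
    return OccurrenceSet(species, records)


def gen_scenario(stack: RasterStack, shifts: dict[str, float]) -> RasterStack:
    """Additive per-variable deltas (standardized units); unknown variable
    names are an error."""
    unknown = [v for v in shifts if v not in stack.names]
    if unknown:
        raise ConfigError(f"scenario shift for unknown variable(s): {unknown}")
    layers = []
    for lyr in stack.layers:
        delta = shifts.get(lyr.name, 0.0)
        layers.append(Raster(lyr.spec, lyr.values + delta, lyr.name))
    return RasterStack(layers, mask=stack.mask)


def truth_bundle(cfg: GeneratorConfig) -> tuple[dict[str, RasterStack], TruthBundle]:
    """All scenario stacks plus the exact truth (suitability, class areas,
    centroids) under the shared generator coefficients."""
    base = gen_env_stack(cfg)
    stacks = {"current": base}
    for name, shifts in cfg.scenario_shifts.items():
        stacks[name] = gen_scenario(base, shifts)
    suits = {name: true_suitability(s, cfg) for name, s in stacks.items()}
    cmaps = {name: classify(s) for name, s in suits.items()}
    areas = {name: class_areas(cm) for name, cm in cmaps.items()}
    cents = {name: centroid(cm) for name, cm in cmaps.items()}
    bundle = TruthBundle(cfg, suits, areas, cents, dict(cfg.coefficients))
    return stacks, bundle


def end_to_end_fixture(cfg: GeneratorConfig, out_dir) -> dict:
    """Write every input the pipeline consumes: occurrence CSV, per-scenario
    ASCII grids, a pipeline config file, and the truth tables.

    Returns paths plus the in-memory :class:`TruthBundle`.
    """
    from .occurrences import write_occurrences_csv

    os.makedirs(out_dir, exist_ok=True)
    stacks, bundle = truth_bundle(cfg)
    presences = sample_presences(
        bundle.suitability["current"], cfg.n_presences, cfg.seed + 1, cfg.species
    )
    occ_path = os.path.join(out_dir, "occurrences.csv")
    write_occurrences_csv(presences, occ_path)

    scenario_dirs = {}
    for name, stack in stacks.items():
        sdir = os.path.join(out_dir, "layers", name)
        os.makedirs(sdir, exist_ok=True)
        for lyr in stack.layers:
            write_ascii_grid(lyr, os.path.join(sdir, f"{lyr.name}.asc"))
        scenario_dirs[name] = sdir

    truth_rows = []
    for name, a in bundle.class_areas.items():
        row = {"scenario": name, **{k: v for k, v in a.items()}}
        row["centroid_lon"], row["centroid_lat"] = bundle.centroids[name]
        truth_rows.append(row)
    truth_path = os.path.join(out_dir, "truth_areas.csv")
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)

    config = {
        "species": cfg.species,
        "occurrences": occ_path,
        "scenarios": scenario_dirs,
        "baseline": "current",
        "output_dir": os.path.join(out_dir, "run"),
        "seed": cfg.seed,
        "thinning": {"cellsize": 2.5 / 60},
        "selection": {"threshold": 0.8},
        "model": {
            "feature_classes": ["linear", "quadratic", "hinge"],
            "beta_multiplier": 1.0,
            "background_size": 10000,
            "replicates": 10,
            "transform": "cloglog",
            "clamp": True,
        },
        "classification": {"breaks": [0.25, 0.5, 0.75]},
    }
    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    return {
        "occurrences": occ_path,
        "scenario_dirs": scenario_dirs,
        "config": config_path,
        "truth_csv": truth_path,
        "truth": bundle,
        "stacks": stacks,
        "presences": presences,
    }


def run_synthetic_study(seed: int, workdir) -> dict:
    """Generate the default synthetic study for one seed, run the full
    pipeline on it, and collect the headline results alongside the truth.

    Returns a dict with the kept variables, drop log, evaluation summary,
    importance table (DataFrame), area table (DataFrame), centroid track
    (DataFrame), and the :class:`TruthBundle`.
    """
    import json

    from .pipeline import load_config, run_full

    fx = end_to_end_fixture(GeneratorConfig(seed=seed), workdir)
    out = run_full(load_config(fx["config"]))
    manifest = json.load(open(os.path.join(out, "manifest.json")))
    return {
        "out": out,
        "truth": fx["truth"],
        "kept": manifest["kept_variables"],
        "evaluation": manifest["evaluation"],
        "drop_log": pd.read_csv(os.path.join(out, "variable_drop_log.csv")),
        "importance": pd.read_csv(os.path.join(out, "importance_table.csv")),
        "areas": pd.read_csv(os.path.join(out, "area_table.csv")),
        "centroids": pd.read_csv(os.path.join(out, "centroid_track.csv")),
    }
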