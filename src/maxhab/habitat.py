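"""Habitat products derived from suitability rasters.

Four suitability bands (non [0, 0.25), low [0.25, 0.5), medium
[0.5, 0.75), high [0.75, 1]), geodesic class areas in 1e4 km^2 with
percent changes against a baseline, expansion/stability/contraction
change maps, and area-weighted centroid-migration tracks.  "Suitable"
means any class >= low throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, ValidationError
from .raster_io import EARTH_RADIUS_KM, GridSpec, Raster, area_grid_km2

__all__ = [
    "CLASS_CODES",
    "CHANGE_CODES",
    "SuitabilityClassMap",
    "ChangeMap",
    "CentroidTrack",
    "classify",
    "class_areas",
    "percent_change",
    "change_map",
    "centroid",
    "centroid_track",
    "scenario_report",
]

CLASS_CODES = {"non": 0, "low": 1, "medium": 2, "high": 3}
CLASS_NODATA = -1
CHANGE_CODES = {"never_suitable": 0, "expansion": 1, "stable": 2, "contraction": 3}
CHANGE_NODATA = -1


@dataclass
class SuitabilityClassMap:
    spec: GridSpec
    classes: np.ndarray  # int matrix, CLASS_NODATA outside the data region

    def suitable_mask(self) -> np.ndarray:
        return self.classes >= CLASS_CODES["low"]

    def to_raster(self, name: str = "classes") -> Raster:
        vals = self.classes.astype(float)
        vals[self.classes == CLASS_NODATA] = np.nan
        return Raster(self.spec, vals, name)


@dataclass
class ChangeMap:
    spec: GridSpec
    states: np.ndarray

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.states == code).sum())
            for name, code in CHANGE_CODES.items()
        }

    def to_raster(self, name: str = "change") -> Raster:
        vals = self.states.astype(float)
        vals[self.states == CHANGE_NODATA] = np.nan
        return Raster(self.spec, vals, name)


@dataclass
class CentroidTrack:
    scenarios: list[str]
    lons: list[float]
    lats: list[float]
    displacements_km: list[float]  # length len(scenarios) - 1
    bearings_deg: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenarios,
                "lon": self.lons,
                "lat": self.lats,
                "displacement_km": [float("nan")] + self.displacements_km,
                "bearing_deg": [float("nan")] + self.bearings_deg,
            }
        )


def classify(
    suitability: Raster, breaks: tuple[float, float, float] = (0.25, 0.50, 0.75)
) -> SuitabilityClassMap:
    """Reclassify a [0, 1] suitability raster into the four bands.

    Intervals are left-closed/right-open, with the top band closed at 1.
    Values outside [0, 1] raise a validation error.
    """
    v = suitability.values
    finite = ~np.isnan(v)
    if finite.any() and ((v[finite] < 0).any() or (v[finite] > 1).any()):
        bad = v[finite][(v[finite] < 0) | (v[finite] > 1)][0]
        raise ValidationError(f"suitability value {bad} outside [0, 1]")
    b1, b2, b3 = breaks
    classes = np.full(v.shape, CLASS_NODATA, dtype=int)
    classes[finite & (v < b1)] = CLASS_CODES["non"]
    classes[finite & (v >= b1) & (v < b2)] = CLASS_CODES["low"]
    classes[finite & (v >= b2) & (v < b3)] = CLASS_CODES["medium"]
    classes[finite & (v >= b3)] = CLASS_CODES["high"]
    return SuitabilityClassMap(suitability.spec, classes)


def class_areas(cmap: SuitabilityClassMap) -> dict[str, float]:
    """Geodesic area per class in 1e4 km^2, plus ``total_suitable``
    (low + medium + high) and ``total`` (all classified cells)."""
    areas_km2 = area_grid_km2(cmap.spec)
    out = {}
    for name, code in CLASS_CODES.items():
        out[name] = float(areas_km2[cmap.classes == code].sum()) / 1e4
    out["total_suitable"] = out["low"] + out["medium"] + out["high"]
    out["total"] = out["total_suitable"] + out["non"]
    return out


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed area tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_change(area: float, baseline: float, ndigits: int = 2):
    """``100 * (area - baseline) / baseline`` rounded half-away-from-zero.

    A zero baseline with nonzero area is undefined and returns None
    (an "undefined" flag, not a number); zero against zero is 0.0.
    """
    if baseline == 0:
        return 0.0 if area == 0 else None
    return round_half_away(100.0 * (area - baseline) / baseline, ndigits)


def change_map(
    baseline: SuitabilityClassMap, scenario: SuitabilityClassMap
) -> ChangeMap:
    """Per-cell transition of the binary suitable region (class >= low):
    expansion, stable, contraction, or never-suitable."""
    if not baseline.spec.aligned_with(scenario.spec):
        raise AlignmentError("baseline and scenario class maps are misaligned")
    b = baseline.suitable_mask()
    s = scenario.suitable_mask()
    valid = (baseline.classes != CLASS_NODATA) & (scenario.classes != CLASS_NODATA)
    states = np.full(b.shape, CHANGE_NODATA, dtype=int)
    states[valid & ~b & ~s] = CHANGE_CODES["never_suitable"]
    states[valid & ~b & s] = CHANGE_CODES["expansion"]
    states[valid & b & s] = CHANGE_CODES["stable"]
    states[valid & b & ~s] = CHANGE_CODES["contraction"]
    return ChangeMap(baseline.spec, states)


def centroid(
    cmap: SuitabilityClassMap,
    mode: str = "binary",
    suitability: Raster | None = None,
) -> tuple[float, float]:
    """Area-weighted centroid (lon, lat) of the suitable region.

    ``mode='binary'`` weights each suitable cell by its area;
    ``mode='weighted'`` weights by suitability x area (requires the
    suitability raster).  Longitudes are assumed non-wrapping within the
    study window.
    """
    mask = cmap.suitable_mask()
    if not mask.any():
        raise DataError("no suitable cells: centroid undefined")
    spec = cmap.spec
    rows, cols = np.nonzero(mask)
    w = area_grid_km2(spec)[rows, cols]
    if mode == "weighted":
        if suitability is None:
            raise DataError("weighted centroid mode needs the suitability raster")
        w = w * suitability.values[rows, cols]
    elif mode != "binary":
        raise DataError(f"unknown centroid mode {mode!r}")
    lon = spec.xllcorner + (cols + 0.5) * spec.cellsize
    lat = spec.yllcorner + (spec.nrows - rows - 0.5) * spec.cellsize
    wsum = w.sum()
    return float((w * lon).sum() / wsum), float((w * lat).sum() / wsum)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance on the sphere (R = 6371.0088 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def initial_bearing_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Forward azimuth from point 1 to point 2, degrees clockwise from north."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    x = math.sin(dl) * math.cos(p2)
    y = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.degrees(math.atan2(x, y)) % 360.0


def centroid_track(
    cmaps: list[SuitabilityClassMap],
    names: list[str],
    mode: str = "binary",
    suitabilities: list[Raster] | None = None,
) -> CentroidTrack:
    """Centroid per scenario plus haversine displacement and initial
    bearing between consecutive scenarios."""
    if len(cmaps) < 2:
        raise DataError("centroid track needs >= 2 scenarios")
    lons, lats = [], []
    for i, cm in enumerate(cmaps):
        suit = suitabilities[i] if suitabilities is not None else None
        lon, lat = centroid(cm, mode=mode, suitability=suit)
        lons.append(lon)
        lats.append(lat)
    disp = [
        haversine_km(lons[i], lats[i], lons[i + 1], lats[i + 1])
        for i in range(len(cmaps) - 1)
    ]
    bear = [
        initial_bearing_deg(lons[i], lats[i], lons[i + 1], lats[i + 1])
        for i in range(len(cmaps) - 1)
    ]
    return CentroidTrack(list(names), lons, lats, disp, bear)


REPORT_COLUMNS = [
    "scenario",
    "non_suitable_area",
    "non_suitable_ratio_pct",
    "low_suitability_area",
    "low_suitability_ratio_pct",
    "medium_suitability_area",
    "medium_suitability_ratio_pct",
    "high_suitability_area",
    "high_suitability_ratio_pct",
    "total_suitable_area",
    "total_suitable_ratio_pct",
]


def scenario_report(
    baseline_name: str,
    cmaps: dict[str, SuitabilityClassMap],
) -> tuple[pd.DataFrame, dict[str, ChangeMap], CentroidTrack | None]:
    """Area/change table (one row per scenario, areas in 1e4 km^2 with
    percent changes vs the baseline), change maps vs the baseline, and the
    centroid track over the scenario order.  Baseline ratios are blank."""
    if baseline_name not in cmaps:
        raise DataError(f"baseline scenario {baseline_name!r} missing")
    base_areas = class_areas(cmaps[baseline_name])
    rows = []
    changes: dict[str, ChangeMap] = {}
    for name, cm in cmaps.items():
        a = class_areas(cm)
        row = {"scenario": name}
        for cls, col in (
            ("non", "non_suitable"),
            ("low", "low_suitability"),
            ("medium", "medium_suitability"),
            ("high", "high_suitability"),
            ("total_suitable", "total_suitable"),
        ):
            # ratios recompute exactly from the printed-precision areas
            rounded = round_half_away(a[cls], 2)
            row[f"{col}_area"] = rounded
            if name == baseline_name:
                row[f"{col}_ratio_pct"] = float("nan")
            else:
                row[f"{col}_ratio_pct"] = percent_change(
                    rounded, round_half_away(base_areas[cls], 2)
                )
        rows.append(row)
        if name != baseline_name:
            changes[name] = change_map(cmaps[baseline_name], cm)
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    track = None
    if len(cmaps) >= 2:
        track = centroid_track(list(cmaps.values()), list(cmaps.keys()))
    return table, changes, track
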