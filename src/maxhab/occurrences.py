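"""Occurrence-record cleaning and grid-based spatial thinning.

Cleaning removes records with missing or unparseable coordinates,
out-of-range or (0, 0) coordinates, exact coordinate duplicates (first
kept), and points outside the study bounds or mask, logging a count per
rule.  Thinning keeps at most one record per cell of a regular lon/lat
grid (default 2.5 arc-minutes), mitigating sampling-density bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .raster_io import GridSpec, Raster, cell_of

DEFAULT_THIN_CELLSIZE = 2.5 / 60  # degrees

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "clean",
    "thin",
    "read_occurrences_csv",
    "write_occurrences_csv",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float | None
    lat: float | None
    source: str = ""
    raw_id: str = ""


@dataclass
class OccurrenceSet:
    species: str
    records: list[OccurrenceRecord]
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return np.array([(r.lon, r.lat) for r in self.records], dtype=float).reshape(
            -1, 2
        )


def _parse_coord(value):
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(v):
        return None
    return v


def clean(
    records,
    species: str = "species",
    bounds: GridSpec | tuple | None = None,
    mask_raster: Raster | None = None,
) -> OccurrenceSet:
    """Apply the mechanical cleaning rules in a fixed order per record:
    incomplete -> invalid (out of range or exactly (0,0)) -> duplicate ->
    out_of_bounds (outside bbox, or nodata/zero in ``mask_raster``).

    ``bounds`` may be a GridSpec or a (xmin, ymin, xmax, ymax) tuple.
    An empty result warns rather than fails.
    """
    if bounds is None:
        bbox = None
    elif isinstance(bounds, GridSpec):
        bbox = (bounds.xllcorner, bounds.yllcorner, bounds.xmax, bounds.ymax)
    else:
        bbox = tuple(bounds)

    counts = {"incomplete": 0, "invalid": 0, "duplicate": 0, "out_of_bounds": 0}
    seen: set[tuple[float, float]] = set()
    kept: list[OccurrenceRecord] = []
    n_in = 0
    for rec in records:
        n_in += 1
        lon = _parse_coord(rec.lon)
        lat = _parse_coord(rec.lat)
        if lon is None or lat is None:
            counts["incomplete"] += 1
            continue
        if not (-180 <= lon <= 180 and -90 <= lat <= 90) or (lon == 0 and lat == 0):
            counts["invalid"] += 1
            continue
        if (lon, lat) in seen:
            counts["duplicate"] += 1
            continue
        if bbox is not None and not (
            bbox[0] <= lon <= bbox[2] and bbox[1] <= lat <= bbox[3]
        ):
            counts["out_of_bounds"] += 1
            continue
        if mask_raster is not None:
            try:
                r, c = cell_of(lon, lat, mask_raster.spec)
            except Exception:
                counts["out_of_bounds"] += 1
                continue
            v = mask_raster.values[r, c]
            if np.isnan(v) or v == 0:
                counts["out_of_bounds"] += 1
                continue
        seen.add((lon, lat))
        kept.append(OccurrenceRecord(lon, lat, rec.source, rec.raw_id))

    assert sum(counts.values()) == n_in - len(kept)
    if not kept:
        warnings.warn("cleaning removed every record", stacklevel=2)
    return OccurrenceSet(species, kept, counts)


def thin(
    occ: OccurrenceSet,
    cellsize: float = DEFAULT_THIN_CELLSIZE,
    anchor: tuple[float, float] = (-180.0, -90.0),
) -> OccurrenceSet:
    """Keep the first record (input order) per thinning-grid cell.

    ``anchor`` is the (lon, lat) of the grid's lower-left corner; the
    environmental grid's corner is the conventional choice.  Idempotent,
    order-preserving, never increases the record count.
    """
    if not cellsize > 0:
        raise ValidationError("thinning cellsize must be positive")
    x0, y0 = anchor
    occupied: set[tuple[int, int]] = set()
    kept: list[OccurrenceRecord] = []
    dropped = 0
    for rec in occ.records:
        key = (
            int(math.floor((rec.lon - x0) / cellsize)),
            int(math.floor((rec.lat - y0) / cellsize)),
        )
        if key in occupied:
            dropped += 1
            continue
        occupied.add(key)
        kept.append(rec)
    prov = dict(occ.provenance)
    prov["thinned"] = prov.get("thinned", 0) + dropped
    return OccurrenceSet(occ.species, kept, prov)


def read_occurrences_csv(path, species: str | None = None) -> list[OccurrenceRecord]:
    """Read a CSV with columns ``species, lon, lat`` and optional
    ``source``/``id``; returns raw (uncleaned) records."""
    df = pd.read_csv(path, dtype={"source": str, "id": str})
    cols = {c.lower(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise ValidationError(f"{path}: occurrence CSV needs lon and lat columns")
    recs = []
    for _, row in df.iterrows():
        recs.append(
            OccurrenceRecord(
                lon=row[cols["lon"]],
                lat=row[cols["lat"]],
                source=str(row[cols["source"]]) if "source" in cols else "",
                raw_id=str(row[cols["id"]]) if "id" in cols else "",
            )
        )
    return recs


def write_occurrences_csv(occ: OccurrenceSet, path) -> str:
    df = pd.DataFrame(
        {
            "species": occ.species,
            "lon": [r.lon for r in occ.records],
            "lat": [r.lat for r in occ.records],
            "source": [r.source for r in occ.records],
            "id": [r.raw_id for r in occ.records],
        }
    )
    df.to_csv(path, index=False)
    return str(path)
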