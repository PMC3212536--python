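"""Survey data model, validation and readers/writers.

Line-transect dung surveys are stored as two delimited tables:

* an observation table (``transect_id, epoch, perpendicular_distance_m``),
  one row per detected dung pile with its perpendicular distance from the
  transect line in metres;
* a transect table (``transect_id, location_id, x_km, y_km, bearing_deg,
  length_km``), one row per transect, grouped into sampling locations
  (1-4 transects radiating from a shared departure point).

All planar coordinates are kilometres; detection distances are metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

__all__ = [
    "Observation",
    "Transect",
    "SamplingLocation",
    "SurveyDataset",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "pool_by_location",
    "read_landscape_geojson",
    "write_landscape_geojson",
]

OBS_COLUMNS = ["transect_id", "epoch", "perpendicular_distance_m"]
TRANSECT_COLUMNS = ["transect_id", "location_id", "x_km", "y_km", "bearing_deg", "length_km"]


class SurveyValidationError(ValueError):
    """Raised when a survey table violates the schema or its invariants."""


@dataclass(frozen=True)
class Observation:
    """A single detected dung pile."""

    transect_id: str
    perpendicular_distance: float  # metres, >= 0
    epoch: str
    sign_type: str = "dung"

    def __post_init__(self):
        d = self.perpendicular_distance
        if not np.isfinite(d) or d < 0:
            raise SurveyValidationError(
                f"perpendicular distance must be finite and >= 0, got {d!r}"
            )


@dataclass(frozen=True)
class Transect:
    """A single line transect: origin + bearing + length, member of a location."""

    transect_id: str
    location_id: str
    origin: tuple[float, float]  # planar km
    bearing: float  # degrees
    length: float  # km

    def __post_init__(self):
        if not self.length > 0:
            raise SurveyValidationError(f"transect length must be > 0, got {self.length}")

    @property
    def midpoint(self) -> tuple[float, float]:
        theta = np.deg2rad(90.0 - self.bearing)  # compass bearing -> math angle
        half = self.length / 2.0
        return (self.origin[0] + half * np.cos(theta), self.origin[1] + half * np.sin(theta))


@dataclass(frozen=True)
class SamplingLocation:
    """Departure point sharing 1-4 transects; the independent sampling unit."""

    location_id: str
    point: tuple[float, float]
    transect_ids: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.transect_ids) <= 4:
            raise SurveyValidationError(
                f"location {self.location_id}: needs 1-4 transects, got {len(self.transect_ids)}"
            )


@dataclass
class SurveyDataset:
    """One survey epoch: observations, transects and sampling locations.

    Attributes
    ----------
    epoch : str
        Survey label (e.g. ``"1995"``).
    observations, transects, locations : lists of the component records.
    """

    epoch: str
    observations: list[Observation] = field(default_factory=list)
    transects: list[Transect] = field(default_factory=list)
    locations: list[SamplingLocation] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        tids = {t.transect_id for t in self.transects}
        if len(tids) != len(self.transects):
            raise SurveyValidationError("duplicate transect_id in transect table")
        for ob in self.observations:
            if ob.transect_id not in tids:
                raise SurveyValidationError(
                    f"observation references unknown transect {ob.transect_id!r}"
                )
        if self.transects and not self.total_effort > 0:
            raise SurveyValidationError("total effort must be > 0")

    # -- summaries --------------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of observations."""
        return len(self.observations)

    @property
    def total_effort(self) -> float:
        """Total transect length L (km)."""
        return float(sum(t.length for t in self.transects))

    @property
    def k(self) -> int:
        """Number of sampling locations (independent units)."""
        return len(self.locations)

    def distances(self) -> np.ndarray:
        """Perpendicular distances (m) as an array."""
        return np.array([ob.perpendicular_distance for ob in self.observations], dtype=float)


def _locations_from_transects(transects: Iterable[Transect]) -> list[SamplingLocation]:
    by_loc: dict[str, list[Transect]] = {}
    for t in transects:
        by_loc.setdefault(t.location_id, []).append(t)
    locs = []
    for loc_id in sorted(by_loc):
        members = by_loc[loc_id]
        locs.append(
            SamplingLocation(
                location_id=loc_id,
                point=members[0].origin,
                transect_ids=tuple(sorted(t.transect_id for t in members)),
            )
        )
    return locs


def read_survey(observations_table, transects_table, epoch: str | None = None) -> SurveyDataset:
    """Read and validate a survey from two CSV tables.

    Parameters
    ----------
    observations_table, transects_table : path or file-like
        CSV with headers ``transect_id,epoch,perpendicular_distance_m`` and
        ``transect_id,location_id,x_km,y_km,bearing_deg,length_km``.
    epoch : str, optional
        Keep only observations with this epoch label; default: all rows
        (which must then share one label).
    """
    obs_df = pd.read_csv(observations_table, dtype={"transect_id": str, "epoch": str})
    tr_df = pd.read_csv(transects_table, dtype={"transect_id": str, "location_id": str})
    for col in OBS_COLUMNS:
        if col not in obs_df.columns:
            raise SurveyValidationError(f"observation table missing column {col!r}")
    for col in TRANSECT_COLUMNS:
        if col not in tr_df.columns:
            raise SurveyValidationError(f"transect table missing column {col!r}")
    if epoch is not None:
        obs_df = obs_df[obs_df["epoch"] == str(epoch)]
    epochs = set(obs_df["epoch"].astype(str))
    if epoch is None:
        if len(epochs) > 1:
            raise SurveyValidationError(
                f"observation table holds several epochs {sorted(epochs)}; pass epoch="
            )
        epoch = epochs.pop() if epochs else "unknown"

    dists = pd.to_numeric(obs_df["perpendicular_distance_m"], errors="coerce")
    if dists.isna().any():
        raise SurveyValidationError("non-numeric perpendicular distance")
    if (dists < 0).any():
        bad = float(dists[dists < 0].iloc[0])
        raise SurveyValidationError(f"negative perpendicular distance {bad}")

    transects = [
        Transect(
            transect_id=str(r.transect_id),
            location_id=str(r.location_id),
            origin=(float(r.x_km), float(r.y_km)),
            bearing=float(r.bearing_deg),
            length=float(r.length_km),
        )
        for r in tr_df.itertuples()
    ]
    observations = [
        Observation(transect_id=str(t), perpendicular_distance=float(d), epoch=str(epoch))
        for t, d in zip(obs_df["transect_id"], dists)
    ]
    return SurveyDataset(
        epoch=str(epoch),
        observations=observations,
        transects=transects,
        locations=_locations_from_transects(transects),
    )


def write_survey(ds: SurveyDataset, observations_path, transects_path) -> None:
    """Write a dataset back to the two-table CSV schema (fixed precision)."""
    obs_df = pd.DataFrame(
        {
            "transect_id": [o.transect_id for o in ds.observations],
            "epoch": [o.epoch for o in ds.observations],
            "perpendicular_distance_m": [f"{o.perpendicular_distance:.4f}" for o in ds.observations],
        }
    )
    tr_df = pd.DataFrame(
        {
            "transect_id": [t.transect_id for t in ds.transects],
            "location_id": [t.location_id for t in ds.transects],
            "x_km": [f"{t.origin[0]:.4f}" for t in ds.transects],
            "y_km": [f"{t.origin[1]:.4f}" for t in ds.transects],
            "bearing_deg": [f"{t.bearing:.4f}" for t in ds.transects],
            "length_km": [f"{t.length:.4f}" for t in ds.transects],
        }
    )
    obs_df.to_csv(observations_path, index=False)
    tr_df.to_csv(transects_path, index=False)


def pool_by_location(ds: SurveyDataset) -> pd.DataFrame:
    """Pool transects within each sampling location into independent units.

    Returns a DataFrame indexed by ``location_id`` with columns
    ``effort_km`` (l_i, summed member lengths), ``count`` (n_i, summed
    observations), ``x_km``/``y_km`` (departure point). Pooling conserves
    totals: sum(effort_km) == L and sum(count) == n.
    """
    counts_by_transect: dict[str, int] = {}
    for ob in ds.observations:
        counts_by_transect[ob.transect_id] = counts_by_transect.get(ob.transect_id, 0) + 1
    by_transect = {t.transect_id: t for t in ds.transects}
    rows = []
    for loc in ds.locations:
        effort = sum(by_transect[tid].length for tid in loc.transect_ids)
        count = sum(counts_by_transect.get(tid, 0) for tid in loc.transect_ids)
        rows.append(
            {
                "location_id": loc.location_id,
                "effort_km": effort,
                "count": count,
                "x_km": loc.point[0],
                "y_km": loc.point[1],
            }
        )
    return pd.DataFrame(rows).set_index("location_id")


# ---------------------------------------------------------------------------
# Landscape GeoJSON
# ---------------------------------------------------------------------------

def write_landscape_geojson(features: Mapping[str, object], path) -> None:
    """Write named shapely geometries as a GeoJSON FeatureCollection.

    Each feature carries a ``role`` property (e.g. ``park_boundary``,
    ``road``, ``village``, ``town``, ``headquarters``). Values may be single
    geometries or lists of geometries sharing a role.
    """
    feats = []
    for role, geom in features.items():
        geoms = geom if isinstance(geom, (list, tuple)) else [geom]
        for g in geoms:
            feats.append(
                {"type": "Feature", "properties": {"role": role}, "geometry": mapping(g)}
            )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_landscape_geojson(path) -> dict[str, list]:
    """Read a FeatureCollection into ``{role: [shapely geometry, ...]}``."""
    fc = json.loads(Path(path).read_text())
    out: dict[str, list] = {}
    for feat in fc["features"]:
        out.setdefault(feat["properties"]["role"], []).append(shape(feat["geometry"]))
    return out
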