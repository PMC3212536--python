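"""Per-transect landscape covariates.

Builds the covariate table that the density-surface models consume:
Euclidean distances (km) from each transect midpoint to the nearest road,
village, major town, the park boundary and the headquarters; optional slope
and habitat columns; and a composite deforestation index

    I_t = sum_j a_j(t) / d_tj^p

summing deforested area a_j over every cell j of a buffer grid, weighted by
inverse distance d_tj from the transect midpoint to the cell centre
(exponent p, default 1). Large deforested areas close to a transect give a
high index — a proxy for the intensity and proximity of human activity.

Collinear covariates are screened at |Pearson r| >= 0.6, keeping the
higher-priority member of each offending pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .io import SurveyDataset

__all__ = [
    "Landscape",
    "distance_covariates",
    "deforestation_change",
    "deforestation_index",
    "collinearity_screen",
    "DEFAULT_PRIORITY",
]

GRID_COLUMNS = ["cx_km", "cy_km", "cell_km", "nonforest_t1_km2", "nonforest_t2_km2"]

DEFAULT_PRIORITY = (
    "dist_road",
    "dist_village",
    "dist_town",
    "dist_boundary",
    "dist_hq",
    "deforestation_index",
    "slope",
    "habitat",
)


@dataclass
class Landscape:
    """Park geometry plus the deforestation buffer grid.

    All geometries are planar (km). ``deforestation_grid`` is a DataFrame
    with columns ``cx_km, cy_km, cell_km, nonforest_t1_km2, nonforest_t2_km2``
    (cell centre, cell edge length, non-forested area at the two mapping
    epochs). Optional per-transect ``slope`` / ``habitat`` values ride along
    in ``extra_covariates`` keyed by transect_id.
    """

    park_boundary: Polygon
    roads: list[LineString] = field(default_factory=list)
    villages: list[Point] = field(default_factory=list)
    towns: list[Point] = field(default_factory=list)
    headquarters: Point | None = None
    deforestation_grid: pd.DataFrame | None = None
    extra_covariates: pd.DataFrame | None = None  # indexed by transect_id

    def __post_init__(self):
        if self.deforestation_grid is not None:
            g = self.deforestation_grid
            missing = [c for c in GRID_COLUMNS if c not in g.columns]
            if missing:
                raise ValueError(f"deforestation grid missing columns {missing}")
            areas = g["cell_km"] ** 2
            for col in ("nonforest_t1_km2", "nonforest_t2_km2"):
                bad = (g[col] < 0) | (g[col] > areas + 1e-9)
                if bad.any():
                    raise ValueError(f"{col} outside [0, cell area] in {int(bad.sum())} cells")

    def save_grid(self, path) -> None:
        self.deforestation_grid.to_csv(path, index=False)

    @staticmethod
    def load_grid(path) -> pd.DataFrame:
        return pd.read_csv(path)


def _min_distance(point: Point, geoms) -> float:
    if not geoms:
        return float("nan")
    return min(point.distance(g) for g in geoms)


def distance_covariates(ds: SurveyDataset, landscape: Landscape) -> pd.DataFrame:
    """Distance covariates (km) per transect, evaluated at the midpoint.

    Columns: dist_road, dist_village, dist_town, dist_boundary, dist_hq,
    plus ``inside_park`` flag. ``dist_boundary`` is the distance to the
    boundary polyline; midpoints outside the park are flagged but still get
    a distance. Any slope/habitat columns in ``landscape.extra_covariates``
    are joined in.
    """
    boundary = landscape.park_boundary.exterior
    rows = []
    for t in ds.transects:
        mp = Point(*t.midpoint)
        rows.append(
            {
                "transect_id": t.transect_id,
                "location_id": t.location_id,
                "dist_road": _min_distance(mp, landscape.roads),
                "dist_village": _min_distance(mp, landscape.villages),
                "dist_town": _min_distance(mp, landscape.towns),
                "dist_boundary": mp.distance(boundary),
                "dist_hq": (mp.distance(landscape.headquarters)
                            if landscape.headquarters is not None else float("nan")),
                "inside_park": landscape.park_boundary.covers(mp),
            }
        )
    out = pd.DataFrame(rows).set_index("transect_id")
    if landscape.extra_covariates is not None:
        out = out.join(landscape.extra_covariates)
    return out


def deforestation_change(grid: pd.DataFrame) -> pd.Series:
    """Per-cell deforested area (km^2) between the two mapping epochs.

    Delta_j = max(0, nonforest_t2 - nonforest_t1): reforestation is clamped
    to zero — the index tracks forest loss, not regrowth.
    """
    return (grid["nonforest_t2_km2"] - grid["nonforest_t1_km2"]).clip(lower=0.0)


def deforestation_index(midpoint, grid: pd.DataFrame, epoch_col: str = "nonforest_t1_km2",
                        exponent: float = 1.0, min_distance: float | None = None) -> float:
    """Composite deforestation index at a transect midpoint.

    I = sum_j a_j / d_j^exponent over every grid cell, a_j the cell's
    non-forested (or deforested) area taken from ``epoch_col`` and d_j the
    distance (km) from the midpoint to the cell centre. Distances below
    ``min_distance`` (default cell_size / 2, guarding the singularity at a
    cell centre) are floored to it.
    """
    if grid is None or len(grid) == 0:
        warnings.warn("empty deforestation grid: index = 0", stacklevel=2)
        return 0.0
    mx, my = float(midpoint[0]), float(midpoint[1])
    d = np.hypot(grid["cx_km"].to_numpy() - mx, grid["cy_km"].to_numpy() - my)
    if min_distance is None:
        min_distance = 0.5 * float(grid["cell_km"].iloc[0])
    d = np.maximum(d, min_distance)
    a = grid[epoch_col].to_numpy(dtype=float)
    return float(np.sum(a / d**exponent))


def deforestation_index_column(ds: SurveyDataset, landscape: Landscape,
                               epoch_col: str = "nonforest_t1_km2",
                               exponent: float = 1.0) -> pd.Series:
    """Deforestation index for every transect of a dataset."""
    vals = {
        t.transect_id: deforestation_index(t.midpoint, landscape.deforestation_grid,
                                           epoch_col=epoch_col, exponent=exponent)
        for t in ds.transects
    }
    return pd.Series(vals, name="deforestation_index").rename_axis("transect_id")


def collinearity_screen(table: pd.DataFrame, r_max: float = 0.6,
                        priority: tuple[str, ...] = DEFAULT_PRIORITY):
    """Drop the lower-priority member of every highly-correlated pair.

    Covariates are visited in ``priority`` order (columns absent from the
    table are skipped; columns not listed come last in table order); a
    covariate is retained iff its |Pearson r| with every already-retained
    covariate is < ``r_max``. Constant columns have undefined correlation
    and are dropped with a warning.

    Returns (retained column list, full correlation matrix).
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValueError("need >= 3 transects to screen collinearity")
    ordered = [c for c in priority if c in numeric.columns]
    ordered += [c for c in numeric.columns if c not in ordered]
    corr = numeric[ordered].corr()
    retained: list[str] = []
    for col in ordered:
        if numeric[col].nunique() <= 1:
            warnings.warn(f"constant covariate {col!r} dropped", stacklevel=2)
            continue
        if all(abs(corr.loc[col, kept]) < r_max for kept in retained):
            retained.append(col)
    return retained, corr


def covariate_table(ds: SurveyDataset, landscape: Landscape,
                    epoch_col: str = "nonforest_t1_km2",
                    exponent: float = 1.0) -> pd.DataFrame:
    """Full per-transect covariate table: distances + deforestation index."""
    tab = distance_covariates(ds, landscape)
    tab["deforestation_index"] = deforestation_index_column(
        ds, landscape, epoch_col=epoch_col, exponent=exponent
    )
    return tab
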