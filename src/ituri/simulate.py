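"""Synthetic landscapes and two-epoch line-transect dung surveys.

Emulates the design of a large-reserve dung survey: a ~13,700 km^2
rectangular park bisected by a national road with a second road along its
eastern boundary, villages strung along the roads, four towns outside the
boundary, headquarters on the central road, and a deforestation grid over a
15 km buffer. A log-linear true density surface responds to
distance-to-headquarters, distance-to-boundary and the deforestation index;
the second epoch is the first scaled by a decline factor, optionally with a
protected-core refuge around headquarters.

Surveys draw 51 sampling locations with 1-4 transects of 2.5-5 km each;
per-transect dung counts are negative-binomial (mean mu, variance phi*mu)
around the surface expectation, and each dung pile receives a perpendicular
distance, thinned by a known detection function so that observed distances
follow f(x) = g(x)/mu. A truth ledger records every expectation so any
pipeline estimate can be checked against the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .covariates import Landscape, deforestation_index
from .detection import _g
from .io import Observation, SamplingLocation, SurveyDataset, Transect

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "generate_landscape",
    "simulate_density_surface",
    "simulate_survey",
    "simulate_two_epoch_survey",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic surveys.

    Defaults mirror the emulated design: a 130 x 105.4 km park
    (13,702 km^2), 51 sampling locations of 1-4 transects (2.5-5 km),
    half-normal detection with sigma = 2 m, a 50% epoch-2 decline,
    negative-binomial overdispersion phi = 2, and a 10 km deforestation
    grid over a 15 km buffer.
    """

    seed: int = 0
    park_width_km: float = 130.0
    park_height_km: float = 105.4
    n_locations: int = 51
    transect_length_range: tuple[float, float] = (2.5, 5.0)
    transects_per_location_probs: tuple[float, ...] = (0.25, 0.45, 0.20, 0.10)
    detection_family: str = "half-normal"
    detection_params: tuple[float, ...] = (2.0,)  # sigma metres
    w_sim_m: float = 10.0  # strip half-width actually populated with dung
    mean_density_epoch1: float = 4.0  # dung piles per ha, park average
    beta_hq: float = -0.5  # per (dist_hq / 50 km)
    beta_boundary: float = 0.4  # per (dist_boundary / 30 km)
    beta_deforestation: float = -0.6  # per (index / park-mean index)
    decline_factor: float = 0.5
    refuge_multiplier: float = 1.0  # >1 softens the decline near HQ
    refuge_radius_km: float = 30.0
    phi: float = 2.0  # var = phi * mean
    grid_cell_km: float = 10.0
    buffer_km: float = 15.0

    def __post_init__(self):
        if not 0 < self.decline_factor <= 1:
            raise ValueError("decline factor must be in (0, 1]")
        if self.phi < 1:
            raise ValueError("phi must be >= 1")
        if not self.park_width_km * self.park_height_km > 0:
            raise ValueError("park area must be > 0")

    @property
    def area_km2(self) -> float:
        return self.park_width_km * self.park_height_km


@dataclass
class TruthLedger:
    """Everything needed to recompute the generator's expectations."""

    seed: int
    epoch: str
    true_density_at_transects: dict[str, float]  # dung per ha at midpoints
    expected_counts: dict[str, float]  # within-strip expectation per transect
    expected_observed_counts: dict[str, float]  # after detection thinning
    mean_detection_prob: float
    true_mean_density: float  # park-average dung per ha
    true_total_dung: float  # piles standing in the park
    n_emitted: int  # observations actually drawn

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def generate_landscape(config: SimulationConfig) -> Landscape:
    """Deterministic landscape for a config (same seed -> same landscape)."""
    rng = _rng(config.seed, 1)
    W, H = config.park_width_km, config.park_height_km
    park = Polygon([(0, 0), (W, 0), (W, H), (0, H)])
    main_y = 0.35 * H
    roads = [
        LineString([(-20.0, main_y), (W + 20.0, main_y)]),  # national road
        LineString([(W + 2.0, -10.0), (W + 2.0, H + 10.0)]),  # eastern boundary road
        LineString([(-10.0, -10.0), (-10.0, H + 10.0)]),  # western road, outside
    ]
    villages = []
    for road in roads:
        n_v = max(3, int(road.length / 9.0))
        for frac in np.linspace(0.05, 0.95, n_v):
            base = road.interpolate(frac * road.length)
            dx, dy = rng.uniform(-3.0, 3.0, size=2)  # stays within 5 km of the road
            villages.append(Point(base.x + dx, base.y + dy))
    towns = [
        Point(W + 8.0, 0.70 * H),
        Point(-12.0, 0.50 * H),
        Point(0.30 * W, H + 8.0),
        Point(0.60 * W, -8.0),
    ]
    hq = Point(0.5 * W, main_y)

    cell = config.grid_cell_km
    buf = config.buffer_km
    cxs = np.arange(-buf + cell / 2, W + buf, cell)
    cys = np.arange(-buf + cell / 2, H + buf, cell)
    gx, gy = np.meshgrid(cxs, cys)
    gx, gy = gx.ravel(), gy.ravel()
    area = cell**2
    # clearing concentrates around the towns outside the boundary; village
    # fields along the interior road contribute only marginally
    d_town = np.min(
        [np.hypot(gx - t.x, gy - t.y) for t in towns], axis=0
    )
    d_road = np.array([Point(x, y).distance(roads[0]) for x, y in zip(gx, gy)])
    d_road = np.minimum(d_road, np.abs(gx - (W + 2.0)))
    frac1 = 0.55 * np.exp(-d_town / 18.0) + 0.06 * np.exp(-d_road / 10.0)
    frac1 = frac1 * rng.uniform(0.6, 1.0, size=gx.size)
    extra = 0.25 * np.exp(-d_town / 15.0) * rng.uniform(0.3, 1.0, size=gx.size)
    t1 = np.clip(frac1, 0, 1) * area
    t2 = np.clip(frac1 + extra, 0, 1) * area
    grid = pd.DataFrame(
        {
            "cx_km": gx,
            "cy_km": gy,
            "cell_km": cell,
            "nonforest_t1_km2": t1,
            "nonforest_t2_km2": t2,
        }
    )
    return Landscape(park_boundary=park, roads=roads, villages=villages,
                     towns=towns, headquarters=hq, deforestation_grid=grid)


class DensitySurface:
    """True dung-density surface D(x, y) in piles per hectare."""

    def __init__(self, landscape: Landscape, config: SimulationConfig, epoch: int = 1):
        self.landscape = landscape
        self.config = config
        self.epoch = epoch
        self._boundary = landscape.park_boundary.exterior
        # normalize the deforestation index by its park-average so the
        # coefficient has a stable meaning across landscapes
        xs = np.linspace(5, config.park_width_km - 5, 12)
        ys = np.linspace(5, config.park_height_km - 5, 10)
        vals = [self._raw_index(x, y) for x in xs for y in ys]
        self._index_scale = float(np.mean(vals)) or 1.0
        self._b0 = 0.0
        self._b0 = np.log(config.mean_density_epoch1) - np.log(self._grid_mean(step=4.0))

    def _raw_index(self, x, y) -> float:
        col = "nonforest_t1_km2" if self.epoch == 1 else "nonforest_t2_km2"
        return deforestation_index((x, y), self.landscape.deforestation_grid, epoch_col=col)

    def _log_shape(self, x, y) -> float:
        c = self.config
        hq = self.landscape.headquarters
        d_hq = np.hypot(x - hq.x, y - hq.y)
        d_bnd = Point(x, y).distance(self._boundary)
        idx = self._raw_index(x, y) / self._index_scale
        return (c.beta_hq * d_hq / 50.0 + c.beta_boundary * d_bnd / 30.0
                + c.beta_deforestation * idx)

    def __call__(self, x, y) -> float:
        c = self.config
        d = np.exp(self._b0 + self._log_shape(x, y))
        if self.epoch == 2:
            d *= c.decline_factor
            hq = self.landscape.headquarters
            if np.hypot(x - hq.x, y - hq.y) <= c.refuge_radius_km:
                d *= c.refuge_multiplier
        return float(d)

    def _grid_mean(self, step: float = 4.0) -> float:
        c = self.config
        xs = np.arange(step / 2, c.park_width_km, step)
        ys = np.arange(step / 2, c.park_height_km, step)
        vals = [np.exp(self._b0 + self._log_shape(x, y)) for x in xs for y in ys]
        return float(np.mean(vals))

    def park_mean_density(self, step: float = 4.0) -> float:
        """Park-average dung density (per ha) by midpoint quadrature."""
        c = self.config
        xs = np.arange(step / 2, c.park_width_km, step)
        ys = np.arange(step / 2, c.park_height_km, step)
        return float(np.mean([[self(x, y) for x in xs] for y in ys]))


def simulate_density_surface(landscape: Landscape, config: SimulationConfig,
                             epoch: int = 1) -> DensitySurface:
    """True density surface for an epoch (1 or 2)."""
    return DensitySurface(landscape, config, epoch=epoch)


def _draw_locations(config: SimulationConfig) -> list[tuple[str, float, float, int]]:
    rng = _rng(config.seed, 2)
    margin = 6.0
    out = []
    n_tr = rng.choice(
        np.arange(1, len(config.transects_per_location_probs) + 1),
        size=config.n_locations, p=config.transects_per_location_probs,
    )
    for i in range(config.n_locations):
        x = rng.uniform(margin, config.park_width_km - margin)
        y = rng.uniform(margin, config.park_height_km - margin)
        out.append((f"L{i+1:02d}", x, y, int(n_tr[i])))
    return out


def draw_survey_design(config: SimulationConfig):
    """Transect geometry and sampling locations, shared by both epochs.

    The field design is marked once and revisited, so geometry depends only
    on the seed, never on the epoch: bearings are random per location,
    lengths uniform on the configured range.
    """
    rng = _rng(config.seed, 4)
    locations = _draw_locations(config)
    transects: list[Transect] = []
    for loc_id, x, y, n_tr in locations:
        bearings = rng.uniform(0.0, 360.0, size=n_tr)
        lengths = rng.uniform(*config.transect_length_range, size=n_tr)
        for j, (b, l) in enumerate(zip(bearings, lengths)):
            transects.append(Transect(
                transect_id=f"{loc_id}T{j+1}", location_id=loc_id,
                origin=(x, y), bearing=float(b), length=float(l),
            ))
    sampling_locations = [
        SamplingLocation(location_id=loc_id, point=(x, y),
                         transect_ids=tuple(t.transect_id for t in transects
                                            if t.location_id == loc_id))
        for loc_id, x, y, _ in locations
    ]
    return transects, sampling_locations


def _transect_extras(transects: list[Transect], config: SimulationConfig) -> pd.DataFrame:
    """Slope (degrees) and habitat class at each transect midpoint.

    Slope is a smooth hill bump in the park's northeast plus noise; habitat
    is hill forest on steep ground, swamp forest in the southern lowland,
    mixed forest elsewhere (emitted both as a label and as indicator
    columns usable as linear model terms).
    """
    rng = _rng(config.seed, 3)
    W, H = config.park_width_km, config.park_height_km
    rows = []
    for t in transects:
        x, y = t.midpoint
        slope = (
            2.0
            + 9.0 * np.exp(-(((x - 0.8 * W) ** 2 + (y - 0.8 * H) ** 2) / (2 * 25.0**2)))
            + rng.normal(0, 0.4)
        )
        slope = max(slope, 0.1)
        if slope > 6.0:
            habitat = "hill_forest"
        elif y < 0.18 * H:
            habitat = "swamp_forest"
        else:
            habitat = "mixed_forest"
        rows.append({"transect_id": t.transect_id, "slope": slope, "habitat": habitat,
                     "hab_hill": float(habitat == "hill_forest"),
                     "hab_swamp": float(habitat == "swamp_forest")})
    return pd.DataFrame(rows).set_index("transect_id")


def simulate_survey(landscape: Landscape, surface: DensitySurface,
                    config: SimulationConfig, epoch_label: str,
                    seed_stream: int = 10) -> tuple[SurveyDataset, TruthLedger]:
    """Draw one epoch's survey from the true surface.

    Per transect the within-strip expectation is
    mu_i = D(mid) * 2 * w_sim * l_i (in hectares); counts are negative
    binomial (variance phi * mu), each dung pile gets a uniform
    perpendicular distance on [0, w_sim] and is kept with probability
    g(x), so observed distances follow the detection density g/mu.
    """
    rng = _rng(config.seed, seed_stream)
    transects, sampling_locations = draw_survey_design(config)

    w = config.w_sim_m
    fam, pars = config.detection_family, config.detection_params
    xs_grid = np.linspace(0, w, 2001)
    p_detect = float(np.trapezoid(_g(fam, pars, xs_grid), xs_grid) / w)

    observations: list[Observation] = []
    true_d, exp_counts, exp_obs = {}, {}, {}
    for t in transects:
        d_ha = surface(*t.midpoint)
        area_ha = 2.0 * w * t.length * 0.1  # m * km = 0.1 ha
        mu = d_ha * area_ha
        true_d[t.transect_id] = d_ha
        exp_counts[t.transect_id] = mu
        exp_obs[t.transect_id] = mu * p_detect
        if mu <= 0:
            continue
        if config.phi == 1.0:
            count = rng.poisson(mu)
        else:
            p = 1.0 / config.phi
            r = mu * p / (1.0 - p)
            count = rng.negative_binomial(r, p)
        if count == 0:
            continue
        x = rng.uniform(0.0, w, size=count)
        keep = rng.uniform(0.0, 1.0, size=count) < _g(fam, pars, x)
        for xi in x[keep]:
            observations.append(Observation(transect_id=t.transect_id,
                                            perpendicular_distance=float(xi),
                                            epoch=epoch_label))

    ds = SurveyDataset(epoch=epoch_label, observations=observations,
                       transects=transects, locations=sampling_locations)
    mean_d = surface.park_mean_density(step=2.0)
    ledger = TruthLedger(
        seed=config.seed, epoch=epoch_label,
        true_density_at_transects=true_d, expected_counts=exp_counts,
        expected_observed_counts=exp_obs, mean_detection_prob=p_detect,
        true_mean_density=mean_d,
        true_total_dung=mean_d * config.area_km2 * 100.0,  # km^2 -> ha
        n_emitted=len(observations),
    )
    return ds, ledger


def simulate_two_epoch_survey(config: SimulationConfig):
    """Full two-epoch study: landscape, surfaces, datasets, ledgers, extras.

    Returns a dict with keys ``landscape``, ``surface1``, ``surface2``,
    ``ds1``, ``ds2``, ``ledger1``, ``ledger2``, ``extras`` (per-transect
    slope/habitat table, attached to the landscape as well).
    """
    landscape = generate_landscape(config)
    surf1 = simulate_density_surface(landscape, config, epoch=1)
    surf2 = simulate_density_surface(landscape, config, epoch=2)
    ds1, led1 = simulate_survey(landscape, surf1, config, "1995", seed_stream=10)
    ds2, led2 = simulate_survey(landscape, surf2, config, "2006", seed_stream=11)
    extras = _transect_extras(ds1.transects, config)
    landscape.extra_covariates = extras
    return {"landscape": landscape, "surface1": surf1, "surface2": surf2,
            "ds1": ds1, "ds2": ds2, "ledger1": led1, "ledger2": led2,
            "extras": extras}
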