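"""Synthetic metropolitan regions for mobile-stroke-unit siting studies.

The analysis needs a city with age-structured suburb populations, a set of
hospitals split into endovascular-clot-retrieval (ECR) hubs and
thrombolysis-only spokes, and a road network over which ambulance travel
times can be computed.  Real studies draw these from census tables, hospital
registries and a commercial routing API; this module generates statistically
comparable stand-ins so the whole pipeline is exercisable offline, and it can
plant a hospital-free, densely populated corner region for
parameter-recovery tests.

All randomness flows through a single integer seed per operation via
:func:`numpy.random.default_rng`; there is no global RNG state.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AgeBand",
    "Suburb",
    "Hospital",
    "RoadNetwork",
    "City",
    "CityConfig",
    "default_band_scheme",
    "DEFAULT_AGE_STRUCTURE",
    "generate_city",
    "plant_underserved_region",
    "generate_incidence_schedule",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AgeBand:
    """A 5-year census age band; ``upper is None`` marks the open top band.

    Bands are compared and sorted by their lower edge, so a band scheme can
    be kept in a sorted container.
    """

    lower: int
    upper: int | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.lower < 0 or self.lower % 5 != 0:
            raise ValueError(f"band lower edge must be a non-negative multiple of 5, got {self.lower}")
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError(f"band upper edge {self.upper} must exceed lower edge {self.lower}")

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    @classmethod
    def from_label(cls, label: str) -> "AgeBand":
        label = label.strip()
        if label.endswith("+"):
            return cls(int(label[:-1]), None)
        lo, hi = label.split("-")
        return cls(int(lo), int(hi))


def default_band_scheme(top: int = 85) -> list[AgeBand]:
    """Standard census scheme: 0-4, 5-9, ..., (top-5)-(top-1), top+."""
    bands = [AgeBand(lo, lo + 4) for lo in range(0, top, 5)]
    bands.append(AgeBand(top, None))
    return bands


def validate_band_scheme(bands: list[AgeBand]) -> None:
    """Bands must partition [0, inf): consecutive, starting at 0, open-ended top."""
    if not bands:
        raise ValueError("band scheme is empty")
    if bands[0].lower != 0:
        raise ValueError("first age band must start at 0")
    for a, b in zip(bands, bands[1:]):
        if a.upper is None:
            raise ValueError("only the last band may be open-ended")
        if b.lower != a.upper + 1:
            raise ValueError(f"bands {a.label} and {b.label} are not consecutive")
    if bands[-1].upper is not None:
        raise ValueError("last age band must be open-ended")


@dataclass
class Suburb:
    """A suburb represented by its centroid and an age-banded population."""

    id: str
    name: str
    lat: float
    lon: float
    population: dict[AgeBand, int]

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"suburb {self.id}: coordinates ({self.lat}, {self.lon}) out of range")
        for band, n in self.population.items():
            if n < 0:
                raise ValueError(f"suburb {self.id}: negative population in band {band.label}")

    @property
    def total_population(self) -> int:
        return int(sum(self.population.values()))


@dataclass
class Hospital:
    """A hospital with treatment-capability flags.

    Every ECR-capable hub also delivers thrombolysis, so ``ecr_capable``
    implies ``thrombolysis_capable``.
    """

    id: str
    name: str
    lat: float
    lon: float
    thrombolysis_capable: bool = True
    ecr_capable: bool = False

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"hospital {self.id}: coordinates out of range")
        if self.ecr_capable and not self.thrombolysis_capable:
            raise ValueError(f"hospital {self.id}: ECR capability implies thrombolysis capability")


@dataclass
class RoadNetwork:
    """Undirected road graph: nodes are (lat, lon); edges carry length and free speed."""

    nodes: dict[str, tuple[float, float]]
    edges: dict[tuple[str, str], dict[str, float]]

    def __post_init__(self) -> None:
        for (u, v), attrs in self.edges.items():
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            if attrs["length_km"] <= 0 or attrs["free_speed_kmh"] <= 0:
                raise ValueError(f"edge ({u}, {v}) must have positive length and speed")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for nid, (lat, lon) in self.nodes.items():
            g.add_node(nid, lat=lat, lon=lon)
        for (u, v), attrs in self.edges.items():
            minutes = attrs["length_km"] / attrs["free_speed_kmh"] * 60.0
            g.add_edge(u, v, length_km=attrs["length_km"],
                       free_speed_kmh=attrs["free_speed_kmh"], time_min=minutes)
        return g


@dataclass
class City:
    """Full study region: suburbs, hospitals, band scheme and optional roads.

    Coordinates are WGS84 decimal degrees throughout.
    """

    suburbs: list[Suburb]
    hospitals: list[Hospital]
    band_scheme: list[AgeBand]
    network: RoadNetwork | None = None
    crs_note: str = "WGS84 (EPSG:4326), coordinates as (lat, lon)"

    def __post_init__(self) -> None:
        validate_band_scheme(self.band_scheme)
        for cls_name, items in (("suburb", self.suburbs), ("hospital", self.hospitals)):
            ids = [it.id for it in items]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {cls_name} ids")
        if not any(h.ecr_capable for h in self.hospitals):
            raise ValueError("city must contain at least one ECR-capable hospital")
        scheme = set(self.band_scheme)
        for s in self.suburbs:
            if set(s.population) != scheme:
                raise ValueError(f"suburb {s.id} does not cover the city band scheme")

    @property
    def total_population(self) -> int:
        return int(sum(s.total_population for s in self.suburbs))

    def ecr_hospitals(self) -> list[Hospital]:
        return [h for h in self.hospitals if h.ecr_capable]

    def suburb_by_id(self) -> dict[str, Suburb]:
        return {s.id: s for s in self.suburbs}


# Age distribution of a large Australian metropolitan population, as
# proportions per 5-year band (18 bands, 0-4 ... 85+); sums to 1.
DEFAULT_AGE_STRUCTURE: tuple[float, ...] = (
    0.065, 0.065, 0.060, 0.060, 0.070, 0.080, 0.080, 0.075, 0.065,
    0.065, 0.060, 0.060, 0.050, 0.045, 0.035, 0.025, 0.020, 0.020,
)


@dataclass
class CityConfig:
    """Knobs for :func:`generate_city`.

    Defaults mirror a large Australian metropolis at desk scale: ~5.1 million
    people over 250 suburbs in a 60 km square, served by 5 ECR hubs and
    8 thrombolysis-only hospitals, with a 1.4x peak-hour congestion factor.
    """

    n_suburbs: int = 250
    n_ecr_hubs: int = 5
    n_thrombolysis_only: int = 8
    total_population: int = 5_100_000
    extent_km: float = 60.0
    age_structure: tuple[float, ...] = DEFAULT_AGE_STRUCTURE
    congestion_factor: float = 1.4
    seed: int = 0
    origin_lat: float = -33.87
    origin_lon: float = 151.21
    # Centre bias of hospital placement: probability of hosting a hospital
    # decays as exp(-bias * distance_to_centre / extent). The defaults mirror
    # the inner-city clustering of tertiary ECR hubs; 0 gives uniform placement.
    ecr_centre_bias: float = 6.0
    spoke_centre_bias: float = 3.0

    def validate(self) -> None:
        for name in ("n_suburbs", "n_ecr_hubs", "n_thrombolysis_only", "total_population"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("extent_km", "congestion_factor", "origin_lat", "origin_lon",
                     "ecr_centre_bias", "spoke_centre_bias"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.extent_km <= 0:
            raise ValueError("extent_km must be positive")
        if self.congestion_factor < 1:
            raise ValueError("congestion_factor must be >= 1")
        if self.ecr_centre_bias < 0 or self.spoke_centre_bias < 0:
            raise ValueError("centre bias values must be non-negative")
        props = np.asarray(self.age_structure, dtype=float)
        if not np.all(np.isfinite(props)) or np.any(props < 0):
            raise ValueError("age_structure proportions must be finite and non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"age_structure proportions must sum to 1, got {props.sum()}")
        if self.n_suburbs < self.n_ecr_hubs + self.n_thrombolysis_only:
            raise ValueError(
                "n_suburbs must be at least n_ecr_hubs + n_thrombolysis_only "
                "(hospitals are co-located with distinct suburbs)"
            )


# --------------------------------------------------------------------------
# Coordinate helpers (small-region equirectangular mapping)
# --------------------------------------------------------------------------

_KM_PER_DEG_LAT = 111.32


def _xy_to_latlon(x_km: float, y_km: float, cfg: CityConfig) -> tuple[float, float]:
    """Map km offsets within the square extent to WGS84 (lat, lon)."""
    half = cfg.extent_km / 2.0
    lat = cfg.origin_lat + (y_km - half) / _KM_PER_DEG_LAT
    lon = cfg.origin_lon + (x_km - half) / (_KM_PER_DEG_LAT * math.cos(math.radians(cfg.origin_lat)))
    return (round(lat, 6), round(lon, 6))


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def generate_city(config: CityConfig) -> City:
    """Generate a synthetic city; deterministic for a fixed config and seed.

    Suburb centroids are uniform over the square extent; suburb sizes follow
    a log-normal weight so the population is realistically uneven; the joint
    (suburb, age-band) allocation is a single multinomial draw, so the city
    total equals ``config.total_population`` exactly.  ECR hubs are placed at
    suburbs biased toward the region centre, mirroring the inner-city
    clustering of tertiary hospitals, with thrombolysis-only hospitals more
    dispersed.  The road network is a jittered grid; every suburb and
    hospital is served via its nearest grid node.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bands = default_band_scheme()
    if len(config.age_structure) != len(bands):
        raise ValueError(f"age_structure must have {len(bands)} proportions")

    n = config.n_suburbs
    xy = rng.uniform(0.0, config.extent_km, size=(n, 2))

    # Joint multinomial over (suburb, band) cells conserves the total exactly.
    weights = rng.lognormal(mean=0.0, sigma=0.8, size=n)
    weights /= weights.sum()
    probs = np.outer(weights, np.asarray(config.age_structure, dtype=float)).ravel()
    probs /= probs.sum()
    counts = rng.multinomial(config.total_population, probs).reshape(n, len(bands))

    suburbs = []
    for i in range(n):
        lat, lon = _xy_to_latlon(xy[i, 0], xy[i, 1], config)
        suburbs.append(Suburb(
            id=f"S{i:03d}", name=f"Suburb {i:03d}", lat=lat, lon=lon,
            population={b: int(counts[i, j]) for j, b in enumerate(bands)},
        ))

    hospitals = _place_hospitals(config, xy, suburbs, rng)
    network = _grid_network(config, rng)
    return City(suburbs=suburbs, hospitals=hospitals, band_scheme=bands, network=network)


def _place_hospitals(config: CityConfig, xy: np.ndarray, suburbs: list[Suburb],
                     rng: np.random.Generator) -> list[Hospital]:
    centre = config.extent_km / 2.0
    dist_centre = np.hypot(xy[:, 0] - centre, xy[:, 1] - centre)

    def pick(k: int, bias: float, taken: set[int]) -> list[int]:
        avail = np.array([i for i in range(len(suburbs)) if i not in taken])
        p = np.exp(-bias * dist_centre[avail] / config.extent_km)
        p /= p.sum()
        return list(rng.choice(avail, size=k, replace=False, p=p))

    taken: set[int] = set()
    ecr_idx = pick(config.n_ecr_hubs, config.ecr_centre_bias, taken)
    taken.update(ecr_idx)
    thromb_idx = pick(config.n_thrombolysis_only, config.spoke_centre_bias, taken)

    hospitals = []
    for k, i in enumerate(ecr_idx, start=1):
        hospitals.append(Hospital(
            id=f"H_ECR{k}", name=f"ECR Hub {k}", lat=suburbs[i].lat, lon=suburbs[i].lon,
            thrombolysis_capable=True, ecr_capable=True,
        ))
    for k, i in enumerate(thromb_idx, start=1):
        hospitals.append(Hospital(
            id=f"H_TPA{k}", name=f"Thrombolysis Hospital {k}", lat=suburbs[i].lat, lon=suburbs[i].lon,
            thrombolysis_capable=True, ecr_capable=False,
        ))
    return hospitals


def _grid_network(config: CityConfig, rng: np.random.Generator) -> RoadNetwork:
    """Perturbed m x m grid over the extent; connected by construction."""
    from .travel_time import haversine_km

    m = max(4, int(round(math.sqrt(config.n_suburbs))) + 1)
    spacing = config.extent_km / (m - 1)
    jitter = rng.uniform(-0.25, 0.25, size=(m, m, 2)) * spacing

    nodes: dict[str, tuple[float, float]] = {}
    for r in range(m):
        for c in range(m):
            x = np.clip(c * spacing + jitter[r, c, 0], 0.0, config.extent_km)
            y = np.clip(r * spacing + jitter[r, c, 1], 0.0, config.extent_km)
            nodes[f"N{r}_{c}"] = _xy_to_latlon(float(x), float(y), config)

    edges: dict[tuple[str, str], dict[str, float]] = {}
    for r in range(m):
        for c in range(m):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= m or c2 >= m:
                    continue
                u, v = f"N{r}_{c}", f"N{r2}_{c2}"
                length = max(haversine_km(nodes[u], nodes[v]), 1e-6)
                speed = float(rng.uniform(40.0, 70.0))
                edges[(u, v)] = {"length_km": round(length, 6), "free_speed_kmh": round(speed, 3)}
    return RoadNetwork(nodes=nodes, edges=edges)


# --------------------------------------------------------------------------
# Planted underserved region
# --------------------------------------------------------------------------

def corner_bounds(city: City, corner_fraction: float) -> tuple[float, float]:
    """South-west corner cut lines (lat_cut, lon_cut) over the city's bounding box.

    A point belongs to the corner iff lat <= lat_cut and lon <= lon_cut.
    The bounding box spans all suburb and hospital locations.
    """
    pts = [(s.lat, s.lon) for s in city.suburbs] + [(h.lat, h.lon) for h in city.hospitals]
    lats, lons = zip(*pts)
    lat_cut = min(lats) + corner_fraction * (max(lats) - min(lats))
    lon_cut = min(lons) + corner_fraction * (max(lons) - min(lons))
    return lat_cut, lon_cut


def plant_underserved_region(city: City, corner_fraction: float,
                             population_share: float, seed: int) -> City:
    """Return a copy of *city* with a hospital-free, heavily populated corner.

    The south-west corner of the bounding box, of linear size
    ``corner_fraction`` of the extent, is cleared of hospitals, and the
    population is re-drawn so the corner suburbs hold exactly
    ``round(population_share * total)`` people while the city total is
    unchanged.  Within each side of the split, the new counts follow the
    existing (suburb, band) proportions.  Used as a ground-truth harness:
    the corner is, by construction, the least-served part of the city.
    """
    if not (0.0 < corner_fraction < 0.5):
        raise ValueError("corner_fraction must be in (0, 0.5)")
    if not (0.0 < population_share < 1.0):
        raise ValueError("population_share must be in (0, 1)")

    lat_cut, lon_cut = corner_bounds(city, corner_fraction)

    def in_corner(lat: float, lon: float) -> bool:
        return lat <= lat_cut and lon <= lon_cut

    corner_mask = np.array([in_corner(s.lat, s.lon) for s in city.suburbs])
    if not corner_mask.any():
        raise ValueError("no suburb centroid falls inside the requested corner")

    hospitals = [h for h in city.hospitals if not in_corner(h.lat, h.lon)]
    if not any(h.ecr_capable for h in hospitals):
        raise ValueError("removing corner hospitals would leave zero ECR hubs")

    bands = city.band_scheme
    counts = np.array([[s.population[b] for b in bands] for s in city.suburbs], dtype=np.int64)
    total = int(counts.sum())
    target = int(round(population_share * total))

    rng = np.random.default_rng(seed)
    new_counts = np.zeros_like(counts)
    for mask, quota in ((corner_mask, target), (~corner_mask, total - target)):
        cell = counts[mask].astype(float).ravel()
        p = cell / cell.sum() if cell.sum() > 0 else np.full(cell.size, 1.0 / cell.size)
        new_counts[mask] = rng.multinomial(quota, p).reshape(mask.sum(), len(bands))

    suburbs = []
    for i, s in enumerate(city.suburbs):
        suburbs.append(replace(
            s, population={b: int(new_counts[i, j]) for j, b in enumerate(bands)}
        ))
    return City(suburbs=suburbs, hospitals=copy.deepcopy(hospitals),
                band_scheme=list(bands), network=copy.deepcopy(city.network),
                crs_note=city.crs_note)


# --------------------------------------------------------------------------
# Synthetic incidence schedules
# --------------------------------------------------------------------------

#: Ratio of the "low" to the "high" schedule, the contrast between two
#: Australian incidence studies conducted 13 years apart (the later one
#: documenting substantially lower stroke incidence).
LOW_TO_HIGH_RATIO = 0.58


def generate_incidence_schedule(profile: str, band_scheme: list[AgeBand] | None = None):
    """Synthetic stroke-incidence schedule (cases per 100,000 person-years).

    Stroke incidence rises steeply with age; the schedule follows an
    exponential gradient from ~2 per 100k in early childhood to ~2,800 per
    100k in the open 85+ band.  ``profile="high"`` emulates the higher of two
    published Australian city studies, ``"low"`` the markedly lower one
    (every low rate is 0.58x its high counterpart, hence strictly below it).
    Deterministic; no randomness involved.
    """
    from .incidence import IncidenceSchedule

    if band_scheme is None:
        band_scheme = default_band_scheme()
    validate_band_scheme(band_scheme)
    if profile not in ("high", "low"):
        raise ValueError(f"unknown incidence profile {profile!r}; expected 'high' or 'low'")

    rates = {}
    for i, band in enumerate(band_scheme):
        high = 2.2 * math.exp(0.42 * i)
        rate = high if profile == "high" else LOW_TO_HIGH_RATIO * high
        rates[band] = round(min(rate, 3000.0), 1)
    return IncidenceSchedule(name=profile, rates=rates)
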