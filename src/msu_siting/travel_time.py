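"""Directional hospital-to-suburb travel-time and distance matrices.

The study design needs, for every (hospital, suburb-centroid) pair, the
peak-morning-traffic driving time in minutes and the route length in km.
Live routing APIs are deliberately out of scope; instead a small provider
abstraction supplies the matrix from

* ``network`` — time-optimal shortest paths over the city's road network
  (Dijkstra on edge times ``length_km / free_speed_kmh * 60``), km measured
  along the same minimal-time path;
* ``haversine`` — great-circle distance at a single fallback road speed;
* ``file`` — a long-format CSV, so exports from a real routing service can
  be plugged in unchanged.

Peak traffic is modelled as a uniform multiplicative congestion factor on
minutes (default 1.4); distances are unaffected.  Direction is hospital ->
suburb throughout, but nothing prevents building the transposed matrix by
swapping the point sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_city import City, Hospital

__all__ = [
    "EARTH_RADIUS_KM",
    "TravelMatrix",
    "ProviderSpec",
    "haversine_km",
    "compute_travel_matrix",
    "compute_hub_to_hospital_matrix",
    "load_travel_matrix",
    "write_travel_matrix",
]

EARTH_RADIUS_KM = 6371.0088

TRAVEL_CSV_COLUMNS = ["hospital_id", "suburb_id", "minutes", "km", "time_of_day", "provider"]


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two WGS84 (lat, lon) points."""
    for p in (a, b):
        lat, lon = p
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValueError(f"non-finite coordinate {p}")
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinate {p} out of range")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (math.sin((lat2 - lat1) / 2.0) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def _haversine_matrix(origins: np.ndarray, dests: np.ndarray) -> np.ndarray:
    """Vectorized great-circle distances, origins (m,2) x dests (n,2) -> (m,n) km."""
    o = np.radians(origins)[:, None, :]
    d = np.radians(dests)[None, :, :]
    s = (np.sin((d[..., 0] - o[..., 0]) / 2.0) ** 2
         + np.cos(o[..., 0]) * np.cos(d[..., 0]) * np.sin((d[..., 1] - o[..., 1]) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))


@dataclass
class ProviderSpec:
    """How to obtain the travel matrix.

    congestion_factor multiplies minutes when time_of_day == "peak";
    fallback_speed_kmh is the assumed road speed of the haversine provider;
    path points at the CSV for the "file" provider.
    """

    kind: str = "network"
    congestion_factor: float = 1.4
    fallback_speed_kmh: float = 60.0
    path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("network", "haversine", "file"):
            raise ValueError(f"unknown provider kind {self.kind!r}")
        if self.congestion_factor < 1.0:
            raise ValueError("congestion_factor must be >= 1")
        if self.fallback_speed_kmh <= 0.0:
            raise ValueError("fallback_speed_kmh must be positive")


@dataclass
class TravelMatrix:
    """Hospital x suburb minutes and km, with provider provenance."""

    hospital_ids: list[str]
    suburb_ids: list[str]
    minutes: np.ndarray
    km: np.ndarray
    provider: str
    time_of_day: str

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        self.km = np.asarray(self.km, dtype=float)
        shape = (len(self.hospital_ids), len(self.suburb_ids))
        for name, arr in (("minutes", self.minutes), ("km", self.km)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} entries must be finite and non-negative")
        if self.time_of_day not in ("peak", "offpeak"):
            raise ValueError(f"time_of_day must be 'peak' or 'offpeak', got {self.time_of_day!r}")
        self._h_index = {h: i for i, h in enumerate(self.hospital_ids)}
        self._s_index = {s: j for j, s in enumerate(self.suburb_ids)}
        if len(self._h_index) != len(self.hospital_ids) or len(self._s_index) != len(self.suburb_ids):
            raise ValueError("duplicate ids in travel matrix")

    def minutes_between(self, hospital_id: str, suburb_id: str) -> float:
        return float(self.minutes[self._h_index[hospital_id], self._s_index[suburb_id]])

    def km_between(self, hospital_id: str, suburb_id: str) -> float:
        return float(self.km[self._h_index[hospital_id], self._s_index[suburb_id]])

    def row(self, hospital_id: str) -> np.ndarray:
        """Minutes from one hospital to every suburb, in suburb_ids order."""
        return self.minutes[self._h_index[hospital_id]]

    def hospital_index(self, hospital_id: str) -> int:
        if hospital_id not in self._h_index:
            raise KeyError(f"hospital id {hospital_id!r} not in travel matrix")
        return self._h_index[hospital_id]

    def layer(self, metric: str) -> np.ndarray:
        if metric == "minutes":
            return self.minutes
        if metric == "km":
            return self.km
        raise ValueError(f"unknown metric {metric!r}; expected 'minutes' or 'km'")

    def to_frame(self) -> pd.DataFrame:
        h = np.repeat(self.hospital_ids, len(self.suburb_ids))
        s = np.tile(self.suburb_ids, len(self.hospital_ids))
        return pd.DataFrame({
            "hospital_id": h, "suburb_id": s,
            "minutes": self.minutes.ravel(), "km": self.km.ravel(),
            "time_of_day": self.time_of_day, "provider": self.provider,
        })


# --------------------------------------------------------------------------
# Providers
# --------------------------------------------------------------------------

def _points(items) -> tuple[list[str], np.ndarray]:
    ids = [it.id for it in items]
    coords = np.array([(it.lat, it.lon) for it in items], dtype=float)
    return ids, coords


def _network_matrix(city: City, origin_coords: np.ndarray,
                    dest_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import networkx as nx

    if city.network is None:
        raise ValueError("network provider requires city.network")
    g = city.network.to_networkx()
    node_ids = list(g.nodes)
    node_coords = np.array([(g.nodes[n]["lat"], g.nodes[n]["lon"]) for n in node_ids])

    def attach(coords: np.ndarray) -> list[str]:
        d = _haversine_matrix(coords, node_coords)
        return [node_ids[j] for j in d.argmin(axis=1)]

    o_nodes, d_nodes = attach(origin_coords), attach(dest_coords)
    minutes = np.empty((len(o_nodes), len(d_nodes)))
    km = np.empty_like(minutes)
    for i, src in enumerate(o_nodes):
        dist, paths = nx.single_source_dijkstra(g, src, weight="time_min")
        missing = [t for t in set(d_nodes) if t not in dist]
        if missing:
            raise ValueError(f"road network is disconnected: no route from {src} to {sorted(missing)}")
        for j, tgt in enumerate(d_nodes):
            minutes[i, j] = dist[tgt]
            path = paths[tgt]
            km[i, j] = sum(g.edges[u, v]["length_km"] for u, v in zip(path, path[1:]))
    return minutes, km


def _build_matrix(city: City, origins, dests, spec: ProviderSpec,
                  time_of_day: str) -> tuple[np.ndarray, np.ndarray]:
    o_ids, o_coords = _points(origins)
    d_ids, d_coords = _points(dests)
    if spec.kind == "network":
        minutes, km = _network_matrix(city, o_coords, d_coords)
    elif spec.kind == "haversine":
        km = _haversine_matrix(o_coords, d_coords)
        minutes = km / spec.fallback_speed_kmh * 60.0
    else:
        raise ValueError(f"provider kind {spec.kind!r} not handled here")

    # Exactly co-located origin/destination pairs are zero by definition.
    same = (o_coords[:, None, :] == d_coords[None, :, :]).all(axis=2)
    minutes[same] = 0.0
    km[same] = 0.0
    if time_of_day == "peak":
        minutes = minutes * spec.congestion_factor
    return minutes, km


def compute_travel_matrix(city: City, spec: ProviderSpec,
                          time_of_day: str = "peak") -> TravelMatrix:
    """Hospital -> suburb-centroid travel matrix under the given provider.

    For ``spec.kind == "file"`` the CSV at ``spec.path`` is loaded and
    checked to cover every (hospital, suburb) pair of the city.
    """
    if time_of_day not in ("peak", "offpeak"):
        raise ValueError(f"time_of_day must be 'peak' or 'offpeak', got {time_of_day!r}")
    h_ids = [h.id for h in city.hospitals]
    s_ids = [s.id for s in city.suburbs]
    if spec.kind == "file":
        if spec.path is None:
            raise ValueError("file provider requires spec.path")
        return load_travel_matrix(spec.path, h_ids, s_ids)
    minutes, km = _build_matrix(city, city.hospitals, city.suburbs, spec, time_of_day)
    return TravelMatrix(hospital_ids=h_ids, suburb_ids=s_ids, minutes=minutes,
                        km=km, provider=spec.kind, time_of_day=time_of_day)


def compute_hub_to_hospital_matrix(city: City, spec: ProviderSpec,
                                   time_of_day: str = "peak") -> TravelMatrix:
    """ECR-hub -> hospital travel matrix, for spoke-proximity reporting.

    Rows are the ECR hubs, columns every hospital of the city (hospitals act
    as destinations); the id lists live in the same TravelMatrix container.
    """
    if spec.kind == "file":
        raise ValueError("hub-to-hospital matrix supports network and haversine providers")
    hubs = city.ecr_hospitals()
    minutes, km = _build_matrix(city, hubs, city.hospitals, spec, time_of_day)
    return TravelMatrix(hospital_ids=[h.id for h in hubs],
                        suburb_ids=[h.id for h in city.hospitals],
                        minutes=minutes, km=km, provider=spec.kind, time_of_day=time_of_day)


# --------------------------------------------------------------------------
# CSV interchange (long format)
# --------------------------------------------------------------------------

def write_travel_matrix(matrix: TravelMatrix, path: str | Path) -> None:
    """Write the long-format CSV: hospital_id,suburb_id,minutes,km,time_of_day,provider."""
    frame = matrix.to_frame()
    frame.to_csv(path, index=False, float_format="%.6f")


def load_travel_matrix(path: str | Path, hospital_ids: list[str],
                       suburb_ids: list[str]) -> TravelMatrix:
    """Load a long-format travel CSV covering exactly the requested id sets.

    Strict by design: duplicated pairs, missing pairs, unknown ids and
    negative or non-numeric values are all errors, never silently repaired.
    """
    frame = pd.read_csv(path, dtype={"hospital_id": str, "suburb_id": str})
    missing_cols = [c for c in TRAVEL_CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"travel CSV {path} missing columns {missing_cols}")

    h_set, s_set = set(hospital_ids), set(suburb_ids)
    unknown_h = sorted(set(frame["hospital_id"]) - h_set)
    unknown_s = sorted(set(frame["suburb_id"]) - s_set)
    if unknown_h or unknown_s:
        raise ValueError(f"travel CSV contains unknown ids: hospitals {unknown_h}, suburbs {unknown_s}")

    dup = frame.duplicated(subset=["hospital_id", "suburb_id"])
    if dup.any():
        pairs = frame.loc[dup, ["hospital_id", "suburb_id"]].itertuples(index=False)
        raise ValueError(f"duplicated (hospital, suburb) rows: {[tuple(p) for p in pairs]}")

    for col in ("minutes", "km"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            raise ValueError(f"non-numeric or non-finite values in column {col!r}")
        if (vals < 0).any():
            raise ValueError(f"negative values in column {col!r}")
        frame[col] = vals

    h_pos = {h: i for i, h in enumerate(hospital_ids)}
    s_pos = {s: j for j, s in enumerate(suburb_ids)}
    minutes = np.full((len(hospital_ids), len(suburb_ids)), np.nan)
    km = np.full_like(minutes, np.nan)
    rows = frame["hospital_id"].map(h_pos).to_numpy()
    cols = frame["suburb_id"].map(s_pos).to_numpy()
    minutes[rows, cols] = frame["minutes"].to_numpy()
    km[rows, cols] = frame["km"].to_numpy()
    if np.isnan(minutes).any():
        i, j = np.argwhere(np.isnan(minutes))[0]
        raise ValueError(f"travel CSV missing pair ({hospital_ids[i]}, {suburb_ids[j]})")

    tod = frame["time_of_day"].iloc[0]
    provider = str(frame["provider"].iloc[0])
    return TravelMatrix(hospital_ids=list(hospital_ids), suburb_ids=list(suburb_ids),
                        minutes=minutes, km=km, provider=provider, time_of_day=str(tod))
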