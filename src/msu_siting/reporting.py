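"""Serialization of cities and analysis results to GeoJSON, CSV and JSON.

GeoJSON is the canonical map artifact (coordinate order [lon, lat] per the
standard): a city serializes to one FeatureCollection of suburb-centroid
Point features carrying per-band populations plus hospital Point features
carrying capability flags; a coverage export adds each suburb's membership
count as a feature property, ready for choropleth rendering.  The road
network rides along as LineString features so a round-tripped city stays
analysable with the network travel-time provider.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .coverage import CoverageResult
from .hub_selection import HubRanking
from .incidence import CatchmentTable
from .synthetic_city import (AgeBand, City, Hospital, RoadNetwork, Suburb,
                             validate_band_scheme)

__all__ = [
    "city_to_geojson",
    "city_from_geojson",
    "save_city_geojson",
    "load_city_geojson",
    "export_geojson",
    "AnalysisReport",
]


# --------------------------------------------------------------------------
# City <-> GeoJSON
# --------------------------------------------------------------------------

def _suburb_feature(s: Suburb, extra: dict | None = None) -> dict:
    props = {"kind": "suburb", "id": s.id, "name": s.name}
    for band in sorted(s.population):
        props[f"population_{band.label}"] = s.population[band]
    if extra:
        props.update(extra)
    return {"type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
            "properties": props}


def _hospital_feature(h: Hospital) -> dict:
    return {"type": "Feature",
            "geometry": {"type": "Point", "coordinates": [h.lon, h.lat]},
            "properties": {"kind": "hospital", "id": h.id, "name": h.name,
                           "thrombolysis": h.thrombolysis_capable, "ecr": h.ecr_capable}}


def city_to_geojson(city: City, membership: dict[str, int] | None = None) -> dict:
    """FeatureCollection of suburbs, hospitals and (optionally) road edges."""
    features = []
    for s in city.suburbs:
        extra = {"membership": membership[s.id]} if membership is not None else None
        features.append(_suburb_feature(s, extra))
    features.extend(_hospital_feature(h) for h in city.hospitals)
    if city.network is not None:
        for (u, v), attrs in city.network.edges.items():
            lu = city.network.nodes[u]
            lv = city.network.nodes[v]
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [[lu[1], lu[0]], [lv[1], lv[0]]]},
                "properties": {"kind": "road", "u": u, "v": v,
                               "u_lat": lu[0], "u_lon": lu[1],
                               "v_lat": lv[0], "v_lon": lv[1],
                               "length_km": attrs["length_km"],
                               "free_speed_kmh": attrs["free_speed_kmh"]},
            })
    return {"type": "FeatureCollection", "features": features}


def city_from_geojson(obj: dict) -> City:
    """Rebuild a City from its FeatureCollection serialization."""
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    suburbs: list[Suburb] = []
    hospitals: list[Hospital] = []
    nodes: dict[str, tuple[float, float]] = {}
    edges: dict[tuple[str, str], dict[str, float]] = {}
    for feat in obj.get("features", []):
        props = feat.get("properties", {})
        kind = props.get("kind")
        if kind == "suburb":
            lon, lat = feat["geometry"]["coordinates"]
            population = {
                AgeBand.from_label(key.removeprefix("population_")): int(val)
                for key, val in props.items() if key.startswith("population_")
            }
            suburbs.append(Suburb(id=props["id"], name=props.get("name", props["id"]),
                                  lat=lat, lon=lon, population=population))
        elif kind == "hospital":
            lon, lat = feat["geometry"]["coordinates"]
            hospitals.append(Hospital(id=props["id"], name=props.get("name", props["id"]),
                                      lat=lat, lon=lon,
                                      thrombolysis_capable=bool(props["thrombolysis"]),
                                      ecr_capable=bool(props["ecr"])))
        elif kind == "road":
            nodes[props["u"]] = (props["u_lat"], props["u_lon"])
            nodes[props["v"]] = (props["v_lat"], props["v_lon"])
            edges[(props["u"], props["v"])] = {"length_km": props["length_km"],
                                               "free_speed_kmh": props["free_speed_kmh"]}
    if not suburbs:
        raise ValueError("GeoJSON contains no suburb features")
    band_scheme = sorted(suburbs[0].population)
    validate_band_scheme(band_scheme)
    network = RoadNetwork(nodes=nodes, edges=edges) if edges else None
    return City(suburbs=suburbs, hospitals=hospitals, band_scheme=band_scheme,
                network=network)


def save_city_geojson(city: City, path: str | Path) -> None:
    Path(path).write_text(json.dumps(city_to_geojson(city), sort_keys=True) + "\n")


def load_city_geojson(path: str | Path) -> City:
    return city_from_geojson(json.loads(Path(path).read_text()))


def export_geojson(city: City, result: CoverageResult, path: str | Path) -> None:
    """Coverage choropleth export: suburb features carry their membership."""
    missing = [s for s in result.membership if s not in {x.id for x in city.suburbs}]
    if missing:
        raise ValueError(f"coverage result names suburbs absent from city: {sorted(missing)}")
    unmapped = [s.id for s in city.suburbs if s.id not in result.membership]
    if unmapped:
        raise ValueError(f"coverage result missing suburbs: {unmapped}")
    obj = city_to_geojson(city, membership=result.membership)
    Path(path).write_text(json.dumps(obj, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# Analysis report
# --------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Bundle of everything a siting run produced, JSON round-trippable.

    ``provenance`` records seed, provider, thresholds and an optional
    timestamp; the timestamp is excluded from determinism guarantees.
    """

    histograms: dict[str, dict[str, int]]  # class -> {membership count (str): n suburbs}
    least_served: list[str]
    ranking: list[dict]
    selected_hub: str
    catchment: list[dict]
    provenance: dict = field(default_factory=dict)
    config_echo: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, obj: dict) -> "AnalysisReport":
        return cls(**obj)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @staticmethod
    def build(histograms: dict[str, dict[int, int]], ranking: HubRanking,
              selected_hub: str, table: CatchmentTable,
              provenance: dict, config_echo: dict | None = None) -> "AnalysisReport":
        return AnalysisReport(
            histograms={cls_: {str(k): v for k, v in hist.items()}
                        for cls_, hist in histograms.items()},
            least_served=sorted(ranking.least_served),
            ranking=[{"hospital_id": h, "score_minutes": round(s, 6),
                      "aggregator": ranking.aggregator, "n_least_served": n}
                     for h, s, n in ranking.entries],
            selected_hub=selected_hub,
            catchment=[
                {"hospital_id": r.hospital_id, "metric": r.metric,
                 "threshold": r.threshold, "schedule": r.schedule,
                 "cases": round(r.cases, 6)}
                for r in table.frame.itertuples(index=False)
            ],
            provenance=provenance, config_echo=config_echo,
        )
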