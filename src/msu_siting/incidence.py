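"""Projection of annual stroke cases and hub-catchment totals.

Expected annual stroke cases in a suburb are the age-band populations
multiplied by age-specific incidence rates (cases per 100,000 person-years)
and summed over bands.  A hub's *catchment* at a threshold is the set of
suburbs within that travel time (minutes) or route distance (km) of the
hub; its projected caseload is the sum of suburb cases over the catchment.
Each candidate hub is evaluated independently, so catchments of different
hubs overlap by design.  Cases are kept real-valued throughout; rounding is
a formatting decision left to report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_city import AgeBand, City, Suburb
from .travel_time import TravelMatrix

__all__ = [
    "IncidenceSchedule",
    "CatchmentTable",
    "suburb_cases",
    "catchment_cases",
    "catchment_table",
    "spoke_proximity",
    "load_incidence_schedule",
    "write_incidence_schedule",
]

DEFAULT_MINUTE_THRESHOLDS = (30.0, 45.0, 60.0)
DEFAULT_KM_THRESHOLDS = (20.0, 30.0, 50.0)


@dataclass
class IncidenceSchedule:
    """Age-specific stroke incidence: cases per 100,000 person-years per band."""

    name: str
    rates: dict[AgeBand, float]

    def __post_init__(self) -> None:
        for band, r in self.rates.items():
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"schedule {self.name}: invalid rate {r} for band {band.label}")

    def rate(self, band: AgeBand) -> float:
        return self.rates[band]


def suburb_cases(suburb: Suburb, schedule: IncidenceSchedule) -> float:
    """Expected annual stroke cases: sum over bands of pop * rate / 100,000."""
    total = 0.0
    for band, pop in suburb.population.items():
        if band not in schedule.rates:
            raise ValueError(
                f"band {band.label} of suburb {suburb.id} missing from schedule {schedule.name}")
        total += pop * schedule.rates[band] / 100_000.0
    return total


def _city_case_vector(city: City, schedule: IncidenceSchedule) -> np.ndarray:
    return np.array([suburb_cases(s, schedule) for s in city.suburbs])


def catchment_cases(hub: str, matrix: TravelMatrix, city: City,
                    schedule: IncidenceSchedule, metric: str = "minutes",
                    threshold: float = 30.0) -> float:
    """Projected annual cases in the suburbs within *threshold* of *hub*.

    ``metric`` selects the minutes or km layer of the matrix; the boundary
    is inclusive, consistent with coverage membership.
    """
    layer = matrix.layer(metric)
    row = layer[matrix.hospital_index(hub)]
    if list(matrix.suburb_ids) != [s.id for s in city.suburbs]:
        raise ValueError("matrix suburb order does not match city suburb order")
    cases = _city_case_vector(city, schedule)
    return float(cases[row <= threshold].sum())


@dataclass
class CatchmentTable:
    """Hub x (metric, threshold) x schedule projected caseloads (long form)."""

    frame: pd.DataFrame  # columns: hospital_id, metric, threshold, schedule, cases

    def __post_init__(self) -> None:
        expected = ["hospital_id", "metric", "threshold", "schedule", "cases"]
        if list(self.frame.columns) != expected:
            raise ValueError(f"catchment frame must have columns {expected}")
        for (_, _, _), grp in self.frame.groupby(["hospital_id", "metric", "schedule"]):
            ordered = grp.sort_values("threshold")["cases"].to_numpy()
            if np.any(np.diff(ordered) < 0):
                raise ValueError("catchment cases must be non-decreasing in threshold")

    def cell(self, hospital_id: str, metric: str, threshold: float, schedule: str) -> float:
        f = self.frame
        sel = f[(f.hospital_id == hospital_id) & (f.metric == metric)
                & (f.threshold == threshold) & (f.schedule == schedule)]
        if len(sel) != 1:
            raise KeyError((hospital_id, metric, threshold, schedule))
        return float(sel.cases.iloc[0])

    def to_wide(self) -> pd.DataFrame:
        """One row per hub, columns like ``high 30 min`` / ``low 50 km``."""
        f = self.frame.copy()
        unit = f.metric.map({"minutes": "min", "km": "km"})
        f["column"] = f.schedule + " " + f.threshold.map(lambda t: f"{t:g}") + " " + unit
        wide = f.pivot(index="hospital_id", columns="column", values="cases")
        order = [f"{sch} {t:g} {u}"
                 for sch in dict.fromkeys(self.frame.schedule)
                 for (u, ts) in (("min", sorted(set(f.threshold[f.metric == 'minutes']))),
                                 ("km", sorted(set(f.threshold[f.metric == 'km']))))
                 for t in ts]
        return wide[[c for c in order if c in wide.columns]]

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6f")


def catchment_table(city: City, matrix: TravelMatrix,
                    schedules: list[IncidenceSchedule],
                    minute_thresholds=DEFAULT_MINUTE_THRESHOLDS,
                    km_thresholds=DEFAULT_KM_THRESHOLDS) -> CatchmentTable:
    """Projected caseloads for every ECR hub across time and distance catchments.

    Default thresholds: 30/45/60 minutes and 20/30/50 km, one cell per
    hub x threshold x incidence schedule.
    """
    for ths in (minute_thresholds, km_thresholds):
        arr = np.asarray(ths, dtype=float)
        if arr.size and (np.any(arr <= 0) or np.any(np.diff(arr) <= 0)):
            raise ValueError("thresholds must be positive and strictly ascending")
    hubs = city.ecr_hospitals()
    records = []
    for schedule in schedules:
        for hub in hubs:
            for metric, thresholds in (("minutes", minute_thresholds), ("km", km_thresholds)):
                for t in thresholds:
                    records.append({
                        "hospital_id": hub.id, "metric": metric, "threshold": float(t),
                        "schedule": schedule.name,
                        "cases": catchment_cases(hub.id, matrix, city, schedule, metric, float(t)),
                    })
    frame = pd.DataFrame.from_records(
        records, columns=["hospital_id", "metric", "threshold", "schedule", "cases"])
    return CatchmentTable(frame=frame)


def spoke_proximity(city: City, matrix_hub_to_hospital: TravelMatrix,
                    max_spokes: int = 2) -> dict[str, list[tuple[str, float, float]]]:
    """Nearest thrombolysis-only spoke hospitals for each ECR hub.

    Returns, per hub, up to ``max_spokes`` (spoke_id, minutes, km) triples
    sorted by minutes.  A hub is never its own spoke, and ECR hubs are not
    spokes of one another.
    """
    if max_spokes < 1:
        raise ValueError("max_spokes must be at least 1")
    spokes = [h for h in city.hospitals if h.thrombolysis_capable and not h.ecr_capable]
    if not spokes:
        raise ValueError("city has no thrombolysis-only spoke hospitals")
    out: dict[str, list[tuple[str, float, float]]] = {}
    for hub in city.ecr_hospitals():
        triples = [
            (sp.id,
             matrix_hub_to_hospital.minutes_between(hub.id, sp.id),
             matrix_hub_to_hospital.km_between(hub.id, sp.id))
            for sp in spokes
        ]
        triples.sort(key=lambda t: (t[1], t[0]))
        out[hub.id] = triples[:max_spokes]
    return out


# --------------------------------------------------------------------------
# CSV interchange: band_lower,band_upper,rate_per_100k (upper empty for 85+)
# --------------------------------------------------------------------------

def write_incidence_schedule(schedule: IncidenceSchedule, path: str | Path) -> None:
    rows = []
    for band in sorted(schedule.rates):
        rows.append({
            "band_lower": band.lower,
            "band_upper": "" if band.upper is None else band.upper,
            "rate_per_100k": schedule.rates[band],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_incidence_schedule(path: str | Path, name: str | None = None) -> IncidenceSchedule:
    frame = pd.read_csv(path)
    required = {"band_lower", "band_upper", "rate_per_100k"}
    if not required.issubset(frame.columns):
        raise ValueError(f"incidence CSV {path} must have columns {sorted(required)}")
    rates = {}
    for row in frame.itertuples(index=False):
        upper = None if pd.isna(row.band_upper) or row.band_upper == "" else int(row.band_upper)
        rates[AgeBand(int(row.band_lower), upper)] = float(row.rate_per_100k)
    return IncidenceSchedule(name=name or Path(path).stem, rates=rates)
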