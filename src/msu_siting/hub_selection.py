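"""Equity-based choice of the mobile-stroke-unit operating base.

Among the ECR-capable hospitals, the base is the one *closest to the least
well-served suburbs*.  "Closest to a set" is made precise by aggregating the
hub-to-suburb travel times over the least-served set: mean (default, the
equity-oriented average), median, or max (worst-case guarantee).  A
population-weighted mean is available for the mean aggregator, reflecting
where the people at risk of stroke actually live.  Ties are broken by
lexicographic hospital id so the selection is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageResult, least_served_suburbs, membership_counts
from .synthetic_city import City, Hospital
from .travel_time import TravelMatrix

__all__ = ["HubRanking", "rank_hubs", "select_hub", "run_site_analysis"]

AGGREGATORS = ("mean", "median", "max")


@dataclass
class HubRanking:
    """ECR hubs ordered by aggregate travel time to the least-served suburbs."""

    entries: list[tuple[str, float, int]]  # (hospital_id, score_minutes, n_least_served)
    aggregator: str
    least_served: set[str]


def rank_hubs(matrix: TravelMatrix, hospitals: list[Hospital], least_served: set[str],
              aggregator: str = "mean",
              population_weights: dict[str, float] | None = None) -> HubRanking:
    """Score every ECR hub by aggregate minutes to the least-served suburbs.

    ``population_weights`` (suburb id -> weight, e.g. population) turns the
    mean into a population-weighted mean; it is only meaningful with
    ``aggregator="mean"``.
    """
    if not least_served:
        raise ValueError("least_served set is empty")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")
    hubs = [h for h in hospitals if h.ecr_capable]
    if not hubs:
        raise ValueError("no ECR-capable hospital to rank")
    if population_weights is not None and aggregator != "mean":
        raise ValueError("population_weights require aggregator='mean'")

    targets = sorted(least_served)
    cols = {s: j for j, s in enumerate(matrix.suburb_ids)}
    missing = [s for s in targets if s not in cols]
    if missing:
        raise ValueError(f"suburbs missing from travel matrix: {missing}")
    idx = [cols[s] for s in targets]

    weights = None
    if population_weights is not None:
        weights = np.array([float(population_weights[s]) for s in targets])
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("population weights must be non-negative with positive sum")

    entries = []
    for h in hubs:
        times = matrix.minutes[matrix.hospital_index(h.id), idx]
        if aggregator == "mean":
            score = float(np.average(times, weights=weights))
        elif aggregator == "median":
            score = float(np.median(times))
        else:
            score = float(times.max())
        entries.append((h.id, score, len(targets)))
    entries.sort(key=lambda e: (e[1], e[0]))
    return HubRanking(entries=entries, aggregator=aggregator, least_served=set(targets))


def select_hub(ranking: HubRanking) -> str:
    """The proposed MSU base: head of the ranking."""
    if not ranking.entries:
        raise ValueError("empty hub ranking")
    return ranking.entries[0][0]


def run_site_analysis(city: City, matrix: TravelMatrix, threshold_minutes: float = 30.0,
                      hospital_class: str = "all", aggregator: str = "mean",
                      population_weighted: bool = False,
                      ) -> tuple[CoverageResult, HubRanking, str]:
    """Full siting pass: coverage -> least-served set -> hub ranking -> selection.

    Returns the intermediates alongside the selected hub id so reports can
    show the whole chain of evidence.
    """
    result = membership_counts(matrix, city.hospitals, threshold_minutes, hospital_class)
    least = least_served_suburbs(result)
    weights = None
    if population_weighted:
        weights = {s.id: float(s.total_population) for s in city.suburbs}
    ranking = rank_hubs(matrix, city.hospitals, least, aggregator, weights)
    return result, ranking, select_hub(ranking)
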