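"""Threshold-coverage membership: how many hospitals can reach each suburb.

The siting method is a variant of the maximum-coverage problem in which the
facility sites already exist, so instead of choosing sites it scores how
well each suburb is already served.  A suburb's *membership* is the number
of hospitals of a class ("all" = every thrombolysis- or ECR-capable
hospital, "ecr" = ECR hubs only) that can reach its centroid within a
travel-time threshold (inclusive boundary; the canonical threshold is
30 minutes).  Suburbs at the observed minimum membership are the least
well-served and are the equity targets for a mobile stroke unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .synthetic_city import Hospital
from .travel_time import TravelMatrix

__all__ = [
    "CoverageResult",
    "membership_counts",
    "coverage_histogram",
    "least_served_suburbs",
    "class_mask",
]

HOSPITAL_CLASSES = ("all", "ecr")


def class_mask(hospitals: list[Hospital], hospital_class: str) -> list[bool]:
    """Which hospitals belong to the class ("all": thrombolysis or ECR; "ecr": ECR only)."""
    if hospital_class == "all":
        return [h.thrombolysis_capable or h.ecr_capable for h in hospitals]
    if hospital_class == "ecr":
        return [h.ecr_capable for h in hospitals]
    raise ValueError(f"unknown hospital class {hospital_class!r}; expected 'all' or 'ecr'")


@dataclass
class CoverageResult:
    """Per-suburb count of class hospitals reachable within the threshold."""

    threshold_minutes: float
    hospital_class: str
    membership: dict[str, int]
    n_class_hospitals: int

    def __post_init__(self) -> None:
        for s, k in self.membership.items():
            if not (0 <= k <= self.n_class_hospitals):
                raise ValueError(
                    f"membership[{s}] = {k} outside [0, {self.n_class_hospitals}]")


def membership_counts(matrix: TravelMatrix, hospitals: list[Hospital],
                      threshold_minutes: float, hospital_class: str = "all") -> CoverageResult:
    """Count, per suburb, the class hospitals within the travel-time threshold.

    Reachable means ``minutes <= threshold`` (inclusive boundary).
    """
    if threshold_minutes <= 0:
        raise ValueError("threshold_minutes must be positive")
    mask = class_mask(hospitals, hospital_class)
    selected = [h for h, m in zip(hospitals, mask) if m]
    if not selected:
        raise ValueError(f"no hospitals of class {hospital_class!r}")
    rows = [matrix.hospital_index(h.id) for h in selected]
    counts = (matrix.minutes[rows] <= threshold_minutes).sum(axis=0)
    membership = {s: int(k) for s, k in zip(matrix.suburb_ids, counts)}
    return CoverageResult(threshold_minutes=float(threshold_minutes),
                          hospital_class=hospital_class, membership=membership,
                          n_class_hospitals=len(selected))


def coverage_histogram(result: CoverageResult) -> dict[int, int]:
    """membership count -> number of suburbs at exactly that count."""
    return dict(sorted(Counter(result.membership.values()).items()))


def least_served_suburbs(result: CoverageResult) -> set[str]:
    """All suburbs at the minimum observed membership (possibly zero)."""
    if not result.membership:
        raise ValueError("coverage result covers no suburbs")
    lo = min(result.membership.values())
    return {s for s, k in result.membership.items() if k == lo}
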