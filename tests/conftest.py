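import numpy as np
import pytest

from msu_siting import (AgeBand, City, CityConfig, Hospital, ProviderSpec, Suburb,
                        TravelMatrix, compute_travel_matrix, default_band_scheme,
                        generate_city)

BANDS = default_band_scheme()


def make_suburb(sid, lat, lon, total=0, band_pops=None):
    """Suburb with all population in the 85+ band unless band_pops given."""
    pops = {b: 0 for b in BANDS}
    if band_pops:
        for label, n in band_pops.items():
            pops[AgeBand.from_label(label)] = n
    else:
        pops[AgeBand(85, None)] = total
    return Suburb(id=sid, name=sid, lat=lat, lon=lon, population=pops)


def make_matrix(hospital_ids, suburb_ids, minutes, km=None, time_of_day="offpeak"):
    minutes = np.asarray(minutes, dtype=float)
    return TravelMatrix(hospital_ids=list(hospital_ids), suburb_ids=list(suburb_ids),
                        minutes=minutes, km=np.asarray(km, float) if km is not None else minutes.copy(),
                        provider="test", time_of_day=time_of_day)


@pytest.fixture(scope="session")
def default_city():
    """The default Sydney-scale synthetic city (250 suburbs, 5 ECR + 8 spokes, 5.1M)."""
    return generate_city(CityConfig(seed=7))


@pytest.fixture(scope="session")
def default_matrix(default_city):
    return compute_travel_matrix(default_city, ProviderSpec(kind="network"), "peak")


@pytest.fixture()
def toy_city():
    """Three suburbs on a line, two hospitals co-located with the outer suburbs."""
    suburbs = [
        make_suburb("s_west", -33.90, 151.10, total=10_000),
        make_suburb("s_mid", -33.90, 151.20, total=20_000),
        make_suburb("s_east", -33.90, 151.30, total=5_000),
    ]
    hospitals = [
        Hospital(id="h_ecr", name="ECR", lat=-33.90, lon=151.10,
                 thrombolysis_capable=True, ecr_capable=True),
        Hospital(id="h_tpa", name="TPA", lat=-33.90, lon=151.30,
                 thrombolysis_capable=True, ecr_capable=False),
    ]
    return City(suburbs=suburbs, hospitals=hospitals, band_scheme=BANDS)


def brute_force_membership(minutes, threshold, rows):
    """Independent double-loop oracle for coverage membership counts."""
    counts = []
    for j in range(minutes.shape[1]):
        k = 0
        for i in rows:
            if minutes[i, j] <= threshold:
                k += 1
        counts.append(k)
    return counts


def brute_force_best_hub(matrix, hubs, least_served, aggregator):
    """Independent exhaustive-enumeration oracle for the hub choice."""
    import statistics
    best = None
    for h in hubs:
        times = [matrix.minutes_between(h, s) for s in sorted(least_served)]
        if aggregator == "mean":
            score = sum(times) / len(times)
        elif aggregator == "median":
            score = statistics.median(times)
        else:
            score = max(times)
        if best is None or (score, h) < best:
            best = (score, h)
    return best[1]
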