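"""Retrospective space-time scan statistic (discrete Poisson, cylindrical windows).

The scan slides cylinders over the study region: the base is the set of the
k nearest regions to a center (great-circle centroid distance), the height a
run of consecutive years.  For each cylinder with observed count c and
expected count e (calibrated so the expected study total equals the observed
total C), the Poisson log-likelihood ratio against a homogeneous-risk null is

    LLR = c*log(c/e) + (C-c)*log((C-c)/(C-e)),    0*log(0/x) := 0,

maximized separately over high-rate (c > e) and low-rate (c < e) cylinders.
Significance comes from Monte Carlo replication: null panels are multinomial
redistributions of the C cases over cells with probabilities E_ij / sum(E),
and the pseudo p-value is (1 + #{replicates with direction-restricted max
LLR >= observed}) / (1 + n_monte_carlo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .panel_io import CountPanel, RegionCentroids
from .standardization import ExpectedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "Cylinder",
    "ClusterResult",
    "poisson_llr",
    "relative_risk",
    "great_circle_km",
    "enumerate_cylinders",
    "scan",
    "cluster_table",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    max_spatial_fraction : largest share of the population at risk (person-time
        within the scanned window) a cylinder base may cover; default 0.5.
    max_temporal_fraction : largest share of the study period a window may
        span; default 0.5.
    n_monte_carlo : number of null replicates; default 999, so the smallest
        attainable pseudo p is 0.001.
    directions : subset of {"high", "low"}; both by default.
    distance : "great_circle" (lat/lon degrees) or "euclidean" (projected).
    """

    max_spatial_fraction: float = 0.5
    max_temporal_fraction: float = 0.5
    n_monte_carlo: int = 999
    directions: tuple = ("high", "low")
    seed: int = 0
    distance: str = "great_circle"

    def __post_init__(self):
        if not 0 < self.max_spatial_fraction <= 0.5 + 1e-12:
            raise ValueError("max_spatial_fraction must be in (0, 0.5]")
        if not 0 < self.max_temporal_fraction <= 0.5 + 1e-12:
            raise ValueError("max_temporal_fraction must be in (0, 0.5]")
        if self.n_monte_carlo < 1:
            raise ValueError("n_monte_carlo must be positive")
        bad = set(self.directions) - {"high", "low"}
        if bad:
            raise ValueError(f"unknown scan directions: {sorted(bad)}")


@dataclass(frozen=True)
class Cylinder:
    """One scanning window: a k-nearest-regions base over a year interval."""

    center_region: int
    member_regions: tuple
    start_year: int
    end_year: int
    c: int          # observed cases inside
    e: float        # expected cases inside (calibrated to the observed total)
    person_time: float = 0.0


@dataclass(frozen=True)
class ClusterResult:
    """A reported cluster with its scan statistics."""

    cylinder: Cylinder
    direction: str            # "high" or "low"
    oe: float                 # c / e
    rr: float                 # risk inside vs outside
    llr: float
    p_value: float
    rank: str                 # "primary" or "secondary"


def poisson_llr(c, e, C):
    """Discrete-Poisson scan log-likelihood ratio for one cylinder.

    Parameters are the cylinder observed count ``c``, the cylinder expected
    count ``e`` (with the study-wide expected total calibrated to the case
    total ``C``), and ``C`` itself.  Vectorized over c and e.
    """
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0) or np.any(e >= C):
        raise ValueError("cylinder expected count must satisfy 0 < e < C "
                         "(expected totals calibrated to the observed total)")
    if np.any(c < 0) or np.any(c > C):
        raise ValueError("cylinder observed count must satisfy 0 <= c <= C")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0) / e), 0.0)
        rem = C - c
        t_out = np.where(rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0) / (C - e)), 0.0)
    out = t_in + t_out
    return out if out.ndim else float(out)


def relative_risk(c, e, C):
    """Relative risk inside vs outside the cylinder, with O/E alongside.

    RR = (c/e) / ((C-c)/(C-e)).  Returns ``(rr, oe)``; when c == C the RR is
    infinite and reported as ``inf``.
    """
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0) or np.any(e >= C):
        raise ValueError("expected count must satisfy 0 < e < C")
    oe = c / e
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (C - c) / (C - e)
        rr = np.where(denom > 0, oe / np.where(denom > 0, denom, 1.0), np.inf)
    if rr.ndim:
        return rr, oe
    return float(rr), float(oe)


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km between degree coordinates."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _distance_matrix(centroids: RegionCentroids, metric: str) -> np.ndarray:
    lat = centroids.latitude
    lon = centroids.longitude
    if metric == "great_circle":
        return great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    if metric == "euclidean":
        return np.hypot(lat[:, None] - lat[None, :], lon[:, None] - lon[None, :])
    raise ValueError(f"unknown distance metric {metric!r}")


def _neighbor_order(dist: np.ndarray) -> np.ndarray:
    """Per-center region ordering by distance; ties broken by region index."""
    n = dist.shape[0]
    order = np.empty((n, n), dtype=int)
    for i in range(n):
        # stable sort on distance keeps region order as the tie-break
        order[i] = np.argsort(dist[i], kind="stable")
        if order[i, 0] != i:  # exact-tie duplicate centroid: force center first
            logger.info("duplicate centroid near region %d: tie broken by region order", i)
            k = np.nonzero(order[i] == i)[0][0]
            order[i, 1:k + 1] = order[i, :k]
            order[i, 0] = i
    return order


def enumerate_cylinders(panel: CountPanel, centroids: RegionCentroids,
                        expected: ExpectedMatrix, config: ScanConfig):
    """Yield every admissible cylinder with its observed and expected sums.

    For each center region, bases grow over the k nearest regions (k = 1 is
    the center alone); for each base, every window of consecutive years up to
    the temporal cap is scanned.  A base is admissible for a window when its
    person-time does not exceed ``max_spatial_fraction`` of the all-region
    person-time in the same window; base growth stops at the first k whose
    base violates the cap for every window.
    """
    Y = panel.observed
    E = np.asarray(expected.expected, dtype=float)
    pop = panel.population
    n, T = Y.shape
    max_len = int(np.floor(config.max_temporal_fraction * T + 1e-9))
    max_len = max(max_len, 1)
    dist = _distance_matrix(centroids, config.distance)
    order = _neighbor_order(dist)

    # cumulative sums over years for O(1) window sums
    cY = np.concatenate([np.zeros((n, 1)), np.cumsum(Y, axis=1)], axis=1)
    cE = np.concatenate([np.zeros((n, 1)), np.cumsum(E, axis=1)], axis=1)
    cP = np.concatenate([np.zeros((n, 1)), np.cumsum(pop, axis=1)], axis=1)
    totP = pop.sum(axis=0)
    ctotP = np.concatenate([[0.0], np.cumsum(totP)])

    seen = set()
    for center in range(n):
        base_Y = np.zeros(T + 1)
        base_E = np.zeros(T + 1)
        base_P = np.zeros(T + 1)
        members = []
        for k in range(n):
            r = order[center, k]
            members.append(r)
            base_Y += cY[r]
            base_E += cE[r]
            base_P += cP[r]
            key = frozenset(members)
            any_admissible = False
            first_time = key not in seen
            for t1 in range(T):
                for t2 in range(t1, min(t1 + max_len, T)):
                    pt = base_P[t2 + 1] - base_P[t1]
                    tot_pt = ctotP[t2 + 1] - ctotP[t1]
                    # the cap limits base growth beyond the center; a
                    # single-region base is always admissible
                    if k > 0 and pt > config.max_spatial_fraction * tot_pt + 1e-9:
                        continue
                    any_admissible = True
                    if not first_time:
                        continue
                    yield Cylinder(
                        center_region=center,
                        member_regions=tuple(members),
                        start_year=panel.years[t1],
                        end_year=panel.years[t2],
                        c=int(base_Y[t2 + 1] - base_Y[t1]),
                        e=float(base_E[t2 + 1] - base_E[t1]),
                        person_time=float(pt),
                    )
            seen.add(key)
            if not any_admissible:
                break  # population cap exceeded for every window; stop growing


def _calibrate(expected: ExpectedMatrix, C: int) -> np.ndarray:
    """Scale expecteds so their total equals the observed case total."""
    E = np.asarray(expected.expected, dtype=float)
    tot = E.sum()
    if tot <= 0:
        raise ValueError("expected counts sum to zero; cannot calibrate")
    return E * (C / tot)


def scan(panel: CountPanel, centroids: RegionCentroids, expected: ExpectedMatrix,
         config: ScanConfig = ScanConfig()) -> list:
    """Run the full space-time scan and return ranked clusters per direction.

    Within each requested direction the max-LLR cylinder is the primary
    cluster; further clusters are reported greedily in decreasing LLR among
    cylinders sharing no region with any better-ranked reported cluster of
    the same direction.  Pseudo p-values compare each reported cluster's LLR
    with the null distribution of the direction-restricted maximum LLR over
    ``n_monte_carlo`` conditional (multinomial) replicates.
    """
    C = panel.total_cases
    if C == 0:
        return []
    Ecal = _calibrate(expected, C)
    exp_cal = ExpectedMatrix(Ecal, expected.stratification)

    cylinders = list(enumerate_cylinders(panel, centroids, exp_cal, config))
    if not cylinders:
        return []
    n, T = panel.observed.shape
    # cell-membership mask per cylinder for vectorized null replication
    yindex = {y: j for j, y in enumerate(panel.years)}
    M = np.zeros((len(cylinders), n * T), dtype=bool)
    for q, cyl in enumerate(cylinders):
        j1, j2 = yindex[cyl.start_year], yindex[cyl.end_year]
        for r in cyl.member_regions:
            M[q, r * T + j1: r * T + j2 + 1] = True

    evec = np.array([cyl.e for cyl in cylinders])
    cvec = np.array([cyl.c for cyl in cylinders], dtype=float)
    valid = (evec > 0) & (evec < C)
    llr_all = np.zeros(len(cylinders))
    llr_all[valid] = poisson_llr(cvec[valid], evec[valid], C)

    rng = np.random.default_rng(config.seed)
    probs = (Ecal / C).ravel()
    sims = rng.multinomial(C, probs, size=config.n_monte_carlo).astype(float)
    cs = sims @ M.T  # (nsim, ncyl)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(valid[None, :],
                      np.where(cs > 0, cs * np.log(np.where(cs > 0, cs, 1.0) / evec[None, :]), 0.0)
                      + np.where(C - cs > 0,
                                 (C - cs) * np.log(np.where(C - cs > 0, C - cs, 1.0)
                                                   / (C - evec[None, :])), 0.0),
                      -np.inf)

    results = []
    for direction in config.directions:
        if direction == "high":
            dmask = cvec > evec
            null_max = np.where(cs > evec[None, :], ll, -np.inf).max(axis=1)
        else:
            dmask = cvec < evec
            null_max = np.where(cs < evec[None, :], ll, -np.inf).max(axis=1)
        idx = np.nonzero(dmask & valid)[0]
        if idx.size == 0:
            continue
        idx = idx[np.argsort(-llr_all[idx], kind="stable")]
        taken_regions: set = set()
        rank = "primary"
        for q in idx:
            cyl = cylinders[q]
            if taken_regions & set(cyl.member_regions):
                continue
            p = (1 + int(np.sum(null_max >= llr_all[q] - 1e-12))) / (1 + config.n_monte_carlo)
            rr, oe = relative_risk(cyl.c, cyl.e, C)
            results.append(ClusterResult(
                cylinder=cyl, direction=direction, oe=oe, rr=rr,
                llr=float(llr_all[q]), p_value=float(p), rank=rank,
            ))
            taken_regions |= set(cyl.member_regions)
            rank = "secondary"
    return results


def cluster_table(results: list, panel: CountPanel) -> "pandas.DataFrame":
    """Flatten ClusterResults into the standard report schema."""
    import pandas as pd

    rows = []
    for k, res in enumerate(results):
        cyl = res.cylinder
        regions = ", ".join(panel.region_ids[r] for r in cyl.member_regions)
        rows.append({
            "cluster_rank": res.rank,
            "direction": res.direction,
            "regions": regions,
            "start": cyl.start_year,
            "end": cyl.end_year,
            "population": cyl.person_time / (cyl.end_year - cyl.start_year + 1),
            "observed": cyl.c,
            "expected": cyl.e,
            "OE": res.oe,
            "RR": res.rr,
            "LLR": res.llr,
            "p": res.p_value,
        })
    cols = ["cluster_rank", "direction", "regions", "start", "end", "population",
            "observed", "expected", "OE", "RR", "LLR", "p"]
    return pd.DataFrame(rows, columns=cols)
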