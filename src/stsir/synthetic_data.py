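"""Synthetic region-by-year panels with the structure the models assume.

The registry extract behind the original Hamadan province analysis is not
public, so every pipeline stage is exercised on synthetic panels generated
from the models' own data-generating process: spatially structured risk
(ICAR field on the county adjacency graph), a smooth RW2 temporal trend,
unstructured spatial/temporal heterogeneity, an optional space-time
interaction, and Poisson counts around population-proportional baseline
expecteds.  High- or low-risk cylinders can be injected for scan power
studies.

:func:`hamadan_fixture` provides a 9-county x 10-year skeleton whose
populations, adjacency and centroids are *synthetic stand-ins*: the county
names, the study years, a handful of populations printed in the original
cluster table (Nahavand 193745, Malayer 299070, and cluster sums that pin
down Bahar and Asadabad) and the approximate centroid geography are real;
the remaining populations, the contiguity list and exact centroids are
plausible inventions, documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gmrf
from .panel_io import AdjacencyGraph, CountPanel, RegionCentroids
from .st_models import ModelSpec

__all__ = [
    "SimulationTruth",
    "hamadan_fixture",
    "simulate_panel",
    "inject_cluster",
    "CRC_DECADE_RATE",
    "GC_DECADE_RATE",
]

# cumulative incidence per 100k population over the ten study years
CRC_DECADE_RATE = 107.72e-5
GC_DECADE_RATE = 135.23e-5

_COUNTIES = (
    # (name, population, latitude, longitude)
    ("Hamadan", 660000, 34.80, 48.52),
    ("Malayer", 299070, 34.30, 48.82),
    ("Nahavand", 193745, 34.19, 48.37),
    ("Tuyserkan", 106614, 34.55, 48.45),
    ("Asadabad", 113590, 34.78, 48.12),
    ("Kabudarahang", 150000, 35.21, 48.72),
    ("Razan", 96000, 35.39, 49.03),
    ("Bahar", 124646, 34.91, 48.44),
    ("Famenin", 39358, 35.11, 48.97),
)

# hand-specified symmetric contiguity (approximate county geography)
_CONTIGUITY = {
    "Hamadan": ["Bahar", "Kabudarahang", "Famenin", "Razan", "Malayer", "Tuyserkan"],
    "Malayer": ["Hamadan", "Tuyserkan", "Nahavand"],
    "Nahavand": ["Tuyserkan", "Malayer"],
    "Tuyserkan": ["Asadabad", "Bahar", "Hamadan", "Malayer", "Nahavand"],
    "Asadabad": ["Bahar", "Tuyserkan", "Kabudarahang"],
    "Kabudarahang": ["Asadabad", "Bahar", "Hamadan", "Famenin", "Razan"],
    "Razan": ["Kabudarahang", "Famenin", "Hamadan"],
    "Bahar": ["Asadabad", "Kabudarahang", "Hamadan", "Tuyserkan"],
    "Famenin": ["Kabudarahang", "Razan", "Hamadan"],
}


@dataclass
class SimulationTruth:
    """Ground truth of a simulated panel, for recovery experiments."""

    params: dict
    theta_true: np.ndarray
    baseline_expected: np.ndarray
    injected_clusters: list = field(default_factory=list)


def hamadan_fixture():
    """A 9-county x 10-year (2010-2019) panel skeleton with graph and centroids.

    Returns ``(panel, graph, centroids)``; the panel's counts are zero (it is
    a skeleton for :func:`simulate_panel`) and populations are constant over
    years.  See the module docstring for which numbers are real and which
    are synthetic placeholders.
    """
    names = [c[0] for c in _COUNTIES]
    pops = np.array([c[1] for c in _COUNTIES], dtype=float)
    years = list(range(2010, 2020))
    T = len(years)
    panel = CountPanel(names, years,
                       np.zeros((len(names), T)),
                       np.tile(pops[:, None], (1, T)))
    idx = {n: i for i, n in enumerate(names)}
    neighbors = tuple(tuple(sorted(idx[nb] for nb in _CONTIGUITY[n])) for n in names)
    graph = AdjacencyGraph(names, neighbors)
    centroids = RegionCentroids(
        names,
        np.array([c[2] for c in _COUNTIES]),
        np.array([c[3] for c in _COUNTIES]),
    )
    return panel, graph, centroids


_DEFAULT_HYPER = {
    "alpha": 0.0,
    "sd_v": 0.1,
    "sd_u": 0.2,
    "sd_gamma": 0.1,
    "sd_phi": 0.05,
    "sd_delta": 0.15,
    "beta": 0.02,
    "sd_delta_i": 0.05,
}


def simulate_panel(skeleton: CountPanel, graph: AdjacencyGraph,
                   spec: ModelSpec = ModelSpec(), hyper: dict | None = None,
                   seed: int = 0, baseline_rate: float = CRC_DECADE_RATE):
    """Simulate counts from a space-time model variant on a panel skeleton.

    Baseline expecteds are population-proportional, ``e_ij = n_ij * rate/T``
    with ``rate`` the per-decade cumulative incidence (the CRC printed rate
    by default, so fixture totals land near the printed case total).  Random
    effects are drawn from the same intrinsic-GMRF priors the models use,
    via exact constrained sampling in the structure-matrix eigenbasis, then
    ``Y_ij ~ Poisson(e_ij * theta_ij)``.

    Returns ``(panel, truth)``; fully reproducible from (spec, hyper, seed).
    """
    hp = dict(_DEFAULT_HYPER)
    if hyper:
        hp.update(hyper)
    rng = np.random.default_rng(seed)
    n, T = skeleton.n_regions, skeleton.n_years
    e = skeleton.population * (baseline_rate / T)

    params = {"alpha": hp["alpha"]}
    log_theta = np.full((n, T), hp["alpha"], dtype=float)

    v = gmrf.sample_igmrf(gmrf.iid_contrast_basis(n), hp["sd_v"], rng)
    u = gmrf.sample_igmrf(gmrf.penalized_basis(gmrf.icar_structure(graph)),
                          hp["sd_u"], rng)
    log_theta += (v + u)[:, None]
    params.update(v=v, u=u, sd_v=hp["sd_v"], sd_u=hp["sd_u"])

    if spec.kind == "nonparametric":
        gam = gmrf.sample_igmrf(
            gmrf.penalized_basis(gmrf.rw_structure(T, spec.temporal_walk_order)),
            hp["sd_gamma"], rng)
        phi = gmrf.sample_igmrf(gmrf.iid_contrast_basis(T), hp["sd_phi"], rng)
        log_theta += (gam + phi)[None, :]
        params.update(gamma=gam, phi=phi, sd_gamma=hp["sd_gamma"], sd_phi=hp["sd_phi"])
        if spec.interaction != "none":
            ib = gmrf.interaction_basis(spec.interaction, graph, T,
                                        spec.interaction_walk_order)
            delta = gmrf.sample_igmrf(ib, hp["sd_delta"], rng).reshape(n, T)
            log_theta += delta
            params.update(delta=delta, sd_delta=hp["sd_delta"])
    else:
        t = np.arange(T, dtype=float)
        t -= t.mean()
        slopes = gmrf.sample_igmrf(gmrf.iid_contrast_basis(n), hp["sd_delta_i"], rng)
        log_theta += (hp["beta"] + slopes)[:, None] * t[None, :]
        params.update(beta=hp["beta"], delta_i=slopes, sd_delta_i=hp["sd_delta_i"])

    with np.errstate(over="ignore"):
        theta = np.exp(log_theta)
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(e * theta)):
        raise ValueError("non-finite relative risk; hyper values too extreme")
    Y = rng.poisson(e * theta)
    panel = CountPanel(list(skeleton.region_ids), list(skeleton.years),
                       Y, skeleton.population.copy())
    return panel, SimulationTruth(params, theta, e)


def inject_cluster(panel: CountPanel, truth: SimulationTruth, regions,
                   window: tuple, rr: float, seed: int = 0):
    """Multiply true risk by ``rr`` inside a cylinder and redraw its counts.

    ``regions`` are region labels or indices; ``window`` is the inclusive
    ``(start_year, end_year)``.  Returns a new ``(panel, truth)`` pair with
    the injection recorded.
    """
    rng = np.random.default_rng(seed)
    ridx = [panel.region_ids.index(r) if not isinstance(r, (int, np.integer)) else int(r)
            for r in regions]
    jmask = [j for j, y in enumerate(panel.years) if window[0] <= y <= window[1]]
    if not jmask:
        raise ValueError(f"window {window} outside panel years")
    theta = truth.theta_true.copy()
    Y = panel.observed.copy()
    for i in ridx:
        for j in jmask:
            theta[i, j] *= rr
            Y[i, j] = rng.poisson(truth.baseline_expected[i, j] * theta[i, j])
    new_panel = CountPanel(list(panel.region_ids), list(panel.years),
                           Y, panel.population.copy())
    new_truth = SimulationTruth(
        dict(truth.params), theta, truth.baseline_expected.copy(),
        truth.injected_clusters + [(tuple(ridx), tuple(window), rr)],
    )
    return new_panel, new_truth
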