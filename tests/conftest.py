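import numpy as np
import pytest

from stsir import synthetic_data
from stsir.panel_io import AdjacencyGraph, CountPanel, RegionCentroids
from stsir.st_models import McmcConfig


@pytest.fixture(scope="session")
def fixture_triple():
    """The 9-county x 10-year skeleton, graph and centroids."""
    return synthetic_data.hamadan_fixture()


@pytest.fixture
def toy_panel():
    """4 regions x 2 years with equal populations and simple counts."""
    obs = np.array([[10, 12], [8, 9], [11, 7], [9, 14]])
    pop = np.full((4, 2), 1e5)
    return CountPanel(["A", "B", "C", "D"], [2000, 2001], obs, pop)


@pytest.fixture
def toy_centroids():
    # an irregular line so nearest-neighbour orderings are unambiguous
    return RegionCentroids(["A", "B", "C", "D"],
                           np.array([30.0, 30.1, 30.35, 30.8]),
                           np.array([50.0, 50.0, 50.0, 50.0]))


@pytest.fixture
def path_graph():
    return AdjacencyGraph(["A", "B", "C"], ((1,), (0, 2), (1,)))


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short but converging MCMC settings used throughout the test suite."""
    return McmcConfig(chains=2, warmup=500, draws=500, seed=123)


def grid_geojson(k, size=1.0):
    """A k x k lattice of unit squares as a GeoJSON FeatureCollection."""
    feats = []
    for r in range(k):
        for c in range(k):
            x0, y0 = c * size, r * size
            feats.append({
                "type": "Feature",
                "properties": {"region": f"r{r}c{c}"},
                "geometry": {"type": "Polygon", "coordinates": [[
                    [x0, y0], [x0 + size, y0], [x0 + size, y0 + size],
                    [x0, y0 + size], [x0, y0],
                ]]},
            })
    return {"type": "FeatureCollection", "features": feats}
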