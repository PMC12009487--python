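"""Reading, validating and writing region-by-year count panels and geography.

The canonical in-memory objects are :class:`CountPanel` (observed cases and
population at risk on a complete region x year grid), :class:`AdjacencyGraph`
(queen-contiguity neighbourhood structure) and :class:`RegionCentroids`
(geographic coordinates used by the space-time scan).  Region order is fixed
by the panel's first-appearance order and is the canonical index everywhere;
adjacency and centroid containers are aligned to it on construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape as _shapely_shape

logger = logging.getLogger(__name__)

__all__ = [
    "CountPanel",
    "AdjacencyGraph",
    "RegionCentroids",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "build_adjacency",
    "read_adjacency_list",
    "write_results_table",
]


class PanelValidationError(ValueError):
    """Raised when an input panel, graph or centroid table is inconsistent."""


@dataclass(frozen=True)
class CountPanel:
    """A complete region x year grid of observed counts and populations.

    Attributes
    ----------
    region_ids : list of str
        Region labels in canonical (first-appearance) order.
    years : list of int
        Consecutive calendar years.
    observed : ndarray, shape (n_regions, n_years)
        Non-negative integer case counts Y_ij.
    population : ndarray, shape (n_regions, n_years)
        Positive person counts n_ij (population at risk).
    """

    region_ids: list
    years: list
    observed: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.observed)
        pop = np.asarray(self.population, dtype=float)
        n, T = len(self.region_ids), len(self.years)
        if obs.shape != (n, T) or pop.shape != (n, T):
            raise PanelValidationError(
                f"matrix shapes {obs.shape}/{pop.shape} do not match "
                f"{n} regions x {T} years"
            )
        if len(set(self.region_ids)) != n:
            raise PanelValidationError("region_ids are not unique")
        yrs = np.asarray(self.years)
        if T > 1 and not np.all(np.diff(yrs) == 1):
            raise PanelValidationError(f"years not consecutive: {list(self.years)}")
        if not np.allclose(obs, np.round(obs)) or np.any(obs < 0):
            raise PanelValidationError("observed counts must be non-negative integers")
        if np.any(pop <= 0):
            raise PanelValidationError("all populations must be positive")
        object.__setattr__(self, "observed", np.round(obs).astype(np.int64))
        object.__setattr__(self, "population", pop)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def total_cases(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns region, year, observed, population."""
        rows = [
            (r, y, int(self.observed[i, j]), self.population[i, j])
            for i, r in enumerate(self.region_ids)
            for j, y in enumerate(self.years)
        ]
        return pd.DataFrame(rows, columns=["region", "year", "observed", "population"])


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric region neighbourhood structure (queen contiguity).

    ``neighbors[i]`` is the sorted tuple of neighbour indices of region i;
    ``degree[i]`` is the neighbour count n_delta_i that scales the conditional
    variance of the intrinsic CAR prior.  Islands (degree 0) are permitted but
    flagged via ``connected`` / ``islands``.
    """

    region_ids: list
    neighbors: tuple  # tuple of sorted tuples of int

    def __post_init__(self):
        n = len(self.region_ids)
        nb = tuple(tuple(sorted(set(v))) for v in self.neighbors)
        if len(nb) != n:
            raise PanelValidationError("neighbor list length != number of regions")
        for i, vs in enumerate(nb):
            for j in vs:
                if j == i:
                    raise PanelValidationError(f"self-loop at region {self.region_ids[i]}")
                if not 0 <= j < n:
                    raise PanelValidationError(f"neighbor index {j} out of range")
                if i not in nb[j]:
                    raise PanelValidationError(
                        f"asymmetric adjacency: {i}->{j} without {j}->{i}"
                    )
        object.__setattr__(self, "neighbors", nb)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def degree(self) -> np.ndarray:
        return np.array([len(v) for v in self.neighbors], dtype=int)

    @property
    def islands(self) -> list:
        return [self.region_ids[i] for i, v in enumerate(self.neighbors) if not v]

    @property
    def edges(self) -> list:
        """Unique undirected edges as (i, j) with i < j."""
        return [(i, j) for i, vs in enumerate(self.neighbors) for j in vs if i < j]

    @property
    def connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components

        ncomp, _ = connected_components(self.to_sparse(), directed=False)
        return ncomp == 1

    def to_sparse(self):
        from scipy.sparse import coo_matrix

        ij = [(i, j) for i, vs in enumerate(self.neighbors) for j in vs]
        n = self.n_regions
        if not ij:
            return coo_matrix((n, n))
        r, c = zip(*ij)
        return coo_matrix((np.ones(len(ij)), (r, c)), shape=(n, n))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - A, the ICAR structure matrix."""
        A = self.to_sparse().toarray()
        return np.diag(A.sum(axis=1)) - A


@dataclass(frozen=True)
class RegionCentroids:
    """Geographic centroid per region, aligned to panel region order."""

    region_ids: list
    latitude: np.ndarray
    longitude: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.latitude, dtype=float)
        lon = np.asarray(self.longitude, dtype=float)
        n = len(self.region_ids)
        if lat.shape != (n,) or lon.shape != (n,):
            raise PanelValidationError("centroid arrays must have one entry per region")
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise PanelValidationError("centroid coordinates outside valid degree ranges")
        object.__setattr__(self, "latitude", lat)
        object.__setattr__(self, "longitude", lon)


_DEFAULT_COLUMNS = {
    "region": "region",
    "year": "year",
    "observed": "observed",
    "population": "population",
}


def read_panel(path, column_map: dict | None = None) -> CountPanel:
    """Read a long-format delimited panel into a validated :class:`CountPanel`.

    Parameters
    ----------
    path : path-like
        CSV file with one row per (region, year) cell.
    column_map : dict, optional
        Maps the canonical names ``region``, ``year``, ``observed``,
        ``population`` to the file's column names.

    Raises
    ------
    PanelValidationError
        On duplicate or missing (region, year) cells, non-integer counts,
        or non-positive populations; the error message names offending cells.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"panel file lacks columns: {missing_cols}")
    df = df.rename(columns={v: k for k, v in cols.items()})

    dup = df.duplicated(subset=["region", "year"], keep=False)
    if dup.any():
        cells = sorted({(r, int(y)) for r, y in df.loc[dup, ["region", "year"]].values})
        raise PanelValidationError(f"duplicate (region, year) cells: {cells}")

    regions = list(dict.fromkeys(df["region"]))  # first-appearance order
    years = sorted(df["year"].astype(int).unique())
    full = {(r, y) for r in regions for y in years}
    have = {(r, int(y)) for r, y in df[["region", "year"]].values}
    gaps = sorted(full - have)
    if gaps:
        raise PanelValidationError(
            "missing (region, year) cells: "
            + ", ".join(f"{r}/{y}" for r, y in gaps)
        )

    obs_vals = df["observed"].to_numpy()
    if not np.allclose(obs_vals, np.round(obs_vals)):
        bad = df.loc[~np.isclose(obs_vals, np.round(obs_vals)), ["region", "year"]]
        raise PanelValidationError(
            f"non-integer observed counts at: {bad.values.tolist()}"
        )

    ridx = {r: i for i, r in enumerate(regions)}
    yidx = {y: j for j, y in enumerate(years)}
    obs = np.zeros((len(regions), len(years)))
    pop = np.zeros_like(obs)
    for r, y, o, p in df[["region", "year", "observed", "population"]].values:
        obs[ridx[r], yidx[int(y)]] = o
        pop[ridx[r], yidx[int(y)]] = p
    return CountPanel(regions, years, obs, pop)


def write_panel(panel: CountPanel, path) -> None:
    """Write a panel in the long format that :func:`read_panel` accepts."""
    panel.to_frame().to_csv(path, index=False)


def build_adjacency(path_or_geojson, panel: CountPanel | None = None,
                    id_property: str = "region") -> AdjacencyGraph:
    """Queen-contiguity adjacency from a GeoJSON FeatureCollection.

    Two regions are neighbours iff their polygons share at least one boundary
    point (edge or corner touch).  If ``panel`` is given, features are aligned
    to its region order and every panel region must have a polygon.
    """
    if isinstance(path_or_geojson, dict):
        gj = path_or_geojson
    else:
        with open(path_or_geojson) as fh:
            gj = json.load(fh)
    feats = gj["features"]
    geoms, labels = [], []
    for f in feats:
        labels.append(f["properties"][id_property])
        geoms.append(_shapely_shape(f["geometry"]))

    if panel is not None:
        missing = [r for r in panel.region_ids if r not in labels]
        if missing:
            raise PanelValidationError(f"panel regions without polygons: {missing}")
        order = [labels.index(r) for r in panel.region_ids]
        labels = [labels[k] for k in order]
        geoms = [geoms[k] for k in order]

    n = len(geoms)
    neighbors = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            # queen rule: any shared point counts (touch or shared boundary)
            if geoms[i].intersects(geoms[j]) and not geoms[i].equals(geoms[j]):
                neighbors[i].add(j)
                neighbors[j].add(i)
    graph = AdjacencyGraph(labels, tuple(tuple(sorted(v)) for v in neighbors))
    if graph.islands:
        logger.warning("island regions with no neighbours: %s", graph.islands)
    return graph


def read_adjacency_list(path, panel: CountPanel | None = None) -> AdjacencyGraph:
    """Read a plain-text adjacency list: one ``region: nb1 nb2 ...`` line each.

    Asymmetric entries are symmetrized (and logged); unknown neighbour labels
    raise.  Region order follows the file, or the panel when given.
    """
    entries = {}
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, rest = line.partition(":")
            name = name.strip()
            order.append(name)
            entries[name] = rest.split()
    if panel is not None:
        missing = [r for r in panel.region_ids if r not in entries]
        if missing:
            raise PanelValidationError(f"panel regions absent from adjacency list: {missing}")
        order = list(panel.region_ids)
    idx = {r: i for i, r in enumerate(order)}
    neighbors = [set() for _ in order]
    for name, nbs in entries.items():
        if name not in idx:
            continue
        for nb in nbs:
            if nb not in idx:
                raise PanelValidationError(
                    f"adjacency list names unknown region {nb!r} (neighbour of {name!r})"
                )
            neighbors[idx[name]].add(idx[nb])
    # symmetrize, logging completions
    for i, vs in enumerate(neighbors):
        for j in list(vs):
            if i not in neighbors[j]:
                logger.info(
                    "symmetrizing adjacency: adding %s -> %s", order[j], order[i]
                )
                neighbors[j].add(i)
    graph = AdjacencyGraph(order, tuple(tuple(sorted(v)) for v in neighbors))
    if graph.islands:
        logger.warning("island regions with no neighbours: %s", graph.islands)
    return graph


def read_centroids(path, panel: CountPanel | None = None) -> RegionCentroids:
    """Read a CSV with columns region, latitude, longitude."""
    df = pd.read_csv(path)
    if panel is not None:
        missing = [r for r in panel.region_ids if r not in set(df["region"])]
        if missing:
            raise PanelValidationError(f"panel regions without centroids: {missing}")
        df = df.set_index("region").loc[list(panel.region_ids)].reset_index()
    return RegionCentroids(
        list(df["region"]), df["latitude"].to_numpy(), df["longitude"].to_numpy()
    )


def write_results_table(records, path, columns: list | None = None) -> None:
    """Write a result set as deterministic delimited text.

    ``records`` may be a DataFrame, a list of dataclasses or a list of dicts.
    Column order follows ``columns`` (or the first record); rows keep input
    order.  Identical input always produces byte-identical output.
    """
    import dataclasses

    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
                rows.append(dataclasses.asdict(rec))
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    if columns:
        df = df.reindex(columns=columns)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
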