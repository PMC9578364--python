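"""Contiguity adjacency from area polygons and river-accessibility indicators.

Coordinates are assumed planar (a projected CRS); all geometry predicates and
distances are delegated to shapely.  Adjacency is rook by default — two areas
are neighbours iff their boundaries share a segment of positive length —
with queen (any shared point) available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

#: The contiguity graph is a plain networkx Graph (symmetric, no self-loops).
AdjacencyGraph = nx.Graph


@dataclass
class GeometrySet:
    """Area polygons keyed by area_id plus river polylines."""

    areas: dict  # area_id -> shapely Polygon/MultiPolygon
    rivers: list = field(default_factory=list)  # LineString/MultiLineString

    def __post_init__(self) -> None:
        ids = list(self.areas)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate area_id in geometry set")
        for aid, geom in self.areas.items():
            if geom.is_empty:
                raise ValueError(f"empty polygon for area {aid!r}")
            if not geom.is_valid:
                raise ValueError(f"invalid (self-intersecting?) polygon for area {aid!r}")

    @property
    def area_ids(self) -> list:
        return list(self.areas)


def build_adjacency(geoms: GeometrySet, contiguity: str = "rook") -> nx.Graph:
    """Contiguity graph over areas.

    rook: edge iff the shared boundary has positive length.
    queen: edge iff the boundaries share at least one point.
    Areas with no neighbours remain as isolated nodes.
    """
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    ids = geoms.area_ids
    polys = [geoms.areas[a] for a in ids]
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    tree = STRtree(polys)
    for i, poly in enumerate(polys):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            inter = poly.boundary.intersection(polys[j].boundary)
            if inter.is_empty:
                continue
            if contiguity == "queen" or inter.length > 0:
                graph.add_edge(ids[i], ids[j])
    return graph


def river_adjacent(geoms: GeometrySet) -> pd.Series:
    """1 iff any river polyline crosses the area or runs along its boundary."""
    if not geoms.rivers:
        raise ValueError("geometry set has no river layer")
    flags = {
        aid: int(any(r.intersects(poly) for r in geoms.rivers))
        for aid, poly in geoms.areas.items()
    }
    return pd.Series(flags, name="river_adjacent")


def centroid_river_distance(geoms: GeometrySet) -> pd.Series:
    """Euclidean distance from each area centroid to the nearest river."""
    if not geoms.rivers:
        raise ValueError("geometry set has no river layer")
    dist = {
        aid: float(min(poly.centroid.distance(r) for r in geoms.rivers))
        for aid, poly in geoms.areas.items()
    }
    return pd.Series(dist, name="river_distance")


# ---------------------------------------------------------------------------
# GeoJSON I/O (FeatureCollections; areas carry an `area_id` property)

def read_geometry_set(areas_path, rivers_path=None) -> GeometrySet:
    with open(areas_path) as fh:
        fc = json.load(fh)
    areas = {}
    for feat in fc["features"]:
        aid = feat["properties"]["area_id"]
        if aid in areas:
            raise ValueError(f"duplicate area_id {aid!r} in {areas_path}")
        areas[aid] = shape(feat["geometry"])
    rivers = []
    if rivers_path is not None:
        with open(rivers_path) as fh:
            rc = json.load(fh)
        rivers = [shape(feat["geometry"]) for feat in rc["features"]]
    return GeometrySet(areas=areas, rivers=rivers)


def write_geometry_set(geoms: GeometrySet, areas_path, rivers_path=None) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"area_id": aid},
                "geometry": mapping(poly),
            }
            for aid, poly in geoms.areas.items()
        ],
    }
    with open(areas_path, "w") as fh:
        json.dump(fc, fh)
    if rivers_path is not None:
        rc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {}, "geometry": mapping(r)}
                for r in geoms.rivers
            ],
        }
        with open(rivers_path, "w") as fh:
            json.dump(rc, fh)


def write_edge_list(graph: nx.Graph, path) -> None:
    pd.DataFrame(sorted(graph.edges()), columns=["area_i", "area_j"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Precomputed sampler-facing structure

class SpatialStructure:
    """Adjacency recast as arrays for the ICAR density and the sampler.

    Nodes are indexed by position in ``area_ids``.  A greedy colouring
    partitions non-isolated nodes into classes with no internal edges, so
    single-site Metropolis updates within a class are conditionally
    independent and can be evaluated vectorised.
    """

    def __init__(self, graph: nx.Graph, area_ids) -> None:
        area_ids = list(area_ids)
        if set(graph.nodes) != set(area_ids):
            raise ValueError("graph node set does not match area set")
        self.area_ids = area_ids
        self.n = len(area_ids)
        index = {a: k for k, a in enumerate(area_ids)}
        rows, cols = [], []
        for a, b in graph.edges():
            i, j = index[a], index[b]
            rows.extend((i, j))
            cols.extend((j, i))
        import scipy.sparse as sp

        data = np.ones(len(rows))
        self.W = sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
        self.degree = np.asarray(self.W.sum(axis=1)).ravel()
        self.edges_i = np.array([index[a] for a, b in graph.edges()], dtype=int)
        self.edges_j = np.array([index[b] for a, b in graph.edges()], dtype=int)
        comps = [np.array(sorted(index[a] for a in c), dtype=int)
                 for c in nx.connected_components(graph)]
        self.components = comps
        self.isolated = np.array([len(c) == 1 for c in comps])
        self.isolate_mask = np.zeros(self.n, dtype=bool)
        for c in comps:
            if len(c) == 1:
                self.isolate_mask[c[0]] = True
        self.rank = self.n - len(comps)
        colour = nx.greedy_color(graph, strategy="largest_first")
        classes: dict[int, list[int]] = {}
        for a, c in colour.items():
            k = index[a]
            if not self.isolate_mask[k]:
                classes.setdefault(c, []).append(k)
        self.colour_classes = [np.array(sorted(v), dtype=int) for _, v in sorted(classes.items())]

    def pairwise_ss(self, u: np.ndarray) -> float:
        """Sum over edges of (u_i - u_j)^2."""
        if self.edges_i.size == 0:
            return 0.0
        d = u[self.edges_i] - u[self.edges_j]
        return float(d @ d)

    def center(self, u: np.ndarray) -> tuple[np.ndarray, float]:
        """Subtract per-component means (components with >= 2 nodes).

        Returns the centred vector and the population-unweighted overall mean
        removed, which the sampler transfers to the intercept.
        """
        u = u.copy()
        shift = 0.0
        for c in self.components:
            if len(c) < 2:
                continue
            m = u[c].mean()
            u[c] -= m
            shift += m * len(c)
        return u, shift / self.n
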