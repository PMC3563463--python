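"""Nuclear architecture features from spatial graphs on centroids.

Four families quantify how nuclei are arranged in a tile, 48 features in
total:

* Voronoi tessellation (12): each centroid owns the polygon of pixels
  nearer to it than to any other centroid; polygon area, chord lengths and
  perimeter are pooled and summarized.
* Delaunay triangulation (8): triangle areas and perimeters of the dual
  triangulation.
* Minimum spanning tree (4): branch lengths of the shortest tree through
  all centroids (computed on the Delaunay edge set, of which the MST is a
  subgraph).
* Nuclear density (24): neighbour counts within radii of 10-50 px and the
  mean distance to the nearest 3, 5 and 7 neighbours.

Each measurement pool is summarized by its mean B, population standard
deviation A, the disorder statistic ``1 - 1/(1 + A/B)`` and (for the graph
families) the min/max ratio.

Unbounded Voronoi cells are clipped to the image rectangle by reflecting
the centroid set across each of the four rectangle edges before the
tessellation is built: every original centroid then owns a finite cell and
cell areas partition the rectangle exactly.  A polygon's "chord lengths"
are all pairwise distances between its vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree

from .errors import DegenerateGeometryError, DegenerateInputError

__all__ = [
    "SummaryStats",
    "SpatialGraph",
    "VoronoiTessellation",
    "summarize",
    "voronoi_features",
    "delaunay_features",
    "mst_features",
    "density_features",
    "architecture_vector",
    "ARCHITECTURE_FEATURE_NAMES",
    "DENSITY_RADII",
    "DENSITY_NEIGHBOR_COUNTS",
]

DENSITY_RADII = (10.0, 20.0, 30.0, 40.0, 50.0)
DENSITY_NEIGHBOR_COUNTS = (3, 5, 7)

_STAT4 = ("mean", "std", "disorder", "minmax")
_STAT3 = ("mean", "std", "disorder")


def _names() -> list[str]:
    names = []
    for pool in ("area", "chord", "perimeter"):
        names += [f"voronoi_{pool}_{s}" for s in _STAT4]
    for pool in ("area", "perimeter"):
        names += [f"delaunay_{pool}_{s}" for s in _STAT4]
    names += [f"mst_branch_{s}" for s in _STAT4]
    for r in DENSITY_RADII:
        names += [f"density_neighbors_r{int(r)}_{s}" for s in _STAT3]
    for k in DENSITY_NEIGHBOR_COUNTS:
        names += [f"density_knn{k}_dist_{s}" for s in _STAT3]
    return names


ARCHITECTURE_FEATURE_NAMES: tuple[str, ...] = tuple(_names())
assert len(ARCHITECTURE_FEATURE_NAMES) == 48


@dataclass(frozen=True)
class SummaryStats:
    """Pool summary: mean B, population std A, disorder, min/max ratio."""

    mean: float
    std: float
    disorder: float
    min_max_ratio: float

    def four(self) -> list[float]:
        return [self.mean, self.std, self.disorder, self.min_max_ratio]

    def three(self) -> list[float]:
        return [self.mean, self.std, self.disorder]


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected weighted graph on centroids; weights are edge lengths."""

    vertices: np.ndarray  # (n, 2)
    edges: np.ndarray  # (m, 2) int, each pair stored once, i < j
    weights: np.ndarray  # (m,) > 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.vertices)))
        g.add_weighted_edges_from(
            (int(i), int(j), float(w)) for (i, j), w in zip(self.edges, self.weights)
        )
        return g

    @property
    def total_weight(self) -> float:
        return float(np.sum(self.weights))


@dataclass(frozen=True)
class VoronoiTessellation:
    """Clipped Voronoi cells: one closed convex polygon per centroid."""

    polygons: list[np.ndarray]  # each (k, 2), counter-clockwise vertex ring
    owners: np.ndarray  # (m,) centroid index per polygon
    bounds: tuple[float, float, float, float]  # (rmin, cmin, rmax, cmax)

    @property
    def areas(self) -> np.ndarray:
        return np.array([_polygon_area(p) for p in self.polygons])


def summarize(values) -> SummaryStats:
    """Summary statistics of a pool of non-negative measurements.

    disorder = ``1 - 1/(1 + A/B)`` (0 when either the mean B or the std A
    vanishes); min/max ratio is 1 for an all-zero pool.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateInputError("cannot summarize an empty pool")
    b = float(np.mean(v))
    a = float(np.std(v))  # population convention
    disorder = 0.0 if (b == 0.0 or a == 0.0) else 1.0 - 1.0 / (1.0 + a / b)
    vmax = float(np.max(v))
    ratio = 1.0 if vmax == 0.0 else float(np.min(v)) / vmax
    return SummaryStats(mean=b, std=a, disorder=disorder, min_max_ratio=ratio)


# ---------------------------------------------------------------------------
# geometry helpers


def _polygon_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_perimeter(ring: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)))


def _polygon_chords(ring: np.ndarray) -> np.ndarray:
    diffs = ring[:, None, :] - ring[None, :, :]
    d = np.linalg.norm(diffs, axis=-1)
    iu = np.triu_indices(len(ring), k=1)
    return d[iu]


def _dedupe(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    uniq, idx = np.unique(np.round(pts, 9), axis=0, return_index=True)
    if len(uniq) < len(pts):
        warnings.warn(f"removed {len(pts) - len(uniq)} duplicate centroids")
        pts = pts[np.sort(idx)]
    return pts


def _check_geometry(points: np.ndarray, minimum: int) -> None:
    if len(points) < minimum:
        raise DegenerateGeometryError(
            f"need at least {minimum} centroids, got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateGeometryError("centroids are collinear")


# ---------------------------------------------------------------------------
# Voronoi


def voronoi_features(
    points: np.ndarray, bounds: tuple[float, float]
) -> tuple[VoronoiTessellation, np.ndarray]:
    """Clipped Voronoi tessellation and its 12 summary features.

    ``bounds`` is the image extent ``(height, width)``; cells are clipped
    to the rectangle [0, height] x [0, width] via edge reflection.
    """
    pts = _dedupe(points)
    _check_geometry(pts, 4)
    h, w = float(bounds[0]), float(bounds[1])

    reflections = [
        pts * np.array([-1.0, 1.0]),                         # across r = 0
        pts * np.array([-1.0, 1.0]) + np.array([2 * h, 0]),  # across r = h
        pts * np.array([1.0, -1.0]),                         # across c = 0
        pts * np.array([1.0, -1.0]) + np.array([0, 2 * w]),  # across c = w
    ]
    augmented = np.vstack([pts] + reflections)
    vor = Voronoi(augmented)

    polygons: list[np.ndarray] = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # cannot happen after reflection
            raise DegenerateGeometryError("unbounded cell after reflection")
        ring = vor.vertices[region]
        # convex cell: order vertices counter-clockwise around the centroid
        center = ring.mean(axis=0)
        ang = np.arctan2(ring[:, 0] - center[0], ring[:, 1] - center[1])
        polygons.append(ring[np.argsort(ang)])

    tess = VoronoiTessellation(
        polygons=polygons, owners=np.arange(len(pts)), bounds=(0.0, 0.0, h, w)
    )
    areas = [_polygon_area(p) for p in polygons]
    chords = np.concatenate([_polygon_chords(p) for p in polygons])
    perims = [_polygon_perimeter(p) for p in polygons]
    feats = np.array(
        summarize(areas).four() + summarize(chords).four() + summarize(perims).four()
    )
    return tess, feats


# ---------------------------------------------------------------------------
# Delaunay


def _triangle_metrics(tri_pts: np.ndarray) -> tuple[float, float]:
    a = np.linalg.norm(tri_pts[1] - tri_pts[0])
    b = np.linalg.norm(tri_pts[2] - tri_pts[1])
    c = np.linalg.norm(tri_pts[0] - tri_pts[2])
    area = 0.5 * abs(
        (tri_pts[1, 0] - tri_pts[0, 0]) * (tri_pts[2, 1] - tri_pts[0, 1])
        - (tri_pts[2, 0] - tri_pts[0, 0]) * (tri_pts[1, 1] - tri_pts[0, 1])
    )
    return area, a + b + c


def delaunay_features(points: np.ndarray) -> tuple[SpatialGraph, np.ndarray]:
    """Delaunay triangulation graph and its 8 summary features."""
    pts = _dedupe(points)
    _check_geometry(pts, 3)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # pragma: no cover - guarded above
        raise DegenerateGeometryError(str(exc)) from exc

    areas, perims = [], []
    edge_set: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        area, perim = _triangle_metrics(pts[simplex])
        areas.append(area)
        perims.append(perim)
        for u, v in ((0, 1), (1, 2), (0, 2)):
            i, j = int(simplex[u]), int(simplex[v])
            edge_set.add((min(i, j), max(i, j)))

    edges = np.array(sorted(edge_set), dtype=int)
    weights = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    graph = SpatialGraph(vertices=pts, edges=edges, weights=weights)
    feats = np.array(summarize(areas).four() + summarize(perims).four())
    return graph, feats


# ---------------------------------------------------------------------------
# MST


def mst_features(graph: SpatialGraph) -> tuple[SpatialGraph, np.ndarray]:
    """Minimum spanning tree of the (Delaunay) graph and its 4 features."""
    g = graph.to_networkx()
    if len(g) == 0 or not nx.is_connected(g):
        raise DegenerateGeometryError("graph must be connected for an MST")
    mst = nx.minimum_spanning_tree(g, weight="weight")
    edges = np.array(sorted((min(u, v), max(u, v)) for u, v in mst.edges), dtype=int)
    weights = np.array(
        [mst[u][v]["weight"] for u, v in edges], dtype=float
    )
    tree = SpatialGraph(vertices=graph.vertices, edges=edges, weights=weights)
    return tree, np.array(summarize(weights).four())


# ---------------------------------------------------------------------------
# density


def neighbor_counts(points: np.ndarray, radius: float) -> np.ndarray:
    """Number of other centroids within ``radius`` (inclusive) of each one."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    tree = cKDTree(pts)
    # tiny slack makes the <= radius inclusion robust to float round-off
    return np.array(
        [len(tree.query_ball_point(p, radius + 1e-9)) - 1 for p in pts]
    )


def knn_mean_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Mean Euclidean distance from each centroid to its k nearest others."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)
    return dists[:, 1:].mean(axis=1)


def density_features(points: np.ndarray) -> np.ndarray:
    """24 nuclear-density features (15 count-in-radius + 9 k-NN distance)."""
    pts = _dedupe(points)
    if len(pts) < max(DENSITY_NEIGHBOR_COUNTS) + 1:
        raise DegenerateInputError(
            f"need at least {max(DENSITY_NEIGHBOR_COUNTS) + 1} centroids "
            f"for density features, got {len(pts)}"
        )
    feats: list[float] = []
    for radius in DENSITY_RADII:
        feats += summarize(neighbor_counts(pts, radius)).three()
    for k in DENSITY_NEIGHBOR_COUNTS:
        feats += summarize(knn_mean_distances(pts, k)).three()
    return np.array(feats)


# ---------------------------------------------------------------------------
# assembly


def architecture_vector(points: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """All 48 architecture features in the fixed documented order."""
    pts = _dedupe(points)
    _, vor = voronoi_features(pts, bounds)
    delaunay_graph, del_feats = delaunay_features(pts)
    _, mst_feats = mst_features(delaunay_graph)
    dens = density_features(pts)
    vec = np.concatenate([vor, del_feats, mst_feats, dens])
    assert vec.shape == (48,)
    return vec
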