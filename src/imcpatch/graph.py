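"""Spatial cell–cell graphs: pruned Delaunay and fixed-radius adjacency.

Interaction testing uses the Delaunay triangulation of cell centroids with
edges pruned to ≤ 20 µm; neighbourhood composition profiles use the plain
20 µm radius graph. Distances are Euclidean between centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

DEFAULT_CUTOFF_UM = 20.0


@dataclass
class SpatialGraph:
    """Undirected cell adjacency for one image.

    node_ids: cell ids (order defines node index); edges: (m, 2) int array
    of node indices with a < b; dist_um: (m,) edge lengths.
    """

    node_ids: np.ndarray
    edges: np.ndarray
    dist_um: np.ndarray
    method: str
    cutoff_um: float
    image_id: str = "image"
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_ids(self) -> np.ndarray:
        """Edges expressed as (cell_id_a, cell_id_b) pairs."""
        if not self.n_edges:
            return np.empty((0, 2), dtype=self.node_ids.dtype)
        return self.node_ids[self.edges]

    def subgraph(self, node_mask: np.ndarray) -> "SpatialGraph":
        """Induced subgraph on the nodes where node_mask is True."""
        idx = np.flatnonzero(node_mask)
        remap = -np.ones(self.n_nodes, dtype=int)
        remap[idx] = np.arange(idx.size)
        if self.n_edges:
            keep = node_mask[self.edges[:, 0]] & node_mask[self.edges[:, 1]]
            edges = remap[self.edges[keep]]
            dist = self.dist_um[keep]
        else:
            edges = np.empty((0, 2), dtype=int)
            dist = np.empty(0)
        return SpatialGraph(
            node_ids=self.node_ids[idx],
            edges=edges,
            dist_um=dist,
            method=self.method,
            cutoff_um=self.cutoff_um,
            image_id=self.image_id,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        ids = self.edge_ids()
        return pd.DataFrame(
            {
                "image_id": self.image_id,
                "cell_a": ids[:, 0],
                "cell_b": ids[:, 1],
                "dist_um": self.dist_um,
            }
        )


def _dedupe(edges: np.ndarray) -> np.ndarray:
    if not len(edges):
        return np.empty((0, 2), dtype=int)
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def _points(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    return pts, ids


def _image_id(cells: pd.DataFrame, image_id: str | None) -> str:
    if image_id is not None:
        return image_id
    if "image_id" in cells.columns and len(cells):
        vals = pd.unique(cells["image_id"])
        if len(vals) > 1:
            raise ValueError("cells from multiple images; build one graph per image")
        return str(vals[0])
    return "image"


def build_radius_graph(
    cells: pd.DataFrame,
    radius: float = DEFAULT_CUTOFF_UM,
    image_id: str | None = None,
) -> SpatialGraph:
    """Edge iff centroid distance ≤ radius (all pairs, KD-tree backed).

    image_id defaults to the table's (unique) image_id column value."""
    image_id = _image_id(cells, image_id)
    pts, ids = _points(cells)
    if len(pts) and radius > 0:
        pairs = cKDTree(pts).query_pairs(radius, output_type="ndarray")
        edges = _dedupe(pairs)
    else:
        edges = np.empty((0, 2), dtype=int)
    dist = (
        np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
        if len(edges)
        else np.empty(0)
    )
    return SpatialGraph(ids, edges, dist, "radius", radius, image_id)


def build_delaunay_graph(
    cells: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF_UM,
    image_id: str | None = None,
) -> SpatialGraph:
    """Delaunay triangulation of centroids, pruned to edges ≤ cutoff.

    Fewer than 3 cells, collinear points, or other triangulation
    degeneracies fall back to the radius graph with a warning. Duplicate
    centroids are jittered by < 0.01 µm before triangulating.
    """
    image_id = _image_id(cells, image_id)
    pts, ids = _points(cells)
    if len(pts) < 3:
        warnings.warn(
            "fewer than 3 cells: falling back to radius graph", stacklevel=2
        )
        g = build_radius_graph(cells, cutoff, image_id)
        return SpatialGraph(g.node_ids, g.edges, g.dist_um, "radius_fallback", cutoff, image_id)

    work = pts
    if len(np.unique(pts, axis=0)) < len(pts):
        warnings.warn("duplicate centroids jittered by < 0.01 µm", stacklevel=2)
        rng = np.random.default_rng(0)
        work = pts + rng.uniform(-0.005, 0.005, pts.shape)
    try:
        tri = Delaunay(work)
    except QhullError:
        warnings.warn(
            "degenerate point set (collinear?): falling back to radius graph",
            stacklevel=2,
        )
        g = build_radius_graph(cells, cutoff, image_id)
        return SpatialGraph(g.node_ids, g.edges, g.dist_um, "radius_fallback", cutoff, image_id)

    simp = tri.simplices
    edges = _dedupe(
        np.concatenate([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]])
    )
    dist = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = dist <= cutoff
    return SpatialGraph(
        ids, edges[keep], dist[keep], "delaunay_pruned", cutoff, image_id
    )


def neighbour_type_counts(
    graph: SpatialGraph, labels: pd.Series | dict, categories: list[str] | None = None
):
    """Per-cell counts of each population among its graph neighbours.

    labels maps cell id -> population. Returns (counts DataFrame indexed by
    cell id with one column per category, category list). Row sums equal
    node degrees.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    lab = labels.reindex(graph.node_ids)
    if lab.isna().any():
        missing = graph.node_ids[lab.isna().to_numpy()].tolist()
        raise ValueError(f"unlabelled nodes: {missing[:10]}")
    if categories is None:
        categories = sorted(pd.unique(lab))
    cat_index = {c: i for i, c in enumerate(categories)}
    codes = lab.map(cat_index).to_numpy()
    if np.isnan(codes.astype(float)).any():
        raise ValueError("labels outside the provided category list")
    codes = codes.astype(int)

    counts = np.zeros((graph.n_nodes, len(categories)), dtype=int)
    if graph.n_edges:
        a, b = graph.edges[:, 0], graph.edges[:, 1]
        np.add.at(counts, (a, codes[b]), 1)
        np.add.at(counts, (b, codes[a]), 1)
    out = pd.DataFrame(counts, index=pd.Index(graph.node_ids, name="cell_id"), columns=categories)
    return out, categories


def write_graph_csv(graph: SpatialGraph, path) -> None:
    """Edge-list CSV with a commented metadata header block."""
    with open(path, "w") as fh:
        fh.write(f"# method={graph.method}\n# cutoff_um={graph.cutoff_um}\n")
        fh.write(f"# image_id={graph.image_id}\n")
        graph.to_frame().to_csv(fh, index=False)
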