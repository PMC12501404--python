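"""B-cell patch detection on the spatial interaction graph.

A patch core is a connected component of ≥ 10 interacting B cells (all
B-lineage subpopulations pooled) on the Delaunay-based graph. The patch
region is the convex hull of the core centroids buffered outward by 1 µm
(the 1 µm/pixel expansion); every cell whose centroid falls inside the
region is an expanded member. Patch area is the buffered-hull area; patches
above 12,000 µm² are classified as large follicles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import MultiPoint, Point

from .graph import SpatialGraph

MIN_CORE_SIZE = 10
LARGE_AREA_THRESHOLD_UM2 = 12_000.0
DEFAULT_EXPANSION_UM = 1.0


@dataclass
class Patch:
    """A detected B-cell aggregate."""

    patch_id: int
    image_id: str
    core_cell_ids: np.ndarray
    expanded_cell_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    area_um2: float = np.nan
    size_class: str = ""
    segment: str = ""

    @property
    def n_core(self) -> int:
        return len(self.core_cell_ids)

    @property
    def n_expanded(self) -> int:
        return len(self.expanded_cell_ids)


def detect_patches(
    cells: pd.DataFrame,
    graph: SpatialGraph,
    b_populations: tuple[str, ...] = ("B",),
    min_size: int = MIN_CORE_SIZE,
    label_col: str = "population",
) -> list[Patch]:
    """Connected components of the B–B subgraph with ≥ min_size cells.

    Patch ids are deterministic: ordered by image, then by the smallest core
    cell id. No B cells yields an empty list.
    """
    labels = cells.set_index("cell_id")[label_col].reindex(graph.node_ids)
    is_b = labels.isin(b_populations).to_numpy()
    sub = graph.subgraph(is_b)
    if sub.n_nodes == 0:
        return []
    adj = coo_matrix(
        (np.ones(sub.n_edges), (sub.edges[:, 0], sub.edges[:, 1])),
        shape=(sub.n_nodes, sub.n_nodes),
    )
    n_comp, comp = connected_components(adj, directed=False)
    patches = []
    for c in range(n_comp):
        members = sub.node_ids[comp == c]
        if len(members) >= min_size:
            patches.append((int(np.min(members)), np.sort(members)))
    patches.sort(key=lambda t: t[0])
    return [
        Patch(patch_id=i, image_id=graph.image_id, core_cell_ids=m)
        for i, (_, m) in enumerate(patches)
    ]


def patch_region(patch: Patch, cells: pd.DataFrame, distance: float = DEFAULT_EXPANSION_UM):
    """Shapely polygon for a patch: convex hull of core centroids buffered
    outward by `distance` µm. Cores with < 3 cells fall back to the union
    of buffered points."""
    pts = (
        cells.set_index("cell_id")
        .loc[patch.core_cell_ids, ["x_um", "y_um"]]
        .to_numpy(dtype=float)
    )
    mp = MultiPoint([tuple(p) for p in pts])
    if len(pts) >= 3:
        region = mp.convex_hull
        if region.area == 0:  # collinear core
            region = mp.buffer(max(distance, 1e-9))
            return region
        if distance > 0:
            region = region.buffer(distance, quad_segs=32)
        return region
    return mp.buffer(max(distance, 1e-9), quad_segs=32)


def expand_patch(
    patch: Patch,
    cells: pd.DataFrame,
    distance: float = DEFAULT_EXPANSION_UM,
    image_col: str = "image_id",
) -> Patch:
    """Expanded membership: every cell (any population) of the patch's image
    whose centroid lies inside the buffered patch region; core cells are
    always included. Membership is monotone in the buffer distance."""
    region = patch_region(patch, cells, distance)
    img_cells = (
        cells[cells[image_col] == patch.image_id] if image_col in cells.columns else cells
    )
    xy = img_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    inside = np.fromiter(
        (region.covers(Point(x, y)) for x, y in xy), dtype=bool, count=len(xy)
    )
    expanded = set(img_cells.loc[inside, "cell_id"].tolist()) | set(
        patch.core_cell_ids.tolist()
    )
    patch.expanded_cell_ids = np.array(sorted(expanded))
    return patch


def patch_area_and_class(
    patch: Patch,
    cells: pd.DataFrame,
    distance: float = DEFAULT_EXPANSION_UM,
    large_threshold: float = LARGE_AREA_THRESHOLD_UM2,
) -> Patch:
    """Area of the buffered hull polygon (µm²); class is "large" only when
    the area strictly exceeds the threshold."""
    region = patch_region(patch, cells, distance)
    patch.area_um2 = float(region.area)
    patch.size_class = "large" if patch.area_um2 > large_threshold else "small"
    return patch


def locate_patch(patch: Patch, cells: pd.DataFrame) -> Patch:
    """Containing tissue segment = majority vote over core members."""
    seg = (
        cells.set_index("cell_id")
        .loc[patch.core_cell_ids, "segment"]
        .mode(dropna=False)
    )
    patch.segment = str(seg.iloc[0])
    return patch


def patch_composition(
    patch: Patch,
    cells: pd.DataFrame,
    neighbourhood_labels: pd.Series | None = None,
    label_col: str = "population",
) -> pd.DataFrame:
    """Long-format frequencies of cell types (and, when a neighbourhood
    label series is given, neighbourhood classes) over expanded members."""
    members = cells.set_index("cell_id").loc[patch.expanded_cell_ids]
    rows = []
    freq = members[label_col].value_counts(normalize=True)
    for name, f in freq.items():
        rows.append(
            {"patch_id": patch.patch_id, "image_id": patch.image_id,
             "kind": "cell_type", "name": name, "frequency": float(f)}
        )
    if neighbourhood_labels is not None:
        nb = neighbourhood_labels.reindex(patch.expanded_cell_ids).dropna()
        for name, f in nb.value_counts(normalize=True).items():
            rows.append(
                {"patch_id": patch.patch_id, "image_id": patch.image_id,
                 "kind": "neighbourhood", "name": name, "frequency": float(f)}
            )
    return pd.DataFrame(rows)


def analyse_patches(
    cells: pd.DataFrame,
    graph: SpatialGraph,
    b_populations: tuple[str, ...] = ("B",),
    min_size: int = MIN_CORE_SIZE,
    distance: float = DEFAULT_EXPANSION_UM,
    large_threshold: float = LARGE_AREA_THRESHOLD_UM2,
    neighbourhood_labels: pd.Series | None = None,
):
    """Detect, expand, measure, classify and profile all patches of one
    image. Returns (patch table, composition table, list of Patch)."""
    patches = detect_patches(cells, graph, b_populations, min_size)
    comp_frames = []
    for p in patches:
        expand_patch(p, cells, distance)
        patch_area_and_class(p, cells, distance, large_threshold)
        if "segment" in cells.columns:
            locate_patch(p, cells)
        comp_frames.append(patch_composition(p, cells, neighbourhood_labels))
    table = pd.DataFrame(
        [
            {
                "patch_id": p.patch_id,
                "image_id": p.image_id,
                "n_core": p.n_core,
                "n_expanded": p.n_expanded,
                "area_um2": p.area_um2,
                "size_class": p.size_class,
                "segment": p.segment,
            }
            for p in patches
        ],
        columns=["patch_id", "image_id", "n_core", "n_expanded", "area_um2",
                 "size_class", "segment"],
    )
    comp = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(columns=["patch_id", "image_id", "kind", "name", "frequency"])
    )
    return table, comp, patches
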