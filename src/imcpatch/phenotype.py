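"""Cell phenotyping: hierarchical gating, probability-feature augmentation,
unsupervised subclustering with an annotation merge map, and population
frequency/density tables.

Gating is two-level: CD45 vs E-Cadherin separates immune from epithelial
cells, then CD3 vs CD20 splits immune cells into T, B and other immune.
Hard T-cell splits (CD4 vs CD8 in densely packed regions) are helped by a
random-forest classifier whose class probabilities are appended to the
feature table before subclustering, mirroring pixel-classifier probability
channels. Within each gate, k-means clusters are merged into annotated
populations via a user-supplied (total) merge map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from skimage.filters import threshold_otsu

# Controlled vocabulary for annotated populations.
POPULATIONS = (
    "B", "CD4_T_naive", "CD4_T_mature", "CD8_T_naive", "CD8_T_mature",
    "CD8_T_CD38", "Treg", "monocyte", "macrophage", "epithelial", "other",
)

GATE_LABELS = ("T cell", "B cell", "other immune", "epithelial", "other")

PROB_CLASSES = ("CD4_T", "CD8_T", "non_T", "epithelial")


@dataclass
class GateSpec:
    """Two-level gate tree with per-marker threshold rules.

    thresholds: marker -> fixed threshold on the transformed (arcsinh)
    scale; markers missing from the dict fall back to a per-image Otsu
    threshold.
    """

    cd45: str = "CD45"
    ecadherin: str = "ECadherin"
    cd3: str = "CD3"
    cd20: str = "CD20"
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def markers(self) -> list[str]:
        return [self.cd45, self.ecadherin, self.cd3, self.cd20]


def _resolve_threshold(values: np.ndarray, marker: str, spec: GateSpec) -> float:
    if marker in spec.thresholds:
        t = float(spec.thresholds[marker])
        if not np.isfinite(t):
            raise ValueError(f"non-finite threshold for {marker}")
        return t
    if np.ptp(values) == 0:
        return float(values[0]) + 1.0  # constant channel: nothing gates positive
    return float(threshold_otsu(values))


def gate_cells(
    cells: pd.DataFrame, gates: GateSpec | None = None, image_col: str = "image_id"
) -> pd.DataFrame:
    """Assign each cell a major-class gate label.

    Level 1: CD45+ -> immune, else E-Cadherin+ -> epithelial, else other.
    Level 2 (immune): CD3+/CD20- -> T cell, CD20+/CD3- -> B cell, both
    positive resolved by the larger margin over threshold, neither -> other
    immune. Thresholds used are recorded in the frame's attrs.
    """
    gates = gates or GateSpec()
    for m in gates.markers:
        if f"tr_{m}" not in cells.columns:
            raise ValueError(f"gate marker {m!r} absent from the cell table")
    cells = cells.copy()
    out = np.empty(len(cells), dtype=object)
    thresholds_used: dict[tuple, dict] = {}

    groups = (
        cells.groupby(image_col, sort=False)
        if image_col in cells.columns
        else [("all", cells)]
    )
    for img, df in groups:
        idx = df.index
        vals = {m: df[f"tr_{m}"].to_numpy(dtype=float) for m in gates.markers}
        thr = {m: _resolve_threshold(vals[m], m, gates) for m in gates.markers}
        thresholds_used[img] = thr
        cd45 = vals[gates.cd45] > thr[gates.cd45]
        ecad = vals[gates.ecadherin] > thr[gates.ecadherin]
        cd3 = vals[gates.cd3] - thr[gates.cd3]
        cd20 = vals[gates.cd20] - thr[gates.cd20]
        lab = np.where(cd45, "other immune", np.where(ecad, "epithelial", "other"))
        t_pos, b_pos = cd3 > 0, cd20 > 0
        lab = np.where(cd45 & t_pos & (~b_pos | (cd3 >= cd20)), "T cell", lab)
        lab = np.where(cd45 & b_pos & (~t_pos | (cd20 > cd3)), "B cell", lab)
        out[cells.index.get_indexer(idx)] = lab
    cells["gate"] = out
    cells.attrs["gate_thresholds"] = thresholds_used
    return cells


# ---------------------------------------------------------------------------
# probability features


def train_probability_classifier(
    cells: pd.DataFrame,
    label_col: str = "prob_label",
    feature_cols: list[str] | None = None,
    min_per_class: int = 10,
    n_estimators: int = 200,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a random forest on the labelled subset of the cell table.

    The label column holds one of PROB_CLASSES for training cells and NaN
    elsewhere; every class must appear at least min_per_class times.
    """
    if feature_cols is None:
        feature_cols = [c for c in cells.columns if c.startswith("tr_")]
    labelled = cells.dropna(subset=[label_col])
    counts = labelled[label_col].value_counts()
    missing = [c for c in PROB_CLASSES if counts.get(c, 0) < min_per_class]
    if missing:
        raise ValueError(
            f"classes with fewer than {min_per_class} training cells: {missing}"
        )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(labelled[feature_cols].to_numpy(), labelled[label_col].to_numpy())
    clf.feature_cols_ = list(feature_cols)
    return clf


def apply_probability_classifier(
    cells: pd.DataFrame, clf: RandomForestClassifier
) -> pd.DataFrame:
    """Append per-cell class probabilities as prob_<class> feature columns."""
    cells = cells.copy()
    proba = clf.predict_proba(cells[clf.feature_cols_].to_numpy())
    for i, cls in enumerate(clf.classes_):
        cells[f"prob_{cls}"] = proba[:, i]
    return cells


def neighbour_context_features(
    cells: pd.DataFrame, graph, feature_cols: list[str] | None = None
) -> pd.DataFrame:
    """Mean feature values over each cell's spatial neighbours (context
    features mimicking pixel-level surroundings); zero-degree cells reuse
    their own values. Columns are suffixed `_nb`."""
    if feature_cols is None:
        feature_cols = [c for c in cells.columns if c.startswith("tr_")]
    cells = cells.set_index("cell_id", drop=False) if cells.index.name != "cell_id" else cells.copy()
    X = cells.loc[graph.node_ids, feature_cols].to_numpy(dtype=float)
    sums = np.zeros_like(X)
    deg = np.zeros(len(X))
    if graph.n_edges:
        a, b = graph.edges[:, 0], graph.edges[:, 1]
        np.add.at(sums, a, X[b])
        np.add.at(sums, b, X[a])
        np.add.at(deg, a, 1)
        np.add.at(deg, b, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(deg[:, None] > 0, sums / np.maximum(deg[:, None], 1), X)
    nb = pd.DataFrame(
        means, index=pd.Index(graph.node_ids, name="cell_id"),
        columns=[c + "_nb" for c in feature_cols],
    )
    out = cells.join(nb, on="cell_id")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# subclustering


def subcluster(
    cells: pd.DataFrame,
    branch_features: dict[str, list[str]],
    k: dict[str, int],
    seed: int = 0,
    gate_col: str = "gate",
) -> pd.DataFrame:
    """k-means within each gate branch on branch-specific features.

    Adds a `cluster` column "<branch>:<id>". Branches absent from
    branch_features get a single cluster 0.
    """
    cells = cells.copy()
    cells["cluster"] = ""
    ss = np.random.SeedSequence(seed)
    branches = sorted(pd.unique(cells[gate_col]))
    children = ss.spawn(len(branches))
    for child, branch in zip(children, branches):
        mask = (cells[gate_col] == branch).to_numpy()
        n = int(mask.sum())
        feats = branch_features.get(branch)
        kb = k.get(branch, 1)
        if feats is None or kb <= 1 or n == 0:
            cells.loc[mask, "cluster"] = f"{branch}:0"
            continue
        if kb > n:
            raise ValueError(f"k={kb} exceeds {n} cells in branch {branch!r}")
        X = cells.loc[mask, feats].to_numpy(dtype=float)
        if np.allclose(X, X[0]):
            cells.loc[mask, "cluster"] = f"{branch}:0"
            continue
        km = KMeans(
            n_clusters=kb, n_init=10, random_state=int(child.generate_state(1)[0] % 2**31)
        ).fit(X)
        cells.loc[mask, "cluster"] = [f"{branch}:{c}" for c in km.labels_]
    return cells


def apply_merge_map(
    cells: pd.DataFrame, merge_map: dict[str, str], cluster_col: str = "cluster"
) -> pd.DataFrame:
    """Rename clusters to annotated populations; the map must cover every
    cluster (totality) and use only the controlled vocabulary."""
    present = set(pd.unique(cells[cluster_col]))
    unmapped = present - set(merge_map)
    if unmapped:
        raise ValueError(f"merge map misses clusters: {sorted(unmapped)}")
    bad = set(merge_map.values()) - set(POPULATIONS)
    if bad:
        raise ValueError(f"populations outside the controlled vocabulary: {sorted(bad)}")
    cells = cells.copy()
    cells["population"] = cells[cluster_col].map(merge_map)
    return cells


def suggest_merge_map(
    cells: pd.DataFrame,
    signatures: pd.DataFrame,
    cluster_col: str = "cluster",
    cofactor: float = 1.0,
) -> dict[str, str]:
    """Propose a merge map by matching each cluster's mean transformed
    profile to the nearest population signature (cosine similarity on the
    shared markers, signatures arcsinh-scaled to match)."""
    markers = [m for m in signatures.columns if f"tr_{m}" in cells.columns]
    sig = np.arcsinh(signatures[markers].to_numpy(dtype=float) / cofactor)
    sig_norm = sig / np.maximum(np.linalg.norm(sig, axis=1, keepdims=True), 1e-12)
    merge = {}
    for cl, df in cells.groupby(cluster_col):
        prof = df[[f"tr_{m}" for m in markers]].mean().to_numpy()
        prof = prof / max(np.linalg.norm(prof), 1e-12)
        best = int(np.argmax(sig_norm @ prof))
        name = str(signatures.index[best])
        merge[cl] = name if name in POPULATIONS else "other"
    return merge


def subcluster_and_annotate(
    cells: pd.DataFrame,
    branch_features: dict[str, list[str]],
    k: dict[str, int],
    merge_map: dict[str, str] | None = None,
    signatures: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subcluster within gates and annotate via a merge map (or one
    suggested from signatures when no explicit map is given)."""
    clustered = subcluster(cells, branch_features, k, seed=seed)
    if merge_map is None:
        if signatures is None:
            raise ValueError("provide either a merge map or signatures")
        merge_map = suggest_merge_map(clustered, signatures)
    return apply_merge_map(clustered, merge_map)


# ---------------------------------------------------------------------------
# frequency / density tables


def frequencies_and_densities(
    cells: pd.DataFrame, segment_areas: pd.DataFrame
) -> pd.DataFrame:
    """Per sample × segment × population: cell count, frequency (fraction of
    the segment's cells) and density (cells/µm² of the segment).

    segment_areas: columns sample_id, segment, area_um2.
    """
    counts = (
        cells.groupby(["sample_id", "segment", "population"])
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["sample_id", "segment"])["n"].transform("sum")
    counts["frequency"] = counts["n"] / totals
    merged = counts.merge(segment_areas, on=["sample_id", "segment"], how="left")
    zero = merged["area_um2"].fillna(0.0) <= 0
    if zero.any():
        bad = merged.loc[zero, ["sample_id", "segment"]].drop_duplicates()
        raise ValueError(f"cells in zero-area segments:\n{bad}")
    merged["density"] = merged["n"] / merged["area_um2"]
    return merged
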