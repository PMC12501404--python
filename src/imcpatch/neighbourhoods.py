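"""Cellular neighbourhoods: per-cell composition vectors within a 20 µm
radius, k-means clustering of those vectors (40 centres by default, with a
cluster sweep to suggest k), and two-level annotation of the resulting
micro-environment classes (dominant population, then co-enriched ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .graph import SpatialGraph, neighbour_type_counts


@dataclass
class NeighbourhoodModel:
    """Fitted neighbourhood clustering: centres on the population simplex,
    per-cell labels, and the two-level annotation map."""

    k: int
    centres: pd.DataFrame  # k × populations, rows sum to 1
    labels: pd.Series  # cell_id -> neighbourhood cluster id
    seed: int
    populations: list[str]
    sweep: pd.DataFrame | None = None
    annotation: dict[int, dict] = field(default_factory=dict)

    def annotation_label(self, cluster: int, level: int = 2) -> str:
        a = self.annotation.get(cluster)
        if not a:
            return f"NB{cluster}"
        label = " & ".join(a["level1"]) + "-rich"
        if level >= 2 and a["level2"]:
            label += " (+ " + ", ".join(a["level2"]) + ")"
        return label


def neighbourhood_profiles(
    cells: pd.DataFrame,
    graph: SpatialGraph,
    label_col: str = "population",
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell composition vector: neighbour type counts divided by degree.

    Zero-degree cells receive their own one-hot population vector and a
    `zero_degree` flag so they remain assignable downstream.
    """
    labels = cells.set_index("cell_id")[label_col]
    counts, categories = neighbour_type_counts(graph, labels, categories)
    deg = counts.sum(axis=1).to_numpy()
    profiles = counts.to_numpy(dtype=float)
    nz = deg > 0
    profiles[nz] /= deg[nz, None]
    own = labels.reindex(counts.index).to_numpy()
    for i in np.flatnonzero(~nz):
        profiles[i, categories.index(own[i])] = 1.0
    out = pd.DataFrame(profiles, index=counts.index, columns=categories)
    out["zero_degree"] = ~nz
    return out


def _profile_matrix(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in profiles.columns if c != "zero_degree"]
    return profiles[cols].to_numpy(dtype=float), cols


def cluster_sweep(
    profiles: pd.DataFrame,
    k_range=range(2, 16),
    seed: int = 0,
    silhouette_subsample: int = 2000,
) -> tuple[pd.DataFrame, int]:
    """Fit k-means across a range of k; return (sweep table, suggested k).

    The table holds within-cluster sum of squares (WSS) and mean silhouette
    on a subsample; the suggestion is the elbow of the WSS curve (largest
    second difference), overridable by the caller.
    """
    X, _ = _profile_matrix(profiles)
    if np.allclose(X, X[0]):
        warnings.warn("all profiles identical: suggesting k=1", stacklevel=2)
        table = pd.DataFrame({"k": list(k_range)})
        table["wss"] = 0.0
        table["silhouette"] = np.nan
        return table, 1
    rng = np.random.default_rng(seed)
    rows = []
    # anchor the elbow curve at k=1 (total sum of squares about the mean)
    ks = sorted(set(k_range) | {1})
    for k in ks:
        if k >= len(X):
            break
        km = KMeans(n_clusters=k, n_init=10 if k > 1 else 1, random_state=seed).fit(X)
        sil = np.nan
        if k >= 2:
            idx = (
                rng.choice(len(X), silhouette_subsample, replace=False)
                if len(X) > silhouette_subsample
                else np.arange(len(X))
            )
            if len(np.unique(km.labels_[idx])) >= 2:
                sil = silhouette_score(X[idx], km.labels_[idx])
        rows.append({"k": k, "wss": km.inertia_, "silhouette": sil})
    table = pd.DataFrame(rows)
    wss = table["wss"].to_numpy()
    if len(wss) >= 3:
        second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        suggested = int(table["k"].iloc[int(np.argmax(second_diff)) + 1])
    else:
        suggested = int(table["k"].iloc[0])
    return table, suggested


def fit_neighbourhoods(
    profiles: pd.DataFrame, k: int = 40, seed: int = 0, sweep: pd.DataFrame | None = None
) -> NeighbourhoodModel:
    """k-means on composition vectors: k-means++ init, 10 restarts, best
    inertia kept; deterministic for a given seed."""
    X, populations = _profile_matrix(profiles)
    if len(X) < k:
        raise ValueError(f"k={k} exceeds {len(X)} profiled cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    centres = pd.DataFrame(km.cluster_centers_, columns=populations)
    # numerical cleanup: clip tiny negatives and renormalise onto the simplex
    centres = centres.clip(lower=0.0)
    centres = centres.div(centres.sum(axis=1), axis=0)
    labels = pd.Series(km.labels_, index=profiles.index, name="neighbourhood")
    return NeighbourhoodModel(
        k=k, centres=centres, labels=labels, seed=seed,
        populations=populations, sweep=sweep,
    )


def annotate_neighbourhoods(
    model: NeighbourhoodModel,
    dominance_threshold: float = 0.4,
    enrichment_factor: float = 2.0,
) -> NeighbourhoodModel:
    """Two-level annotation of each cluster centre.

    Level 1: populations whose centre fraction exceeds the dominance
    threshold, or the arg-max (ties broken by population order, flagged
    ambiguous) when none does. Level 2: populations exceeding the global
    mean fraction times the enrichment factor, excluding level-1 ones.
    """
    global_mean = model.centres.mean(axis=0)
    annotation = {}
    for cl in range(model.k):
        centre = model.centres.iloc[cl]
        level1 = [p for p in model.populations if centre[p] > dominance_threshold]
        ambiguous = False
        if not level1:
            top = float(centre.max())
            argmaxes = [p for p in model.populations if centre[p] == top]
            level1 = [argmaxes[0]]
            ambiguous = len(argmaxes) > 1
        level2 = [
            p
            for p in model.populations
            if p not in level1 and centre[p] > enrichment_factor * global_mean[p]
        ]
        annotation[cl] = {"level1": level1, "level2": level2, "ambiguous": ambiguous}
    model.annotation = annotation
    return model


def assign_from_centres(model: NeighbourhoodModel, profiles: pd.DataFrame) -> pd.Series:
    """Nearest-centre assignment of (possibly new) profiles."""
    X, pops = _profile_matrix(profiles)
    C = model.centres[pops].to_numpy()
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    return pd.Series(np.argmin(d2, axis=1), index=profiles.index, name="neighbourhood")
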