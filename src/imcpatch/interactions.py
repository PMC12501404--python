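"""Permutation testing of pairwise cell-type attraction and avoidance.

For each ordered type pair (A, B) on one image the statistic is the mean
number of B-labelled neighbours per A cell on the spatial graph. The null
distribution comes from shuffling cell labels uniformly over the tested
region's nodes while keeping the graph fixed; Monte-Carlo p-values use the
add-one estimator so p is never 0. A pair is called *attraction* when the
observed statistic sits in the upper tail (p_attraction < α) and *avoidance*
in the lower tail; tests run globally and within annotated tissue regions,
where shuffling is restricted to that region's cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import SpatialGraph

RESULT_COLUMNS = [
    "image_id", "region", "from_type", "to_type", "n_from", "statistic",
    "n_perm", "p_attraction", "p_avoidance", "call", "alpha", "undefined",
]


def _cooccurrence(codes: np.ndarray, a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """Ordered co-occurrence counts C[A, B] = directed neighbour tallies."""
    C = np.zeros((k, k), dtype=np.int64)
    if len(a):
        np.add.at(C, (codes[a], codes[b]), 1)
        np.add.at(C, (codes[b], codes[a]), 1)
    return C


def permutation_interaction_test(
    cells: pd.DataFrame,
    graph: SpatialGraph,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    region: str | None = None,
    categories: list[str] | None = None,
    label_col: str = "population",
) -> pd.DataFrame:
    """Label-shuffle permutation test for every ordered type pair.

    cells must carry cell_id, the label column, and (for region runs) a
    segment column. Returns one row per ordered pair with the observed
    statistic, add-one Monte-Carlo p-values for attraction (upper tail) and
    avoidance (lower tail), and the significance call at α.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cells = cells.set_index("cell_id", drop=False) if cells.index.name != "cell_id" else cells
    region_name = region if region is not None else "all"
    g = graph
    if region is not None:
        seg = cells["segment"].reindex(graph.node_ids).to_numpy()
        g = graph.subgraph(seg == region)

    labels = cells[label_col].reindex(g.node_ids)
    if labels.isna().any():
        raise ValueError("graph nodes missing from the cell table")
    if categories is None:
        categories = sorted(pd.unique(labels))
    if g.n_nodes < 2 or not categories:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    cat_index = {c: i for i, c in enumerate(categories)}
    codes = labels.map(cat_index).to_numpy(dtype=int)
    k = len(categories)
    a = g.edges[:, 0] if g.n_edges else np.empty(0, dtype=int)
    b = g.edges[:, 1] if g.n_edges else np.empty(0, dtype=int)

    C_obs = _cooccurrence(codes, a, b, k)
    n_per_type = np.bincount(codes, minlength=k)

    rng = np.random.default_rng(seed)
    ge = np.zeros((k, k), dtype=np.int64)
    le = np.zeros((k, k), dtype=np.int64)
    for _ in range(n_perm):
        Cp = _cooccurrence(rng.permutation(codes), a, b, k)
        ge += Cp >= C_obs
        le += Cp <= C_obs
    p_att = (1.0 + ge) / (1.0 + n_perm)
    p_avo = (1.0 + le) / (1.0 + n_perm)

    rows = []
    for i, fa in enumerate(categories):
        for j, fb in enumerate(categories):
            nf = int(n_per_type[i])
            undefined = nf == 0
            stat = C_obs[i, j] / nf if nf else np.nan
            pa = p_att[i, j] if not undefined else 1.0
            pv = p_avo[i, j] if not undefined else 1.0
            if undefined:
                call = "none"
            elif pa < alpha:
                call = "attraction"
            elif pv < alpha:
                call = "avoidance"
            else:
                call = "none"
            rows.append(
                (g.image_id, region_name, fa, fb, nf, stat, n_perm, pa, pv,
                 call, alpha, undefined)
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_interaction_analysis(
    cells: pd.DataFrame,
    graphs: dict[str, SpatialGraph],
    regions: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    label_col: str = "population",
) -> pd.DataFrame:
    """Run the permutation test per image, globally and per region.

    graphs maps image_id -> SpatialGraph built on that image's cells.
    Categories are fixed across images to the union of observed labels so
    results align. Seeds derive deterministically from `seed` per
    (image, region).
    """
    categories = sorted(pd.unique(cells[label_col]))
    region_list: list[str | None] = [None] + list(regions or [])
    out = []
    ss = np.random.SeedSequence(seed)
    image_ids = sorted(graphs)
    children = ss.spawn(len(image_ids) * len(region_list))
    ci = 0
    for image_id in image_ids:
        img_cells = cells[cells["image_id"] == image_id]
        for region in region_list:
            child_seed = int(children[ci].generate_state(1)[0] % 2**31)
            ci += 1
            res = permutation_interaction_test(
                img_cells, graphs[image_id], n_perm=n_perm, alpha=alpha,
                seed=child_seed, region=region, categories=categories,
                label_col=label_col,
            )
            out.append(res)
    return (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )


def summarize_significance(
    results: pd.DataFrame, group_map: dict[str, str]
) -> pd.DataFrame:
    """Per group × region × ordered pair: number of samples called
    attraction and avoidance, with the per-pair denominator (samples where
    the pair was defined)."""
    missing = set(results["image_id"]) - set(group_map)
    if missing:
        raise ValueError(f"samples missing from group map: {sorted(missing)}")
    res = results.copy()
    res["group"] = res["image_id"].map(group_map)
    defined = res[~res["undefined"]]
    out = (
        defined.groupby(["group", "region", "from_type", "to_type"])
        .agg(
            n_attraction=("call", lambda s: int((s == "attraction").sum())),
            n_avoidance=("call", lambda s: int((s == "avoidance").sum())),
            n_samples=("image_id", "nunique"),
        )
        .reset_index()
    )
    return out


def region_log2_ratio(
    results: pd.DataFrame,
    region_a: str,
    region_b: str,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per ordered pair: log2 of mean interaction frequency in region A over
    region B, with pseudocount eps in numerator and denominator. Positive
    values mean the pair is enriched in region A. Pairs undefined in both
    regions are omitted."""
    for r in (region_a, region_b):
        if r not in set(results["region"]):
            raise ValueError(f"unknown region {r!r}")
    defined = results[~results["undefined"]]
    freq = (
        defined[defined["region"].isin([region_a, region_b])]
        .groupby(["region", "from_type", "to_type"])["statistic"]
        .mean()
        .unstack("region")
    )
    freq = freq.dropna(how="all")
    fa = freq.get(region_a)
    fb = freq.get(region_b)
    out = pd.DataFrame(
        {
            "freq_a": fa,
            "freq_b": fb,
            "log2_ratio": np.log2((fa.fillna(0.0) + eps) / (fb.fillna(0.0) + eps)),
        }
    ).reset_index()
    out.insert(0, "region_b", region_b)
    out.insert(0, "region_a", region_a)
    return out
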