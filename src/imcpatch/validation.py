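"""Self-validation experiments: calibration, power, recovery and exactness
checks of the pipeline on synthetic data with known ground truth.

Each function runs one experiment at a stated scale and returns plain
numbers, so the same code backs both the test suite and the reproducibility
script. Oracles here are written independently of the implementation they
check: exhaustive enumeration for permutation p-values, O(n²) geometry for
spatial graphs.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from . import graph as graphmod
from . import interactions as inter
from . import neighbourhoods as nbh
from . import patches as patchmod
from . import phenotype as pheno
from . import preprocess as prep
from . import synth


def _seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# permutation test vs exhaustive enumeration


def _enumerate_pvalues(codes: np.ndarray, edges: np.ndarray, k: int):
    """Exact attraction/avoidance p-values over all label orderings."""

    def cooc(c):
        C = np.zeros((k, k), dtype=int)
        for a, b in edges:
            C[c[a], c[b]] += 1
            C[c[b], c[a]] += 1
        return C

    C_obs = cooc(codes)
    ge = np.zeros((k, k), dtype=int)
    le = np.zeros((k, k), dtype=int)
    total = 0
    for perm in permutations(range(len(codes))):
        Cp = cooc(codes[list(perm)])
        ge += Cp >= C_obs
        le += Cp <= C_obs
        total += 1
    return ge / total, le / total


def permutation_vs_exact(n_configs: int = 20, n_perm: int = 5000, seed: int = 0) -> dict:
    """Monte-Carlo p-values vs exhaustive enumeration on ≤ 6-cell instances.

    Returns the worst absolute deviation in units of the Monte-Carlo
    standard error and the fraction of comparisons within 3 SE (an add-one
    allowance of 1/(n_perm+1) is folded into the SE unit).
    """
    rng = np.random.default_rng(seed)
    devs = []
    for t in range(n_configs):
        n = int(rng.integers(4, 7))
        pts = rng.uniform(0, 30, (n, 2))
        labs = rng.choice(["A", "B"], n).tolist()
        if len(set(labs)) == 1:
            labs[0] = "B" if labs[0] == "A" else "A"
        cells = pd.DataFrame(
            {"cell_id": np.arange(1, n + 1), "x_um": pts[:, 0], "y_um": pts[:, 1],
             "population": labs}
        )
        g = graphmod.build_radius_graph(cells, 15.0)
        res = inter.permutation_interaction_test(cells, g, n_perm=n_perm, seed=t)
        cats = sorted(set(labs))
        codes = np.array([cats.index(l) for l in labs])
        p_att, p_avo = _enumerate_pvalues(codes, g.edges, len(cats))
        for i, a in enumerate(cats):
            for j, b in enumerate(cats):
                row = res[(res.from_type == a) & (res.to_type == b)].iloc[0]
                for p_mc, p_ex in [(row.p_attraction, p_att[i, j]),
                                   (row.p_avoidance, p_avo[i, j])]:
                    se = np.sqrt(max(p_ex * (1 - p_ex), 1e-12) / n_perm) + 1 / (n_perm + 1)
                    devs.append(abs(p_mc - p_ex) / se)
    devs = np.array(devs)
    return {
        "max_dev_se_units": float(devs.max()),
        "frac_within_3se": float((devs <= 3.0).mean()),
        "n_comparisons": int(len(devs)),
    }


# ---------------------------------------------------------------------------
# calibration and power


def type_i_error_rate(
    n_images: int = 500,
    n_cells: int = 400,
    n_types: int = 3,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Attraction-call rate under complete spatial randomness of labels.

    Images hold n_cells at a follicle-like density (0.008 cells/µm²) with
    labels assigned uniformly at random; enough cells per image keep the
    discrete co-occurrence counts fine-grained so the add-one p-value stays
    close to nominal. Returns the rate over all (image, ordered pair) tests
    together with the 99% binomial interval around alpha.
    """
    types = [f"T{i}" for i in range(n_types)]
    side = float(np.sqrt(n_cells / 0.008))
    seeds = _seeds(seed, n_images)
    calls = 0
    trials = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        pts = rng.uniform(0, side, (n_cells, 2))
        labs = rng.choice(types, n_cells)
        cells = pd.DataFrame(
            {"cell_id": np.arange(1, n_cells + 1), "x_um": pts[:, 0],
             "y_um": pts[:, 1], "population": labs}
        )
        g = graphmod.build_delaunay_graph(cells, 20.0)
        res = inter.permutation_interaction_test(
            cells, g, n_perm=n_perm, alpha=alpha, seed=s, categories=types
        )
        defined = res[~res.undefined]
        calls += int((defined.call == "attraction").sum())
        trials += len(defined)
    rate = calls / trials
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / trials)
    return {
        "rate": float(rate),
        "n_trials": trials,
        "interval_low": float(alpha - half),
        "interval_high": float(alpha + half),
    }


def _planted_image_cells(seed: int, rule: str):
    layout = synth.TissueLayout(
        width=360, height=360, epithelium_depth=1, submucosa_depth=1
    )
    pop = synth.default_population()
    pop.densities = {"lamina_propria": {"B": 0.0012, "CD4_T_naive": 0.0008}}
    if rule == "attraction":
        pop.attraction_rules = [("B", "CD4_T_naive", 5.0, 1.0)]
    elif rule == "avoidance":
        pop.avoidance_rules = [("B", "CD4_T_naive", 15.0)]
    cells = synth.place_cells(layout, pop, seed=seed)
    return cells.rename(columns={"cell_type": "population"})


def planted_structure_power(
    rule: str,
    n_images: int = 50,
    n_perm: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of simulated images where the planted B ↔ naive-CD4-T
    structure (attraction via 5 µm Thomas displacement, or avoidance via a
    15 µm exclusion zone) is called significantly at alpha."""
    hits = 0
    for s in _seeds(seed, n_images):
        cells = _planted_image_cells(s, rule)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        res = inter.permutation_interaction_test(
            cells, g, n_perm=n_perm, alpha=alpha, seed=s
        )
        row = res[(res.from_type == "CD4_T_naive") & (res.to_type == "B")]
        if len(row) and row.iloc[0].call == rule:
            hits += 1
    return hits / n_images


# ---------------------------------------------------------------------------
# patch recovery


def _grid(n_side, spacing, origin=(0.0, 0.0)):
    xs = np.arange(n_side) * spacing + origin[0]
    ys = np.arange(n_side) * spacing + origin[1]
    return np.array([(x, y) for y in ys for x in xs])


def patch_recovery_checks() -> dict:
    """Deterministic patch-detection layouts with exact expectations:
    component-size and area-threshold boundary behaviour, and exact
    recovery of planted aggregates."""

    def cells_of(pts):
        pts = np.asarray(pts, dtype=float)
        return pd.DataFrame(
            {"cell_id": np.arange(1, len(pts) + 1), "x_um": pts[:, 0],
             "y_um": pts[:, 1], "population": "B", "image_id": "img"}
        )

    out = {}
    # 9-cell component rejected, 10-cell accepted
    nine = cells_of(_grid(3, 10.0))
    g9 = graphmod.build_delaunay_graph(nine, 20.0)
    out["nine_cell_rejected"] = len(patchmod.detect_patches(nine, g9)) == 0
    ten = cells_of(np.vstack([_grid(3, 10.0), [[10.0, 25.0]]]))
    out["ten_cell_accepted"] = len(
        patchmod.detect_patches(ten, graphmod.build_delaunay_graph(ten, 20.0))
    ) == 1

    # two planted aggregates separated beyond the cutoff: exact membership
    a = _grid(4, 10.0)
    b = _grid(5, 10.0, origin=(200.0, 0.0))
    both = cells_of(np.vstack([a, b]))
    patches = patchmod.detect_patches(
        both, graphmod.build_delaunay_graph(both, 20.0)
    )
    out["planted_count_exact"] = len(patches) == 2
    out["planted_membership_exact"] = (
        len(patches) == 2
        and set(patches[0].core_cell_ids) == set(range(1, 17))
        and set(patches[1].core_cell_ids) == set(range(17, 42))
    )

    # area exactly at the large threshold stays small; above becomes large
    rect = cells_of(
        [(0, 0), (100, 0), (0, 120), (100, 120)]
        + [(10 * i, 60) for i in range(1, 7)]
    )
    p = patchmod.Patch(0, "img", rect.cell_id.to_numpy())
    p = patchmod.patch_area_and_class(p, rect, distance=0.0, large_threshold=12000.0)
    out["threshold_area_small"] = (abs(p.area_um2 - 12000.0) < 1e-9) and p.size_class == "small"
    lattice = cells_of(_grid(13, 10.0))
    p2 = patchmod.Patch(0, "img", lattice.cell_id.to_numpy())
    p2 = patchmod.patch_area_and_class(p2, lattice, distance=1.0)
    out["large_class_correct"] = p2.size_class == "large"
    out["all_exact"] = all(out.values())
    return out


# ---------------------------------------------------------------------------
# graph oracle


def graph_oracle_agreement(n_points: int = 200, seed: int = 0) -> dict:
    """Radius and pruned-Delaunay graphs vs brute-force constructions.

    The radius oracle is O(n²) thresholding; the Delaunay oracle checks the
    empty-circumcircle property for every candidate pair within the cutoff.
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 260, (n_points, 2))
    cells = pd.DataFrame(
        {"cell_id": np.arange(1, n_points + 1), "x_um": pts[:, 0], "y_um": pts[:, 1]}
    )
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    iu = np.triu_indices(n_points, 1)
    radius_oracle = {
        (int(i), int(j)) for i, j in zip(*iu) if d[i, j] <= 20.0
    }
    gr = graphmod.build_radius_graph(cells, 20.0)
    radius_ok = {tuple(sorted(e)) for e in gr.edges} == radius_oracle

    def delaunay_pair(i, j):
        others = np.delete(np.arange(n_points), [i, j])
        p, q = pts[i], pts[j]
        c = (p + q) / 2
        r = np.linalg.norm(p - q) / 2
        if (np.linalg.norm(pts[others] - c, axis=1) > r - 1e-9).all():
            return True
        for k in others:
            s = pts[k]
            den = 2 * (
                p[0] * (q[1] - s[1]) + q[0] * (s[1] - p[1]) + s[0] * (p[1] - q[1])
            )
            if abs(den) < 1e-12:
                continue
            ux = ((p @ p) * (q[1] - s[1]) + (q @ q) * (s[1] - p[1])
                  + (s @ s) * (p[1] - q[1])) / den
            uy = ((p @ p) * (s[0] - q[0]) + (q @ q) * (p[0] - s[0])
                  + (s @ s) * (q[0] - p[0])) / den
            centre = np.array([ux, uy])
            rad = np.linalg.norm(p - centre)
            rest = np.delete(np.arange(n_points), [i, j, k])
            if (np.linalg.norm(pts[rest] - centre, axis=1) > rad - 1e-9).all():
                return True
        return False

    delaunay_oracle = {
        (i, j) for i, j in radius_oracle if delaunay_pair(i, j)
    }
    gd = graphmod.build_delaunay_graph(cells, 20.0)
    delaunay_ok = {tuple(sorted(e)) for e in gd.edges} == delaunay_oracle
    return {
        "radius_ok": bool(radius_ok),
        "delaunay_ok": bool(delaunay_ok),
        "n_radius_edges": len(radius_oracle),
        "n_delaunay_edges": len(delaunay_oracle),
    }


# ---------------------------------------------------------------------------
# phenotype and neighbourhood recovery


TRUTH_TO_GATE = {
    "B": "B cell",
    "CD4_T_naive": "T cell", "CD4_T_mature": "T cell",
    "CD8_T_naive": "T cell", "CD8_T_mature": "T cell",
    "CD8_T_CD38": "T cell", "Treg": "T cell",
    "monocyte": "other immune", "macrophage": "other immune",
    "epithelial": "epithelial",
}

FIXED_GATES = pheno.GateSpec(
    thresholds={"CD45": 1.5, "ECadherin": 1.5, "CD3": 1.5, "CD20": 1.5}
)


def gating_accuracy_noise_free(seed: int = 0) -> float:
    """Full image path — render without noise, extract, normalize, gate —
    scored against generator truth. Expected: exactly 1.0."""
    layout = synth.TissueLayout(
        width=300, height=300,
        follicles=[synth.FollicleSpec(cx=110.0, cy=160.0, radius=50.0)],
    )
    pop = synth.default_population()
    pop.noise_sigma = {m: 0.0 for m in pop.markers}
    pop.background = {m: 0.0 for m in pop.markers}
    ss = _seeds(seed, 2)
    mask, _ = synth.generate_layout(layout, ss[0])
    truth = synth.place_cells(layout, pop, ss[1], tissue_mask=mask)
    bundle = synth.render_images(truth, pop, mask, seed=0)
    cells = prep.extract_cell_features(bundle)
    cells["sample_id"] = "s"
    cells = prep.normalize_and_filter(cells)
    cells = cells.merge(truth[["cell_id", "cell_type"]], on="cell_id")
    cells = pheno.gate_cells(cells, FIXED_GATES, image_col=None)
    expected = cells["cell_type"].map(TRUTH_TO_GATE)
    return float((cells["gate"] == expected).mean())


def subcluster_recovery_ari(n_per_type: int = 80, sigma: float = 0.3, seed: int = 0) -> float:
    """ARI of k-means subclustering against 4 planted T subtypes under the
    generator's lognormal intensity noise."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    sig = synth.default_signatures()
    t_types = ["CD4_T_naive", "CD4_T_mature", "CD8_T_naive", "CD8_T_mature"]
    rows = []
    for t in t_types:
        for _ in range(n_per_type):
            row = {"true_type": t, "gate": "T cell"}
            for m in sig.columns:
                row[f"tr_{m}"] = np.arcsinh(
                    sig.loc[t, m] * np.exp(rng.normal(0, sigma))
                )
            rows.append(row)
    cells = pd.DataFrame(rows)
    cells["cell_id"] = np.arange(1, len(cells) + 1)
    feats = ["tr_CD4", "tr_CD8a", "tr_CD45RA", "tr_CD45RO"]
    out = pheno.subcluster(cells, {"T cell": feats}, {"T cell": 4}, seed=seed)
    return float(adjusted_rand_score(cells["true_type"], out["cluster"]))


def neighbourhood_recovery_ari(n_per_block: int = 120, seed: int = 0) -> dict:
    """Three planted composition regimes (pure B, pure T, even mixture in
    separate spatial blocks) recovered by profile k-means at k=3."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    pts, labs, regime = [], [], []
    for b in range(3):
        base = np.array([b * 300.0, 0.0])
        pts.append(base + rng.uniform(0, 60, (n_per_block, 2)))
        if b == 0:
            labs += ["B"] * n_per_block
        elif b == 1:
            labs += ["T"] * n_per_block
        else:
            labs += ["B" if i % 2 == 0 else "T" for i in range(n_per_block)]
        regime += [b] * n_per_block
    pts = np.vstack(pts)
    cells = pd.DataFrame(
        {"cell_id": np.arange(1, len(pts) + 1), "x_um": pts[:, 0],
         "y_um": pts[:, 1], "population": labs}
    )
    g = graphmod.build_radius_graph(cells, 20.0)
    prof = nbh.neighbourhood_profiles(cells, g)
    sums_ok = bool(
        np.allclose(prof.drop(columns="zero_degree").sum(axis=1), 1.0)
    )
    model = nbh.fit_neighbourhoods(prof, k=3, seed=seed)
    ari = adjusted_rand_score(regime, model.labels.to_numpy())
    return {"ari": float(ari), "profiles_sum_to_one": sums_ok}


# ---------------------------------------------------------------------------
# directional fixtures


def follicle_bb_log2_ratio(seed: int = 0) -> float:
    """LP-vs-follicle log2 interaction ratio for (B, B) when B–B contacts
    exist only inside follicles; expected negative."""
    layout = synth.TissueLayout(
        width=400, height=400,
        follicles=[synth.FollicleSpec(cx=150, cy=210, radius=70)],
    )
    pop = synth.default_population()
    pop.densities = {
        "follicle": {"B": 0.008},
        "lamina_propria": {"B": 0.0002, "CD4_T_naive": 0.001},
    }
    mask, _ = synth.generate_layout(layout, seed)
    cells = synth.place_cells(layout, pop, seed=seed, tissue_mask=mask)
    cells = cells.rename(columns={"cell_type": "population", "compartment": "segment"})
    cells["image_id"] = "s1"
    g = graphmod.build_delaunay_graph(cells, 20.0)
    res = inter.run_interaction_analysis(
        cells, {"s1": g}, regions=["lamina_propria", "follicle"],
        n_perm=200, seed=seed,
    )
    out = inter.region_log2_ratio(res, "lamina_propria", "follicle")
    bb = out[(out.from_type == "B") & (out.to_type == "B")]
    return float(bb.log2_ratio.iloc[0])


def patch_t_neighbourhood_contrast(seed: int = 0) -> dict:
    """T-enriched neighbourhood frequency in a T-infiltrated small patch vs
    a pure-B large aggregate; the difference should be positive."""
    pure = _grid(8, 10.0)
    mixed_b = _grid(5, 12.0, origin=(400.0, 0.0))
    mixed_t = _grid(4, 12.0, origin=(406.0, 6.0))
    pts = np.vstack([pure, mixed_b, mixed_t])
    labs = ["B"] * (len(pure) + len(mixed_b)) + ["CD4_T_mature"] * len(mixed_t)
    cells = pd.DataFrame(
        {"cell_id": np.arange(1, len(pts) + 1), "x_um": pts[:, 0],
         "y_um": pts[:, 1], "population": labs, "image_id": "img"}
    )
    g = graphmod.build_delaunay_graph(cells, 20.0)
    gr = graphmod.build_radius_graph(cells, 20.0)
    prof = nbh.neighbourhood_profiles(cells, gr)
    model = nbh.annotate_neighbourhoods(nbh.fit_neighbourhoods(prof, k=3, seed=seed))
    nb_label = pd.Series(
        [model.annotation_label(c, level=1) for c in model.labels],
        index=model.labels.index,
    )
    t_classes = {
        model.annotation_label(c, level=1)
        for c, a in model.annotation.items()
        if any(p.startswith(("CD4_T", "CD8_T")) for p in a["level1"] + a["level2"])
    }
    patches = patchmod.detect_patches(cells, g)
    freqs = {}
    for p in patches:
        p = patchmod.expand_patch(p, cells)
        comp = patchmod.patch_composition(p, cells, neighbourhood_labels=nb_label)
        sub = comp[(comp.kind == "neighbourhood") & comp["name"].isin(t_classes)]
        key = "pure" if 1 in p.core_cell_ids else "mixed"
        freqs[key] = float(sub.frequency.sum())
    return {
        "t_nb_freq_pure": freqs.get("pure", np.nan),
        "t_nb_freq_mixed": freqs.get("mixed", np.nan),
        "contrast": freqs.get("mixed", np.nan) - freqs.get("pure", np.nan),
    }
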