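"""End-to-end analysis pipeline on synthetic cohorts.

Chains every stage — simulation, background correction, feature extraction,
phenotyping, spatial graphs, interaction testing, neighbourhood clustering,
patch detection and group statistics — writing deterministic CSV outputs to
a run directory. A fixed configuration plus seed reproduces every file
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph as graphmod
from . import interactions as inter
from . import neighbourhoods as nbh
from . import patches as patchmod
from . import phenotype as pheno
from . import preprocess as prep
from . import report
from . import synth

PROB_LABEL_MAP = {
    "CD4_T_naive": "CD4_T", "CD4_T_mature": "CD4_T", "Treg": "CD4_T",
    "CD8_T_naive": "CD8_T", "CD8_T_mature": "CD8_T", "CD8_T_CD38": "CD8_T",
    "B": "non_T", "monocyte": "non_T", "macrophage": "non_T",
    "epithelial": "epithelial",
}

T_BRANCH_FEATURES = [
    "tr_CD4", "tr_CD8a", "tr_CD45RA", "tr_CD45RO", "tr_CD38", "tr_FOXP3",
    "prob_CD4_T", "prob_CD8_T",
]


@dataclass
class PipelineConfig:
    """Study conditions for a synthetic cohort run."""

    n_samples: int = 4
    groups: tuple[str, ...] = ("healthy", "CD_colitis")
    layout: synth.TissueLayout = field(default_factory=synth.default_layout)
    population: synth.PopulationSpec = field(default_factory=synth.default_population)
    n_perm: int = 200
    alpha: float = 0.01
    regions: tuple[str, ...] = ("lamina_propria", "follicle")
    cutoff_um: float = 20.0
    k_neighbourhoods: int = 12
    k_t_branch: int = 6
    training_fraction: float = 0.25
    gate_thresholds: dict = field(
        default_factory=lambda: {"CD45": 1.5, "ECadherin": 1.5, "CD3": 1.5, "CD20": 1.5}
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0, out_dir=None):
    """Run the full pipeline; returns a dict of result tables and, when
    out_dir is given, writes them as CSV files."""
    cfg = config or PipelineConfig()
    s_sim, s_clf, s_cluster, s_inter, s_nbh = _child_seeds(seed, 5)
    sim_seeds = _child_seeds(s_sim, cfg.n_samples)

    # --- simulate + preprocess -------------------------------------------
    all_cells, graphs_d, graphs_r = [], {}, {}
    group_map = {}
    for i in range(cfg.n_samples):
        sample_id = f"S{i + 1:02d}"  # zero-padded: lexicographic == numeric order
        group_map[sample_id] = cfg.groups[i % len(cfg.groups)]
        bundle, truth, _ = synth.simulate_sample(cfg.layout, cfg.population, sim_seeds[i])
        cells = prep.preprocess_bundle(bundle, sample_id=sample_id, image_id=sample_id)
        cells = cells.merge(
            truth[["cell_id", "cell_type", "planted_patch_id"]].rename(
                columns={"cell_type": "true_type"}
            ),
            on="cell_id",
            how="left",
        )
        all_cells.append(cells)
    cells = pd.concat(all_cells, ignore_index=True)

    # --- phenotyping ------------------------------------------------------
    gates = pheno.GateSpec(thresholds=dict(cfg.gate_thresholds))
    cells = pheno.gate_cells(cells, gates)

    # annotator-labelled training subset (ground truth plays the annotator)
    rng = np.random.default_rng(s_clf)
    cells["prob_label"] = pd.Series(np.nan, index=cells.index, dtype=object)
    labelled = rng.random(len(cells)) < cfg.training_fraction
    cells.loc[labelled, "prob_label"] = cells.loc[labelled, "true_type"].map(PROB_LABEL_MAP)
    clf = pheno.train_probability_classifier(cells, seed=s_clf)
    cells = pheno.apply_probability_classifier(cells, clf)

    sig = cfg.population.signatures
    branch_features = {
        "T cell": [f for f in T_BRANCH_FEATURES if f in cells.columns],
        "other immune": ["tr_CD14", "tr_CD68"],
    }
    k = {"T cell": cfg.k_t_branch, "other immune": 2}
    clustered = pheno.subcluster(cells, branch_features, k, seed=s_cluster)
    merge_map = pheno.suggest_merge_map(clustered, sig)
    # non-immune, non-epithelial cells stay "other" whatever their profile
    for cl in list(merge_map):
        if cl.startswith("other:"):
            merge_map[cl] = "other"
        if cl.startswith("B cell:"):
            merge_map[cl] = "B"
        if cl.startswith("epithelial:"):
            merge_map[cl] = "epithelial"
    cells = pheno.apply_merge_map(clustered, merge_map)

    # --- spatial graphs ---------------------------------------------------
    for sample_id, df in cells.groupby("sample_id"):
        graphs_d[sample_id] = graphmod.build_delaunay_graph(df, cfg.cutoff_um, sample_id)
        graphs_r[sample_id] = graphmod.build_radius_graph(df, cfg.cutoff_um, sample_id)

    # --- interactions -----------------------------------------------------
    results = inter.run_interaction_analysis(
        cells, graphs_d, regions=list(cfg.regions),
        n_perm=cfg.n_perm, alpha=cfg.alpha, seed=s_inter,
    )
    summary = inter.summarize_significance(results, group_map)
    ratios = (
        inter.region_log2_ratio(results, cfg.regions[0], cfg.regions[1])
        if len(cfg.regions) >= 2
        else pd.DataFrame()
    )

    # --- neighbourhoods ---------------------------------------------------
    prof_frames = []
    populations = sorted(pd.unique(cells["population"]))
    for sample_id, df in cells.groupby("sample_id"):
        prof_frames.append(
            nbh.neighbourhood_profiles(df, graphs_r[sample_id], categories=populations)
        )
    profiles = pd.concat(prof_frames)
    profiles.index = cells["cell_id"].to_numpy()  # unique only within image
    profiles.index.name = "cell_id"
    model = nbh.fit_neighbourhoods(profiles, k=cfg.k_neighbourhoods, seed=s_nbh)
    model = nbh.annotate_neighbourhoods(model)
    cells["neighbourhood"] = model.labels.to_numpy()
    cells["neighbourhood_label"] = [
        model.annotation_label(c, level=1) for c in cells["neighbourhood"]
    ]

    # --- patches ----------------------------------------------------------
    patch_tables, comp_tables = [], []
    for sample_id, df in cells.groupby("sample_id"):
        nb_labels = df.set_index("cell_id")["neighbourhood_label"]
        ptab, pcomp, _ = patchmod.analyse_patches(
            df, graphs_d[sample_id], b_populations=("B",),
            neighbourhood_labels=nb_labels,
        )
        patch_tables.append(ptab)
        comp_tables.append(pcomp)
    patch_table = pd.concat(patch_tables, ignore_index=True)
    patch_comp = pd.concat(comp_tables, ignore_index=True)

    # --- frequencies / densities / statistics -----------------------------
    area_rows = []
    for i in range(cfg.n_samples):
        mask, _ = synth.generate_layout(cfg.layout, 0)
        _, areas = prep.assign_tissue_segments(cells.iloc[:0], mask)
        for seg, a in areas.items():
            area_rows.append({"sample_id": f"S{i + 1:02d}", "segment": seg, "area_um2": a})
    freq = pheno.frequencies_and_densities(cells, pd.DataFrame(area_rows))
    freq["group"] = freq["sample_id"].map(group_map)

    comparisons = pd.DataFrame()
    wide = freq.pivot_table(
        index="sample_id", columns=["segment", "population"], values="frequency",
        fill_value=0.0,
    )
    if len(wide) >= 4 and len(set(group_map.values())) >= 2:
        wide.columns = [f"{s}|{p}" for s, p in wide.columns]
        grouping = pd.Series({s: group_map[s] for s in wide.index})
        by_group = grouping.value_counts()
        pairs = [
            (a, b)
            for ai, a in enumerate(sorted(by_group.index))
            for b in sorted(by_group.index)[ai + 1 :]
            if by_group[a] >= 2 and by_group[b] >= 2
        ]
        if pairs:
            comparisons = report.wilcoxon_bh(wide, grouping, pairs)

    out = {
        "cells": cells,
        "interactions": results,
        "interaction_summary": summary,
        "region_log2_ratios": ratios,
        "neighbourhood_centres": model.centres.assign(
            label=[model.annotation_label(c) for c in range(model.k)]
        ),
        "patches": patch_table,
        "patch_composition": patch_comp,
        "frequencies": freq,
        "comparisons": comparisons,
    }
    out["model"] = model
    out["graphs_delaunay"] = graphs_d
    out["graphs_radius"] = graphs_r
    out["group_map"] = group_map

    if out_dir is not None:
        write_run(out, out_dir)
    return out


def write_run(results: dict, out_dir) -> None:
    """Write every pipeline table as CSV (numeric tables before figures)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in (
        "cells", "interactions", "interaction_summary", "region_log2_ratios",
        "neighbourhood_centres", "patches", "patch_composition",
        "frequencies", "comparisons",
    ):
        df = results[name]
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"{name}.csv", index=name == "neighbourhood_centres")
    for sample_id, g in results.get("graphs_delaunay", {}).items():
        graphmod.write_graph_csv(g, out / f"graph_delaunay_{sample_id}.csv")
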