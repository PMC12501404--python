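"""Gating, probability-feature classification, subclustering and
frequency/density tables."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from imcpatch import phenotype as pheno
from imcpatch import synth
from imcpatch.phenotype import GateSpec

FIXED_GATES = GateSpec(thresholds={"CD45": 1.5, "ECadherin": 1.5, "CD3": 1.5, "CD20": 1.5})

TRUTH_TO_GATE = {
    "B": "B cell",
    "CD4_T_naive": "T cell", "CD4_T_mature": "T cell",
    "CD8_T_naive": "T cell", "CD8_T_mature": "T cell",
    "CD8_T_CD38": "T cell", "Treg": "T cell",
    "monocyte": "other immune", "macrophage": "other immune",
    "epithelial": "epithelial",
}


def noise_free_cells(n_per_type=20, seed=0):
    """Cell table whose transformed intensities equal the arcsinh of the
    exact signature means (no noise, no background)."""
    sig = synth.default_signatures()
    rows = []
    cid = 1
    for t in sig.index:
        for _ in range(n_per_type):
            row = {"cell_id": cid, "image_id": "img", "sample_id": "s",
                   "true_type": t}
            for m in sig.columns:
                row[f"tr_{m}"] = np.arcsinh(sig.loc[t, m])
            rows.append(row)
            cid += 1
    return pd.DataFrame(rows)


def noisy_cells(n_per_type=60, sigma=0.3, seed=1):
    """Signature means with lognormal multiplicative noise, asinh scale."""
    rng = np.random.default_rng(seed)
    sig = synth.default_signatures()
    rows = []
    cid = 1
    for t in sig.index:
        for _ in range(n_per_type):
            row = {"cell_id": cid, "image_id": "img", "sample_id": "s",
                   "true_type": t}
            for m in sig.columns:
                row[f"tr_{m}"] = np.arcsinh(sig.loc[t, m] * np.exp(rng.normal(0, sigma)))
            rows.append(row)
            cid += 1
    return pd.DataFrame(rows)


class TestGating:
    def test_noise_free_cells_gate_to_ground_truth(self):
        cells = pheno.gate_cells(noise_free_cells(), FIXED_GATES)
        expected = cells["true_type"].map(TRUTH_TO_GATE)
        assert (cells["gate"] == expected).all()

    def test_all_zero_intensities_gate_to_other(self):
        cells = noise_free_cells(n_per_type=2)
        for c in cells.columns:
            if c.startswith("tr_"):
                cells[c] = 0.0
        out = pheno.gate_cells(cells, FIXED_GATES)
        assert (out["gate"] == "other").all()

    def test_missing_gate_marker_rejected(self):
        cells = noise_free_cells(n_per_type=2).drop(columns=["tr_CD3"])
        with pytest.raises(ValueError, match="CD3"):
            pheno.gate_cells(cells, FIXED_GATES)

    def test_otsu_thresholds_recover_truth_on_noisy_mixture(self):
        cells = pheno.gate_cells(noisy_cells(sigma=0.2), GateSpec())
        expected = cells["true_type"].map(TRUTH_TO_GATE)
        assert (cells["gate"] == expected).mean() >= 0.95


class TestProbabilityClassifier:
    def _with_labels(self, cells, fraction=0.5, seed=0):
        rng = np.random.default_rng(seed)
        cells = cells.copy()
        lab = cells["true_type"].map(
            {"CD4_T_naive": "CD4_T", "CD4_T_mature": "CD4_T", "Treg": "CD4_T",
             "CD8_T_naive": "CD8_T", "CD8_T_mature": "CD8_T", "CD8_T_CD38": "CD8_T",
             "B": "non_T", "monocyte": "non_T", "macrophage": "non_T",
             "epithelial": "epithelial"}
        )
        mask = rng.random(len(cells)) < fraction
        cells["prob_label"] = pd.Series(np.nan, index=cells.index, dtype=object)
        cells.loc[mask, "prob_label"] = lab[mask]
        cells["truth_4class"] = lab
        return cells

    def test_heldout_accuracy_and_probability_normalization(self):
        cells = self._with_labels(noisy_cells(), fraction=0.5, seed=3)
        clf = pheno.train_probability_classifier(cells, seed=0)
        out = pheno.apply_probability_classifier(cells, clf)
        prob_cols = [f"prob_{c}" for c in clf.classes_]
        assert np.allclose(out[prob_cols].sum(axis=1), 1.0, atol=1e-6)
        heldout = out[out["prob_label"].isna()]
        pred = heldout[prob_cols].to_numpy().argmax(axis=1)
        truth = heldout["truth_4class"].map(
            {c: i for i, c in enumerate(clf.classes_)}
        ).to_numpy()
        assert (pred == truth).mean() >= 0.95

    def test_missing_class_rejected(self):
        cells = self._with_labels(noisy_cells())
        cells.loc[cells["prob_label"] == "epithelial", "prob_label"] = np.nan
        with pytest.raises(ValueError, match="epithelial"):
            pheno.train_probability_classifier(cells)

    def test_probability_features_improve_t_subset_separation(self):
        """With intensity mixing between touching cells, appending classifier
        probabilities must not worsen — and here improves — the CD4/CD8
        silhouette."""
        rng = np.random.default_rng(5)
        cells = noisy_cells(n_per_type=80, sigma=0.35, seed=7)
        t_mask = cells["true_type"].str.startswith(("CD4_T", "CD8_T"))
        cells = cells[t_mask].reset_index(drop=True)
        # mixing: each cell's signal contaminated by a random other cell
        feat = [c for c in cells.columns if c.startswith("tr_")]
        X = cells[feat].to_numpy()
        other = rng.integers(0, len(cells), len(cells))
        cells[feat] = 0.6 * X + 0.4 * X[other]
        cells["truth_cd"] = np.where(
            cells["true_type"].str.startswith("CD4"), "CD4_T", "CD8_T"
        )
        cells["prob_label"] = pd.Series(np.nan, index=cells.index, dtype=object)
        lab_mask = rng.random(len(cells)) < 0.4
        cells.loc[lab_mask, "prob_label"] = cells.loc[lab_mask, "truth_cd"]
        # complete the 4-class vocabulary with clean reference cells
        extra = noisy_cells(n_per_type=30, seed=9)
        extra = extra[extra["true_type"].isin(["B", "epithelial", "monocyte"])]
        extra["prob_label"] = extra["true_type"].map(
            {"B": "non_T", "monocyte": "non_T", "epithelial": "epithelial"}
        )
        train = pd.concat([cells, extra], ignore_index=True)
        clf = pheno.train_probability_classifier(train, min_per_class=5, seed=1)
        out = pheno.apply_probability_classifier(cells, clf)
        sub = [c for c in ("tr_CD4", "tr_CD8a")]
        labels = out["truth_cd"]
        sil_raw = silhouette_score(out[sub], labels)
        sil_aug = silhouette_score(out[sub + ["prob_CD4_T", "prob_CD8_T"]], labels)
        assert sil_aug >= sil_raw


class TestSubclustering:
    T_FEATURES = ["tr_CD4", "tr_CD8a", "tr_CD45RA", "tr_CD45RO"]

    def test_planted_t_subtypes_recovered(self):
        cells = noisy_cells(n_per_type=80, sigma=0.25, seed=2)
        t_types = ["CD4_T_naive", "CD4_T_mature", "CD8_T_naive", "CD8_T_mature"]
        cells = cells[cells["true_type"].isin(t_types)].reset_index(drop=True)
        cells["gate"] = "T cell"
        out = pheno.subcluster(cells, {"T cell": self.T_FEATURES}, {"T cell": 4}, seed=0)
        ari = adjusted_rand_score(cells["true_type"], out["cluster"])
        assert ari >= 0.9

    def test_identical_features_single_cluster(self):
        cells = noise_free_cells(n_per_type=5)
        cells[:] = cells
        cells["gate"] = "T cell"
        for c in cells.columns:
            if c.startswith("tr_"):
                cells[c] = 1.0
        out = pheno.subcluster(cells, {"T cell": self.T_FEATURES}, {"T cell": 3}, seed=0)
        assert out["cluster"].nunique() == 1

    def test_k_exceeding_branch_size_rejected(self):
        cells = noise_free_cells(n_per_type=1)
        cells["gate"] = "T cell"
        with pytest.raises(ValueError, match="exceeds"):
            pheno.subcluster(cells, {"T cell": self.T_FEATURES}, {"T cell": 99}, seed=0)

    def test_merge_map_pure_relabelling(self):
        cells = noisy_cells(n_per_type=30, seed=4)
        cells["gate"] = cells["true_type"].map(TRUTH_TO_GATE)
        clustered = pheno.subcluster(
            cells, {"T cell": self.T_FEATURES}, {"T cell": 3}, seed=0
        )
        merge = {cl: "other" for cl in clustered["cluster"].unique()}
        merge.update({cl: "B" for cl in merge if cl.startswith("B cell")})
        out = pheno.apply_merge_map(clustered, merge)
        # conservation: population counts equal summed cluster counts
        assert out["population"].value_counts()["B"] == (
            clustered["cluster"].str.startswith("B cell").sum()
        )

    def test_merge_map_must_be_total(self):
        cells = noise_free_cells(n_per_type=2)
        cells["gate"] = "T cell"
        clustered = pheno.subcluster(cells, {}, {}, seed=0)
        with pytest.raises(ValueError, match="misses"):
            pheno.apply_merge_map(clustered, {})

    def test_merge_map_vocabulary_enforced(self):
        cells = noise_free_cells(n_per_type=2)
        cells["gate"] = "T cell"
        clustered = pheno.subcluster(cells, {}, {}, seed=0)
        with pytest.raises(ValueError, match="vocabulary"):
            pheno.apply_merge_map(clustered, {"T cell:0": "martian"})

    def test_suggested_merge_map_recovers_types(self):
        cells = noisy_cells(n_per_type=40, sigma=0.2, seed=6)
        cells["gate"] = cells["true_type"].map(TRUTH_TO_GATE)
        branch_feats = {
            "T cell": self.T_FEATURES + ["tr_CD38", "tr_FOXP3"],
            "other immune": ["tr_CD14", "tr_CD68"],
        }
        out = pheno.subcluster_and_annotate(
            cells, branch_feats, {"T cell": 6, "other immune": 2},
            signatures=synth.default_signatures(), seed=0,
        )
        t_cells = out[out["gate"] == "T cell"]
        assert (t_cells["population"] == t_cells["true_type"]).mean() >= 0.9

    def test_determinism_given_seed(self):
        cells = noisy_cells(n_per_type=30, seed=8)
        cells["gate"] = "T cell"
        o1 = pheno.subcluster(cells, {"T cell": self.T_FEATURES}, {"T cell": 4}, seed=3)
        o2 = pheno.subcluster(cells, {"T cell": self.T_FEATURES}, {"T cell": 4}, seed=3)
        assert (o1["cluster"] == o2["cluster"]).all()


class TestFrequenciesAndDensities:
    def test_simple_proportions(self):
        cells = pd.DataFrame(
            {"sample_id": "s", "segment": "lamina_propria",
             "population": ["B"] * 30 + ["CD4_T_naive"] * 70}
        )
        areas = pd.DataFrame(
            [{"sample_id": "s", "segment": "lamina_propria", "area_um2": 1000.0}]
        )
        out = pheno.frequencies_and_densities(cells, areas)
        freq = out.set_index("population")["frequency"]
        assert freq["B"] == pytest.approx(0.3)
        assert freq["CD4_T_naive"] == pytest.approx(0.7)
        assert out.set_index("population")["density"]["B"] == pytest.approx(0.03)

    def test_frequencies_sum_to_one_per_stratum(self, small_sample):
        _, truth, _ = small_sample
        cells = truth.rename(columns={"cell_type": "population",
                                      "compartment": "segment"}).copy()
        cells["sample_id"] = "s"
        areas = pd.DataFrame(
            [{"sample_id": "s", "segment": seg, "area_um2": 10000.0}
             for seg in cells["segment"].unique()]
        )
        out = pheno.frequencies_and_densities(cells, areas)
        sums = out.groupby(["sample_id", "segment"])["frequency"].sum()
        assert np.allclose(sums, 1.0)
        # consistency: frequency × segment total = population count
        totals = out.groupby(["sample_id", "segment"])["n"].transform("sum")
        assert np.allclose(out["frequency"] * totals, out["n"])

    def test_zero_area_segment_with_cells_rejected(self):
        cells = pd.DataFrame(
            {"sample_id": "s", "segment": "follicle", "population": ["B"]}
        )
        areas = pd.DataFrame(
            [{"sample_id": "s", "segment": "follicle", "area_um2": 0.0}]
        )
        with pytest.raises(ValueError, match="zero-area"):
            pheno.frequencies_and_densities(cells, areas)

    def test_densities_match_generator_specification(self):
        layout = synth.TissueLayout(width=500, height=500,
                                    epithelium_depth=1, submucosa_depth=1)
        pop = synth.default_population()
        d = 0.0008
        pop.densities = {"lamina_propria": {"B": d}}
        pop.min_separation = 0.0
        mask, _ = synth.generate_layout(layout)
        cells = synth.place_cells(layout, pop, seed=12, tissue_mask=mask)
        cells = cells.rename(columns={"cell_type": "population",
                                      "compartment": "segment"})
        cells["sample_id"] = "s"
        area = float((mask == synth.SEGMENT_CODES["lamina_propria"]).sum())
        areas = pd.DataFrame(
            [{"sample_id": "s", "segment": "lamina_propria", "area_um2": area}]
        )
        out = pheno.frequencies_and_densities(cells, areas)
        dens = out["density"].iloc[0]
        assert abs(dens - d) < 4 * np.sqrt(d / area)
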