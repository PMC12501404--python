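"""B-cell patch detection, expansion, area/size classification and
composition profiling."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint, Point

from imcpatch import graph as graphmod
from imcpatch import patches as patchmod


def grid_points(n_side, spacing, origin=(0.0, 0.0)):
    xs = np.arange(n_side) * spacing + origin[0]
    ys = np.arange(n_side) * spacing + origin[1]
    return np.array([(x, y) for y in ys for x in xs])


def b_table(make_cells, pts, extra_pts=(), extra_types=()):
    pts = np.asarray(pts, dtype=float)
    all_pts = np.vstack([pts, np.asarray(extra_pts, dtype=float).reshape(-1, 2)])
    types = ["B"] * len(pts) + list(extra_types)
    return make_cells(all_pts, types)


class TestDetectPatches:
    def test_nine_cell_component_rejected(self, make_cells):
        pts = grid_points(3, 10.0)  # 9 cells, all within 20 µm of neighbours
        cells = b_table(make_cells, pts)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        assert patchmod.detect_patches(cells, g) == []

    def test_ten_cell_component_accepted(self, make_cells):
        pts = np.vstack([grid_points(3, 10.0), [[10.0, 25.0]]])
        cells = b_table(make_cells, pts)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patches = patchmod.detect_patches(cells, g)
        assert len(patches) == 1
        assert patches[0].n_core == 10

    def test_planted_follicle_core_recovered_exactly(self, make_cells):
        pts = grid_points(8, 12.0)  # 64 B cells, spacing under the cutoff
        cells = b_table(make_cells, pts)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patches = patchmod.detect_patches(cells, g)
        assert len(patches) == 1
        assert set(patches[0].core_cell_ids) == set(cells.cell_id)

    def test_two_clusters_beyond_cutoff_separate(self, make_cells):
        a = grid_points(4, 10.0)
        b = grid_points(4, 10.0, origin=(60.0, 0.0))  # 25 µm gap edge-to-edge
        cells = b_table(make_cells, np.vstack([a, b]))
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patches = patchmod.detect_patches(cells, g)
        assert len(patches) == 2
        cores = [set(p.core_cell_ids) for p in patches]
        assert cores[0].isdisjoint(cores[1])

    def test_non_b_cells_never_in_cores(self, make_cells):
        pts = grid_points(4, 10.0)
        cells = b_table(make_cells, pts, extra_pts=[(15.0, 15.0)], extra_types=["CD4_T_naive"])
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patches = patchmod.detect_patches(cells, g)
        t_id = cells.loc[cells.population != "B", "cell_id"].iloc[0]
        assert all(t_id not in p.core_cell_ids for p in patches)

    def test_no_b_cells_empty_result(self, make_cells):
        cells = b_table(make_cells, np.empty((0, 2)),
                        extra_pts=grid_points(4, 10.0),
                        extra_types=["CD4_T_naive"] * 16)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        assert patchmod.detect_patches(cells, g) == []

    def test_cores_partition_their_b_cells(self, make_cells):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 400, (300, 2))
        cells = b_table(make_cells, pts)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patches = patchmod.detect_patches(cells, g)
        seen = []
        for p in patches:
            seen += list(p.core_cell_ids)
        assert len(seen) == len(set(seen))


class TestExpandPatch:
    def _patch_with_neighbours(self, make_cells, t_offset):
        pts = grid_points(4, 10.0)  # hull [0,30]²
        cells = b_table(make_cells, pts, extra_pts=[t_offset], extra_types=["CD4_T_naive"])
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patch = patchmod.detect_patches(cells, g)[0]
        return patch, cells

    def test_cell_within_buffer_included(self, make_cells):
        patch, cells = self._patch_with_neighbours(make_cells, (30.5, 15.0))
        patch = patchmod.expand_patch(patch, cells, distance=1.0)
        t_id = cells.loc[cells.population != "B", "cell_id"].iloc[0]
        assert t_id in patch.expanded_cell_ids

    def test_cell_beyond_buffer_excluded(self, make_cells):
        patch, cells = self._patch_with_neighbours(make_cells, (35.0, 15.0))
        patch = patchmod.expand_patch(patch, cells, distance=1.0)
        t_id = cells.loc[cells.population != "B", "cell_id"].iloc[0]
        assert t_id not in patch.expanded_cell_ids
        assert set(patch.core_cell_ids) <= set(patch.expanded_cell_ids)

    def test_zero_distance_matches_hull_membership_and_monotone(self, make_cells):
        rng = np.random.default_rng(1)
        core = rng.uniform(0, 50, (15, 2))
        others = rng.uniform(-10, 60, (40, 2))
        cells = b_table(make_cells, core, extra_pts=others,
                        extra_types=["CD4_T_naive"] * 40)
        g = graphmod.build_delaunay_graph(cells, 60.0)
        patch = patchmod.detect_patches(cells, g)[0]
        m0 = set(patchmod.expand_patch(patch, cells, distance=0.0).expanded_cell_ids)
        core_xy = (
            cells.set_index("cell_id")
            .loc[patch.core_cell_ids, ["x_um", "y_um"]]
            .to_numpy()
        )
        hull = MultiPoint([tuple(p) for p in core_xy]).convex_hull
        oracle = {
            row.cell_id
            for row in cells.itertuples()
            if hull.covers(Point(row.x_um, row.y_um))
        } | set(patch.core_cell_ids)
        assert m0 == oracle
        prev = m0
        for d in (1.0, 3.0, 8.0):
            md = set(patchmod.expand_patch(patch, cells, distance=d).expanded_cell_ids)
            assert prev <= md
            prev = md


class TestAreaAndClass:
    def _patch_from_pts(self, make_cells, pts):
        cells = b_table(make_cells, pts)
        patch = patchmod.Patch(
            patch_id=0, image_id="img",
            core_cell_ids=cells.cell_id.to_numpy(),
        )
        return patch, cells

    def test_right_triangle_area(self, make_cells):
        # 10 cells whose hull is a right triangle with legs 100 µm
        pts = [(0, 0), (100, 0), (0, 100), (10, 10), (20, 10), (10, 20),
               (30, 30), (40, 20), (20, 40), (50, 10)]
        patch, cells = self._patch_from_pts(make_cells, pts)
        patch = patchmod.patch_area_and_class(patch, cells, distance=0.0)
        assert patch.area_um2 == pytest.approx(5000.0)
        assert patch.size_class == "small"

    def test_exactly_threshold_area_is_small(self, make_cells):
        # rectangle 100 × 120 = 12,000 µm² exactly; strict > rule keeps small
        pts = [(0, 0), (100, 0), (0, 120), (100, 120)] + [
            (10 * i, 60) for i in range(1, 7)
        ]
        patch, cells = self._patch_from_pts(make_cells, pts)
        patch = patchmod.patch_area_and_class(patch, cells, distance=0.0,
                                              large_threshold=12000.0)
        assert patch.area_um2 == pytest.approx(12000.0)
        assert patch.size_class == "small"

    def test_square_lattice_area_with_buffer_is_large(self, make_cells):
        pts = grid_points(13, 10.0)  # 120 × 120 µm square hull
        patch, cells = self._patch_from_pts(make_cells, pts)
        patch = patchmod.patch_area_and_class(patch, cells, distance=1.0)
        expected = 14400 + 4 * 120 * 1.0 + np.pi * 1.0**2
        assert patch.area_um2 == pytest.approx(expected, rel=0.03)
        assert patch.size_class == "large"


class TestComposition:
    def test_pure_b_patch_one_hot(self, make_cells):
        pts = grid_points(4, 10.0)
        cells = b_table(make_cells, pts)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patch = patchmod.detect_patches(cells, g)[0]
        patch = patchmod.expand_patch(patch, cells)
        comp = patchmod.patch_composition(patch, cells)
        ct = comp[comp.kind == "cell_type"]
        assert len(ct) == 1
        assert ct.iloc[0]["name"] == "B"
        assert ct.iloc[0].frequency == 1.0

    def test_frequencies_sum_to_one(self, make_cells):
        pts = grid_points(4, 10.0)
        cells = b_table(make_cells, pts, extra_pts=[(15, 15), (25, 12)],
                        extra_types=["CD4_T_naive", "CD8_T_naive"])
        nb = pd.Series("NB0", index=cells.cell_id)
        g = graphmod.build_delaunay_graph(cells, 20.0)
        patch = patchmod.detect_patches(cells, g)[0]
        patch = patchmod.expand_patch(patch, cells)
        comp = patchmod.patch_composition(patch, cells, neighbourhood_labels=nb)
        for kind, df in comp.groupby("kind"):
            assert df.frequency.sum() == pytest.approx(1.0)

    def test_t_infiltrated_core_has_more_t_neighbourhoods(self, make_cells):
        """A mixed (T-infiltrated) patch shows a higher frequency of
        T-enriched neighbourhood classes than a pure-B patch."""
        from imcpatch import neighbourhoods as nbh

        pure = grid_points(8, 10.0)  # pure-B aggregate
        mixed_b = grid_points(5, 12.0, origin=(400.0, 0.0))
        mixed_t = grid_points(4, 12.0, origin=(406.0, 6.0))
        pts = np.vstack([pure, mixed_b])
        cells = b_table(make_cells, pts, extra_pts=mixed_t,
                        extra_types=["CD4_T_mature"] * len(mixed_t))
        g = graphmod.build_delaunay_graph(cells, 20.0)
        gr = graphmod.build_radius_graph(cells, 20.0)
        prof = nbh.neighbourhood_profiles(cells, gr)
        model = nbh.annotate_neighbourhoods(nbh.fit_neighbourhoods(prof, k=3, seed=0))
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
        assert len(patches) == 2
        freqs = []
        for p in patches:
            p = patchmod.expand_patch(p, cells)
            comp = patchmod.patch_composition(p, cells, neighbourhood_labels=nb_label)
            nbf = comp[(comp.kind == "neighbourhood") & comp["name"].isin(t_classes)]
            freqs.append(nbf.frequency.sum())
        pure_freq, mixed_freq = freqs[0], freqs[1]
        assert mixed_freq > pure_freq


def test_analyse_patches_table(make_cells):
    pts = grid_points(6, 10.0)
    cells = b_table(make_cells, pts)
    cells["segment"] = "follicle"
    g = graphmod.build_delaunay_graph(cells, 20.0)
    table, comp, patches = patchmod.analyse_patches(cells, g)
    assert len(table) == 1
    row = table.iloc[0]
    assert row.n_core == 36
    assert row.segment == "follicle"
    assert row.size_class == "small"
    assert row.n_expanded >= row.n_core
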