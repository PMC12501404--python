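# imcpatch

Spatial immune profiling of imaging mass cytometry (IMC) data from
gut-associated lymphoid tissue — built for studying how B-cell follicles and
their surrounding immune micro-environments are organized in intestinal
biopsies (e.g. Peyer's patches in health and Crohn's disease).

IMC produces multichannel images (one channel per metal-tagged antibody,
~1 µm/pixel). Given such images plus cell- and tissue-segmentation masks,
`imcpatch` runs the downstream analysis:

1. **Background correction** per channel with the silver mountain operator
   (SMO): pixels whose local gradient directions are incoherent are
   background-like; the median intensity over that sample is subtracted.
2. **Per-cell quantification**: mean marker intensity per segmentation
   label, area (µm²), centroid, tissue-segment assignment; arcsinh
   normalization (cofactor 1), 1st–99th percentile clipping per sample, and
   a 15–250 µm² size filter.
3. **Phenotyping**: hierarchical gating (CD45 / E-Cadherin, then CD3 /
   CD20), random-forest probability features to sharpen difficult T-cell
   splits, k-means subclustering per gate with an annotation merge map.
4. **Cell–cell interaction testing**: for each ordered type pair (A, B) on
   an image, the statistic T(A,B) = mean number of B neighbours per A cell
   on the Delaunay graph pruned to ≤ 20 µm. Significance comes from a
   label-shuffle permutation null: p_attraction = (1 + #{T\* ≥ T_obs}) /
   (1 + n_perm), analogously for avoidance, globally and within tissue
   regions (shuffling restricted to the region), with log₂ region-ratio
   summaries.
5. **Cellular neighbourhoods**: per-cell composition vectors over a 20 µm
   radius, k-means (40 centres by default, sweep-assisted), two-level
   annotation (dominant population, then co-enriched ones).
6. **B-cell patch detection**: connected components of ≥ 10 interacting
   B cells on the pruned Delaunay graph, expanded by 1 µm; buffered-hull
   area classifies patches as large when strictly above 12,000 µm².
7. **Group statistics**: PCA with feature contributions, Wilcoxon rank-sum
   tests with Benjamini–Hochberg correction, and standard figures.

A first-class **synthetic tissue generator** (`imcpatch.synth`) emulates the
assumed data structure — tissue compartments, marker-signature cell types
with lognormal noise, follicle cores and T-cell mantles, planted
attraction/avoidance and planted B-cell patches — so every stage is testable
with known ground truth and no access to original study data.

## Worked example

Run the full pipeline on a 4-sample synthetic cohort (two groups, one
600×600 µm image per sample, one 80 µm-radius follicle and one planted
15-cell B aggregate each):

```python
from imcpatch.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(), seed=1, out_dir="demo_run")
print(res["patches"][["image_id", "n_core", "area_um2", "size_class", "segment"]])
```

```
 image_id  n_core     area_um2 size_class        segment
      S01      17   963.568405      small lamina_propria
      S01     142 23317.659466      large       follicle
      S02     145 25146.081493      large       follicle
      S02      12   642.189184      small lamina_propria
      ...
```

Each sample yields one *large* patch (the planted follicle: ~140-cell core,
area well above the 12,000 µm² threshold, located in the follicle segment)
and one *small* patch (the planted aggregate in the lamina propria) —
exactly the planted structure. The interaction analysis on the same run
calls B–B attraction in every image (e.g. S01: T(B,B) = 2.43 neighbours per
B cell, p = 0.005 at 200 permutations), and the LP-vs-follicle log₂ ratio
for (B, B) is −2.19: B–B contacts are follicle-enriched, as the follicular
geometry dictates.

The same stages are available from the shell:

```sh
imcpatch simulate --seed 3 --out-dir sim/
imcpatch preprocess --sample-dir sim/ --out cells.csv
imcpatch run --seed 1 --n-samples 4 --out-dir demo_run/
imcpatch report --run-dir demo_run/
```

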