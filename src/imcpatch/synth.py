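"""Synthetic tissue generator for imaging-mass-cytometry-like data.

Produces multichannel intensity images (1 µm/pixel), cell and tissue label
masks, and a ground-truth cell table with the spatial and intensity
structure the downstream analysis assumes: tissue compartments (epithelium,
lamina propria, lymphoid follicles, submucosa, background), cell types with
a marker-signature matrix plus lognormal noise and additive background,
spatially structured placement (B-cell follicle cores, T-cell mantles,
scattered lamina-propria populations), planted pairwise attraction and
avoidance, and planted B-cell patches of controlled size.

All randomness flows from a single seed that fans out to per-stage child
seeds recorded in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# Tissue-segment label codes used in every tissue mask.
SEGMENT_CODES = {
    "background": 0,
    "epithelium": 1,
    "lamina_propria": 2,
    "follicle": 3,
    "submucosa": 4,
}
SEGMENT_NAMES = {v: k for k, v in SEGMENT_CODES.items()}

# Placement zones refine the mask compartments: the follicle mantle is a ring
# of lamina propria around each follicle where T cells concentrate.
PLACEMENT_ZONES = (
    "epithelium",
    "lamina_propria",
    "follicle",
    "follicle_mantle",
    "submucosa",
)

NUCLEAR_MARKERS = ("DNA1", "HistoneH3")


class LayoutConflictError(ValueError):
    """Raised when follicle geometries overlap or leave the tissue."""


@dataclass(frozen=True)
class FollicleSpec:
    """A circular lymphoid follicle: B-cell core plus surrounding mantle."""

    cx: float
    cy: float
    radius: float
    mantle_width: float = 20.0


@dataclass(frozen=True)
class SmallPatchSpec:
    """A planted small B-cell aggregate of controlled cell count.

    Cells are laid out deterministically on concentric rings with the given
    spacing, so the aggregate forms one connected component on any spatial
    graph with cutoff > spacing.
    """

    cx: float
    cy: float
    n_cells: int
    spacing: float = 8.0
    cell_type: str = "B"


@dataclass
class TissueLayout:
    """Geometry of one synthetic tissue image at 1 µm/pixel.

    The tissue is a rectangle with a background margin frame; inside it, an
    epithelial band at the top, a submucosal band at the bottom, circular
    follicles, and the remaining area as lamina propria.
    """

    width: int = 600
    height: int = 600
    margin: int = 20
    epithelium_depth: int = 60
    submucosa_depth: int = 60
    follicles: list[FollicleSpec] = field(default_factory=list)
    small_patches: list[SmallPatchSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("layout dimensions must be positive")
        interior_h = self.height - 2 * self.margin
        if self.epithelium_depth + self.submucosa_depth >= interior_h:
            raise LayoutConflictError("bands leave no lamina propria")
        for f in self.follicles:
            if f.radius <= 0:
                raise LayoutConflictError("follicle radius must be > 0")
            if (
                f.cx - f.radius < self.margin
                or f.cx + f.radius > self.width - self.margin
                or f.cy - f.radius < self.margin
                or f.cy + f.radius > self.height - self.margin
            ):
                raise LayoutConflictError(
                    f"follicle at ({f.cx}, {f.cy}) r={f.radius} leaves the tissue"
                )
        for i, a in enumerate(self.follicles):
            for b in self.follicles[i + 1 :]:
                d = np.hypot(a.cx - b.cx, a.cy - b.cy)
                if d < a.radius + b.radius:
                    raise LayoutConflictError(
                        f"follicles at ({a.cx},{a.cy}) and ({b.cx},{b.cy}) overlap"
                    )


@dataclass
class PopulationSpec:
    """Cell populations, their spatial densities and marker signatures.

    densities: zone -> {cell type -> cells/µm²}; zones from PLACEMENT_ZONES.
    signatures: DataFrame indexed by cell type, columns = markers, mean ion
        counts per pixel.
    noise_sigma: lognormal σ per marker (multiplicative per-cell noise).
    background: additive background ion count per marker.
    radius: (mean, sd) of the cell-disc radius in µm per type; truncated ≥ 1.
    attraction_rules: (parent type, child type, displacement scale µm,
        fraction of children attached) — attached children are re-placed at a
        random parent plus an isotropic Gaussian displacement (Thomas style).
    avoidance_rules: (parent type, child type, exclusion distance µm) —
        children falling within the distance of any parent are re-sampled.
    """

    signatures: pd.DataFrame
    densities: dict[str, dict[str, float]]
    noise_sigma: dict[str, float]
    background: dict[str, float]
    radius: dict[str, tuple[float, float]]
    attraction_rules: list[tuple[str, str, float, float]] = field(default_factory=list)
    avoidance_rules: list[tuple[str, str, float]] = field(default_factory=list)
    min_separation: float = 4.0

    @property
    def cell_types(self) -> list[str]:
        return list(self.signatures.index)

    @property
    def markers(self) -> list[str]:
        return list(self.signatures.columns)

    def validate(self, interaction_cutoff: float = 20.0) -> None:
        if (self.signatures.values < 0).any():
            raise ValueError("signature matrix must be non-negative")
        for zone, dens in self.densities.items():
            if zone not in PLACEMENT_ZONES:
                raise ValueError(f"unknown placement zone {zone!r}")
            for t, d in dens.items():
                if t not in self.signatures.index:
                    raise ValueError(f"density given for unknown type {t!r}")
                if d < 0:
                    raise ValueError("densities must be >= 0")
        for parent, child, scale, frac in self.attraction_rules:
            if scale >= interaction_cutoff:
                raise ValueError(
                    "attraction displacement scale must stay below the "
                    f"interaction cutoff ({interaction_cutoff} µm)"
                )
            if not 0 <= frac <= 1:
                raise ValueError("attraction fraction must be in [0, 1]")
        # every pair of types must differ on at least one marker
        sig = self.signatures.values
        for i in range(len(sig)):
            for j in range(i + 1, len(sig)):
                if np.allclose(sig[i], sig[j]):
                    raise ValueError(
                        f"types {self.signatures.index[i]!r} and "
                        f"{self.signatures.index[j]!r} share a signature"
                    )


@dataclass
class ImageBundle:
    """Co-registered multichannel stack + cell/tissue label masks, 1 µm/pixel."""

    channels: np.ndarray  # (C, H, W) float32
    channel_names: list[str]
    cell_mask: np.ndarray  # (H, W) uint16/uint32 labels, 0 = background
    tissue_mask: np.ndarray  # (H, W) uint16 segment codes
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


# ---------------------------------------------------------------------------
# default study conditions


def default_markers() -> list[str]:
    return [
        "DNA1", "HistoneH3", "CD45", "ECadherin", "CD3", "CD20", "CD4",
        "CD8a", "CD45RA", "CD45RO", "CD38", "FOXP3", "CD14", "CD68",
    ]


def default_signatures() -> pd.DataFrame:
    """Mean ion-count signature per cell type (rows) and marker (columns).

    Chosen to mimic a lineage-marker IMC panel: all cells carry nuclear
    signal; immune cells are CD45+, epithelium E-Cadherin+; T cells split on
    CD3/CD4/CD8 with naive (CD45RA) vs mature (CD45RO) memory markers.
    """
    markers = default_markers()
    rows = {
        "B":            {"CD45": 30, "CD20": 25},
        "CD4_T_naive":  {"CD45": 30, "CD3": 20, "CD4": 15, "CD45RA": 15},
        "CD4_T_mature": {"CD45": 30, "CD3": 20, "CD4": 15, "CD45RO": 15},
        "CD8_T_naive":  {"CD45": 30, "CD3": 20, "CD8a": 15, "CD45RA": 15},
        "CD8_T_mature": {"CD45": 30, "CD3": 20, "CD8a": 15, "CD45RO": 15},
        "CD8_T_CD38":   {"CD45": 30, "CD3": 20, "CD8a": 15, "CD45RO": 8, "CD38": 18},
        "Treg":         {"CD45": 30, "CD3": 20, "CD4": 12, "FOXP3": 15, "CD45RO": 6},
        "monocyte":     {"CD45": 25, "CD14": 20},
        "macrophage":   {"CD45": 25, "CD68": 20, "CD14": 5},
        "epithelial":   {"ECadherin": 30},
    }
    sig = pd.DataFrame(0.0, index=list(rows), columns=markers)
    for t, vals in rows.items():
        sig.loc[t, "DNA1"] = 20.0
        sig.loc[t, "HistoneH3"] = 15.0
        for m, v in vals.items():
            sig.loc[t, m] = float(v)
    return sig


def default_population() -> PopulationSpec:
    """Default densities approximating gut mucosa: dense B-cell follicle
    cores, T-cell mantles, and scattered lamina-propria immune populations."""
    sig = default_signatures()
    densities = {
        "follicle": {"B": 0.008, "CD4_T_mature": 0.0008},
        "follicle_mantle": {
            "B": 0.002,
            "CD4_T_naive": 0.002, "CD4_T_mature": 0.002,
            "CD8_T_naive": 0.001, "CD8_T_mature": 0.001,
        },
        "lamina_propria": {
            "B": 0.0008,
            "CD4_T_naive": 0.0006, "CD4_T_mature": 0.0006,
            "CD8_T_naive": 0.0005, "CD8_T_mature": 0.0005,
            "CD8_T_CD38": 0.0003, "Treg": 0.0003,
            "monocyte": 0.0004, "macrophage": 0.0004,
        },
        "epithelium": {"epithelial": 0.010},
        "submucosa": {"CD4_T_mature": 0.0003, "monocyte": 0.0002},
    }
    radius = {t: (3.5, 0.5) for t in sig.index}
    radius["epithelial"] = (4.0, 0.5)
    radius["macrophage"] = (4.5, 0.5)
    noise = {m: 0.3 for m in sig.columns}
    background = {m: 0.5 for m in sig.columns}
    return PopulationSpec(
        signatures=sig,
        densities=densities,
        noise_sigma=noise,
        background=background,
        radius=radius,
    )


def default_layout() -> TissueLayout:
    return TissueLayout(
        width=600,
        height=600,
        follicles=[FollicleSpec(cx=200.0, cy=330.0, radius=80.0)],
        small_patches=[SmallPatchSpec(cx=470.0, cy=330.0, n_cells=15)],
    )


# ---------------------------------------------------------------------------
# layout


def generate_layout(layout: TissueLayout, seed: int = 0):
    """Rasterize a TissueLayout into a tissue label mask plus ground truth.

    Returns (mask, truth) where mask is (H, W) uint16 of SEGMENT_CODES and
    truth is a DataFrame of follicle and planted-patch records (centre,
    radius, analytic and pixel area). Deterministic for a given layout; the
    seed is accepted for interface symmetry and recorded upstream.
    """
    layout.validate()
    h, w, m = layout.height, layout.width, layout.margin
    mask = np.zeros((h, w), dtype=np.uint16)
    mask[m : h - m, m : w - m] = SEGMENT_CODES["lamina_propria"]
    mask[m : m + layout.epithelium_depth, m : w - m] = SEGMENT_CODES["epithelium"]
    mask[h - m - layout.submucosa_depth : h - m, m : w - m] = SEGMENT_CODES["submucosa"]

    yy, xx = np.mgrid[0:h, 0:w]
    records = []
    for i, f in enumerate(layout.follicles):
        disc = (xx + 0.5 - f.cx) ** 2 + (yy + 0.5 - f.cy) ** 2 <= f.radius**2
        mask[disc] = SEGMENT_CODES["follicle"]
        records.append(
            {
                "kind": "follicle",
                "id": i,
                "cx": f.cx,
                "cy": f.cy,
                "radius": f.radius,
                "area_analytic_um2": np.pi * f.radius**2,
                "area_pixels_um2": int(disc.sum()),
                "n_cells": np.nan,
            }
        )
    for j, p in enumerate(layout.small_patches):
        records.append(
            {
                "kind": "small_patch",
                "id": j,
                "cx": p.cx,
                "cy": p.cy,
                "radius": np.nan,
                "area_analytic_um2": np.nan,
                "area_pixels_um2": np.nan,
                "n_cells": p.n_cells,
            }
        )
    truth = pd.DataFrame(
        records,
        columns=["kind", "id", "cx", "cy", "radius",
                 "area_analytic_um2", "area_pixels_um2", "n_cells"],
    )
    return mask, truth


def placement_zone_masks(layout: TissueLayout, tissue_mask: np.ndarray):
    """Zone masks for cell placement; the mantle ring is carved out of LP."""
    h, w = tissue_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    zones = {
        "epithelium": tissue_mask == SEGMENT_CODES["epithelium"],
        "follicle": tissue_mask == SEGMENT_CODES["follicle"],
        "submucosa": tissue_mask == SEGMENT_CODES["submucosa"],
    }
    lp = tissue_mask == SEGMENT_CODES["lamina_propria"]
    mantle = np.zeros_like(lp)
    for f in layout.follicles:
        r2 = (xx + 0.5 - f.cx) ** 2 + (yy + 0.5 - f.cy) ** 2
        ring = (r2 > f.radius**2) & (r2 <= (f.radius + f.mantle_width) ** 2)
        mantle |= ring & lp
    zones["follicle_mantle"] = mantle
    zones["lamina_propria"] = lp & ~mantle
    return zones


# ---------------------------------------------------------------------------
# cell placement


def _patch_ring_positions(spec: SmallPatchSpec) -> np.ndarray:
    """Deterministic concentric-ring layout for a planted aggregate."""
    pts = [(spec.cx, spec.cy)]
    ring = 1
    while len(pts) < spec.n_cells:
        r = ring * spec.spacing
        n_on_ring = max(1, int(np.floor(2 * np.pi * r / spec.spacing)))
        for k in range(n_on_ring):
            if len(pts) >= spec.n_cells:
                break
            theta = 2 * np.pi * k / n_on_ring
            pts.append((spec.cx + r * np.cos(theta), spec.cy + r * np.sin(theta)))
        ring += 1
    return np.array(pts[: spec.n_cells])


def place_cells(
    layout: TissueLayout,
    pop: PopulationSpec,
    seed: int = 0,
    tissue_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Place cells by homogeneous Poisson sampling within each zone.

    Minimum centre separation is enforced by greedy thinning; attraction
    rules re-place a fraction of child cells at a parent plus isotropic
    Gaussian displacement; avoidance rules re-sample children that land
    within the exclusion distance of a parent. Planted small-patch cells are
    laid out deterministically and exempt from thinning.

    Returns a cell table with columns cell_id, x_um, y_um, radius_um,
    cell_type, zone, compartment, planted_patch_id.
    """
    layout.validate()
    pop.validate()
    if tissue_mask is None:
        tissue_mask, _ = generate_layout(layout, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    zones = placement_zone_masks(layout, tissue_mask)

    xs, ys, types, zone_names, patch_ids = [], [], [], [], []
    for zone in PLACEMENT_ZONES:
        dens = pop.densities.get(zone, {})
        zmask = zones[zone]
        idx = np.flatnonzero(zmask)
        if idx.size == 0:
            continue
        area = idx.size  # µm² at 1 µm/pixel
        w = tissue_mask.shape[1]
        for ctype, d in dens.items():
            n = rng.poisson(d * area)
            if n == 0:
                continue
            pix = rng.choice(idx, size=n, replace=True)
            py, px = np.divmod(pix, w)
            xs.append(px + rng.random(n))
            ys.append(py + rng.random(n))
            types += [ctype] * n
            zone_names += [zone] * n
            patch_ids += [-1] * n

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        x = np.empty(0)
        y = np.empty(0)
    types = np.array(types, dtype=object)
    zone_names = np.array(zone_names, dtype=object)
    patch_ids = np.array(patch_ids, dtype=int)

    # avoidance: re-sample children near parents
    for parent, child, dist in pop.avoidance_rules:
        pmask = types == parent
        cmask = types == child
        if not pmask.any() or not cmask.any():
            continue
        tree = cKDTree(np.column_stack([x[pmask], y[pmask]]))
        cidx = np.flatnonzero(cmask)
        for i in cidx:
            for _ in range(50):
                if tree.query(np.array([x[i], y[i]]), k=1)[0] > dist:
                    break
                zmask = zones[zone_names[i]]
                pix = rng.choice(np.flatnonzero(zmask))
                py, px = np.divmod(pix, tissue_mask.shape[1])
                x[i] = px + rng.random()
                y[i] = py + rng.random()

    # greedy thinning for minimum centre separation (before attraction so
    # attached children are not deleted for sitting close to their parent)
    keep = np.ones(x.size, dtype=bool)
    if x.size > 1 and pop.min_separation > 0:
        tree = cKDTree(np.column_stack([x, y]))
        for i, j in sorted(tree.query_pairs(pop.min_separation)):
            if keep[i] and keep[j]:
                keep[j] = False
        n_dropped = int((~keep).sum())
        if n_dropped > 0.2 * x.size:
            warnings.warn(
                f"separation thinning removed {n_dropped}/{x.size} cells; "
                "requested densities not achievable at "
                f"min_separation={pop.min_separation} µm",
                stacklevel=2,
            )
    x, y = x[keep], y[keep]
    types, zone_names, patch_ids = types[keep], zone_names[keep], patch_ids[keep]

    # attraction: attach a fraction of children to random parents, keeping
    # the separation constraint by re-drawing the displacement when needed
    for parent, child, scale, frac in pop.attraction_rules:
        pmask = types == parent
        cidx = np.flatnonzero(types == child)
        if not pmask.any() or cidx.size == 0 or frac == 0:
            continue
        n_att = int(round(frac * cidx.size))
        chosen = rng.choice(cidx, size=n_att, replace=False)
        pchoice = rng.choice(np.flatnonzero(pmask), size=n_att, replace=True)
        others = np.delete(np.arange(x.size), chosen)
        tree = cKDTree(np.column_stack([x[others], y[others]])) if others.size else None
        h, w = tissue_mask.shape
        placed_xy = []
        for ci, pi in zip(chosen, pchoice):
            best = None
            for _ in range(30):
                nx = float(np.clip(x[pi] + rng.normal(0, scale), 0.5, w - 0.5))
                ny = float(np.clip(y[pi] + rng.normal(0, scale), 0.5, h - 0.5))
                best = (nx, ny)
                ok = tree is None or tree.query([nx, ny], k=1)[0] >= pop.min_separation
                if ok and all(
                    np.hypot(nx - px, ny - py) >= pop.min_separation
                    for px, py in placed_xy[-8:]
                ):
                    break
            x[ci], y[ci] = best
            placed_xy.append(best)

    # planted small patches: deterministic ring layouts, exempt from thinning
    for j, spec in enumerate(layout.small_patches):
        pts = _patch_ring_positions(spec)
        x = np.concatenate([x, pts[:, 0]])
        y = np.concatenate([y, pts[:, 1]])
        types = np.concatenate([types, np.array([spec.cell_type] * len(pts), dtype=object)])
        zone_names = np.concatenate([zone_names, np.array(["lamina_propria"] * len(pts), dtype=object)])
        patch_ids = np.concatenate([patch_ids, np.full(len(pts), j)])

    h, w = tissue_mask.shape
    pix_x = np.clip(x.astype(int), 0, w - 1)
    pix_y = np.clip(y.astype(int), 0, h - 1)
    compartment = [SEGMENT_NAMES[int(c)] for c in tissue_mask[pix_y, pix_x]]

    radius = np.array(
        [max(1.0, rng.normal(*pop.radius[t])) for t in types], dtype=float
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, x.size + 1),
            "x_um": x,
            "y_um": y,
            "radius_um": radius,
            "cell_type": types,
            "zone": zone_names,
            "compartment": compartment,
            "planted_patch_id": patch_ids,
        }
    )
    return cells


# ---------------------------------------------------------------------------
# rendering


def render_images(
    cells: pd.DataFrame,
    pop: PopulationSpec,
    tissue_mask: np.ndarray,
    seed: int = 0,
    read_noise_sd: float = 0.0,
    metadata: dict | None = None,
) -> ImageBundle:
    """Render cells into a multichannel intensity stack and a cell mask.

    The cell mask paints each cell as a disc of its radius; overlapping
    pixels go to the smaller cell id. Each channel is the cell's signature
    mean scaled by one lognormal factor per cell, plus a constant additive
    background, plus optional Gaussian read noise, floored at zero.
    """
    h, w = tissue_mask.shape
    if len(cells) and (
        (cells.x_um < 0).any() or (cells.x_um > w).any()
        or (cells.y_um < 0).any() or (cells.y_um > h).any()
    ):
        raise ValueError("cell positions outside layout bounds")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    markers = pop.markers
    sig = pop.signatures

    dtype = np.uint16 if len(cells) < 65535 else np.uint32
    cell_mask = np.zeros((h, w), dtype=dtype)
    channels = np.empty((len(markers), h, w), dtype=np.float32)
    for ci, m in enumerate(markers):
        channels[ci].fill(pop.background.get(m, 0.0))

    sigma = np.array([pop.noise_sigma.get(m, 0.0) for m in markers])
    # increasing cell_id order: earlier (smaller) ids win overlapping pixels
    for row in cells.sort_values("cell_id").itertuples():
        r = row.radius_um
        x0, x1 = max(0, int(row.x_um - r) - 1), min(w, int(row.x_um + r) + 2)
        y0, y1 = max(0, int(row.y_um - r) - 1), min(h, int(row.y_um + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (xx + 0.5 - row.x_um) ** 2 + (yy + 0.5 - row.y_um) ** 2 <= r**2
        free = disc & (cell_mask[y0:y1, x0:x1] == 0)
        if not free.any():
            continue
        sub = cell_mask[y0:y1, x0:x1]
        sub[free] = row.cell_id
        factors = np.where(sigma > 0, np.exp(rng.normal(0.0, np.maximum(sigma, 1e-12))), 1.0)
        means = sig.loc[row.cell_type].to_numpy() * factors
        fy, fx = np.nonzero(free)
        channels[:, y0 + fy, x0 + fx] += means[:, None].astype(np.float32)

    if read_noise_sd > 0:
        channels += rng.normal(0, read_noise_sd, channels.shape).astype(np.float32)
        np.maximum(channels, 0, out=channels)

    meta = dict(metadata or {})
    meta.setdefault("render_seed", int(seed))
    return ImageBundle(
        channels=channels,
        channel_names=list(markers),
        cell_mask=cell_mask,
        tissue_mask=tissue_mask.astype(np.uint16),
        metadata=meta,
    )


def simulate_sample(
    layout: TissueLayout,
    pop: PopulationSpec,
    seed: int = 0,
    read_noise_sd: float = 0.0,
):
    """Full generator run: layout -> cells -> images.

    Returns (bundle, truth_cells, layout_truth). One master seed fans out to
    child seeds per stage, all recorded in bundle.metadata.
    """
    ss = np.random.SeedSequence(seed)
    s_layout, s_cells, s_render = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    tissue_mask, layout_truth = generate_layout(layout, s_layout)
    cells = place_cells(layout, pop, s_cells, tissue_mask=tissue_mask)
    bundle = render_images(
        cells, pop, tissue_mask, s_render, read_noise_sd=read_noise_sd,
        metadata={
            "seed": int(seed),
            "layout_seed": s_layout,
            "cells_seed": s_cells,
            "render_seed": s_render,
        },
    )
    return bundle, cells, layout_truth


# ---------------------------------------------------------------------------
# I/O


def write_sample(out_dir, bundle: ImageBundle, cells: pd.DataFrame, pop: PopulationSpec):
    """Write a simulated sample: multi-page TIFF stack (channel order =
    panel order), 16-bit label masks, panel and ground-truth cell CSVs."""
    import json
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "channels.tiff", bundle.channels)
    tifffile.imwrite(out / "cell_mask.tiff", bundle.cell_mask)
    tifffile.imwrite(out / "tissue_mask.tiff", bundle.tissue_mask)
    pd.DataFrame({"marker": bundle.channel_names}).to_csv(out / "panel.csv", index=False)
    cells.to_csv(out / "cells_truth.csv", index=False)
    pop.signatures.to_csv(out / "signatures.csv")
    (out / "metadata.json").write_text(json.dumps(bundle.metadata, indent=1))


def read_sample(in_dir):
    """Read back a sample written by write_sample -> (bundle, truth cells)."""
    import json
    from pathlib import Path

    import tifffile

    p = Path(in_dir)
    channels = tifffile.imread(p / "channels.tiff")
    panel = pd.read_csv(p / "panel.csv")["marker"].tolist()
    meta = json.loads((p / "metadata.json").read_text()) if (p / "metadata.json").exists() else {}
    bundle = ImageBundle(
        channels=np.asarray(channels, dtype=np.float32),
        channel_names=panel,
        cell_mask=tifffile.imread(p / "cell_mask.tiff"),
        tissue_mask=tifffile.imread(p / "tissue_mask.tiff"),
        metadata=meta,
    )
    cells = pd.read_csv(p / "cells_truth.csv")
    return bundle, cells
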