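"""Image preprocessing: background correction, per-cell feature extraction,
tissue-segment assignment, intensity normalization and cell filtering.

Background correction uses the silver mountain operator (SMO): the local
coherence of gradient directions separates structured foreground from
direction-incoherent background, giving an unbiased sample of background
pixels from which a scalar background level is estimated and subtracted.

Per-cell features are mean marker intensities over each segmentation label,
area in µm² (pixel count at 1 µm/pixel) and the centroid in µm. Intensities
are arcsinh-transformed (cofactor 1 by default), percentile-clipped per
sample batch, and cells outside a plausible size window (15–250 µm² by
default) are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops_table

from .synth import SEGMENT_NAMES, ImageBundle


@dataclass(frozen=True)
class SMOParams:
    """Silver-mountain-operator settings.

    sigma: Gaussian pre-smoothing scale in pixels.
    size: side of the square averaging window (odd, ≥ 3).
    threshold: quantile of the SMO statistic below which pixels count as
        background.
    """

    sigma: float = 1.3
    size: int = 7
    threshold: float = 0.1

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class TransformParams:
    """Normalization and filtering settings: arcsinh cofactor, clip
    percentiles, and inclusive size-filter bounds in µm²."""

    cofactor: float = 1.0
    clip_low: float = 1.0
    clip_high: float = 99.0
    size_min: float = 15.0
    size_max: float = 250.0

    def validate(self) -> None:
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        if not 0 <= self.clip_low < self.clip_high <= 100:
            raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")
        if not 0 < self.size_min < self.size_max:
            raise ValueError("size bounds must satisfy 0 < min < max")


def smo_statistic(image: np.ndarray, params: SMOParams) -> np.ndarray:
    """Per-pixel SMO statistic in [0, 1]: the norm of the window-averaged
    unit gradient vector. Low values mean direction-incoherent, i.e.
    background-like, neighbourhoods. Borders use replicate-edge padding."""
    img = ndimage.gaussian_filter(image.astype(float), params.sigma, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    norm = np.hypot(gx, gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(norm > 0, gx / norm, 0.0)
        uy = np.where(norm > 0, gy / norm, 0.0)
    mx = ndimage.uniform_filter(ux, params.size, mode="nearest")
    my = ndimage.uniform_filter(uy, params.size, mode="nearest")
    return np.hypot(mx, my)


def smo_background_correct(image: np.ndarray, params: SMOParams | None = None):
    """Estimate and subtract a scalar background level from one channel.

    Background pixels are those whose SMO statistic falls below the
    `threshold` quantile of the SMO image; the estimate is the median
    intensity over that sample; the corrected image is max(image − est, 0).

    Returns (corrected image, background estimate).
    """
    params = params or SMOParams()
    params.validate()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if (image < 0).any():
        raise ValueError("image must be non-negative")

    if np.ptp(image) == 0:
        warnings.warn(
            "constant image: background estimate equals the constant",
            stacklevel=2,
        )
        est = float(image.flat[0])
        return np.zeros_like(image), est

    smo = smo_statistic(image, params)
    cut = np.quantile(smo, params.threshold)
    bg = smo < cut
    if not bg.any():  # ties at the quantile (e.g. large flat regions)
        bg = smo <= cut
    est = float(np.median(image[bg]))
    corrected = np.maximum(image - est, 0.0)
    return corrected, est


def correct_bundle(bundle: ImageBundle, params: SMOParams | None = None) -> ImageBundle:
    """SMO-correct every channel of a bundle; estimates go to metadata."""
    params = params or SMOParams()
    corrected = np.empty_like(bundle.channels)
    estimates = {}
    for i, name in enumerate(bundle.channel_names):
        corrected[i], estimates[name] = smo_background_correct(bundle.channels[i], params)
    meta = dict(bundle.metadata)
    meta["smo_params"] = {"sigma": params.sigma, "size": params.size, "threshold": params.threshold}
    meta["background_estimates"] = estimates
    return ImageBundle(
        channels=corrected,
        channel_names=list(bundle.channel_names),
        cell_mask=bundle.cell_mask,
        tissue_mask=bundle.tissue_mask,
        pixel_size_um=bundle.pixel_size_um,
        metadata=meta,
    )


def extract_cell_features(bundle: ImageBundle) -> pd.DataFrame:
    """Per-cell mean intensity per channel, area (µm²) and centroid (µm).

    One row per nonzero mask label; the centroid is the mean pixel index
    plus 0.5 µm so coordinates refer to pixel centres.
    """
    if bundle.cell_mask.shape != bundle.channels.shape[1:]:
        raise ValueError("image and cell mask shapes differ")
    if bundle.cell_mask.max() == 0:
        cols = ["cell_id", "x_um", "y_um", "area_um2"] + [
            f"raw_{m}" for m in bundle.channel_names
        ]
        return pd.DataFrame(columns=cols)
    intensity = np.moveaxis(bundle.channels, 0, -1).astype(np.float64)  # H, W, C
    props = regionprops_table(
        bundle.cell_mask.astype(np.int64),
        intensity_image=intensity,
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    out = pd.DataFrame(
        {
            "cell_id": props["label"],
            "x_um": props["centroid-1"] + 0.5,
            "y_um": props["centroid-0"] + 0.5,
            "area_um2": props["area"].astype(float) * bundle.pixel_size_um**2,
        }
    )
    for i, m in enumerate(bundle.channel_names):
        out[f"raw_{m}"] = props[f"intensity_mean-{i}"]
    return out


def assign_tissue_segments(cells: pd.DataFrame, tissue_mask: np.ndarray):
    """Label each cell with the tissue segment under its centroid.

    Returns (cells with a `segment` column, per-segment areas in µm²).
    Cells over background keep the label "background" so they can be
    excluded downstream if desired.
    """
    h, w = tissue_mask.shape
    cells = cells.copy()
    if len(cells):
        px = np.floor(cells["x_um"].to_numpy()).astype(int)
        py = np.floor(cells["y_um"].to_numpy()).astype(int)
        oob = (px < 0) | (px >= w) | (py < 0) | (py >= h)
        if oob.any():
            bad = cells.loc[oob, "cell_id"].tolist()
            raise ValueError(f"cell centroid out of mask bounds for cell ids {bad}")
        codes = tissue_mask[py, px]
        cells["segment"] = [SEGMENT_NAMES[int(c)] for c in codes]
    else:
        cells["segment"] = pd.Series(dtype=object)
    counts = np.bincount(tissue_mask.ravel(), minlength=max(SEGMENT_NAMES) + 1)
    areas = {SEGMENT_NAMES[c]: float(n) for c, n in enumerate(counts) if c in SEGMENT_NAMES}
    return cells, areas


def normalize_and_filter(
    cells: pd.DataFrame,
    params: TransformParams | None = None,
    batch_col: str | None = "sample_id",
) -> pd.DataFrame:
    """arcsinh-transform raw intensities, percentile-clip per batch, and
    apply the size filter (inclusive bounds). Raw columns are preserved;
    transformed values land in tr_<marker> columns."""
    params = params or TransformParams()
    params.validate()
    cells = cells.copy()
    raw_cols = [c for c in cells.columns if c.startswith("raw_")]
    if not raw_cols:
        raise ValueError("no raw_<marker> columns present")

    def _transform(df: pd.DataFrame) -> pd.DataFrame:
        for rc in raw_cols:
            tr = np.arcsinh(df[rc].to_numpy(dtype=float) / params.cofactor)
            if len(tr):
                # order-statistic percentiles make the clip exactly idempotent
                lo = np.percentile(tr, params.clip_low, method="lower")
                hi = np.percentile(tr, params.clip_high, method="higher")
                tr = np.clip(tr, lo, hi)
            df["tr_" + rc[4:]] = tr
        return df

    if batch_col is not None and batch_col in cells.columns and len(cells):
        cells = (
            cells.groupby(batch_col, group_keys=False, sort=False)[cells.columns]
            .apply(_transform)
        )
    else:
        cells = _transform(cells)

    kept = cells[
        (cells["area_um2"] >= params.size_min) & (cells["area_um2"] <= params.size_max)
    ].reset_index(drop=True)
    if len(cells) and not len(kept):
        warnings.warn("size filter removed every cell", stacklevel=2)
    return kept


def preprocess_bundle(
    bundle: ImageBundle,
    smo: SMOParams | None = None,
    transform: TransformParams | None = None,
    sample_id: str = "sample",
    image_id: str = "image",
) -> pd.DataFrame:
    """Full preprocessing of one bundle: SMO correction, feature extraction,
    segment assignment, normalization and size filtering."""
    corrected = correct_bundle(bundle, smo)
    cells = extract_cell_features(corrected)
    cells.insert(0, "sample_id", sample_id)
    cells.insert(1, "image_id", image_id)
    cells, _ = assign_tissue_segments(cells, bundle.tissue_mask)
    return normalize_and_filter(cells, transform)
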