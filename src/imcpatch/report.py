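"""Group-level statistics and figure assembly: PCA with feature
contributions, Wilcoxon rank-sum tests with Benjamini–Hochberg correction
and significance stars, and figure-shaped views of the computed tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p <= thr:
            return stars
    return "ns"


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows × components
    loadings: pd.DataFrame  # features × components, orthonormal columns
    variance_ratio: np.ndarray
    contributions: pd.DataFrame  # features × components, columns sum to 1
    mean: pd.Series
    scale: pd.Series | None


def run_pca(table: pd.DataFrame, scale: bool = True, n_components: int | None = None) -> PCAResult:
    """PCA of a numeric feature table (rows = observations).

    Always centred; scaling to unit variance is on by default. Constant
    features are dropped with a warning. Component signs are fixed so each
    component's largest-magnitude loading is positive. The contribution of
    feature j to component c is its squared loading share.
    """
    X = table.select_dtypes(include=[np.number])
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 numeric columns")
    sd = X.std(ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping constant features: {list(X.columns[const])}", stacklevel=2)
        X = X.loc[:, ~const]
        sd = sd[~const]
    mean = X.mean()
    Z = X - mean
    scale_s = None
    if scale:
        scale_s = sd
        Z = Z / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    var = S**2
    ratio = var / var.sum() if var.sum() > 0 else var
    ncomp = n_components or len(S)
    comps = [f"PC{i+1}" for i in range(len(S))][:ncomp]
    loadings = pd.DataFrame(Vt.T[:, :ncomp], index=X.columns, columns=comps)
    scores = pd.DataFrame((U * S)[:, :ncomp], index=table.index, columns=comps)
    contrib = loadings**2
    contrib = contrib / contrib.sum(axis=0)
    return PCAResult(scores, loadings, ratio[:ncomp], contrib, mean, scale_s)


def wilcoxon_bh(
    table: pd.DataFrame,
    grouping: pd.Series,
    pairs: list[tuple[str, str]],
    features: list[str] | None = None,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per feature per group pair, with
    Benjamini–Hochberg correction across the whole family (all features ×
    pairs of one analysis panel).

    The exact null distribution is used for combined n ≤ exact_max_n
    without ties, the normal approximation with continuity and tie
    correction otherwise. All-tied comparisons report p = 1 with a warning.
    """
    if features is None:
        features = list(table.select_dtypes(include=[np.number]).columns)
    rows = []
    for ga, gb in pairs:
        ia = grouping[grouping == ga].index
        ib = grouping[grouping == gb].index
        for feat in features:
            a = table.loc[ia, feat].dropna().to_numpy(dtype=float)
            b = table.loc[ib, feat].dropna().to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"pair ({ga}, {gb}) needs >= 2 observations per side for {feat!r}"
                )
            pooled = np.concatenate([a, b])
            has_ties = len(np.unique(pooled)) < len(pooled)
            if np.ptp(pooled) == 0:
                warnings.warn(f"all-tied data for {feat!r} ({ga} vs {gb}): p = 1", stacklevel=2)
                stat, p = np.nan, 1.0
            else:
                method = (
                    "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
                )
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
                stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
            rows.append(
                {"feature": feat, "group_a": ga, "group_b": gb,
                 "statistic": stat, "p_raw": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
        out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    else:
        out["p_adj"] = []
        out["stars"] = []
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin statsmodels wrapper)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# figures


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_heatmap(values: pd.DataFrame, path, title: str = "", cmap: str = "RdBu_r", center: float | None = 0.0):
    """Matrix heatmap (e.g. attraction/avoidance counts: attraction on the
    positive scale, avoidance negative)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(0.4 * len(values.columns) + 3, 0.4 * len(values) + 2))
    data = values.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(data)) if data.size else 1.0
    kw = {"vmin": -vmax, "vmax": vmax} if center == 0.0 else {}
    im = ax.imshow(data, cmap=cmap, **kw)
    ax.set_xticks(range(len(values.columns)), values.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(values.index)), values.index, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ratio_bars(ratios: pd.DataFrame, path, title: str = ""):
    """Horizontal bars of per-pair log2 region ratios."""
    plt = _mpl()
    df = ratios.sort_values("log2_ratio")
    labels = df["from_type"] + " → " + df["to_type"]
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(df) + 2))
    ax.barh(labels, df["log2_ratio"], color=np.where(df["log2_ratio"] >= 0, "#b2182b", "#2166ac"))
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("log2 ratio")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_patch_scatter(patch_table: pd.DataFrame, path, large_threshold: float = 12_000.0):
    """Patch area by tissue segment, large-class threshold marked."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(patch_table):
        segs = sorted(patch_table["segment"].unique())
        for i, seg in enumerate(segs):
            sub = patch_table[patch_table["segment"] == seg]
            ax.scatter(np.full(len(sub), i) + np.linspace(-0.15, 0.15, len(sub)),
                       sub["area_um2"], s=18, label=seg)
        ax.set_xticks(range(len(segs)), segs)
    ax.axhline(large_threshold, color="k", ls="--", lw=0.8)
    ax.set_yscale("log")
    ax.set_ylabel("patch area (µm²)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_biplot(pca: PCAResult, path, colour: pd.Series | None = None, title: str = ""):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 5))
    xs, ys = pca.scores.iloc[:, 0], pca.scores.iloc[:, 1]
    if colour is not None:
        for g in sorted(colour.unique()):
            m = (colour == g).to_numpy()
            ax.scatter(xs[m], ys[m], s=25, label=str(g))
        ax.legend(fontsize=7)
    else:
        ax.scatter(xs, ys, s=25)
    ax.set_xlabel(f"PC1 ({100 * pca.variance_ratio[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pca.variance_ratio[1]:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def boxplot_whiskers(values: np.ndarray) -> tuple[float, float]:
    """Whisker positions under the 1.5·IQR rule: most extreme data points
    within [Q1 − 1.5·IQR, Q3 + 1.5·IQR]."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr][0]
    hi = v[v <= q3 + 1.5 * iqr][-1]
    return float(lo), float(hi)


def plot_box_jitter(table: pd.DataFrame, value_col: str, group_col: str, path, title: str = ""):
    """Boxplot (median, IQR, 1.5·IQR whiskers) with jittered points."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = sorted(table[group_col].unique())
    if not groups:
        ax.text(0.5, 0.5, "no data", ha="center", va="center", transform=ax.transAxes)
    else:
        data = [table.loc[table[group_col] == g, value_col].dropna().to_numpy() for g in groups]
        ax.boxplot(data, tick_labels=[str(g) for g in groups], whis=1.5, showfliers=False)
        rng = np.random.default_rng(0)
        for i, vals in enumerate(data):
            ax.scatter(1 + i + rng.uniform(-0.12, 0.12, len(vals)), vals, s=12, alpha=0.7)
    ax.set_ylabel(value_col)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def assemble_figures(run_dir) -> list[str]:
    """Render the standard figure set from a pipeline run directory's CSV
    tables. Missing upstream tables raise an error naming the stage to run.
    Returns the list of figure files written."""
    from pathlib import Path

    run = Path(run_dir)
    fig_dir = run / "figures"
    fig_dir.mkdir(exist_ok=True)
    written = []

    def need(name: str, stage: str) -> Path:
        p = run / name
        if not p.exists():
            raise FileNotFoundError(f"missing {name}: run the {stage!r} stage first")
        return p

    summary = pd.read_csv(need("interaction_summary.csv", "interactions"))
    if len(summary):
        for (group, region), df in summary.groupby(["group", "region"]):
            signed = df.assign(signed=df["n_attraction"] - df["n_avoidance"]).pivot_table(
                index="from_type", columns="to_type", values="signed", fill_value=0
            )
            p = fig_dir / f"interactions_{group}_{region}.png"
            plot_heatmap(signed, p, title=f"{group} / {region} (attraction − avoidance)")
            written.append(str(p))

    ratios_p = run / "region_log2_ratios.csv"
    if ratios_p.exists():
        ratios = pd.read_csv(ratios_p)
        if len(ratios):
            p = fig_dir / "region_log2_ratios.png"
            plot_ratio_bars(ratios, p, title="region preference (log2 ratio)")
            written.append(str(p))

    patches_p = run / "patches.csv"
    if patches_p.exists():
        patch_table = pd.read_csv(patches_p)
        p = fig_dir / "patch_sizes.png"
        plot_patch_scatter(patch_table, p)
        written.append(str(p))

    freq_p = run / "frequencies.csv"
    if freq_p.exists():
        freq = pd.read_csv(freq_p)
        if len(freq):
            p = fig_dir / "frequencies_box.png"
            plot_box_jitter(freq, "frequency", "population", p, title="population frequencies")
            written.append(str(p))
    return written
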