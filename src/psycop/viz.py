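"""Profile visualizations: RDoC-blocked heatmap, CDA dimension plots,
per-variable boxplots and residual diagnostics.

The heatmap shows group-mean z-scores relative to the healthy reference
group (wildtype, no stress), columns blocked by RDoC domain and rows
ordered by complete-linkage clustering of Manhattan distances. Dimension
plots show canonical scores with per-group normal-theory coverage ellipses
(default 75%), either with individual animals as dots or with one labeled
vector per variable whose coordinates are its canonical coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from matplotlib.patches import Ellipse
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import GROUP_ORDER, BehaviorTable, RDoCMap, ValidationError
from .dimred import CDAResult
from .stats import FactorialModel, significance_stars

GROUP_COLORS = {
    "wt-ns": "#4477aa",
    "wt-sd": "#66ccee",
    "tg-ns": "#ee6677",
    "tg-sd": "#aa3377",
}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_groups(group_z_means: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering of Manhattan distances between group profiles.

    Rows are pre-sorted lexicographically by label so ties break
    deterministically; leaf order follows scipy's standard dendrogram rule.
    Returns (linkage matrix, leaf labels in display order).
    """
    if len(group_z_means) < 2:
        raise ValidationError("clustering needs at least 2 groups")
    ordered = group_z_means.sort_index()
    Z = hierarchy.linkage(pdist(ordered.to_numpy(), metric="cityblock"), method="complete")
    leaves = hierarchy.leaves_list(Z)
    return Z, [ordered.index[i] for i in leaves]


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------

@dataclass
class HeatmapSpec:
    cells: pd.DataFrame            # groups x variables, reference-centered
    row_order: list[str]
    column_blocks: dict[str, int]  # domain -> block size, in display order
    reference_group: str


def group_mean_z(z: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    gm = z.groupby(groups.loc[z.index]).mean()
    order = [g for g in GROUP_ORDER if g in gm.index] + [
        g for g in gm.index if g not in GROUP_ORDER
    ]
    return gm.loc[order]


def make_heatmap(
    z: pd.DataFrame,
    groups: pd.Series,
    rdoc_map: RDoCMap,
    reference_group: str = "wt-ns",
    clip_quantile: float = 0.99,
    stars: pd.DataFrame | None = None,
) -> tuple[HeatmapSpec, plt.Figure]:
    """Reference-centered group-mean z-score heatmap, RDoC column blocks.

    Cell values are group means of z-scores minus the reference group's
    means, so the reference row is zero by construction. The diverging
    color scale is symmetric about 0 and clipped at the ``clip_quantile``
    of absolute cell values to prevent single-cell saturation.
    """
    gm = group_mean_z(z, groups)
    if reference_group not in gm.index:
        raise ValidationError(f"reference group {reference_group!r} not present")
    cells = gm - gm.loc[reference_group]
    col_order = rdoc_map.blocked_order(cells.columns)
    cells = cells[col_order]
    _, row_order = cluster_groups(cells)
    cells = cells.loc[row_order]
    blocks = rdoc_map.block_sizes(col_order)

    vmax = float(np.quantile(np.abs(cells.to_numpy()), clip_quantile))
    vmax = vmax if vmax > 0 else 1.0
    fig, ax = plt.subplots(figsize=(max(6.0, 0.45 * len(col_order)), 3.2))
    sns.heatmap(
        cells, ax=ax, cmap="RdBu_r", center=0.0, vmin=-vmax, vmax=vmax,
        linewidths=0.5, linecolor="white",
        cbar_kws={"label": "group mean z vs. reference"},
    )
    x = 0
    for dom, size in blocks.items():
        if x > 0:
            ax.axvline(x, color="black", lw=1.5)
        ax.text(x + size / 2, -0.35, dom, ha="center", va="bottom", fontsize=11)
        x += size
    if stars is not None:
        for j, var in enumerate(cells.columns):
            if var in stars.index:
                mark = "".join(
                    s for s in stars.loc[var].tolist() if s and s != "n.s."
                )
                if mark:
                    ax.text(j + 0.5, len(cells) + 0.25, mark, ha="center", fontsize=7)
    ax.set_xlabel("")
    ax.set_ylabel("")
    fig.tight_layout()
    spec = HeatmapSpec(
        cells=cells, row_order=row_order, column_blocks=blocks,
        reference_group=reference_group,
    )
    return spec, fig


# ---------------------------------------------------------------------------
# dimension plots
# ---------------------------------------------------------------------------

@dataclass
class EllipseSpec:
    group: str
    center: np.ndarray
    shape: np.ndarray          # 2x2 covariance
    coverage: float
    degenerate: bool = False


def coverage_radius(coverage: float, dim: int = 2) -> float:
    """Mahalanobis radius enclosing ``coverage`` of a normal distribution."""
    if not 0 < coverage < 1:
        raise ValidationError("coverage must lie in (0, 1)")
    return float(np.sqrt(stats.chi2.ppf(coverage, dim)))


def group_ellipses(
    scores: pd.DataFrame, groups: pd.Series, coverage: float = 0.75
) -> list[EllipseSpec]:
    """Normal-theory data ellipses of the first two score columns per group."""
    out = []
    s2 = scores.iloc[:, :2]
    for gname in [g for g in GROUP_ORDER if g in set(groups)] + sorted(
        set(groups) - set(GROUP_ORDER)
    ):
        pts = s2[(groups.loc[s2.index] == gname).to_numpy()].to_numpy()
        center = pts.mean(axis=0)
        if len(pts) < 3:
            cov, degen = np.zeros((2, 2)), True
        else:
            cov = np.cov(pts.T)
            degen = not np.all(np.linalg.eigvalsh(cov) > 1e-12)
        out.append(EllipseSpec(gname, center, cov, coverage, degen))
    return out


def _draw_ellipse(ax, spec: EllipseSpec, color: str) -> None:
    if spec.degenerate:
        ax.plot(*spec.center, marker="D", ms=6, color=color)
        return
    vals, vecs = np.linalg.eigh(spec.shape)
    r = coverage_radius(spec.coverage)
    angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
    width, height = 2 * r * np.sqrt(vals[-1]), 2 * r * np.sqrt(vals[0])
    ax.add_patch(
        Ellipse(spec.center, width, height, angle=angle, facecolor=color,
                alpha=0.18, edgecolor=color, lw=1.5)
    )


def make_dimension_plot(
    cda: CDAResult,
    groups: pd.Series,
    mode: str = "points",
    coverage: float = 0.75,
    vector_scale: float | None = None,
) -> plt.Figure:
    """Canonical score plot on components 1-2.

    ``mode='points'`` draws each animal as a dot with per-group coverage
    ellipses; ``mode='vectors'`` keeps the ellipses and draws one labeled
    vector per variable at its canonical coefficients, all scaled by a
    single factor (default: 80% of the score range over the largest
    coefficient norm).
    """
    if mode not in ("points", "vectors"):
        raise ValidationError("mode must be 'points' or 'vectors'")
    if cda.scores.shape[1] < 2:
        raise ValidationError("dimension plot needs at least 2 canonical components")
    ellipses = group_ellipses(cda.scores, groups, coverage)
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    for spec in ellipses:
        color = GROUP_COLORS.get(spec.group, "gray")
        _draw_ellipse(ax, spec, color)
        if spec.degenerate:
            continue
    if mode == "points":
        for gname in [e.group for e in ellipses]:
            pts = cda.scores.iloc[:, :2][(groups.loc[cda.scores.index] == gname).to_numpy()]
            ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=18,
                       color=GROUP_COLORS.get(gname, "gray"), label=gname)
        ax.legend(frameon=False, fontsize=8)
    else:
        coef = cda.coefficients.iloc[:, :2].to_numpy()
        if vector_scale is None:
            span = float(np.abs(cda.scores.iloc[:, :2].to_numpy()).max())
            cmax = float(np.linalg.norm(coef, axis=1).max())
            vector_scale = 0.8 * span / cmax if cmax > 0 else 1.0
        for name, (x, y) in zip(cda.coefficients.index, coef):
            ax.annotate(
                "", xy=(x * vector_scale, y * vector_scale), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="0.25", lw=0.9),
            )
            ax.text(x * vector_scale * 1.06, y * vector_scale * 1.06, name,
                    fontsize=6.5, ha="center", va="center")
    ax.axhline(0, color="0.85", lw=0.8, zorder=0)
    ax.axvline(0, color="0.85", lw=0.8, zorder=0)
    pct = cda.percent
    ax.set_xlabel(f"Can1 ({pct[0]:.1f}% of canonical correlation)")
    ax.set_ylabel(f"Can2 ({pct[1]:.1f}% of canonical correlation)")
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# boxplots
# ---------------------------------------------------------------------------

def make_boxplots(
    table: BehaviorTable,
    variable: str,
    stats_rows: pd.DataFrame | None = None,
    jitter_width: float = 0.08,
    seed: int = 0,
) -> plt.Figure:
    """Four-group boxplot with 1.5-IQR whiskers and jittered near-duplicates.

    Points closer than 3% of the variable's total range to another point in
    the same group are shifted horizontally (seeded jitter). Significant
    terms from ``stats_rows`` (index term, column ``p_adj``) are annotated
    with stars: * <0.05, ** <0.01, *** <0.001.
    """
    if variable not in table.variables:
        raise ValidationError(f"unknown variable {variable!r}")
    rng = np.random.default_rng(seed)
    values = table.data[variable]
    groups = table.groups
    fig, ax = plt.subplots(figsize=(3.4, 3.6))
    data, positions = [], []
    total_range = float(values.max() - values.min()) or 1.0
    for i, gname in enumerate(GROUP_ORDER):
        v = values[(groups == gname).to_numpy()].dropna().to_numpy()
        data.append(v)
        positions.append(i)
        order = np.argsort(v)
        x = np.full(len(v), float(i))
        sorted_v = v[order]
        close = np.zeros(len(v), dtype=bool)
        if len(v) > 1:
            near = np.abs(np.diff(sorted_v)) < 0.03 * total_range
            close_sorted = np.zeros(len(v), dtype=bool)
            close_sorted[1:] |= near
            close_sorted[:-1] |= near
            close[order] = close_sorted
        x[close] += rng.uniform(-jitter_width, jitter_width, int(close.sum()))
        ax.scatter(x, v, s=12, color=GROUP_COLORS[gname], zorder=3, alpha=0.85)
    bp = ax.boxplot(
        data, positions=positions, whis=1.5, widths=0.55, showfliers=False,
        medianprops=dict(color="black"),
    )
    ax.set_xticks(positions)
    ax.set_xticklabels(GROUP_ORDER, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(variable)
    if stats_rows is not None:
        notes = []
        for term in stats_rows.index:
            p = stats_rows.loc[term, "p_adj"]
            mark = significance_stars(float(p))
            if mark and mark != "n.s.":
                notes.append(f"{term}: {mark}")
        if notes:
            ax.set_title("   ".join(notes), fontsize=9)
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(model: FactorialModel) -> plt.Figure:
    """QQ plot and kernel-density plot of pooled scaled residuals."""
    resid = model.residuals / model.residuals.std(axis=0, ddof=1)
    pooled = np.sort(resid.ravel())
    n = len(pooled)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7.6, 3.4))
    ax1.scatter(theo, pooled, s=6, color="#4477aa")
    lim = [min(theo[0], pooled[0]), max(theo[-1], pooled[-1])]
    ax1.plot(lim, lim, color="0.4", lw=1)
    ax1.set_xlabel("standard normal quantiles")
    ax1.set_ylabel("scaled residuals")
    ax1.set_title("QQ plot")
    kde = stats.gaussian_kde(pooled)
    xs = np.linspace(pooled[0] - 0.5, pooled[-1] + 0.5, 256)
    ax2.plot(xs, kde(xs), color="#4477aa", label="residuals")
    ax2.plot(xs, stats.norm.pdf(xs), color="0.4", ls="--", label="standard normal")
    ax2.set_xlabel("scaled residual")
    ax2.set_ylabel("density")
    ax2.legend(frameon=False, fontsize=8)
    ax2.set_title("density")
    fig.tight_layout()
    return fig


def save_figure(fig: plt.Figure, basepath, formats=("svg", "png")) -> list:
    """Write a figure deterministically (fixed hash salt, no embedded date)."""
    paths = []
    with plt.rc_context({"svg.hashsalt": "psycop"}):
        for ext in formats:
            p = f"{basepath}.{ext}"
            meta = {"Date": None} if ext == "svg" else {}
            fig.savefig(p, metadata=meta, dpi=150)
            paths.append(p)
    plt.close(fig)
    return paths
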