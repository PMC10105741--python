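"""Gene dynamics along the severity axis.

Axis-differential genes via a natural-cubic-spline likelihood-ratio test,
four dynamic modules from LOESS-smoothed profiles, per-gene linear trend,
and switch-timing from 50-bin local regressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core_io import CellAnnotation, ExpressionMatrix
from .severity_axis import SeverityAxis

logger = logging.getLogger("encc_severity")

GRID = np.linspace(0.0, 1.0, 100)
SWITCH_COLUMNS = ["gene_id", "start", "end", "direction", "n_significant_bins"]


@dataclass
class AxisDynamics:
    gene_id: str
    p_value: float
    q_value: float
    slope: float | None = None
    slope_p: float | None = None
    module: int | None = None


@dataclass
class SwitchPeriod:
    gene_id: str
    significant_bins: set[int]
    interval: tuple[float, float] | None
    direction: str | None        # 'up' | 'down' | None when no significant bins


@dataclass
class ModulesResult:
    table: pd.DataFrame          # gene_id, module
    profiles: np.ndarray         # genes x len(GRID), z-scored
    grid: np.ndarray


def _axis_values(axis: SeverityAxis | np.ndarray, cell_ids: Sequence[str]) -> np.ndarray:
    if isinstance(axis, SeverityAxis):
        return np.array([axis.pseudo_severity[c] for c in cell_ids])
    return np.asarray(axis, dtype=float)


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Uses the truncated-power natural basis with df+1 knots at quantiles of x.
    """
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    if len(knots) < 3:
        # not enough distinct values for a spline; fall back to linear
        return x[:, None] - x.mean()

    def d(k: float) -> np.ndarray:
        num = np.maximum(x - k, 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - k)

    cols = [x]
    for k in knots[:-2]:
        cols.append(d(k) - d(knots[-2]))
    basis = np.column_stack(cols[:df]) if len(cols) >= df else np.column_stack(cols)
    return basis - basis.mean(axis=0)


def axis_differential_test(
    matrix: ExpressionMatrix,
    axis: SeverityAxis | np.ndarray,
    q_threshold: float = 0.01,
) -> list[AxisDynamics]:
    """Per-gene LRT of a 3-df natural cubic spline in pseudo-severity against
    an intercept-only model (Gaussian errors on lognorm); BH q-values.

    Constant genes get p = 1 by convention.
    """
    if matrix.lognorm is None:
        raise ValueError("axis_differential_test requires the lognorm layer")
    t = _axis_values(axis, matrix.cell_ids)
    n = len(t)
    if n < 50:
        raise ValueError(f"axis_differential_test needs >= 50 cells, got {n}")
    basis = natural_spline_basis(t, df=3)
    X = np.column_stack([np.ones(n), basis])
    Y = matrix.lognorm.T  # cells x genes

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    dof = X.shape[1] - 1
    p = np.ones(matrix.n_genes)
    ok = rss0 > 0
    with np.errstate(divide="ignore"):
        lr = np.where(rss1 > 0, n * np.log(rss0 / np.maximum(rss1, 1e-300)), np.inf)
    p[ok] = stats.chi2.sf(lr[ok], dof)
    p[~ok] = 1.0  # constant gene
    q = multipletests(p, method="fdr_bh")[1]
    q[~ok] = 1.0
    out = [
        AxisDynamics(gene_id=g, p_value=float(p[i]), q_value=float(q[i]))
        for i, g in enumerate(matrix.gene_ids)
    ]
    n_sig = sum(d.q_value < q_threshold for d in out)
    logger.info("axis_differential_test: %d/%d significant at q<%g", n_sig, len(out), q_threshold)
    return out


def loess_profile(
    y: np.ndarray, t: np.ndarray, span: float = 0.5, grid: np.ndarray = GRID
) -> np.ndarray:
    """LOESS fit of y on t evaluated on the axis grid."""
    sm = lowess(y, t, frac=span, it=1, xvals=grid)
    return np.asarray(sm, dtype=float)


def smooth_and_cluster(
    matrix: ExpressionMatrix,
    axis: SeverityAxis | np.ndarray,
    significant_genes: Sequence[str],
    k: int = 4,
    loess_span: float = 0.5,
) -> ModulesResult:
    """LOESS profiles on a 100-point grid, z-scored per gene, Ward-clustered
    with distance 1 - Pearson correlation, cut at k modules.

    Modules are renumbered so module 1 has the highest mean profile at low
    severity (first quarter of the grid), descending — a deterministic
    function of the profiles alone.
    """
    if len(significant_genes) < k:
        raise ValueError(f"need >= {k} genes to form {k} modules")
    t = _axis_values(axis, matrix.cell_ids)
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    prof = np.empty((len(significant_genes), len(GRID)))
    for i, g in enumerate(significant_genes):
        prof[i] = loess_profile(matrix.lognorm[pos[g]], t, span=loess_span)
    mean = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (prof - mean) / sd

    # Ward on sqrt(2*(1-r)) == Euclidean distance between unit-scaled profiles
    r = np.corrcoef(z)
    r = np.clip(r, -1.0, 1.0)
    dist = np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = hierarchy.linkage(condensed, method="ward")
    raw_labels = hierarchy.fcluster(link, t=k, criterion="maxclust")

    # deterministic renumbering: early-severity mean, descending
    quarter = len(GRID) // 4
    early = {
        lab: z[raw_labels == lab, :quarter].mean() for lab in np.unique(raw_labels)
    }
    order = sorted(early, key=lambda lab: -early[lab])
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in raw_labels])

    table = pd.DataFrame({"gene_id": list(significant_genes), "module": labels})
    return ModulesResult(table=table, profiles=z, grid=GRID.copy())


def linear_trend(
    y: np.ndarray, axis: SeverityAxis | np.ndarray, cell_ids: Sequence[str] | None = None
) -> tuple[float, float]:
    """OLS slope of expression on pseudo-severity and its two-sided t-test p."""
    if isinstance(axis, SeverityAxis):
        if cell_ids is None:
            raise ValueError("cell_ids required when axis is a SeverityAxis")
        t = _axis_values(axis, cell_ids)
    else:
        t = np.asarray(axis, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("linear_trend needs >= 3 cells")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in axis")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.pvalue)


def switch_timing(
    y: np.ndarray,
    axis: SeverityAxis | np.ndarray,
    n_bins: int = 50,
    alpha: float = 0.05,
    min_cells_per_bin: int = 10,
    cell_ids: Sequence[str] | None = None,
    gene_id: str = "",
) -> SwitchPeriod:
    """Locate a gene's switch period from per-bin local regressions.

    The axis [0,1] is divided into ``n_bins`` equal-width half-open bins
    (last bin closed); bins with fewer than ``min_cells_per_bin`` cells are
    skipped; per retained bin, OLS of expression on within-bin pseudo-severity
    gives a slope and p-value; significant bins have p < alpha.  The period is
    the interquartile range of significant-bin centers expanded to bin
    boundaries; direction is the sign of the mean significant-bin slope.
    """
    if isinstance(axis, SeverityAxis):
        if cell_ids is None:
            raise ValueError("cell_ids required when axis is a SeverityAxis")
        t = _axis_values(axis, cell_ids)
    else:
        t = np.asarray(axis, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = np.minimum((t * n_bins).astype(int), n_bins - 1)

    any_bin = False
    sig_bins: set[int] = set()
    slopes: dict[int, float] = {}
    for b in range(n_bins):
        m = idx == b
        if m.sum() < min_cells_per_bin:
            continue
        any_bin = True
        tb, yb = t[m], y[m]
        if np.ptp(tb) == 0:
            continue
        res = stats.linregress(tb, yb)
        if np.isnan(res.pvalue):
            continue
        if res.pvalue < alpha:
            sig_bins.add(b)
            slopes[b] = res.slope
    if not any_bin:
        raise ValueError("axis too sparse: no bin reaches min_cells_per_bin")
    if not sig_bins:
        return SwitchPeriod(gene_id=gene_id, significant_bins=set(), interval=None, direction=None)

    centers = np.array(sorted((b + 0.5) / n_bins for b in sig_bins))
    q1, q3 = np.percentile(centers, [25, 75])
    start = np.floor(round(q1 * n_bins, 9)) / n_bins
    end = np.ceil(round(q3 * n_bins, 9)) / n_bins
    mean_slope = np.mean([slopes[b] for b in sig_bins])
    return SwitchPeriod(
        gene_id=gene_id,
        significant_bins=sig_bins,
        interval=(float(start), float(end)),
        direction="up" if mean_slope > 0 else "down",
    )


def core_gene_set(
    matrix: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    dynamics: Sequence[AxisDynamics],
    deg_tables: Mapping[str, pd.DataFrame],
    adf: pd.DataFrame,
    core_fdr: float = 0.05,
) -> list[str]:
    """Consensus DEGs shared between the S and L groups, intersected with
    axis-significant genes at FDR < core_fdr."""
    group_of = dict(zip(adf["sample_id"], adf["group"]))
    s_genes: set[str] = set()
    l_genes: set[str] = set()
    for sample, table in deg_tables.items():
        grp = group_of.get(sample)
        if grp == "S":
            s_genes.update(table["gene_id"])
        elif grp == "L":
            l_genes.update(table["gene_id"])
    shared = s_genes & l_genes
    axis_sig = {d.gene_id for d in dynamics if d.q_value < core_fdr}
    core = sorted(shared & axis_sig)
    logger.info("core_gene_set: %d shared S/L DEGs, %d core after axis filter",
                len(shared), len(core))
    return core


def dynamics_frame(dyn: Sequence[AxisDynamics]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.gene_id, d.p_value, d.q_value) for d in dyn],
        columns=["gene_id", "p_value", "q_value"],
    )


def switch_row(sp: SwitchPeriod) -> tuple:
    if sp.interval is None:
        return (sp.gene_id, np.nan, np.nan, "NA", 0)
    return (sp.gene_id, sp.interval[0], sp.interval[1], sp.direction, len(sp.significant_bins))
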