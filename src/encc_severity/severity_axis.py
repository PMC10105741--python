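"""Pseudo-disease-severity axis from PCA of normalized expression.

The axis is the principal component whose per-cell scores best track the
ordinal clinical severity scores (max |Spearman|); its scores are oriented
controls-low and min-max rescaled to [0,1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CellAnnotation, ExpressionMatrix, annotation_frame

logger = logging.getLogger("encc_severity")


@dataclass
class PcaResult:
    gene_ids: list[str]          # HVGs actually used
    cell_ids: list[str]
    scores: np.ndarray           # cells x n_pcs
    loadings: np.ndarray         # genes x n_pcs, unit-norm columns
    gene_mean: np.ndarray        # standardization applied before SVD
    gene_sd: np.ndarray


@dataclass
class SeverityAxis:
    """Selected severity PC with per-cell scores and [0,1] pseudo-severity."""

    pc_index: int                        # 1-based
    loadings: dict[str, float]
    cell_score: dict[str, float]
    pseudo_severity: dict[str, float]
    orientation: int
    selection_correlation: float


def _sign_convention(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-magnitude loading is positive."""
    scores = scores.copy()
    loadings = loadings.copy()
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def select_hvg(lognorm: np.ndarray, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    """Top-dispersion gene mask: dispersion = var/mean of expm1(lognorm),
    z-scored within 20 mean-expression bins."""
    expr = np.expm1(lognorm)
    mean = expr.mean(axis=1)
    var = expr.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="mergesort")
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        d = disp[b]
        sd = d.std()
        z[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    n_genes = lognorm.shape[0]
    if n_hvg >= n_genes:
        logger.warning("n_hvg=%d >= %d genes: using all genes", n_hvg, n_genes)
        return np.ones(n_genes, bool)
    top = np.argsort(-z, kind="mergesort")[:n_hvg]
    mask = np.zeros(n_genes, bool)
    mask[top] = True
    return mask


def fit_pca(
    matrix: ExpressionMatrix,
    n_pcs: int = 15,
    n_hvg: int | None = 4500,
) -> PcaResult:
    """PCA of cells on gene-standardized lognorm expression.

    Genes are centered and scaled to unit variance across cells before the
    decomposition; loadings follow a deterministic sign convention (largest-
    magnitude element positive).
    """
    if matrix.lognorm is None:
        raise ValueError("fit_pca requires the lognorm layer (run normalize first)")
    x = matrix.lognorm
    if n_hvg is not None:
        mask = select_hvg(x, n_hvg)
    else:
        mask = np.ones(x.shape[0], bool)
    gene_ids = [g for g, k in zip(matrix.gene_ids, mask) if k]
    x = x[mask]
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mean[:, None]) / sd_safe[:, None]

    n_pcs = min(n_pcs, min(z.shape) - 1)
    if n_pcs < 1:
        raise ValueError("matrix too small for PCA")
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)  # cells x genes
    scores = u[:, :n_pcs] * s[:n_pcs]
    loadings = vt[:n_pcs].T
    scores, loadings = _sign_convention(scores, loadings)
    return PcaResult(
        gene_ids=gene_ids,
        cell_ids=list(matrix.cell_ids),
        scores=scores,
        loadings=loadings,
        gene_mean=mean,
        gene_sd=sd_safe,
    )


def _select_pc(scores: np.ndarray, clinical: np.ndarray) -> tuple[int, int, float]:
    """Return (1-based pc index, orientation, signed Spearman rho) maximizing
    |rho| against the clinical scores; ties broken by lower index."""
    if np.allclose(clinical, clinical[0]):
        raise ValueError("axis undefined without severity contrast")
    best = (-1.0, 0, 0, 0.0)
    for k in range(scores.shape[1]):
        rho = stats.spearmanr(scores[:, k], clinical).statistic
        if np.isnan(rho):
            continue
        if abs(rho) > best[0] + 1e-15:
            orient = 1 if rho >= 0 else -1
            best = (abs(rho), k + 1, orient, float(rho))
    if best[1] == 0:
        raise ValueError("no PC correlates with clinical scores")
    return best[1], best[2], best[3]


def select_severity_pc(
    pca: PcaResult,
    ann: Sequence[CellAnnotation],
    candidate_pcs: int = 15,
) -> SeverityAxis:
    """Pick the PC with maximal |Spearman| vs clinical score; orient it so the
    correlation is positive (controls low) and min-max rescale to [0,1]."""
    adf = annotation_frame(ann)
    clin = np.array([adf.loc[c, "clinical_score"] for c in pca.cell_ids], dtype=float)
    k = min(candidate_pcs, pca.scores.shape[1])
    pc_index, orientation, rho = _select_pc(pca.scores[:, :k], clin)
    raw = pca.scores[:, pc_index - 1]
    v = orientation * raw
    lo, hi = v.min(), v.max()
    pseudo = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return SeverityAxis(
        pc_index=pc_index,
        loadings=dict(zip(pca.gene_ids, pca.loadings[:, pc_index - 1])),
        cell_score=dict(zip(pca.cell_ids, raw)),
        pseudo_severity=dict(zip(pca.cell_ids, pseudo)),
        orientation=orientation,
        selection_correlation=rho,
    )


def build_axis(
    matrix: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    n_pcs: int = 15,
    n_hvg: int | None = 4500,
    exclude_groups: tuple[str, ...] = ("TCA",),
) -> SeverityAxis:
    """Fit the axis on cells outside ``exclude_groups`` and project the
    excluded cells onto it; pseudo-severity stays min 0 / max 1 over the
    retained cells, excluded cells are clipped into [0,1]."""
    adf = annotation_frame(ann)
    keep = ~adf.loc[matrix.cell_ids, "group"].isin(exclude_groups).to_numpy()
    sub = matrix.subset(cell_mask=keep)
    sub_ann = [a for a, k in zip(ann, keep) if k]
    pca = fit_pca(sub, n_pcs=n_pcs, n_hvg=n_hvg)
    axis = select_severity_pc(pca, sub_ann, candidate_pcs=n_pcs)
    if keep.all():
        return axis

    # project excluded cells with the same standardization and loadings
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = [gene_pos[g] for g in pca.gene_ids]
    x = matrix.lognorm[np.ix_(rows, ~keep)]
    z = (x - pca.gene_mean[:, None]) / pca.gene_sd[:, None]
    raw = z.T @ pca.loadings[:, axis.pc_index - 1]
    retained = np.array([axis.cell_score[c] for c in pca.cell_ids])
    v_ret = axis.orientation * retained
    lo, hi = v_ret.min(), v_ret.max()
    excluded_cells = [c for c, k in zip(matrix.cell_ids, keep) if not k]
    for c, r in zip(excluded_cells, raw):
        axis.cell_score[c] = float(r)
        p = (axis.orientation * r - lo) / (hi - lo) if hi > lo else 0.0
        axis.pseudo_severity[c] = float(np.clip(p, 0.0, 1.0))
    return axis


def group_axis_test(
    axis: SeverityAxis,
    ann: Sequence[CellAnnotation],
    group_a: str,
    group_b: str,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on pseudo-severity between two groups."""
    adf = annotation_frame(ann)
    va = [axis.pseudo_severity[c] for c in adf.index[adf["group"] == group_a]
          if c in axis.pseudo_severity]
    vb = [axis.pseudo_severity[c] for c in adf.index[adf["group"] == group_b]
          if c in axis.pseudo_severity]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(f"groups need >= 2 cells each (got {len(va)}, {len(vb)})")
    res = stats.mannwhitneyu(va, vb, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def axis_cells_frame(axis: SeverityAxis) -> pd.DataFrame:
    cells = sorted(axis.pseudo_severity)
    return pd.DataFrame(
        {
            "cell_id": cells,
            "pc_score": [axis.cell_score[c] for c in cells],
            "pseudo_severity": [axis.pseudo_severity[c] for c in cells],
        }
    )


def axis_meta_frame(axis: SeverityAxis) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "field": ["pc_index", "orientation", "selection_correlation"],
            "value": [axis.pc_index, axis.orientation, axis.selection_correlation],
        }
    )
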