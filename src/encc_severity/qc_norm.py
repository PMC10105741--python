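"""Cell/gene quality filtering, normalization, and consensus DEG calling.

Boundary conventions follow a literal reading of the filtering rules:
"fewer than 3000" / "more than 9000" detected genes and "greater than 20%"
mitochondrial fraction are strict, so cells at exactly 3000, 9000 or 0.20
are retained; genes detected in fewer than five cells are removed, so five
cells retains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CellAnnotation, ExpressionMatrix, annotation_frame

logger = logging.getLogger("encc_severity")


@dataclass
class DegRecord:
    gene_id: str
    log2fc: float          # case vs pooled controls
    p_value: float         # max over the two per-control comparisons
    q_value: float
    direction: str         # 'up' | 'down'


def filter_cells(
    matrix: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    min_genes: int = 3000,
    max_genes: int = 9000,
    max_mito: float = 0.20,
) -> tuple[ExpressionMatrix, list[CellAnnotation]]:
    """Retain cells with min_genes <= n_genes_detected <= max_genes and
    mito_fraction <= max_mito (all bounds inclusive)."""
    if not min_genes < max_genes:
        raise ValueError("min_genes must be < max_genes")
    if not 0 < max_mito <= 1:
        raise ValueError("max_mito must be in (0,1]")
    by_id = {a.cell_id: a for a in ann}
    missing = [c for c in matrix.cell_ids if c not in by_id]
    if missing:
        raise ValueError(f"annotation missing cells: {missing[:5]}")
    low = high = mito = 0
    keep = np.zeros(matrix.n_cells, bool)
    for j, c in enumerate(matrix.cell_ids):
        a = by_id[c]
        if a.n_genes_detected < min_genes:
            low += 1
        elif a.n_genes_detected > max_genes:
            high += 1
        elif a.mito_fraction > max_mito:
            mito += 1
        else:
            keep[j] = True
    logger.info(
        "filter_cells: %d/%d kept (removed: %d low-genes, %d high-genes, %d high-mito)",
        keep.sum(), matrix.n_cells, low, high, mito,
    )
    if not keep.any():
        raise ValueError(
            f"all cells removed (low-genes={low}, high-genes={high}, high-mito={mito})"
        )
    out = matrix.subset(cell_mask=keep)
    out_ann = [by_id[c] for c in out.cell_ids]
    return out, out_ann


def filter_genes(matrix: ExpressionMatrix, min_cells: int = 5) -> ExpressionMatrix:
    """Retain genes with nonzero counts in at least ``min_cells`` cells."""
    if matrix.n_genes == 0:
        raise ValueError("empty matrix")
    detected = (matrix.counts > 0).sum(axis=1)
    keep = detected >= min_cells
    logger.info("filter_genes: %d/%d kept (min_cells=%d)", keep.sum(), matrix.n_genes, min_cells)
    if not keep.any():
        logger.warning("filter_genes removed every gene")
    return matrix.subset(gene_mask=keep)


def drop_sample_unique_genes(
    matrix: ExpressionMatrix, ann: Sequence[CellAnnotation]
) -> ExpressionMatrix:
    """Remove genes whose expression is confined to a single sample."""
    adf = annotation_frame(ann)
    samples = adf.loc[matrix.cell_ids, "sample_id"].to_numpy()
    uniq = np.unique(samples)
    expressed = matrix.counts > 0
    n_samples_expressing = np.zeros(matrix.n_genes, int)
    for s in uniq:
        n_samples_expressing += expressed[:, samples == s].any(axis=1)
    keep = n_samples_expressing != 1
    logger.info("drop_sample_unique_genes: %d/%d kept", keep.sum(), matrix.n_genes)
    return matrix.subset(gene_mask=keep)


def normalize(matrix: ExpressionMatrix, scale_factor: float = 200_000.0) -> ExpressionMatrix:
    """Fill the lognorm layer: ln(1 + counts/cell_total * scale_factor)."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = [c for c, t in zip(matrix.cell_ids, totals) if t == 0]
        raise ValueError(f"zero-total cells cannot be normalized: {bad[:5]}")
    lognorm = np.log1p(matrix.counts / totals * scale_factor)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        counts=matrix.counts,
        tpm=matrix.tpm,
        lognorm=lognorm,
    )


def _log2fc(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """log2 fold-change on expm1-means of lognorm with pseudocount 1."""
    m_case = np.expm1(case).mean(axis=1)
    m_ctrl = np.expm1(ctrl).mean(axis=1)
    return np.log2((m_case + 1.0) / (m_ctrl + 1.0))


def consensus_deg(
    matrix: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    case_sample: str | Sequence[str],
    control_samples: tuple[str, str],
    alpha: float = 0.05,
    min_log2fc: float = 0.5,
) -> list[DegRecord]:
    """Genes differential versus BOTH control samples, same direction.

    Per control: two-sided Wilcoxon rank-sum on lognorm per gene, BH-adjusted
    within that comparison; a gene passes iff q < alpha and |log2FC| >
    min_log2fc against both controls with consistent sign.  The reported
    log2fc is case vs pooled controls.  ``case_sample`` may be one sample id
    or a list (cells pooled).
    """
    if matrix.lognorm is None:
        raise ValueError("consensus_deg requires the lognorm layer")
    adf = annotation_frame(ann)
    samples = adf.loc[matrix.cell_ids, "sample_id"].to_numpy()
    case_ids = [case_sample] if isinstance(case_sample, str) else list(case_sample)
    case_mask = np.isin(samples, case_ids)
    if not case_mask.any():
        raise ValueError(f"case sample(s) {case_ids} absent after QC")
    x_case = matrix.lognorm[:, case_mask]

    per_control = []
    for ctrl in control_samples:
        m = samples == ctrl
        if m.sum() < 3:
            raise ValueError(f"control sample {ctrl} has < 3 cells after QC")
        x_ctrl = matrix.lognorm[:, m]
        res = stats.mannwhitneyu(x_case, x_ctrl, alternative="two-sided", axis=1)
        q = multipletests(res.pvalue, method="fdr_bh")[1]
        lfc = _log2fc(x_case, x_ctrl)
        per_control.append((res.pvalue, q, lfc))

    pooled_mask = np.isin(samples, list(control_samples))
    lfc_pooled = _log2fc(x_case, matrix.lognorm[:, pooled_mask])

    out: list[DegRecord] = []
    for i, g in enumerate(matrix.gene_ids):
        ok = all(
            q[i] < alpha and abs(l[i]) > min_log2fc for (_, q, l) in per_control
        )
        same_sign = np.sign(per_control[0][2][i]) == np.sign(per_control[1][2][i])
        if ok and same_sign:
            out.append(
                DegRecord(
                    gene_id=g,
                    log2fc=float(lfc_pooled[i]),
                    p_value=float(max(pc[0][i] for pc in per_control)),
                    q_value=float(max(pc[1][i] for pc in per_control)),
                    direction="up" if lfc_pooled[i] > 0 else "down",
                )
            )
    logger.info("consensus_deg: %d genes vs case=%s", len(out), case_ids)
    return out


def deg_frame(records: Sequence[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.p_value, r.q_value, r.direction) for r in records],
        columns=["gene_id", "log2fc", "p_value", "q_value", "direction"],
    )
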