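"""Pathway and complex activity scoring.

Pathway score: per-cell arithmetic mean of lognorm over the resolved set
members (an additive model that ignores gene-gene interactions; the mean is
used rather than the sum so scores are comparable across set sizes).
Complex activity: per-cell geometric mean over subunits; zero whenever any
subunit is unexpressed in that cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CellAnnotation, ExpressionMatrix, GeneSet, annotation_frame

logger = logging.getLogger("encc_severity")


@dataclass
class PathwayScores:
    set_name: str
    cell_ids: list[str]
    scores: np.ndarray


@dataclass
class ComplexActivities:
    complex_name: str
    cell_ids: list[str]
    activity: np.ndarray


def _layer(matrix: ExpressionMatrix, layer: str) -> np.ndarray:
    if layer == "lognorm":
        if matrix.lognorm is None:
            raise ValueError("lognorm layer absent (run normalize first)")
        return matrix.lognorm
    if layer == "tpm":
        return matrix.tpm
    raise ValueError(f"unknown layer {layer!r}")


def pathway_score(
    matrix: ExpressionMatrix, gene_set: GeneSet, layer: str = "lognorm"
) -> PathwayScores:
    """Per-cell mean expression over the resolved set members."""
    x = _layer(matrix, layer)
    members = gene_set.resolve(matrix.gene_ids)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r}: no members resolved in the matrix")
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = [pos[g] for g in members]
    return PathwayScores(
        set_name=gene_set.name,
        cell_ids=list(matrix.cell_ids),
        scores=x[rows].mean(axis=0),
    )


def complex_activity(
    matrix: ExpressionMatrix, subunits: GeneSet, layer: str = "lognorm"
) -> ComplexActivities:
    """Per-cell geometric mean of subunit expression; zero if any subunit is
    unexpressed (value 0) in the cell.  All subunits must be present."""
    x = _layer(matrix, layer)
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = sorted(g for g in subunits.genes if g not in pos)
    if missing:
        raise ValueError(f"complex {subunits.name!r}: subunits absent from matrix: {missing}")
    rows = [pos[g] for g in sorted(subunits.genes)]
    vals = x[rows]
    n = len(rows)
    any_zero = np.any(vals <= 0, axis=0)
    with np.errstate(divide="ignore"):
        logmean = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), 0.0).mean(axis=0)
    activity = np.where(any_zero, 0.0, np.exp(logmean))
    # recompute exactly where n is small to avoid exp/log rounding drift
    if n <= 16:
        direct = np.prod(vals, axis=0) ** (1.0 / n)
        activity = np.where(any_zero, 0.0, direct)
    return ComplexActivities(
        complex_name=subunits.name, cell_ids=list(matrix.cell_ids), activity=activity
    )


def compare_pathway_groups(
    scores: PathwayScores,
    ann: Sequence[CellAnnotation],
    grouping: str = "group",
) -> pd.DataFrame:
    """Each case group vs pooled controls: two-sided Wilcoxon rank-sum, BH
    across the comparisons made in this call."""
    adf = annotation_frame(ann)
    lab = adf.loc[scores.cell_ids, grouping].to_numpy()
    vals = np.asarray(scores.scores, dtype=float)
    ctrl = vals[lab == "control"]
    if ctrl.size < 2:
        raise ValueError("pooled controls need >= 2 cells")
    rows = []
    for g in sorted(set(lab) - {"control"}):
        v = vals[lab == g]
        if v.size < 2:
            raise ValueError(f"group {g!r} has < 2 cells")
        res = stats.mannwhitneyu(v, ctrl, alternative="two-sided")
        rows.append((scores.set_name, g, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["set_name", "group", "statistic", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out


def score_frame(s: PathwayScores) -> pd.DataFrame:
    return pd.DataFrame({"cell_id": s.cell_ids, "set_name": s.set_name, "score": s.scores})


def activity_frame(a: ComplexActivities) -> pd.DataFrame:
    return pd.DataFrame(
        {"cell_id": a.cell_ids, "complex_name": a.complex_name, "activity": a.activity}
    )
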