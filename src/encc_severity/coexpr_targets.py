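"""Hub-regulator target prediction by differential co-expression.

Three-step strategy: (1) genes whose expression correlates with the hub in
the case condition (BH q below threshold), (2) restricted to consensus DEGs,
(3) restricted to genes with binding evidence.  Survivors are labeled
activated (positive correlation, up-regulated) or repressed (negative
correlation, down-regulated).  A 2x2 DEG x motif contingency test quantifies
motif enrichment against the non-DEG background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CellAnnotation, ExpressionMatrix, annotation_frame

logger = logging.getLogger("encc_severity")


@dataclass
class HubTargetCall:
    gene_id: str
    r_case: float
    corr_q: float
    is_deg: bool
    deg_direction: str           # 'up' | 'down' | 'none'
    has_binding_evidence: bool
    n_motif_hits: int
    call: str                    # 'activated' | 'repressed' | 'none'
    r_control: float = float("nan")


def condition_correlation(
    matrix: ExpressionMatrix,
    hub: str,
    ann: Sequence[CellAnnotation],
    condition: np.ndarray | str,
) -> pd.DataFrame:
    """Spearman correlation between the hub gene and every other gene over the
    cells of one condition; p from the t-approximation, BH q across genes.

    ``condition`` is either a boolean mask over matrix cells or a group name.
    """
    if matrix.lognorm is None:
        raise ValueError("condition_correlation requires the lognorm layer")
    if isinstance(condition, str):
        adf = annotation_frame(ann)
        mask = (adf.loc[matrix.cell_ids, "group"] == condition).to_numpy()
    else:
        mask = np.asarray(condition, bool)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"condition has {n} cells; >= 10 required")

    hub_row = matrix.lognorm[matrix.gene_index(hub), mask]
    if np.ptp(hub_row) == 0:
        raise ValueError(f"hub gene {hub!r} is constant within the condition")
    x = matrix.lognorm[:, mask]

    hub_rank = stats.rankdata(hub_row)
    ranks = stats.rankdata(x, axis=1)
    hr = hub_rank - hub_rank.mean()
    rr = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rr**2).sum(axis=1) * (hr**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (rr @ hr) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    keep = [i for i, g in enumerate(matrix.gene_ids) if g != hub]
    out = pd.DataFrame(
        {
            "gene_id": [matrix.gene_ids[i] for i in keep],
            "r": r[keep],
            "p_value": p[keep],
        }
    )
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def classify_hub_targets(
    correlations: pd.DataFrame,
    deg_table: pd.DataFrame,
    binding_genes: set[str],
    corr_q_threshold: float = 0.05,
    motif_counts: Mapping[str, int] | None = None,
    control_correlations: pd.DataFrame | None = None,
) -> list[HubTargetCall]:
    """Apply the three filtering steps and label survivors by sign rules:
    activated requires positive case correlation and up-regulation; repressed
    requires negative correlation and down-regulation; any mismatch -> none."""
    if not binding_genes:
        logger.warning("classify_hub_targets: empty binding set; all calls are none")
    motif_counts = motif_counts or {}
    deg = deg_table.set_index("gene_id")
    ctrl_r = (
        control_correlations.set_index("gene_id")["r"]
        if control_correlations is not None
        else None
    )
    calls: list[HubTargetCall] = []
    for row in correlations.itertuples(index=False):
        g = row.gene_id
        is_deg = g in deg.index
        direction = str(deg.loc[g, "direction"]) if is_deg else "none"
        has_binding = g in binding_genes
        call = "none"
        if row.q_value < corr_q_threshold and is_deg and has_binding:
            if row.r > 0 and direction == "up":
                call = "activated"
            elif row.r < 0 and direction == "down":
                call = "repressed"
            else:
                logger.info(
                    "classify_hub_targets: %s passed filters but sign/direction "
                    "mismatch (r=%.3f, %s)", g, row.r, direction,
                )
        calls.append(
            HubTargetCall(
                gene_id=g,
                r_case=float(row.r),
                corr_q=float(row.q_value),
                is_deg=is_deg,
                deg_direction=direction,
                has_binding_evidence=has_binding,
                n_motif_hits=int(motif_counts.get(g, 0)),
                call=call,
                r_control=float(ctrl_r.get(g, np.nan)) if ctrl_r is not None else float("nan"),
            )
        )
    n_called = sum(c.call != "none" for c in calls)
    logger.info("classify_hub_targets: %d/%d genes called", n_called, len(calls))
    return calls


def motif_enrichment_test(
    deg_flags: Mapping[str, bool] | Sequence[bool],
    motif_flags: Mapping[str, bool] | Sequence[bool],
) -> tuple[float, float]:
    """Odds ratio and chi-square p (1 df, no continuity correction) of the
    DEG x motif-present 2x2 table; Haldane-Anscombe 0.5 correction applies to
    the OR iff any cell is zero."""
    if isinstance(deg_flags, Mapping):
        genes = sorted(deg_flags)
        if set(genes) != set(motif_flags):
            raise ValueError("deg_flags and motif_flags must cover the same genes")
        d = np.array([bool(deg_flags[g]) for g in genes])
        m = np.array([bool(motif_flags[g]) for g in genes])
    else:
        d = np.asarray(deg_flags, bool)
        m = np.asarray(motif_flags, bool)
        if d.shape != m.shape:
            raise ValueError("flag vectors differ in length")

    a = int(np.sum(d & m))
    b = int(np.sum(d & ~m))
    c = int(np.sum(~d & m))
    dd = int(np.sum(~d & ~m))
    if a + b < 2 or c + dd < 2 or a + c < 2 or b + dd < 2:
        raise ValueError(f"degenerate margin in 2x2 table ({a},{b};{c},{dd})")

    if min(a, b, c, dd) == 0:
        orr = ((a + 0.5) * (dd + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * dd) / (b * c)
    _, p, _, _ = stats.chi2_contingency([[a, b], [c, dd]], correction=False)
    return float(orr), float(p)


def calls_frame(calls: Sequence[HubTargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene_id, c.r_case, c.r_control, c.corr_q, c.is_deg, c.deg_direction,
                c.has_binding_evidence, c.n_motif_hits, c.call,
            )
            for c in calls
        ],
        columns=[
            "gene_id", "r_case", "r_control", "corr_q", "is_deg", "deg_direction",
            "has_binding_evidence", "n_motif_hits", "call",
        ],
    )
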