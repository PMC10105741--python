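"""Alternative-splicing layer.

Per-cell AS frequency, PSI (percent spliced in) computation from isoform
abundances, per-sample and per-cell differential PSI, PCA on the PSI matrix
with event weights, driver-event target prediction, and the combined
expression/splicing per-sample severity coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CellAnnotation, annotation_frame

logger = logging.getLogger("encc_severity")

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


@dataclass
class SpliceEvent:
    """A local splice event defined by inclusion/total isoform membership."""

    event_id: str
    gene_id: str
    type: str
    inclusion_isoforms: frozenset[str]
    total_isoforms: frozenset[str]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"event {self.event_id}: unknown type {self.type!r}")
        self.inclusion_isoforms = frozenset(self.inclusion_isoforms)
        self.total_isoforms = frozenset(self.total_isoforms)
        if not self.inclusion_isoforms:
            raise ValueError(f"event {self.event_id}: empty inclusion set")
        if not self.inclusion_isoforms < self.total_isoforms:
            raise ValueError(
                f"event {self.event_id}: inclusion isoforms must be a proper "
                "subset of total isoforms"
            )


@dataclass
class PsiMatrix:
    """Events x cells PSI values in [0,1]; missing entries are NaN, never 0."""

    event_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    events: dict[str, SpliceEvent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.event_ids), len(self.cell_ids)):
            raise ValueError("PSI matrix shape does not match ids")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < -1e-12 or present.max() > 1 + 1e-12):
            raise ValueError("PSI values must lie in [0,1]")

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    def row(self, event_id: str) -> np.ndarray:
        try:
            i = self.event_ids.index(event_id)
        except ValueError:
            raise KeyError(f"event {event_id!r} not in PSI matrix") from None
        return self.values[i]

    def subset_cells(self, cell_ids: Sequence[str]) -> "PsiMatrix":
        pos = {c: j for j, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise KeyError(f"cells absent from PSI matrix: {missing[:5]}")
        idx = [pos[c] for c in cell_ids]
        return PsiMatrix(list(self.event_ids), list(cell_ids), self.values[:, idx], self.events)


# ---------------------------------------------------------------------------
# I/O for event catalogs and PSI tables
# ---------------------------------------------------------------------------


def read_events(path: str | Path) -> dict[str, SpliceEvent]:
    df = pd.read_csv(path, sep="\t")
    events = {}
    for r in df.itertuples(index=False):
        ev = SpliceEvent(
            event_id=str(r.event_id),
            gene_id=str(r.gene_id),
            type=str(r.type),
            inclusion_isoforms=frozenset(str(r.inclusion_isoforms).split(",")),
            total_isoforms=frozenset(str(r.total_isoforms).split(",")),
        )
        events[ev.event_id] = ev
    return events


def write_events(events: Mapping[str, SpliceEvent], path: str | Path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "type": e.type,
            "inclusion_isoforms": ",".join(sorted(e.inclusion_isoforms)),
            "total_isoforms": ",".join(sorted(e.total_isoforms)),
        }
        for e in sorted(events.values(), key=lambda e: e.event_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_psi(path: str | Path, events: Mapping[str, SpliceEvent] | None = None) -> PsiMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    return PsiMatrix(
        event_ids=[str(e) for e in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        events=dict(events) if events else {},
    )


def write_psi(psi: PsiMatrix, path: str | Path) -> None:
    df = pd.DataFrame(psi.values, index=psi.event_ids, columns=psi.cell_ids)
    df.index.name = "event_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def as_frequency(ann: Sequence[CellAnnotation]) -> np.ndarray:
    """Per-cell AS frequency = n_splices / uniquely_mapped_reads.

    Cells with zero mapped reads get NaN (warned), never a fake zero.
    """
    reads = np.array([a.uniquely_mapped_reads for a in ann], dtype=float)
    splices = np.array([a.n_splices for a in ann], dtype=float)
    out = np.full(len(ann), np.nan)
    ok = reads > 0
    if not ok.all():
        logger.warning("as_frequency: %d cells with zero mapped reads -> NaN", (~ok).sum())
    out[ok] = splices[ok] / reads[ok]
    return out


def compute_psi(
    isoform_tpm: Mapping[str, float],
    event: SpliceEvent,
    min_total_tpm: float = 1.0,
) -> float:
    """PSI = sum(inclusion TPM) / sum(total TPM); NaN if total < min_total_tpm."""
    missing = [i for i in event.total_isoforms if i not in isoform_tpm]
    if missing:
        raise KeyError(
            f"event {event.event_id}: isoforms absent from abundance map: {sorted(missing)}"
        )
    total = sum(isoform_tpm[i] for i in event.total_isoforms)
    if total < min_total_tpm or total <= 0:
        return float("nan")
    incl = sum(isoform_tpm[i] for i in event.inclusion_isoforms)
    return incl / total


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def differential_psi(
    psi: PsiMatrix,
    ann: Sequence[CellAnnotation],
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    mode: str = "per_sample_t",
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Per-event differential PSI between two sample groups.

    ``per_sample_t``: one PSI value per sample (mean over non-missing cells),
    two-sided t-test across samples.  ``per_cell_ranksum``: two-sided Wilcoxon
    rank-sum over cells.  Events missing in more than ``max_missing`` of the
    cells of either group are skipped.  delta_psi = mean(B) - mean(A).
    """
    adf = annotation_frame(ann)
    sample_of = adf["sample_id"]
    cells = pd.Index(psi.cell_ids)
    in_a = cells.isin(adf.index[sample_of.isin(group_a_samples)])
    in_b = cells.isin(adf.index[sample_of.isin(group_b_samples)])
    if mode == "per_sample_t" and (len(group_a_samples) < 2 or len(group_b_samples) < 2):
        raise ValueError("per_sample_t mode requires >= 2 samples per group")

    samp = np.asarray([sample_of.get(c, "") for c in psi.cell_ids])
    rows = []
    for i, event_id in enumerate(psi.event_ids):
        v = psi.values[i]
        va, vb = v[in_a], v[in_b]
        miss_a = np.isnan(va).mean() if va.size else 1.0
        miss_b = np.isnan(vb).mean() if vb.size else 1.0
        if miss_a > max_missing or miss_b > max_missing:
            logger.info("differential_psi: event %s skipped (missingness)", event_id)
            continue
        if mode == "per_sample_t":
            mean_a = [
                np.nanmean(v[(samp == s) & ~np.isnan(v)]) for s in group_a_samples
                if np.any((samp == s) & ~np.isnan(v))
            ]
            mean_b = [
                np.nanmean(v[(samp == s) & ~np.isnan(v)]) for s in group_b_samples
                if np.any((samp == s) & ~np.isnan(v))
            ]
            if len(mean_a) < 2 or len(mean_b) < 2:
                logger.info("differential_psi: event %s skipped (all-missing sample)", event_id)
                continue
            delta = float(np.mean(mean_b) - np.mean(mean_a))
            if np.allclose(mean_a, mean_a[0]) and np.allclose(mean_b, mean_b[0]) and np.isclose(
                mean_a[0], mean_b[0]
            ):
                p = 1.0
            else:
                p = float(stats.ttest_ind(mean_b, mean_a).pvalue)
            na, nb = len(mean_a), len(mean_b)
        elif mode == "per_cell_ranksum":
            xa, xb = va[~np.isnan(va)], vb[~np.isnan(vb)]
            if xa.size < 5 or xb.size < 5:
                logger.info("differential_psi: event %s skipped (too few cells)", event_id)
                continue
            delta = float(xb.mean() - xa.mean())
            p = float(stats.mannwhitneyu(xb, xa, alternative="two-sided").pvalue)
            na, nb = xa.size, xb.size
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append((event_id, delta, p, na, nb))

    out = pd.DataFrame(rows, columns=["event_id", "delta_psi", "p_value", "n_a", "n_b"])
    out["q_value"] = _bh(out["p_value"].to_numpy()) if len(out) else []
    return out[["event_id", "delta_psi", "p_value", "q_value", "n_a", "n_b"]]


@dataclass
class PsiPcaResult:
    event_ids: list[str]
    cell_ids: list[str]
    scores: np.ndarray          # cells x n_pcs
    weights: np.ndarray         # events x n_pcs, unit-norm columns
    pc_index: int               # 1-based severity PC
    orientation: int
    pseudo_severity: dict[str, float]
    selection_correlation: float


def psi_pca(
    psi: PsiMatrix,
    ann: Sequence[CellAnnotation],
    n_pcs: int = 15,
    max_missing: float = 0.30,
) -> PsiPcaResult:
    """PCA of cells in PSI space with per-event weights and a severity-PC pick.

    Events with >= ``max_missing`` missing cells are dropped; remaining missing
    entries are mean-imputed per event; events are centered (not scaled).  The
    severity PC maximizes |Spearman| against per-cell clinical scores.
    """
    from .severity_axis import _select_pc, _sign_convention

    miss = np.isnan(psi.values).mean(axis=1)
    keep = miss < max_missing
    if keep.sum() < 20:
        raise ValueError(
            f"psi_pca needs >= 20 events below {max_missing:.0%} missingness; have {keep.sum()}"
        )
    event_ids = [e for e, k in zip(psi.event_ids, keep) if k]
    x = psi.values[keep].copy()
    row_mean = np.nanmean(x, axis=1)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = row_mean[nan_r]
    x = x - x.mean(axis=1, keepdims=True)

    n_pcs = min(n_pcs, min(x.shape) - 1)
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)  # cells x events
    scores = u[:, :n_pcs] * s[:n_pcs]
    weights = vt[:n_pcs].T
    scores, weights = _sign_convention(scores, weights)

    adf = annotation_frame(ann)
    clin = np.array([adf.loc[c, "clinical_score"] for c in psi.cell_ids], dtype=float)
    pc_index, orientation, rho = _select_pc(scores, clin)
    v = orientation * scores[:, pc_index - 1]
    lo, hi = v.min(), v.max()
    pseudo = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return PsiPcaResult(
        event_ids=event_ids,
        cell_ids=list(psi.cell_ids),
        scores=scores,
        weights=weights,
        pc_index=pc_index,
        orientation=orientation,
        pseudo_severity=dict(zip(psi.cell_ids, pseudo)),
        selection_correlation=rho,
    )


def weights_frame(res: PsiPcaResult) -> pd.DataFrame:
    k = res.pc_index - 1
    return pd.DataFrame(
        {
            "event_id": res.event_ids,
            "weight": res.weights[:, k],
            "abs_weight": np.abs(res.weights[:, k]),
            "pc_index": res.pc_index,
        }
    )


def _spearman_vs_driver(values: np.ndarray, driver: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Spearman of each event row against the driver row."""
    n_ev = values.shape[0]
    r = np.full(n_ev, np.nan)
    p = np.full(n_ev, np.nan)
    for i in range(n_ev):
        ok = ~np.isnan(values[i]) & ~np.isnan(driver)
        n = ok.sum()
        if n < 5:
            continue
        ri, pi = stats.spearmanr(values[i][ok], driver[ok])
        r[i], p[i] = ri, pi
    return r, p


def driver_target_prediction(
    psi: PsiMatrix,
    driver_event: str,
    motif_target_events: set[str],
    disease_events: set[str],
    corr_q_threshold: float = 0.05,
) -> dict[str, object]:
    """Three-step driver-event target prediction.

    Keep events whose PSI correlates with the driver's (BH q < threshold),
    intersect with motif-flagged events, intersect with disease-associated
    events; enhanced = positive correlation, repressed = negative.
    """
    driver = psi.row(driver_event)
    if np.isnan(driver).mean() >= 0.30:
        raise ValueError(f"driver event {driver_event} has >= 30% missing cells")
    present = driver[~np.isnan(driver)]
    if np.allclose(present, present[0]):
        raise ValueError(f"driver event {driver_event} is constant")

    others = [e for e in psi.event_ids if e != driver_event]
    idx = [psi.event_ids.index(e) for e in others]
    r, p = _spearman_vs_driver(psi.values[idx], driver)
    q = _bh(p)

    enhanced, repressed = set(), set()
    detail = []
    for e, ri, qi in zip(others, r, q):
        sig = (not np.isnan(qi)) and qi < corr_q_threshold
        kept = sig and e in motif_target_events and e in disease_events
        cls = "none"
        if kept:
            if ri > 0:
                enhanced.add(e)
                cls = "enhanced"
            elif ri < 0:
                repressed.add(e)
                cls = "repressed"
        detail.append((e, ri, qi, e in motif_target_events, e in disease_events, cls))
    table = pd.DataFrame(
        detail, columns=["event_id", "rho", "corr_q", "motif_flag", "disease_flag", "call"]
    )
    return {"enhanced": enhanced, "repressed": repressed, "table": table}


def targets_frame(targets: dict[str, object]) -> pd.DataFrame:
    return targets["table"]


def overlap_with_known(predicted: set[str], known: set[str]) -> tuple[int, int, int]:
    """(n in both, n predicted-only, n known-only) — exact set arithmetic."""
    return (
        len(predicted & known),
        len(predicted - known),
        len(known - predicted),
    )


def combined_severity_coordinates(
    expr_axis,
    psi_axis: PsiPcaResult,
    ann: Sequence[CellAnnotation],
) -> pd.DataFrame:
    """Per-sample medians of the expression and splicing pseudo-severities."""
    shared = [
        c for c in expr_axis.pseudo_severity if c in psi_axis.pseudo_severity
    ]
    if not shared:
        raise ValueError("no overlapping cells between expression and splicing axes")
    adf = annotation_frame(ann)
    df = pd.DataFrame(
        {
            "cell_id": shared,
            "sample_id": [adf.loc[c, "sample_id"] for c in shared],
            "expr": [expr_axis.pseudo_severity[c] for c in shared],
            "psi": [psi_axis.pseudo_severity[c] for c in shared],
        }
    )
    agg = df.groupby("sample_id", sort=True).median(numeric_only=True).reset_index()
    agg.columns = ["sample_id", "expression_coord", "splicing_coord"]
    return agg
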