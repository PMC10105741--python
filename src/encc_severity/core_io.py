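"""Shared data model, file I/O, configuration and the pipeline driver.

All tabular artifacts are TSV with a header row, floats rendered at six
significant digits, NaN written as the literal ``NA`` and rows sorted on the
primary-key column so repeated runs are byte-identical.  Expression matrices
travel either as Matrix Market coordinate files (genes as rows) with sidecar
id lists, or as dense TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

logger = logging.getLogger("encc_severity")

TPM_TOTAL = 1e6
VALID_GROUPS = ("control", "S", "intermediate", "L", "TCA")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x cells expression data with raw counts plus derived layers.

    ``tpm`` columns each sum to one million (relative tolerance 1e-6);
    ``lognorm`` is filled in by :func:`encc_severity.qc_norm.normalize`.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    tpm: np.ndarray | None = None
    lognorm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError(
                f"id/matrix dimension mismatch: {len(self.gene_ids)} gene ids, "
                f"{len(self.cell_ids)} cell ids, matrix {self.counts.shape}"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {sorted(dup_g)[:5]}")
        dup_c = _duplicates(self.cell_ids)
        if dup_c:
            raise ValueError(f"duplicate cell ids: {sorted(dup_c)[:5]}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.tpm is None:
            self.tpm = counts_to_tpm(self.counts)
        else:
            self.tpm = np.asarray(self.tpm, dtype=float)
            if self.tpm.shape != self.counts.shape:
                raise ValueError("tpm layer shape differs from counts")
        if self.lognorm is not None:
            self.lognorm = np.asarray(self.lognorm, dtype=float)
            if self.lognorm.shape != self.counts.shape:
                raise ValueError("lognorm layer shape differs from counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def subset(
        self,
        gene_mask: np.ndarray | None = None,
        cell_mask: np.ndarray | None = None,
    ) -> "ExpressionMatrix":
        """Return a copy restricted to the masked genes/cells (boolean masks)."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask, bool)
        return ExpressionMatrix(
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            cell_ids=[c for c, k in zip(self.cell_ids, cm) if k],
            counts=self.counts[np.ix_(gm, cm)],
            tpm=self.tpm[np.ix_(gm, cm)],
            lognorm=None if self.lognorm is None else self.lognorm[np.ix_(gm, cm)],
        )


@dataclass
class CellAnnotation:
    """Per-cell sample membership, clinical score and QC covariates."""

    cell_id: str
    sample_id: str
    group: str
    clinical_score: int
    n_genes_detected: int
    mito_fraction: float
    uniquely_mapped_reads: int
    n_splices: int

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r} for cell {self.cell_id}")
        if not 0 <= int(self.clinical_score) <= 5:
            raise ValueError(f"clinical_score out of [0,5] for cell {self.cell_id}")
        if self.group == "control" and int(self.clinical_score) != 0:
            raise ValueError(f"control cell {self.cell_id} must have clinical_score 0")
        if not 0.0 <= float(self.mito_fraction) <= 1.0:
            raise ValueError(f"mito_fraction out of [0,1] for cell {self.cell_id}")
        for name in ("n_genes_detected", "uniquely_mapped_reads", "n_splices"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} negative for cell {self.cell_id}")


ANNOTATION_COLUMNS = [f.name for f in dataclasses.fields(CellAnnotation)]


def annotation_frame(ann: Sequence[CellAnnotation]) -> pd.DataFrame:
    """Tabulate annotations as a DataFrame indexed by cell_id (input order kept)."""
    df = pd.DataFrame([dataclasses.asdict(a) for a in ann], columns=ANNOTATION_COLUMNS)
    return df.set_index("cell_id", drop=False)


@dataclass
class GeneSet:
    """A named gene set (e.g. a GO accession) used for pathway/complex scoring."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def resolve(self, gene_ids: Sequence[str]) -> list[str]:
        """Members present in the matrix, in matrix order; misses are logged."""
        present = [g for g in gene_ids if g in self.genes]
        missing = self.genes.difference(present)
        if missing:
            logger.info(
                "gene set %s: %d/%d members unresolved", self.name, len(missing), len(self.genes)
            )
        return present


@dataclass
class PipelineConfig:
    """All tunable thresholds, paths and stage toggles.

    Defaults follow the published analysis; round-trips through YAML unchanged.
    """

    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 0

    # stage toggles (qc and axis always run; these gate downstream stages)
    run_dynamics: bool = True
    run_pathway: bool = True
    run_targets: bool = True
    run_splicing: bool = True

    # QC
    min_genes: int = 3000
    max_genes: int = 9000
    max_mito: float = 0.20
    min_cells_per_gene: int = 5
    drop_sample_unique_genes: bool = True

    # normalization / DEG
    scale_factor: float = 200_000.0
    deg_alpha: float = 0.05
    deg_min_log2fc: float = 0.5

    # severity axis
    n_pcs: int = 15
    n_hvg: int = 4500
    exclude_groups: list[str] = field(default_factory=lambda: ["TCA"])
    use_hvg: bool = True

    # dynamics / timing
    axis_q_threshold: float = 0.01
    core_fdr: float = 0.05
    n_modules: int = 4
    loess_span: float = 0.5
    n_bins: int = 50
    bin_alpha: float = 0.05
    min_cells_per_bin: int = 10

    # pathway
    gmt_file: str = "gene_sets.gmt"
    pathway_layer: str = "lognorm"

    # hub targets
    hub_gene: str = "HUB"
    binding_file: str = "binding_genes.txt"
    motif_file: str = "motif_hits.tsv"
    corr_q_threshold: float = 0.05
    min_motif_sites: int = 2

    # splicing
    events_file: str = "events.tsv"
    psi_file: str = "psi_matrix.tsv"
    motif_events_file: str = "motif_events.txt"
    driver_event: str = "EV_DRIVER"
    min_total_tpm: float = 1.0
    psi_max_missing: float = 0.30
    psi_alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


def counts_to_tpm(counts: np.ndarray) -> np.ndarray:
    """Scale each cell's counts to sum to one million.

    Gene-length correction is deliberately out of scope: the upstream study
    derives TPM from isoform-level quantification, which requires transcript
    models; this count-scaled stand-in is documented as such.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    tpm = np.zeros_like(counts)
    nz = totals > 0
    tpm[:, nz] = counts[:, nz] / totals[nz] * TPM_TOTAL
    return tpm


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> list[CellAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str, "group": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {sorted(missing)}")
    return [
        CellAnnotation(
            cell_id=str(r.cell_id),
            sample_id=str(r.sample_id),
            group=str(r.group),
            clinical_score=int(r.clinical_score),
            n_genes_detected=int(r.n_genes_detected),
            mito_fraction=float(r.mito_fraction),
            uniquely_mapped_reads=int(r.uniquely_mapped_reads),
            n_splices=int(r.n_splices),
        )
        for r in df.itertuples(index=False)
    ]


def write_annotation(ann: Sequence[CellAnnotation], path: str | Path) -> None:
    write_table(annotation_frame(ann).reset_index(drop=True), path, key="cell_id")


def read_expression(
    path_counts: str | Path,
    path_annotation: str | Path,
    format: str = "mtx",
) -> tuple[ExpressionMatrix, list[CellAnnotation]]:
    """Read a counts matrix plus its per-cell annotation.

    ``format='mtx'`` expects ``<stem>.mtx`` alongside ``<stem>_genes.txt`` and
    ``<stem>_cells.txt`` (one id per line); ``format='tsv'`` expects a dense
    table with gene ids in the first column and cell ids in the header.
    """
    path_counts = Path(path_counts)
    if format == "mtx":
        mat = scipy_io.mmread(path_counts)
        counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        stem = path_counts.with_suffix("")
        gene_ids = Path(f"{stem}_genes.txt").read_text().split()
        cell_ids = Path(f"{stem}_cells.txt").read_text().split()
    elif format == "tsv":
        df = pd.read_csv(path_counts, sep="\t", index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    matrix = ExpressionMatrix(gene_ids=gene_ids, cell_ids=cell_ids, counts=counts)
    ann = read_annotation(path_annotation)
    by_id = {a.cell_id: a for a in ann}
    missing = [c for c in matrix.cell_ids if c not in by_id]
    if missing:
        raise ValueError(f"annotation missing cells: {missing[:10]}")
    # keep matrix column order
    ann = [by_id[c] for c in matrix.cell_ids]
    samples: dict[str, str] = {}
    for a in ann:
        if a.cell_id in samples and samples[a.cell_id] != a.sample_id:
            raise ValueError(f"cell {a.cell_id} assigned to multiple samples")
        samples[a.cell_id] = a.sample_id
    return matrix, ann


def write_expression(matrix: ExpressionMatrix, path_counts: str | Path) -> None:
    """Write counts as Matrix Market coordinate plus sidecar id files."""
    path_counts = Path(path_counts)
    path_counts.parent.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(matrix.counts)
    scipy_io.mmwrite(str(path_counts), coo, field="integer")
    stem = path_counts.with_suffix("")
    Path(f"{stem}_genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    Path(f"{stem}_cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na", *sorted(s.genes)]) for s in sorted(sets, key=lambda s: s.name)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _format_value(v: object) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float) and (np.isnan(v) if isinstance(v, float) else False):
        return "NA"
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        if v == int(v) and abs(v) < 1e15:
            return f"{v:.6g}"
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    return str(v)


def write_table(df: pd.DataFrame, path: str | Path, key: str | None = None) -> None:
    """Write a result table as TSV: header, 6-significant-digit floats,
    NaN as ``NA``, rows sorted by the primary key (first column by default)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if key is None and len(out.columns):
        key = str(out.columns[0])
    if key is not None and key in out.columns and len(out):
        out = out.sort_values(key, kind="mergesort")
    cols = list(out.columns)
    lines = ["\t".join(map(str, cols))]
    for row in out.itertuples(index=False):
        lines.append("\t".join(_format_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> int:
    """Execute pipeline stages in order (qc -> axis -> dynamics -> pathway ->
    targets -> splicing), writing each stage's tables under ``config.out_dir``.

    Returns 0 on success; on stage failure logs the error, keeps partial
    outputs and returns 1.
    """
    from . import (
        coexpr_targets,
        dynamics_timing,
        pathway_activity,
        qc_norm,
        severity_axis,
        splicing_analysis,
    )

    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: data=%s out=%s seed=%d", data, out, config.seed)

    try:
        # ---- qc ----------------------------------------------------------
        matrix, ann = read_expression(data / "matrix.mtx", data / "annotation.tsv", format="mtx")
        logger.info("loaded matrix %dx%d", matrix.n_genes, matrix.n_cells)
        matrix, ann = qc_norm.filter_cells(
            matrix, ann, config.min_genes, config.max_genes, config.max_mito
        )
        matrix = qc_norm.filter_genes(matrix, config.min_cells_per_gene)
        if config.drop_sample_unique_genes:
            matrix = qc_norm.drop_sample_unique_genes(matrix, ann)
        matrix = qc_norm.normalize(matrix, config.scale_factor)
        adf = annotation_frame(ann)
        write_table(
            pd.DataFrame({"cell_id": matrix.cell_ids}), out / "cells_kept.tsv", key="cell_id"
        )
        write_table(
            pd.DataFrame({"gene_id": matrix.gene_ids}), out / "genes_kept.tsv", key="gene_id"
        )
        controls = sorted(adf.loc[adf["group"] == "control", "sample_id"].unique())
        cases = sorted(adf.loc[adf["group"] != "control", "sample_id"].unique())
        if len(controls) < 2:
            raise ValueError("consensus DEG calling requires two control samples")
        deg_tables: dict[str, pd.DataFrame] = {}
        for case in cases:
            deg = qc_norm.consensus_deg(
                matrix, ann, case, (controls[0], controls[1]),
                alpha=config.deg_alpha, min_log2fc=config.deg_min_log2fc,
            )
            deg_df = qc_norm.deg_frame(deg)
            deg_tables[case] = deg_df
            write_table(deg_df, out / f"deg_{case}.tsv", key="gene_id")
        logger.info("qc done: %dx%d cells kept, %d case DEG tables",
                    matrix.n_genes, matrix.n_cells, len(deg_tables))

        # ---- axis --------------------------------------------------------
        axis = severity_axis.build_axis(
            matrix, ann,
            n_pcs=config.n_pcs,
            n_hvg=config.n_hvg if config.use_hvg else None,
            exclude_groups=tuple(config.exclude_groups),
        )
        write_table(severity_axis.axis_cells_frame(axis), out / "axis_cells.tsv", key="cell_id")
        write_table(severity_axis.axis_meta_frame(axis), out / "axis_meta.tsv", key="field")
        logger.info("axis done: pc_index=%d rho=%.3f", axis.pc_index, axis.selection_correlation)

        # ---- dynamics ----------------------------------------------------
        if config.run_dynamics:
            dyn = dynamics_timing.axis_differential_test(
                matrix, axis, q_threshold=config.axis_q_threshold
            )
            sig = [d.gene_id for d in dyn if d.q_value < config.axis_q_threshold]
            write_table(dynamics_timing.dynamics_frame(dyn), out / "axis_deg.tsv", key="gene_id")
            if len(sig) >= config.n_modules:
                modules = dynamics_timing.smooth_and_cluster(
                    matrix, axis, sig, k=config.n_modules, loess_span=config.loess_span
                )
                write_table(modules.table, out / "modules.tsv", key="gene_id")
            core = dynamics_timing.core_gene_set(
                matrix, ann, dyn,
                deg_tables=deg_tables, adf=adf, core_fdr=config.core_fdr,
            )
            rows = []
            for g in core:
                sp = dynamics_timing.switch_timing(
                    matrix.lognorm[matrix.gene_index(g)], axis,
                    n_bins=config.n_bins, alpha=config.bin_alpha,
                    min_cells_per_bin=config.min_cells_per_bin,
                    cell_ids=matrix.cell_ids, gene_id=g,
                )
                rows.append(dynamics_timing.switch_row(sp))
            write_table(
                pd.DataFrame(rows, columns=dynamics_timing.SWITCH_COLUMNS),
                out / "switch_periods.tsv", key="gene_id",
            )
            logger.info("dynamics done: %d significant, %d core genes", len(sig), len(core))

        # ---- pathway -----------------------------------------------------
        if config.run_pathway:
            sets = read_gmt(data / config.gmt_file)
            pathway_sets = [s for s in sets if not s.name.startswith("COMPLEX")]
            complex_sets = [s for s in sets if s.name.startswith("COMPLEX")]
            score_rows, test_rows = [], []
            for s in pathway_sets:
                scores = pathway_activity.pathway_score(matrix, s)
                score_rows.append(pathway_activity.score_frame(scores))
                test_rows.append(pathway_activity.compare_pathway_groups(scores, ann))
            if score_rows:
                write_table(pd.concat(score_rows), out / "pathway_scores.tsv", key="cell_id")
                write_table(pd.concat(test_rows, ignore_index=True),
                            out / "pathway_tests.tsv", key="set_name")
            act_rows = [
                pathway_activity.activity_frame(pathway_activity.complex_activity(matrix, s))
                for s in complex_sets
            ]
            if act_rows:
                write_table(pd.concat(act_rows), out / "complex_activity.tsv", key="cell_id")
            logger.info("pathway done: %d sets, %d complexes",
                        len(pathway_sets), len(complex_sets))

        # ---- targets -----------------------------------------------------
        if config.run_targets:
            binding = set(
                (data / config.binding_file).read_text().split()
            )
            motif = pd.read_csv(data / config.motif_file, sep="\t")
            motif_counts = dict(zip(motif["gene_id"].astype(str), motif["n_sites"].astype(int)))
            case_cells = adf["group"] != "control"
            corr = coexpr_targets.condition_correlation(
                matrix, config.hub_gene, ann, condition=case_cells.to_numpy()
            )
            pooled_deg = qc_norm.consensus_deg(
                matrix, ann, list(cases), (controls[0], controls[1]),
                alpha=config.deg_alpha, min_log2fc=config.deg_min_log2fc,
            )
            calls = coexpr_targets.classify_hub_targets(
                corr, qc_norm.deg_frame(pooled_deg), binding,
                corr_q_threshold=config.corr_q_threshold,
                motif_counts=motif_counts,
            )
            write_table(coexpr_targets.calls_frame(calls),
                        out / "hub_target_calls.tsv", key="gene_id")
            deg_genes = {d.gene_id for d in pooled_deg}
            deg_flags = {g: g in deg_genes for g in matrix.gene_ids if g != config.hub_gene}
            motif_flags = {
                g: motif_counts.get(g, 0) >= config.min_motif_sites for g in deg_flags
            }
            orr, chi_p = coexpr_targets.motif_enrichment_test(deg_flags, motif_flags)
            write_table(
                pd.DataFrame({"metric": ["odds_ratio", "chi2_p"], "value": [orr, chi_p]}),
                out / "motif_enrichment.tsv", key="metric",
            )
            logger.info("targets done: %d calls, OR=%.3f",
                        sum(c.call != "none" for c in calls), orr)

        # ---- splicing ----------------------------------------------------
        if config.run_splicing:
            events = splicing_analysis.read_events(data / config.events_file)
            psi = splicing_analysis.read_psi(data / config.psi_file, events)
            psi = psi.subset_cells(matrix.cell_ids)
            freq = splicing_analysis.as_frequency(ann)
            write_table(
                pd.DataFrame({"cell_id": [a.cell_id for a in ann], "as_frequency": freq}),
                out / "as_frequency.tsv", key="cell_id",
            )
            ctrl_samples = list(controls)
            case_samples = list(cases)
            dpsi = splicing_analysis.differential_psi(
                psi, ann, ctrl_samples, case_samples, mode="per_cell_ranksum"
            )
            write_table(dpsi, out / "differential_psi.tsv", key="event_id")
            ppca = splicing_analysis.psi_pca(psi, ann, max_missing=config.psi_max_missing)
            write_table(splicing_analysis.weights_frame(ppca),
                        out / "psi_pca_weights.tsv", key="event_id")
            motif_events = set((data / config.motif_events_file).read_text().split())
            disease_events = set(
                dpsi.loc[dpsi["q_value"] < config.psi_alpha, "event_id"]
            )
            targets = splicing_analysis.driver_target_prediction(
                psi, config.driver_event, motif_events, disease_events,
                corr_q_threshold=config.corr_q_threshold,
            )
            write_table(splicing_analysis.targets_frame(targets),
                        out / "driver_targets.tsv", key="event_id")
            coords = splicing_analysis.combined_severity_coordinates(axis, ppca, ann)
            write_table(coords, out / "severity_2d.tsv", key="sample_id")
            logger.info("splicing done: %d events, %d driver targets",
                        psi.n_events, len(targets["enhanced"]) + len(targets["repressed"]))
    except Exception:
        logger.exception("pipeline stage failed; partial outputs retained in %s", out)
        return 1
    logger.info("pipeline complete")
    return 0
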