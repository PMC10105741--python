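"""Synthetic dataset generator with planted ground truth.

Plants every statistical structure the downstream stages assume: a per-sample
severity gradient with within-sample jitter, four dynamic gene-module
archetypes on the log-mean, switch-like genes with known switch centers, a
hub regulator with activated/repressed targets driven by a shared latent
activity, a high-variance severity-orthogonal nuisance factor, negative-
binomial counts with dropout, severity-linked AS frequency covariates, and a
PSI matrix with a severity-linked driver event, correlated target events and
a mutually exclusive partner whose PSI is exactly one minus the driver's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    read_expression,
    write_annotation,
    write_expression,
    write_gmt,
    write_table,
)
from .splicing_analysis import PsiMatrix, SpliceEvent, read_events, read_psi, write_events, write_psi

HUB_GENE = "HUB"
DRIVER_EVENT = "EV_DRIVER"
MXE_PARTNER = "EV_MXE"

_EVENT_TYPE_CYCLE = ("SE", "A5", "A3", "RI", "AF", "AL")


@dataclass
class SimConfig:
    """Knobs for :func:`simulate_dataset`; defaults match the scale used in
    the recovery tests (2 controls + 6 cases, 200 cells each)."""

    n_control_samples: int = 2
    n_case_samples: int = 6
    cells_per_sample: int = 200
    n_genes: int = 1000
    n_module_genes: int = 50          # per module
    n_switch_genes: int = 20
    n_hub_targets: int = 30           # per class (activated / repressed)
    n_nuisance_genes: int = 300
    n_events: int = 200
    n_driver_targets: int = 8         # per class (enhanced / repressed)
    effect_size: float = 2.0          # log-fold amplitude of severity effects
    nuisance_strength: float = 1.0
    nb_dispersion: float = 0.2
    dropout_rate: float = 0.2
    library_size_mean: int = 20000
    mito_gene_fraction: float = 0.01
    severity_jitter_sd: float = 0.03
    psi_concentration: float = 50.0
    psi_missing_rate: float = 0.02
    psi_effect: float = 1.0           # scales the driver PSI's severity link
    n_qc_fail_cells: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_samples < 2:
            raise ValueError("need >= 2 control samples (consensus DEG contract)")
        if self.n_case_samples < 2:
            raise ValueError("need >= 2 case samples for a severity gradient")
        if self.cells_per_sample < 5:
            raise ValueError("cells_per_sample too small")
        if self.effect_size < 0 or self.nb_dispersion <= 0:
            raise ValueError("effect_size must be >= 0 and nb_dispersion > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")
        n_mito = max(1, int(self.n_genes * self.mito_gene_fraction))
        planted = (
            4 * self.n_module_genes + self.n_switch_genes + 1 + 2 * self.n_hub_targets
            + self.n_nuisance_genes + n_mito
        )
        if planted > self.n_genes:
            raise ValueError(f"n_genes={self.n_genes} too small for {planted} planted genes")
        if self.n_events < 2 * self.n_driver_targets + 4:
            raise ValueError("n_events too small for planted events plus nulls")


@dataclass
class SimulationTruth:
    """Planted assignments needed by the recovery tests."""

    sample_severity: dict[str, float]
    cell_severity: dict[str, float]
    module_label: dict[str, int | None]
    switch_center: dict[str, float]
    switch_direction: dict[str, str]
    hub_gene: str
    hub_target_class: dict[str, str]
    driver_event: str
    driver_target_class: dict[str, str]
    mxe_pair: tuple[str, str]
    binding_genes: set[str] = field(default_factory=set)
    motif_counts: dict[str, int] = field(default_factory=dict)
    motif_target_events: set[str] = field(default_factory=set)
    qc_fail_cells: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.hub_target_class.get(self.hub_gene, "none") != "none":
            raise ValueError("hub gene cannot be its own target")
        for s, v in self.sample_severity.items():
            if not 0 <= v <= 1:
                raise ValueError(f"sample severity out of [0,1]: {s}={v}")


@dataclass
class Dataset:
    matrix: ExpressionMatrix
    annotation: list[CellAnnotation]
    psi: PsiMatrix
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# archetype curves (values in [0,1]; scaled by effect_size on the log-mean)
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def module_curve(module: int, t: np.ndarray) -> np.ndarray:
    """The four dynamic archetypes: 1 up-early then decay, 2 monotone down,
    3 up-late, 4 down-late."""
    if module == 1:
        return np.exp(-(((t - 0.2) / 0.15) ** 2))
    if module == 2:
        return 1.0 - t
    if module == 3:
        return _sigmoid((t - 0.7) / 0.08)
    if module == 4:
        return _sigmoid(-(t - 0.7) / 0.08)
    raise ValueError(f"unknown module {module}")


def _case_group(severity: float) -> str:
    if severity >= 0.999:
        return "TCA"
    if severity > 0.6:
        return "L"
    if severity > 0.4:
        return "intermediate"
    return "S"


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> Dataset:
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_expr, rng_ann, rng_psi, rng_aux = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    # --- samples, cells, severity ------------------------------------------
    samples: list[tuple[str, float, str, int]] = []
    for i in range(config.n_control_samples):
        samples.append((f"CTRL{i + 1}", 0.0, "control", 0))
    for i in range(1, config.n_case_samples + 1):
        s = i / config.n_case_samples
        samples.append((f"CASE{i}", s, _case_group(s), int(np.floor(s * 5 + 0.5))))

    cell_ids, cell_sample, cell_group, cell_score, cell_sev = [], [], [], [], []
    sample_severity: dict[str, float] = {}
    for sample_id, sev, group, score in samples:
        sample_severity[sample_id] = sev
        for j in range(config.cells_per_sample):
            cell_ids.append(f"{sample_id}_c{j + 1:03d}")
            cell_sample.append(sample_id)
            cell_group.append(group)
            cell_score.append(score)
            cell_sev.append(float(np.clip(sev + rng_ann.normal(0, config.severity_jitter_sd), 0, 1)))
    n_cells = len(cell_ids)
    t = np.asarray(cell_sev)

    # --- gene layout --------------------------------------------------------
    n_mito = max(1, int(config.n_genes * config.mito_gene_fraction))
    gene_ids: list[str] = [f"MT-{i + 1}" for i in range(n_mito)] + [HUB_GENE]
    gene_ids += [f"G{i + 1:04d}" for i in range(config.n_genes - n_mito - 1)]
    gene_ids = gene_ids[: config.n_genes]

    module_label: dict[str, int | None] = {g: None for g in gene_ids}
    switch_center: dict[str, float] = {}
    switch_direction: dict[str, str] = {}
    hub_target_class: dict[str, str] = {g: "none" for g in gene_ids}

    plain = [g for g in gene_ids if g != HUB_GENE and not g.startswith("MT-")]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = plain[cursor: cursor + n]
        cursor += n
        return out

    module_genes = {m: take(config.n_module_genes) for m in (1, 2, 3, 4)}
    for m, genes in module_genes.items():
        for g in genes:
            module_label[g] = m
    switch_genes = take(config.n_switch_genes)
    for i, g in enumerate(switch_genes):
        switch_center[g] = float(rng_aux.uniform(0.25, 0.75))
        switch_direction[g] = "up" if i % 2 == 0 else "down"
    activated = take(config.n_hub_targets)
    repressed = take(config.n_hub_targets)
    for g in activated:
        hub_target_class[g] = "activated"
    for g in repressed:
        hub_target_class[g] = "repressed"
    nuisance_genes = take(config.n_nuisance_genes)
    null_genes = plain[cursor:]

    # --- log-mean matrix ----------------------------------------------------
    pos = {g: i for i, g in enumerate(gene_ids)}
    base = rng_expr.normal(0.0, 0.6, size=config.n_genes)
    eff = np.zeros((config.n_genes, n_cells))

    h = t + rng_expr.normal(0.0, 0.05, size=n_cells)      # hub latent activity
    u = rng_expr.normal(0.0, 1.0, size=n_cells)           # severity-orthogonal nuisance

    for m, genes in module_genes.items():
        curve = module_curve(m, t)
        for g in genes:
            eff[pos[g]] = config.effect_size * curve
    for g in switch_genes:
        step = _sigmoid((t - switch_center[g]) / 0.05)
        sgn = 1.0 if switch_direction[g] == "up" else -1.0
        eff[pos[g]] = sgn * config.effect_size * step
    eff[pos[HUB_GENE]] = config.effect_size * h
    for g in activated:
        eff[pos[g]] = config.effect_size * h
    for g in repressed:
        eff[pos[g]] = -config.effect_size * h
    nw = rng_expr.uniform(0.5, 1.0, size=len(nuisance_genes)) * rng_expr.choice(
        [-1.0, 1.0], size=len(nuisance_genes)
    )
    for g, w in zip(nuisance_genes, nw):
        eff[pos[g]] = config.nuisance_strength * w * u

    mu = np.exp(base[:, None] + eff)
    mu *= config.library_size_mean / mu.sum(axis=0, keepdims=True)

    # --- NB counts with dropout --------------------------------------------
    shape = 1.0 / config.nb_dispersion
    lam = rng_expr.gamma(shape, mu * config.nb_dispersion)
    counts = rng_expr.poisson(lam).astype(np.int64)
    if config.dropout_rate > 0:
        keep = rng_expr.random(counts.shape) >= config.dropout_rate
        counts = counts * keep

    # --- annotation ---------------------------------------------------------
    mito_rows = [pos[g] for g in gene_ids if g.startswith("MT-")]
    mito_frac = counts[mito_rows].sum(axis=0) / np.maximum(counts.sum(axis=0), 1)
    n_detected = rng_ann.integers(4000, 8001, size=n_cells)
    reads = rng_ann.integers(800_000, 1_200_001, size=n_cells)
    splice_rate = 0.15 + 0.10 * t
    n_splices = rng_ann.poisson(reads * splice_rate)

    mito_obs = np.minimum(mito_frac + 0.02, 0.18)  # keep honest cells under the QC bound
    qc_fail_cells: set[str] = set()
    fail_modes = ("low", "high", "mito")
    for i in range(min(config.n_qc_fail_cells, n_cells)):
        qc_fail_cells.add(cell_ids[i])
        mode = fail_modes[i % 3]
        if mode == "low":
            n_detected[i] = 2000
        elif mode == "high":
            n_detected[i] = 9500
        else:
            mito_obs[i] = 0.5

    annotation = [
        CellAnnotation(
            cell_id=cell_ids[i],
            sample_id=cell_sample[i],
            group=cell_group[i],
            clinical_score=cell_score[i],
            n_genes_detected=int(n_detected[i]),
            mito_fraction=float(mito_obs[i]),
            uniquely_mapped_reads=int(reads[i]),
            n_splices=int(n_splices[i]),
        )
        for i in range(n_cells)
    ]

    # --- PSI layer ----------------------------------------------------------
    conc = config.psi_concentration

    def beta_around(mean: np.ndarray) -> np.ndarray:
        m = np.clip(mean, 0.02, 0.98)
        return rng_psi.beta(m * conc, (1.0 - m) * conc)

    driver_psi = beta_around(0.3 + 0.4 * t * config.psi_effect)
    event_ids: list[str] = [DRIVER_EVENT, MXE_PARTNER]
    values = [driver_psi, 1.0 - driver_psi]
    driver_target_class: dict[str, str] = {DRIVER_EVENT: "none", MXE_PARTNER: "none"}
    events: dict[str, SpliceEvent] = {
        DRIVER_EVENT: _mk_event(DRIVER_EVENT, "GDRIVER", "SE"),
        MXE_PARTNER: _mk_event(MXE_PARTNER, "GDRIVER", "MX"),
    }
    for i in range(config.n_driver_targets):
        e = f"EV_ENH{i + 1:02d}"
        event_ids.append(e)
        values.append(beta_around(0.1 + 0.8 * driver_psi))
        driver_target_class[e] = "enhanced"
        events[e] = _mk_event(e, f"GT{i + 1:03d}", "SE")
    for i in range(config.n_driver_targets):
        e = f"EV_REP{i + 1:02d}"
        event_ids.append(e)
        values.append(beta_around(0.9 - 0.8 * driver_psi))
        driver_target_class[e] = "repressed"
        events[e] = _mk_event(e, f"GR{i + 1:03d}", "SE")
    n_null_events = config.n_events - len(event_ids)
    null_means = rng_psi.uniform(0.2, 0.8, size=n_null_events)
    for i in range(n_null_events):
        e = f"EV_N{i + 1:04d}"
        event_ids.append(e)
        values.append(beta_around(np.full(n_cells, null_means[i])))
        driver_target_class[e] = "none"
        events[e] = _mk_event(e, f"GN{i + 1:04d}", _EVENT_TYPE_CYCLE[i % len(_EVENT_TYPE_CYCLE)])

    psi_vals = np.vstack(values)
    if config.psi_missing_rate > 0:
        miss = rng_psi.random(psi_vals.shape) < config.psi_missing_rate
        miss[1] = miss[0]  # the MX pair is jointly observed, keeping the sum-to-1 invariant
        psi_vals = np.where(miss, np.nan, psi_vals)
    psi = PsiMatrix(event_ids=event_ids, cell_ids=list(cell_ids), values=psi_vals, events=events)

    # --- evidence lists -----------------------------------------------------
    true_targets = activated + repressed
    decoys = list(null_genes[: len(true_targets)])
    binding = set(true_targets) | set(decoys)

    affected = set(true_targets) | set(switch_genes) | {
        g for genes in module_genes.values() for g in genes
    }
    motif_counts: dict[str, int] = {}
    for g in gene_ids:
        if g in affected:
            motif_counts[g] = int(rng_aux.integers(2, 6)) if rng_aux.random() < 0.6 else int(
                rng_aux.integers(0, 2)
            )
        else:
            motif_counts[g] = int(rng_aux.integers(2, 4)) if rng_aux.random() < 0.15 else 0

    motif_events = {e for e, c in driver_target_class.items() if c != "none"}
    motif_events.add(MXE_PARTNER)
    n_decoy_events = max(1, n_null_events // 10)
    motif_events.update(f"EV_N{i + 1:04d}" for i in range(n_decoy_events))

    truth = SimulationTruth(
        sample_severity=sample_severity,
        cell_severity=dict(zip(cell_ids, t)),
        module_label=module_label,
        switch_center=switch_center,
        switch_direction=switch_direction,
        hub_gene=HUB_GENE,
        hub_target_class=hub_target_class,
        driver_event=DRIVER_EVENT,
        driver_target_class=driver_target_class,
        mxe_pair=(DRIVER_EVENT, MXE_PARTNER),
        binding_genes=binding,
        motif_counts=motif_counts,
        motif_target_events=motif_events,
        qc_fail_cells=qc_fail_cells,
    )
    matrix = ExpressionMatrix(gene_ids=gene_ids, cell_ids=cell_ids, counts=counts)
    return Dataset(matrix=matrix, annotation=annotation, psi=psi, truth=truth)


def _mk_event(event_id: str, gene_id: str, etype: str) -> SpliceEvent:
    return SpliceEvent(
        event_id=event_id,
        gene_id=gene_id,
        type=etype,
        inclusion_isoforms=frozenset({f"{event_id}_inc"}),
        total_isoforms=frozenset({f"{event_id}_inc", f"{event_id}_exc"}),
    )


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(dataset: Dataset, out_dir: str | Path) -> None:
    """Write the dataset and its ground truth as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.matrix, out / "matrix.mtx")
    write_annotation(dataset.annotation, out / "annotation.tsv")
    write_psi(dataset.psi, out / "psi_matrix.tsv")
    write_events(dataset.psi.events, out / "events.tsv")

    tr = dataset.truth
    write_table(
        pd.DataFrame(
            {"sample_id": list(tr.sample_severity), "severity": list(tr.sample_severity.values())}
        ),
        out / "truth_samples.tsv",
        key="sample_id",
    )
    genes = dataset.matrix.gene_ids
    write_table(
        pd.DataFrame(
            {
                "gene_id": genes,
                "module": [tr.module_label.get(g) or 0 for g in genes],
                "switch_center": [tr.switch_center.get(g, np.nan) for g in genes],
                "switch_direction": [tr.switch_direction.get(g, "NA") for g in genes],
                "hub_target_class": [tr.hub_target_class.get(g, "none") for g in genes],
                "is_hub": [g == tr.hub_gene for g in genes],
            }
        ),
        out / "truth_genes.tsv",
        key="gene_id",
    )
    write_table(
        pd.DataFrame(
            {
                "cell_id": list(tr.cell_severity),
                "severity": list(tr.cell_severity.values()),
                "qc_fail": [c in tr.qc_fail_cells for c in tr.cell_severity],
            }
        ),
        out / "truth_cells.tsv",
        key="cell_id",
    )
    write_table(
        pd.DataFrame(
            {
                "event_id": dataset.psi.event_ids,
                "driver_target_class": [
                    tr.driver_target_class.get(e, "none") for e in dataset.psi.event_ids
                ],
                "is_driver": [e == tr.driver_event for e in dataset.psi.event_ids],
                "mxe_partner": [
                    tr.mxe_pair[1] if e == tr.mxe_pair[0]
                    else (tr.mxe_pair[0] if e == tr.mxe_pair[1] else "NA")
                    for e in dataset.psi.event_ids
                ],
            }
        ),
        out / "truth_events.tsv",
        key="event_id",
    )
    (out / "binding_genes.txt").write_text("\n".join(sorted(tr.binding_genes)) + "\n")
    write_table(
        pd.DataFrame(
            {"gene_id": list(tr.motif_counts), "n_sites": list(tr.motif_counts.values())}
        ),
        out / "motif_hits.tsv",
        key="gene_id",
    )
    (out / "motif_events.txt").write_text("\n".join(sorted(tr.motif_target_events)) + "\n")

    sets = [
        GeneSet(name=f"SET_MODULE{m}", genes=frozenset(g for g, lab in tr.module_label.items() if lab == m))
        for m in (1, 2, 3, 4)
        if any(lab == m for lab in tr.module_label.values())
    ]
    well_expressed = [g for g in genes if tr.module_label.get(g) is None][:3]
    if len(well_expressed) == 3:
        sets.append(GeneSet(name="COMPLEX_EXAMPLE", genes=frozenset(well_expressed)))
    write_gmt(sets, out / "gene_sets.gmt")


def read_fixture(out_dir: str | Path) -> Dataset:
    """Re-read a fixture directory written by :func:`write_fixture`."""
    out = Path(out_dir)
    matrix, annotation = read_expression(out / "matrix.mtx", out / "annotation.tsv", format="mtx")
    events = read_events(out / "events.tsv")
    psi = read_psi(out / "psi_matrix.tsv", events)

    s = pd.read_csv(out / "truth_samples.tsv", sep="\t")
    g = pd.read_csv(out / "truth_genes.tsv", sep="\t", na_values=["NA"], keep_default_na=False)
    c = pd.read_csv(out / "truth_cells.tsv", sep="\t")
    e = pd.read_csv(out / "truth_events.tsv", sep="\t", na_values=["NA"], keep_default_na=False)
    motif = pd.read_csv(out / "motif_hits.tsv", sep="\t")

    mxe_a = e.loc[e["mxe_partner"].notna(), "event_id"].tolist()
    driver = e.loc[e["is_driver"], "event_id"].iloc[0]
    partner = e.loc[e["event_id"] == driver, "mxe_partner"].iloc[0]
    truth = SimulationTruth(
        sample_severity=dict(zip(s["sample_id"], s["severity"])),
        cell_severity=dict(zip(c["cell_id"], c["severity"])),
        module_label={
            r.gene_id: (int(r.module) if r.module else None) for r in g.itertuples(index=False)
        },
        switch_center={
            r.gene_id: float(r.switch_center)
            for r in g.itertuples(index=False)
            if pd.notna(r.switch_center)
        },
        switch_direction={
            r.gene_id: r.switch_direction
            for r in g.itertuples(index=False)
            if pd.notna(r.switch_direction)
        },
        hub_gene=g.loc[g["is_hub"], "gene_id"].iloc[0],
        hub_target_class=dict(zip(g["gene_id"], g["hub_target_class"])),
        driver_event=driver,
        driver_target_class=dict(zip(e["event_id"], e["driver_target_class"])),
        mxe_pair=(driver, partner),
        binding_genes=set((out / "binding_genes.txt").read_text().split()),
        motif_counts=dict(zip(motif["gene_id"], motif["n_sites"].astype(int))),
        motif_target_events=set((out / "motif_events.txt").read_text().split()),
        qc_fail_cells=set(c.loc[c["qc_fail"], "cell_id"]),
    )
    assert mxe_a  # both pair members carry the link
    return Dataset(matrix=matrix, annotation=annotation, psi=psi, truth=truth)


def small_config(seed: int = 0) -> SimConfig:
    """The committed 20-gene x 60-cell / 6-event fixture configuration."""
    return SimConfig(
        n_control_samples=2,
        n_case_samples=2,
        cells_per_sample=15,
        n_genes=20,
        n_module_genes=2,
        n_switch_genes=2,
        n_hub_targets=2,
        n_nuisance_genes=2,
        n_events=6,
        n_driver_targets=1,
        library_size_mean=2000,
        n_qc_fail_cells=5,
        seed=seed,
    )
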