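# encc-severity

Severity-stratification analysis pipeline for single-cell transcriptomes of
iPSC-derived enteric neural crest cells (ENCCs), with a synthetic-data
generator that plants the statistical structure the analysis assumes.

The pipeline takes a genes x cells count matrix with per-cell annotations
(sample, group, clinical severity score 0-5, QC covariates) plus a PSI
(percent spliced in) matrix, and produces:

- **QC & normalization** — cell filtering (3000-9000 detected genes, <=20%
  mitochondrial fraction), gene filtering (detected in >=5 cells),
  log-normalization with scale factor 200,000, and consensus differential
  expression: a gene is a DEG only if significant (BH q < 0.05, |log2FC| >
  0.5, rank-sum test) against *both* control lines in the same direction.
- **Pseudo-severity axis** — PCA on standardized expression (top-dispersion
  HVGs); the principal component whose scores best track clinical severity
  (max |Spearman|) becomes the axis, oriented controls-low and rescaled to
  [0,1].
- **Gene dynamics & switch timing** — spline likelihood-ratio test for genes
  differential along the axis, LOESS profiles clustered into four dynamic
  modules, and per-gene "switch periods" from 50-bin local regressions
  (interquartile range of significant-bin centers).
- **Pathway & complex activity** — additive (mean) pathway scores per cell
  and geometric-mean complex activity that is zero whenever any subunit is
  unexpressed.
- **Hub-regulator targets** — three-step differential co-expression target
  calling (correlation with the hub in case cells, consensus-DEG filter,
  binding-evidence filter; activated/repressed by sign rules) and a 2x2
  DEG x motif enrichment test against the non-DEG background.
- **Splicing layer** — per-cell AS frequency (splices / uniquely mapped
  reads), PSI computation from isoform abundances, per-sample (t-test) and
  per-cell (rank-sum) differential PSI, PCA on PSI with per-event weights and
  a splicing severity axis, driver-event target prediction (correlation +
  motif + disease-association filters), and combined per-sample
  expression/splicing severity coordinates.

All expected-value thresholds default to the published analysis settings.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: closed-form
oracles (1e-12 against brute force), QC contract on the committed fixture,
null calibration of every inferential test, and recovery of the planted
severity axis, modules, switch centers and hub/driver targets over 10
simulation seeds.

## CLI

```bash
# generate a synthetic dataset with ground truth
encc-severity simulate --seed 1 --out data/

# run stages (each reads/writes per a YAML config)
encc-severity all --config cfg.yaml --seed 1
encc-severity qc --config cfg.yaml        # through QC only
encc-severity splicing --config cfg.yaml  # through the splicing stage
```

A config file is a YAML rendering of `PipelineConfig`
(`python -c "from encc_severity.core_io import PipelineConfig; PipelineConfig().to_yaml('cfg.yaml')"`
writes the defaults). Stage outputs are deterministic TSVs: the same config
and seed produce byte-identical results.

Input formats: Matrix Market counts (`matrix.mtx` + `matrix_genes.txt` /
`matrix_cells.txt`) or dense TSV, per-cell annotation TSV, GMT gene sets,
an event catalog TSV (event id, gene, type, inclusion/total isoforms), a PSI
matrix TSV, and plain-text binding/motif evidence lists. TPM is computed by
per-cell count scaling when absent — a stand-in that ignores gene length
(isoform-level quantification is out of scope).

## Layout

```
src/encc_severity/
  core_io.py            data model, I/O, config, pipeline driver
  synthio.py            synthetic data with planted ground truth
  qc_norm.py            filtering, normalization, consensus DEGs
  severity_axis.py      PCA severity axis
  dynamics_timing.py    axis DEGs, modules, switch timing
  pathway_activity.py   pathway scores, complex activity
  coexpr_targets.py     hub-target prediction, motif enrichment
  splicing_analysis.py  PSI layer
  cli.py                encc-severity command
tests/                  unit + property + acceptance suites
tests/data/fixture_small/   committed 20x60 fixture (seed 0)
```
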