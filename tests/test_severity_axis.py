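import numpy as np
import pandas as pd
import pytest
from scipy import stats

from encc_severity.core_io import CellAnnotation, ExpressionMatrix, annotation_frame
from encc_severity.severity_axis import (
    PcaResult,
    build_axis,
    fit_pca,
    group_axis_test,
    select_severity_pc,
)


def _ann(cell_id, sample="S1", group="control", score=0):
    return CellAnnotation(
        cell_id=cell_id, sample_id=sample, group=group, clinical_score=score,
        n_genes_detected=5000, mito_fraction=0.05,
        uniquely_mapped_reads=1_000_000, n_splices=150_000,
    )


def _lognorm_matrix(lognorm):
    n_genes, n_cells = lognorm.shape
    return ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
        np.zeros((n_genes, n_cells), int),
        lognorm=lognorm,
    )


class TestFitPca:
    def test_planted_factor_recovered(self, rng):
        factor = rng.normal(0, 1, 200)
        loadings = rng.normal(0, 1, 60)
        x = np.outer(loadings, factor) + rng.normal(0, 0.3, (60, 200))
        pca = fit_pca(_lognorm_matrix(x), n_pcs=5, n_hvg=None)
        rho = stats.spearmanr(pca.scores[:, 0], factor).statistic
        assert abs(rho) > 0.95

    def test_duplicate_cells_identical_scores(self, rng):
        x = rng.normal(0, 1, (30, 40))
        dup = np.concatenate([x, x[:, :1]], axis=1)
        pca = fit_pca(_lognorm_matrix(dup), n_pcs=3, n_hvg=None)
        np.testing.assert_allclose(pca.scores[0], pca.scores[-1], atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        x = rng.normal(0, 1, (50, 80))
        pca = fit_pca(_lognorm_matrix(x), n_pcs=6, n_hvg=None)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(0, 1, (50, 80))
        a = fit_pca(_lognorm_matrix(x), n_pcs=4, n_hvg=None)
        b = fit_pca(_lognorm_matrix(x.copy()), n_pcs=4, n_hvg=None)
        np.testing.assert_array_equal(a.scores, b.scores)
        for k in range(4):
            j = np.argmax(np.abs(a.loadings[:, k]))
            assert a.loadings[j, k] > 0

    def test_hvg_larger_than_genes_uses_all(self, rng):
        x = rng.normal(0, 1, (30, 40))
        pca = fit_pca(_lognorm_matrix(np.abs(x)), n_pcs=3, n_hvg=1000)
        assert len(pca.gene_ids) == 30


def _toy_pca(scores, cell_ids=None):
    n, k = scores.shape
    cell_ids = cell_ids or [f"c{j}" for j in range(n)]
    return PcaResult(
        gene_ids=[f"g{i}" for i in range(3)],
        cell_ids=cell_ids,
        scores=np.asarray(scores, float),
        loadings=np.eye(3)[:, :k],
        gene_mean=np.zeros(3),
        gene_sd=np.ones(3),
    )


class TestSelectSeverityPc:
    def _ann_by_score(self, scores):
        out = []
        for j, s in enumerate(scores):
            group = "control" if s == 0 else "L"
            out.append(_ann(f"c{j}", sample=f"P{s}", group=group, score=int(s)))
        return out

    def test_monotone_toy_rho_one(self):
        clin = [0, 0, 1, 2, 3, 4]
        scores = np.column_stack([np.arange(6, dtype=float)])
        axis = select_severity_pc(_toy_pca(scores), self._ann_by_score(clin))
        assert axis.selection_correlation == pytest.approx(
            stats.spearmanr(np.arange(6), clin).statistic
        )
        assert axis.pc_index == 1
        assert min(axis.pseudo_severity.values()) == 0.0
        assert max(axis.pseudo_severity.values()) == 1.0

    def test_orientation_flip_invariance(self):
        clin = [0, 0, 1, 2, 3, 4]
        raw = np.column_stack([np.array([0.1, -0.2, 0.5, 1.0, 1.4, 2.2])])
        a = select_severity_pc(_toy_pca(raw), self._ann_by_score(clin))
        b = select_severity_pc(_toy_pca(-raw), self._ann_by_score(clin))
        for c in a.pseudo_severity:
            assert a.pseudo_severity[c] == pytest.approx(b.pseudo_severity[c], abs=1e-12)

    def test_positive_affine_invariance(self):
        clin = [0, 0, 1, 2, 3, 4]
        raw = np.column_stack([np.array([0.1, -0.2, 0.5, 1.0, 1.4, 2.2])])
        a = select_severity_pc(_toy_pca(raw), self._ann_by_score(clin))
        b = select_severity_pc(_toy_pca(3.5 * raw + 11.0), self._ann_by_score(clin))
        for c in a.pseudo_severity:
            assert a.pseudo_severity[c] == pytest.approx(b.pseudo_severity[c], abs=1e-10)

    def test_all_scores_equal_fatal(self):
        scores = np.column_stack([np.arange(4, dtype=float)])
        ann = [_ann(f"c{j}") for j in range(4)]
        with pytest.raises(ValueError, match="severity contrast"):
            select_severity_pc(_toy_pca(scores), ann)

    def test_tie_broken_by_lower_index(self):
        clin = [0, 0, 1, 2, 3, 4]
        col = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0])
        scores = np.column_stack([col, col * 2.0])
        axis = select_severity_pc(_toy_pca(scores), self._ann_by_score(clin))
        assert axis.pc_index == 1


class TestBuildAxisOnSynthetic:
    def test_severity_pc_is_second(self, default_axis):
        """The planted severity factor sits below the larger nuisance factor."""
        assert default_axis.pc_index == 2

    def test_sample_median_recovery(self, default_dataset, processed_default, default_axis):
        m, ann = processed_default
        adf = annotation_frame(ann)
        med = pd.Series(default_axis.pseudo_severity).groupby(adf["sample_id"]).median()
        truth = pd.Series(default_dataset.truth.sample_severity)
        rho = stats.spearmanr(med.sort_index(), truth.sort_index()).statistic
        assert rho >= 0.9

    def test_controls_below_l_group(self, processed_default, default_axis):
        _, ann = processed_default
        adf = annotation_frame(ann)
        ps = pd.Series(default_axis.pseudo_severity)
        ctrl = ps[adf.index[adf["group"] == "control"]].median()
        lgrp = ps[adf.index[adf["group"] == "L"]].median()
        assert ctrl <= lgrp

    def test_excluded_tca_cells_still_scored(self, processed_default, default_axis):
        m, ann = processed_default
        adf = annotation_frame(ann)
        tca = adf.index[adf["group"] == "TCA"]
        assert len(tca) > 0
        for c in tca:
            assert c in default_axis.pseudo_severity
            assert 0.0 <= default_axis.pseudo_severity[c] <= 1.0

    def test_stability_under_cell_removal(self, default_dataset, processed_default):
        m, ann = processed_default
        rng = np.random.default_rng(42)
        keep = rng.random(m.n_cells) >= 0.10
        sub_ann = [a for a, k in zip(ann, keep) if k]
        axis_full = build_axis(m, ann)
        axis_sub = build_axis(m.subset(cell_mask=keep), sub_ann)
        adf = annotation_frame(ann)
        med_f = pd.Series(axis_full.pseudo_severity).groupby(adf["sample_id"]).median()
        adf_s = annotation_frame(sub_ann)
        med_s = pd.Series(axis_sub.pseudo_severity).groupby(adf_s["sample_id"]).median()
        assert (med_f - med_s).abs().max() < 0.05


class TestGroupAxisTest:
    def _axis(self, values, ann):
        from encc_severity.severity_axis import SeverityAxis

        cells = [a.cell_id for a in ann]
        return SeverityAxis(
            pc_index=1, loadings={}, cell_score=dict(zip(cells, values)),
            pseudo_severity=dict(zip(cells, values)), orientation=1,
            selection_correlation=1.0,
        )

    def test_identical_groups_high_p(self, rng):
        vals = list(rng.random(20)) * 2
        ann = [
            _ann(f"a{j}", sample="A", group="S", score=1) for j in range(20)
        ] + [
            _ann(f"b{j}", sample="B", group="L", score=4) for j in range(20)
        ]
        _, p = group_axis_test(self._axis(vals, ann), ann, "S", "L")
        assert p > 0.9

    def test_disjoint_supports_tiny_p(self, rng):
        vals = list(np.linspace(0, 0.4, 20)) + list(np.linspace(0.6, 1.0, 20))
        ann = [
            _ann(f"a{j}", sample="A", group="S", score=1) for j in range(20)
        ] + [
            _ann(f"b{j}", sample="B", group="L", score=4) for j in range(20)
        ]
        _, p = group_axis_test(self._axis(vals, ann), ann, "S", "L")
        assert p < 1e-6

    def test_planted_s_vs_l_significant(self, processed_default, default_axis):
        _, ann = processed_default
        _, p = group_axis_test(default_axis, ann, "S", "L")
        assert p < 0.01

    def test_empty_group_fatal(self, processed_default, default_axis):
        _, ann = processed_default
        no_tca = [a for a in ann if a.group != "TCA"]
        with pytest.raises(ValueError):
            group_axis_test(default_axis, no_tca, "S", "TCA")
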