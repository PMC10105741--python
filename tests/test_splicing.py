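import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from encc_severity.core_io import CellAnnotation, annotation_frame
from encc_severity.splicing_analysis import (
    PsiMatrix,
    SpliceEvent,
    as_frequency,
    combined_severity_coordinates,
    compute_psi,
    differential_psi,
    driver_target_prediction,
    overlap_with_known,
    psi_pca,
)


def _ann(cell_id, sample="S1", group="control", score=0, reads=1000, splices=100):
    return CellAnnotation(
        cell_id=cell_id, sample_id=sample, group=group, clinical_score=score,
        n_genes_detected=5000, mito_fraction=0.05,
        uniquely_mapped_reads=reads, n_splices=splices,
    )


def _event(event_id="E1", inclusion=("i1",), total=("i1", "i2")):
    return SpliceEvent(
        event_id=event_id, gene_id="G", type="SE",
        inclusion_isoforms=frozenset(inclusion), total_isoforms=frozenset(total),
    )


class TestSpliceEvent:
    def test_inclusion_must_be_proper_subset(self):
        with pytest.raises(ValueError, match="proper"):
            _event(inclusion=("i1", "i2"), total=("i1", "i2"))

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="type"):
            SpliceEvent("E", "G", "XX", frozenset({"a"}), frozenset({"a", "b"}))

    def test_psi_values_bounded(self):
        with pytest.raises(ValueError, match="0,1"):
            PsiMatrix(["e1"], ["c1"], np.array([[1.5]]))


class TestAsFrequency:
    def test_simple_ratio(self):
        out = as_frequency([_ann("c1", reads=1000, splices=100)])
        assert out[0] == pytest.approx(0.1)

    def test_zero_splices(self):
        assert as_frequency([_ann("c1", splices=0)])[0] == 0.0

    def test_zero_reads_is_missing(self):
        out = as_frequency([_ann("c1", reads=0, splices=0), _ann("c2")])
        assert np.isnan(out[0]) and not np.isnan(out[1])

    def test_severity_group_contrast(self, default_dataset):
        """L cells splice more than controls (planted severity link)."""
        ds = default_dataset
        adf = annotation_frame(ds.annotation)
        freq = as_frequency(ds.annotation)
        lab = adf["group"].to_numpy()
        p = stats.mannwhitneyu(
            freq[lab == "L"], freq[lab == "control"], alternative="greater"
        ).pvalue
        assert p < 0.001


class TestComputePsi:
    def test_arithmetic(self):
        psi = compute_psi({"i1": 30.0, "i2": 10.0}, _event())
        assert psi == pytest.approx(0.75, abs=1e-12)

    def test_exclusion_zero_gives_one(self):
        assert compute_psi({"i1": 5.0, "i2": 0.0}, _event()) == pytest.approx(1.0)

    def test_below_threshold_missing(self):
        assert np.isnan(compute_psi({"i1": 0.3, "i2": 0.1}, _event(), min_total_tpm=1.0))

    def test_missing_isoform_fatal(self):
        with pytest.raises(KeyError, match="i2"):
            compute_psi({"i1": 3.0}, _event())

    @settings(max_examples=100, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.floats(0.0, 100.0),
            min_size=4,
            max_size=4,
        )
    )
    def test_matches_brute_force_and_complementarity(self, tpm):
        ev = SpliceEvent("E", "G", "SE", frozenset({"a", "b"}), frozenset({"a", "b", "c", "d"}))
        total = sum(tpm.values())
        psi = compute_psi(tpm, ev, min_total_tpm=0.0 if total > 0 else -1.0)
        expected = (
            (tpm["a"] + tpm["b"]) / total if total > 0 else np.nan
        )
        if np.isnan(expected):
            assert np.isnan(psi)
        else:
            assert psi == pytest.approx(expected, abs=1e-12)
            flipped = SpliceEvent(
                "E2", "G", "SE", frozenset({"c", "d"}), frozenset({"a", "b", "c", "d"})
            )
            assert psi + compute_psi(tpm, flipped, min_total_tpm=0.0) == pytest.approx(
                1.0, abs=1e-12
            )


def _psi_fixture(rng, n_null=30, n_cells_per=40, driver_shift=True):
    """Controls A,B and cases C,D with an optional planted driver event."""
    ann, cells = [], []
    for sample, group, score in [
        ("A", "control", 0), ("B", "control", 0), ("C", "S", 2), ("D", "L", 4),
    ]:
        for j in range(n_cells_per):
            cid = f"{sample}_{j}"
            cells.append(cid)
            ann.append(_ann(cid, sample=sample, group=group, score=score))
    case = np.array([c.startswith(("C", "D")) for c in cells])
    sev = np.array([0, 0, 0.5, 1.0]).repeat(n_cells_per)
    rows, ids = [], []
    mu_d = 0.3 + 0.4 * sev * (1.0 if driver_shift else 0.0)
    driver = rng.beta(mu_d * 50, (1 - mu_d) * 50, len(cells))
    rows.append(driver)
    ids.append("DRV")
    for i in range(n_null):
        mu = rng.uniform(0.3, 0.7)
        rows.append(rng.beta(mu * 50, (1 - mu) * 50, len(cells)))
        ids.append(f"N{i}")
    return PsiMatrix(ids, cells, np.vstack(rows)), ann, case


class TestDifferentialPsi:
    def test_identical_groups_null(self, rng):
        psi, ann, _ = _psi_fixture(rng, driver_shift=False)
        res = differential_psi(psi, ann, ["A", "B"], ["C", "D"], mode="per_sample_t")
        drv = res[res["event_id"] == "DRV"].iloc[0]
        assert abs(drv["delta_psi"]) < 0.1
        assert (res["q_value"] > 0.05).sum() >= len(res) - 1

    def test_planted_driver_detected(self, rng):
        psi, ann, _ = _psi_fixture(rng)
        res = differential_psi(psi, ann, ["A", "B"], ["C", "D"], mode="per_cell_ranksum")
        drv = res[res["event_id"] == "DRV"].iloc[0]
        assert drv["q_value"] < 0.05
        assert drv["delta_psi"] > 0.2

    def test_per_sample_requires_two_samples(self, rng):
        psi, ann, _ = _psi_fixture(rng)
        with pytest.raises(ValueError, match="2 samples"):
            differential_psi(psi, ann, ["A"], ["C", "D"], mode="per_sample_t")

    def test_high_missingness_event_skipped(self, rng):
        psi, ann, _ = _psi_fixture(rng)
        vals = psi.values.copy()
        vals[1, :100] = np.nan
        psi2 = PsiMatrix(psi.event_ids, psi.cell_ids, vals)
        res = differential_psi(psi2, ann, ["A", "B"], ["C", "D"], mode="per_cell_ranksum")
        assert "N0" not in set(res["event_id"])

    def test_delta_sign_convention(self, rng):
        psi, ann, _ = _psi_fixture(rng)
        res = differential_psi(psi, ann, ["A", "B"], ["C", "D"], mode="per_sample_t")
        drv = res[res["event_id"] == "DRV"].iloc[0]
        assert drv["delta_psi"] > 0  # delta = mean(cases) - mean(controls)


class TestPsiPca:
    def test_duplicated_events_equal_weights(self, default_dataset):
        psi = default_dataset.psi
        vals = np.vstack([psi.values, psi.values[:1]])
        dup = PsiMatrix(psi.event_ids + ["dup"], psi.cell_ids, vals)
        res = psi_pca(dup, default_dataset.annotation)
        i = res.event_ids.index(psi.event_ids[0])
        j = res.event_ids.index("dup")
        np.testing.assert_allclose(res.weights[i], res.weights[j], atol=1e-8)

    def test_weight_vector_unit_norm(self, default_dataset):
        res = psi_pca(default_dataset.psi, default_dataset.annotation)
        norms = np.linalg.norm(res.weights, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    def test_too_few_events_fatal(self, rng):
        psi, ann, _ = _psi_fixture(rng, n_null=5)
        with pytest.raises(ValueError, match="20 events"):
            psi_pca(psi, ann)

    def test_planted_events_top_weighted(self, default_dataset):
        ds = default_dataset
        res = psi_pca(ds.psi, ds.annotation)
        w = pd.Series(
            np.abs(res.weights[:, res.pc_index - 1]), index=res.event_ids
        ).sort_values(ascending=False)
        linked = {e for e, c in ds.truth.driver_target_class.items() if c != "none"}
        linked |= set(ds.truth.mxe_pair)
        top = set(w.index[: len(w) // 10])
        assert len(linked & top) / len(linked) >= 0.8


class TestDriverTargets:
    def test_mxe_partner_repressed_with_perfect_anticorrelation(self, default_dataset):
        ds = default_dataset
        partner = ds.truth.mxe_pair[1]
        res = driver_target_prediction(
            ds.psi, ds.truth.driver_event,
            motif_target_events=ds.truth.motif_target_events,
            disease_events=set(ds.psi.event_ids),
        )
        assert partner in res["repressed"]
        row = res["table"].set_index("event_id").loc[partner]
        assert row["rho"] == pytest.approx(-1.0, abs=1e-12)

    def test_correlated_event_without_motif_excluded(self, default_dataset):
        ds = default_dataset
        enhanced = [e for e, c in ds.truth.driver_target_class.items() if c == "enhanced"]
        motif = ds.truth.motif_target_events - {enhanced[0]}
        res = driver_target_prediction(
            ds.psi, ds.truth.driver_event,
            motif_target_events=motif, disease_events=set(ds.psi.event_ids),
        )
        assert enhanced[0] not in res["enhanced"] | res["repressed"]

    def test_constant_driver_fatal(self, rng):
        psi, ann, _ = _psi_fixture(rng)
        vals = psi.values.copy()
        vals[0] = 0.5
        psi2 = PsiMatrix(psi.event_ids, psi.cell_ids, vals)
        with pytest.raises(ValueError, match="constant"):
            driver_target_prediction(psi2, "DRV", set(), set())


class TestOverlap:
    def test_identical_sets(self):
        assert overlap_with_known({"a", "b"}, {"a", "b"}) == (2, 0, 0)

    def test_disjoint_sets(self):
        assert overlap_with_known({"a"}, {"b", "c"}) == (0, 1, 2)

    def test_random_sets_match_brute_force(self, rng):
        universe = [f"e{i}" for i in range(50)]
        pred = {e for e in universe if rng.random() < 0.4}
        known = {e for e in universe if rng.random() < 0.3}
        n_both = sum(1 for e in universe if e in pred and e in known)
        n_pred = sum(1 for e in universe if e in pred and e not in known)
        n_known = sum(1 for e in universe if e not in pred and e in known)
        assert overlap_with_known(pred, known) == (n_both, n_pred, n_known)


class TestCombinedCoordinates:
    def test_controls_in_lowest_tercile(self, default_dataset, default_axis):
        ds = default_dataset
        ppca = psi_pca(ds.psi, ds.annotation)
        coords = combined_severity_coordinates(default_axis, ppca, ds.annotation)
        adf = annotation_frame(ds.annotation)
        groups = dict(zip(adf["sample_id"], adf["group"]))
        for col in ("expression_coord", "splicing_coord"):
            ranked = coords.sort_values(col)["sample_id"].tolist()
            cutoff = len(ranked) // 3 + 1
            for s, g in groups.items():
                if g == "control":
                    assert ranked.index(s) < cutoff, (col, ranked)

    def test_identical_layers_equal_after_rescale(self, default_axis, processed_default):
        from encc_severity.splicing_analysis import PsiPcaResult

        _, ann = processed_default
        cells = list(default_axis.pseudo_severity)
        fake = PsiPcaResult(
            event_ids=[], cell_ids=cells, scores=np.zeros((len(cells), 1)),
            weights=np.zeros((0, 1)), pc_index=1, orientation=1,
            pseudo_severity=dict(default_axis.pseudo_severity),
            selection_correlation=1.0,
        )
        coords = combined_severity_coordinates(default_axis, fake, ann)
        np.testing.assert_allclose(
            coords["expression_coord"], coords["splicing_coord"], atol=1e-12
        )

    def test_splicing_ablation_decouples_coordinates(self):
        """With the PSI-severity link zeroed, the splicing coordinate loses its
        severity correlation while the expression coordinate keeps it."""
        from encc_severity import qc_norm
        from encc_severity.severity_axis import build_axis
        from encc_severity.synthio import SimConfig, simulate_dataset

        ds = simulate_dataset(SimConfig(seed=5, psi_effect=0.0))
        m, ann = qc_norm.filter_cells(ds.matrix, ds.annotation)
        m = qc_norm.normalize(qc_norm.filter_genes(m))
        axis = build_axis(m, ann)
        ppca = psi_pca(ds.psi.subset_cells(m.cell_ids), ann)
        coords = combined_severity_coordinates(axis, ppca, ann).set_index("sample_id")
        truth = pd.Series(ds.truth.sample_severity)
        rho_expr = stats.spearmanr(
            coords["expression_coord"], truth[coords.index]
        ).statistic
        assert rho_expr >= 0.9
        # null check at cell resolution: with 8 samples the max-|Spearman| PC
        # pick inflates sample-level correlation by selection alone
        t = np.array([ds.truth.cell_severity[c] for c in ppca.cell_ids])
        cells_pseudo = np.array([ppca.pseudo_severity[c] for c in ppca.cell_ids])
        rho_psi = stats.spearmanr(cells_pseudo, t).statistic
        assert abs(rho_psi) < 0.3

    def test_no_overlap_fatal(self, default_axis):
        from encc_severity.splicing_analysis import PsiPcaResult

        fake = PsiPcaResult(
            event_ids=[], cell_ids=[], scores=np.zeros((0, 1)),
            weights=np.zeros((0, 1)), pc_index=1, orientation=1,
            pseudo_severity={}, selection_correlation=0.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            combined_severity_coordinates(default_axis, fake, [])
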