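import numpy as np
import pandas as pd
import pytest

import panelforge as pf


def _panel(subtype, feats, target, control):
    k = len(feats)
    return pf.Panel(
        subtype=subtype,
        features=feats,
        centroid_target=np.asarray(target, dtype=float),
        centroid_control=np.asarray(control, dtype=float),
        centroid_se=np.zeros(k),
        scale=np.ones(k),
        priors=(0.5, 0.5),
        mean_error_rate=0.0,
        sd_error_rate=0.0,
        mean_auc=1.0,
        sd_auc=0.0,
        n_iterations=1,
    )


@pytest.fixture()
def three_panels():
    """Orthogonal 5-gene panels over a shared 15-gene space."""
    gene_ids = [f"g{i}" for i in range(15)]
    panels = []
    for k, subtype in enumerate(pf.SUBTYPES):
        feats = [
            (gene_ids[5 * k + j], "expression", "+" if j < 3 else "-") for j in range(5)
        ]
        target = [1.0, 1.0, 1.0, -1.0, -1.0]
        control = [-0.5, -0.5, -0.5, 0.5, 0.5]
        panels.append(_panel(subtype, feats, target, control))
    return panels, gene_ids


class TestScoreSample:
    def test_sample_at_target_centroid_assigned_to_subtype(self, three_panels):
        panels, gene_ids = three_panels
        for k, panel in enumerate(panels):
            x = pd.Series(0.0, index=gene_ids)
            x[panel.feature_ids] = panel.centroid_target
            # push other panels' features toward their control centroids
            for other in panels:
                if other.subtype != panel.subtype:
                    x[other.feature_ids] = other.centroid_control
            scores, label = pf.score_sample(panels, x)
            assert label == panel.subtype
            assert scores.idxmax() == panel.subtype

    def test_exact_tie_resolved_in_fixed_order(self, three_panels, caplog):
        panels, gene_ids = three_panels
        x = pd.Series(0.0, index=gene_ids)  # equidistant for every panel
        with caplog.at_level("WARNING"):
            _, label = pf.score_sample(panels, x)
        assert label == "Classical"
        assert "tie" in caplog.text.lower()

    def test_missing_feature_rejected(self, three_panels):
        panels, gene_ids = three_panels
        x = pd.Series(0.0, index=gene_ids[1:])
        with pytest.raises(pf.PanelforgeError, match="g0"):
            pf.score_sample(panels, x)


class TestClassifyCohort:
    def test_synthetic_validation_accuracy(self, small_cohort):
        expr, beta, sheet, truth = small_cohort
        mv = pf.beta_to_mvalue(beta)
        panels = []
        for st in pf.SUBTYPES:
            info = truth.informative[st]
            g = info[info["modality"] == "expression"]
            pos = g[g["direction"] == "+"]["feature_id"].tolist()[:3]
            neg = g[g["direction"] == "-"]["feature_id"].tolist()[:2]
            feats = [(f, "expression", "+") for f in pos] + [(f, "expression", "-") for f in neg]
            panels.append(
                pf.estimate_panel(feats, expr, None, sheet, st, n_iter=5, seed=1)
            )
        table = pf.classify_cohort(panels, expr, None)
        truth_labels = sheet.subtype_of().reindex(table.index)
        assert (table["subtype"] == truth_labels).mean() >= 0.85

    def test_single_sample_needs_prescaled_input(self, three_panels):
        panels, gene_ids = three_panels
        m = pf.OmicsMatrix(
            pd.DataFrame(np.zeros((15, 1)), index=gene_ids, columns=["only"]),
            "expression",
        )
        with pytest.raises(pf.PanelforgeError, match="single-sample"):
            pf.classify_cohort(panels, m)
        out = pf.classify_cohort(panels, m, rescale=False)
        assert list(out.index) == ["only"]

    def test_sample_order_permutation_permutes_rows_only(self, three_panels):
        panels, gene_ids = three_panels
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(8)]
        m = pf.OmicsMatrix(
            pd.DataFrame(rng.normal(size=(15, 8)), index=gene_ids, columns=cols),
            "expression",
        )
        a = pf.classify_cohort(panels, m)
        perm = cols[::-1]
        b = pf.classify_cohort(panels, m.select_samples(perm))
        pd.testing.assert_frame_equal(a.loc[perm], b)


@pytest.fixture(scope="module")
def sc_setup():
    cfg = pf.SimCellConfig(
        n_patients=6,
        cells_per_patient=120,
        n_genes=300,
        n_informative_genes=15,
        gene_effect=2.0,
        noise_sd_cell=0.6,
        seed=31,
    )
    cells, patient_map, truth = pf.simulate_cells(cfg)
    panels = []
    for st in pf.SUBTYPES:
        info = truth.informative[st]
        pos = info[info["direction"] == "+"]["feature_id"].tolist()
        neg = info[info["direction"] == "-"]["feature_id"].tolist()
        feats = [(f, "expression", "+") for f in pos[:3]] + [
            (f, "expression", "-") for f in neg[:2]
        ]
        ids = [f for f, _, _ in feats]
        z = pf.zscore_normalize(cells.select_features(ids))
        t_mask = truth.cell_subtype == st
        target = z.values.loc[:, t_mask.to_numpy()].mean(axis=1).to_numpy()
        control = z.values.loc[:, (~t_mask).to_numpy()].mean(axis=1).to_numpy()
        panels.append(_panel(st, feats, target, control))
    return cells, patient_map, truth, panels


class TestSingleCell:
    def test_cell_fractions_close_to_generating_mixture(self, sc_setup):
        cells, patient_map, truth, panels = sc_setup
        table = pf.classify_cells(panels, cells)
        frac = pf.subtype_proportions(table["subtype"], patient_map)
        diff = (frac - truth.patient_mixture.loc[frac.index]).abs().to_numpy()
        assert diff.mean() < 0.1

    def test_fractions_sum_to_one(self, sc_setup):
        cells, patient_map, _, panels = sc_setup
        table = pf.classify_cells(panels, cells)
        frac = pf.subtype_proportions(table["subtype"], patient_map)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_pseudobulk_agrees_with_predominant_subtype(self, sc_setup):
        cells, patient_map, truth, panels = sc_setup
        table = pf.classify_cells(panels, cells)
        frac = pf.subtype_proportions(table["subtype"], patient_map)
        predominant = pf.predominant_subtype(frac)
        pb = pf.pseudobulk(cells, patient_map)
        pb_label = pf.classify_cohort(panels, pb)["subtype"]
        decided = predominant != "none"
        agree = (pb_label[decided] == predominant[decided]).mean()
        assert agree >= 0.8


class TestPredominance:
    def test_strict_majority_rule(self):
        frac = pd.DataFrame(
            {"Classical": [0.5, 0.6], "Mesenchymal": [0.3, 0.2], "Proneural": [0.2, 0.2]},
            index=["p1", "p2"],
        )
        out = pf.predominant_subtype(frac)
        assert out["p1"] == "none"  # 0.5 is not > 0.5
        assert out["p2"] == "Classical"

    def test_pure_patient(self):
        frac = pd.DataFrame(
            {"Classical": [1.0], "Mesenchymal": [0.0], "Proneural": [0.0]}, index=["p"]
        )
        assert pf.predominant_subtype(frac)["p"] == "Classical"


class TestPseudobulk:
    def test_single_cell_identity(self):
        df = pd.DataFrame({"c1": [1.0, 2.0]}, index=["g1", "g2"])
        cells = pf.OmicsMatrix(df, "expression")
        pb = pf.pseudobulk(cells, pd.Series({"c1": "p1"}))
        np.testing.assert_allclose(pb.values["p1"], [1.0, 2.0])

    def test_duplicating_cells_leaves_mean_unchanged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4, 6)),
                          index=[f"g{i}" for i in range(4)],
                          columns=[f"c{i}" for i in range(6)])
        cells = pf.OmicsMatrix(df, "expression")
        pm = pd.Series("p1", index=df.columns)
        doubled = pd.concat([df, df.add_suffix("_dup")], axis=1)
        cells2 = pf.OmicsMatrix(doubled, "expression")
        pm2 = pd.Series("p1", index=doubled.columns)
        np.testing.assert_allclose(
            pf.pseudobulk(cells, pm).values["p1"],
            pf.pseudobulk(cells2, pm2).values["p1"],
            atol=1e-12,
        )

    def test_unmapped_cell_rejected(self):
        df = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g"])
        cells = pf.OmicsMatrix(df, "expression")
        with pytest.raises(pf.PanelforgeError, match="cover"):
            pf.pseudobulk(cells, pd.Series({"c1": "p1"}))
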