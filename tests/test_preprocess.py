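import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panelforge as pf
from oracles import combat_oracle


def _expr(df):
    return pf.OmicsMatrix(df, "expression")


class TestFilterLowExpression:
    def test_quarter_cut_on_u133a_sized_matrix(self):
        # 12,042 genes: ceil(0.25 * 12042) = 3011 removed, 9031 retained
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(7, 2, size=(12042, 4)),
            index=[f"g{i}" for i in range(12042)],
            columns=list("abcd"),
        )
        kept = pf.filter_low_expression(_expr(df), 0.25)
        assert kept.n_features == 9031
        assert 12042 - kept.n_features == 3011

    def test_lowest_mean_gene_removed(self):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0], "s2": [1.0, 2.0, 3.0, 4.0]},
            index=list("dcba"),
        )
        kept = pf.filter_low_expression(_expr(df), 0.25)
        assert "d" not in kept.feature_ids and kept.n_features == 3

    def test_ceil_rounding_on_three_genes(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0]}, index=list("abc"))
        kept = pf.filter_low_expression(_expr(df), 0.25)
        assert kept.n_features == 2

    def test_survivors_keep_original_order(self):
        df = pd.DataFrame({"s1": [5.0, 1.0, 4.0, 3.0]}, index=list("wxyz"))
        kept = pf.filter_low_expression(_expr(df), 0.25)
        assert kept.feature_ids == ["w", "y", "z"]


class TestZscore:
    def test_unit_spaced_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z = pf.zscore_normalize(_expr(df))
        np.testing.assert_allclose(z.values.loc["g"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert z.modality == "zscore"

    def test_constant_row_maps_to_zeros(self, caplog):
        df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc"))
        with caplog.at_level("WARNING"):
            z = pf.zscore_normalize(_expr(df))
        np.testing.assert_array_equal(z.values.loc["g"], [0.0, 0.0, 0.0])
        assert "constant" in caplog.text

    def test_output_standardized_and_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(3, 4, size=(20, 9)))
        z = pf.zscore_normalize(_expr(df))
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-12)
        z2 = pf.zscore_normalize(pf.OmicsMatrix(z.values, "expression"))
        np.testing.assert_allclose(z2.values.to_numpy(), z.values.to_numpy(), atol=1e-9)

    def test_single_sample_rejected(self):
        df = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(pf.PanelforgeError):
            pf.zscore_normalize(_expr(df))


class TestMvalueTransform:
    @pytest.mark.parametrize(
        "beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)]
    )
    def test_known_logit2_values(self, beta, expected):
        df = pd.DataFrame([[beta]], index=["cg"], columns=["s"])
        m = pf.beta_to_mvalue(pf.OmicsMatrix(df, "beta"))
        assert m.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert m.modality == "mvalue"

    def test_clipping_at_the_boundaries(self):
        eps = 1e-6
        df = pd.DataFrame([[1.0], [0.0]], index=["hi", "lo"], columns=["s"])
        m = pf.beta_to_mvalue(pf.OmicsMatrix(df, "beta"), eps=eps)
        expected = np.log2((1 - eps) / eps)
        assert m.values.loc["hi", "s"] == pytest.approx(expected)
        assert m.values.loc["lo", "s"] == pytest.approx(-expected)

    def test_invalid_eps_rejected(self):
        df = pd.DataFrame([[0.5]], index=["cg"], columns=["s"])
        with pytest.raises(pf.PanelforgeError):
            pf.beta_to_mvalue(pf.OmicsMatrix(df, "beta"), eps=0.7)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_round_trip_identity_inside_clipping_range(self, beta):
        df = pd.DataFrame([[beta]], index=["cg"], columns=["s"])
        back = pf.mvalue_to_beta(pf.beta_to_mvalue(pf.OmicsMatrix(df, "beta")))
        assert abs(back.values.iloc[0, 0] - beta) < 1e-9


class TestIntersectCommonFeatures:
    def test_partial_overlap(self):
        a = _expr(pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"]))
        b = _expr(pd.DataFrame(np.ones((3, 2)), index=list("bcd"), columns=["t1", "t2"]))
        ra, rb = pf.intersect_common_features(a, b)
        assert ra.feature_ids == rb.feature_ids == ["b", "c"]
        assert ra.sample_ids == ["s1", "s2"] and rb.sample_ids == ["t1", "t2"]

    def test_identical_inputs_unchanged(self):
        a = _expr(pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"]))
        ra, rb = pf.intersect_common_features(a, a)
        assert ra.feature_ids == list("abc")

    def test_disjoint_inputs_rejected(self):
        a = _expr(pd.DataFrame(np.ones((2, 2)), index=list("ab"), columns=["s1", "s2"]))
        b = _expr(pd.DataFrame(np.ones((2, 2)), index=list("cd"), columns=["t1", "t2"]))
        with pytest.raises(pf.PanelforgeError, match="shared"):
            pf.intersect_common_features(a, b)


class TestCombat:
    def _matrix_with_batches(self, seed=0, p=60):
        rng = np.random.default_rng(seed)
        n1, n2 = 15, 15
        x = rng.normal(0, 1, size=(p, n1 + n2))
        # per-feature additive shift in the second source
        x[:, n1:] += rng.normal(0.0, 1.5, size=(p, 1))
        cols = [f"s{i}" for i in range(n1 + n2)]
        batch = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
        m = pf.OmicsMatrix(pd.DataFrame(x, index=[f"f{j}" for j in range(p)], columns=cols),
                           "mvalue", batch)
        return m, batch

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(3)
        cols = [f"s{i}" for i in range(6)]
        m = pf.OmicsMatrix(
            pd.DataFrame(rng.normal(size=(5, 6)), columns=cols),
            "mvalue",
            pd.Series(["A"] * 6, index=cols),
        )
        out, fit = pf.combat_correct(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-10)

    def test_additive_shift_removed(self):
        m, batch = self._matrix_with_batches()
        out, _ = pf.combat_correct(m, batch)
        pre = (m.values.loc[:, batch == "A"].mean(axis=1)
               - m.values.loc[:, batch == "B"].mean(axis=1)).abs().mean()
        post = (out.values.loc[:, batch == "A"].mean(axis=1)
                - out.values.loc[:, batch == "B"].mean(axis=1)).abs().mean()
        assert post < 0.1 * pre

    def test_ordering_preserved_and_shapes_equal(self):
        m, batch = self._matrix_with_batches(seed=5)
        out, _ = pf.combat_correct(m, batch)
        assert out.feature_ids == m.feature_ids
        assert out.sample_ids == m.sample_ids

    def test_matches_independent_eb_transliteration(self):
        # 20 features x 12 samples, two batches
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, size=(20, 12))
        x[:, 6:] += 1.5
        cols = [f"s{i}" for i in range(12)]
        batch = pd.Series(["A"] * 6 + ["B"] * 6, index=cols)
        m = pf.OmicsMatrix(pd.DataFrame(x, columns=cols), "mvalue", batch)
        ours, _ = pf.combat_correct(m, batch, tol=1e-8)
        ref = combat_oracle([list(r) for r in x], list(batch), tol=1e-8)
        np.testing.assert_allclose(ours.values.to_numpy(), np.array(ref), atol=1e-6)

    def test_singleton_batch_rejected(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(5)]
        m = pf.OmicsMatrix(pd.DataFrame(rng.normal(size=(4, 5)), columns=cols), "mvalue")
        with pytest.raises(pf.PanelforgeError, match="fewer than 2"):
            pf.combat_correct(m, pd.Series(["A"] * 4 + ["B"], index=cols))
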