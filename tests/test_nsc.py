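import numpy as np
import pandas as pd
import pytest

import panelforge as pf
from panelforge.nsc import threshold_grid
from oracles import nsc_fit_oracle, nsc_score_oracle


def _random_instance(rng, p=None, n=None, k=2):
    p = p or rng.integers(3, 10)
    n = n or rng.integers(2 * k + 2, 25)
    x = rng.normal(size=(p, n))
    labels = rng.permutation(np.array([f"C{i % k}" for i in range(n)]))
    cols = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(x, index=[f"f{j}" for j in range(p)], columns=cols)
    return df, pd.Series(labels, index=cols)


class TestFitAgainstOracle:
    @pytest.mark.parametrize("k", [2, 3])
    def test_fit_and_score_match_brute_force(self, k):
        """Full fit + score path vs an independently coded loop oracle."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            df, labels = _random_instance(rng, k=k)
            delta = float(rng.uniform(0, 2))
            model = pf.nsc_fit(df, labels, delta=delta)
            ref = nsc_fit_oracle(
                [list(r) for r in df.to_numpy()], list(labels), delta
            )
            assert model.classes == ref["classes"]
            np.testing.assert_allclose(model.centroids, np.array(ref["centroids"]), atol=1e-10)
            np.testing.assert_allclose(model.s, ref["s"], atol=1e-10)
            assert model.s0 == pytest.approx(ref["s0"], abs=1e-12)
            np.testing.assert_allclose(model.d, np.array(ref["d"]), atol=1e-10)
            np.testing.assert_allclose(
                model.shrunken_centroids, np.array(ref["shrunken"]), atol=1e-10
            )
            xstar = rng.normal(size=df.shape[0])
            sample = pd.Series(xstar, index=df.index)
            disc, post, pred = pf.nsc_score(model, sample)
            rdisc, rpost, rpred = nsc_score_oracle(ref, list(xstar))
            np.testing.assert_allclose(disc.iloc[0].to_numpy(), rdisc, atol=1e-10)
            np.testing.assert_allclose(post.iloc[0].to_numpy(), rpost, atol=1e-10)
            assert pred.iloc[0] == rpred


class TestFitProperties:
    def test_equal_class_means_give_zero_deviation(self):
        cols = list("abcd")
        df = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["f"], columns=cols)
        labels = pd.Series(["X", "X", "Y", "Y"], index=cols)
        model = pf.nsc_fit(df, labels, delta=0.7)
        np.testing.assert_allclose(model.d[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(model.shrunken_centroids[0], model.overall_centroid[0])

    def test_full_shrinkage_collapses_to_overall_centroid(self):
        rng = np.random.default_rng(4)
        df, labels = _random_instance(rng)
        base = pf.nsc_fit(df, labels, delta=0.0)
        big = float(np.abs(base.d).max()) + 0.1
        model = pf.nsc_fit(df, labels, delta=big)
        np.testing.assert_allclose(
            model.shrunken_centroids,
            np.repeat(model.overall_centroid[:, None], len(model.classes), axis=1),
            atol=1e-12,
        )

    def test_zero_delta_preserves_centroids(self):
        rng = np.random.default_rng(5)
        df, labels = _random_instance(rng)
        model = pf.nsc_fit(df, labels, delta=0.0)
        np.testing.assert_allclose(model.shrunken_centroids, model.centroids, atol=1e-12)

    def test_surviving_feature_count_monotone_in_delta(self):
        rng = np.random.default_rng(6)
        df, labels = _random_instance(rng, p=15, n=24)
        base = pf.nsc_fit(df, labels, delta=0.0)
        counts = []
        for delta in np.linspace(0, np.abs(base.d).max(), 12):
            counts.append(len(pf.nsc_fit(df, labels, delta=float(delta)).surviving_features()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_small_class_rejected(self):
        cols = list("abc")
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=cols)
        labels = pd.Series(["X", "X", "Y"], index=cols)
        with pytest.raises(pf.PanelforgeError, match="fewer than 2"):
            pf.nsc_fit(df, labels)

    def test_se_conventions_differ_as_documented(self):
        rng = np.random.default_rng(9)
        df, labels = _random_instance(rng)
        plus = pf.nsc_fit(df, labels, se_convention="+")
        minus = pf.nsc_fit(df, labels, se_convention="-")
        n = df.shape[1]
        nk = plus.n_k
        np.testing.assert_allclose(plus.m_k, np.sqrt(1 / nk + 1 / n))
        np.testing.assert_allclose(minus.m_k, np.sqrt(1 / nk - 1 / n))


class TestScore:
    def test_sample_at_shrunken_centroid_classified_to_that_class(self):
        rng = np.random.default_rng(11)
        df, labels = _random_instance(rng, k=3)
        model = pf.nsc_fit(df, labels, delta=0.2, priors="uniform")
        for ci, cls in enumerate(model.classes):
            sample = pd.Series(model.shrunken_centroids[:, ci], index=df.index)
            assert pf.nsc_score(model, sample)[2].iloc[0] == cls

    def test_equidistant_sample_splits_posterior(self):
        cols = list("abcd")
        df = pd.DataFrame([[0.0, 2.0, 4.0, 6.0]], index=["f"], columns=cols)
        labels = pd.Series(["X", "X", "Y", "Y"], index=cols)
        model = pf.nsc_fit(df, labels, priors="uniform")
        # centroids are 1 and 5; x* = 3 is equidistant
        post = pf.nsc_score(model, pd.Series([3.0], index=["f"]))[1]
        np.testing.assert_allclose(post.iloc[0].to_numpy(), [0.5, 0.5], atol=1e-12)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(12)
        df, labels = _random_instance(rng, k=3)
        model = pf.nsc_fit(df, labels)
        x = pd.DataFrame(rng.normal(size=(df.shape[0], 7)), index=df.index)
        post = pf.nsc_score(model, x)[1]
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_feature_named(self):
        rng = np.random.default_rng(13)
        df, labels = _random_instance(rng)
        model = pf.nsc_fit(df, labels)
        bad = pd.Series(np.zeros(df.shape[0] - 1), index=df.index[1:])
        with pytest.raises(pf.PanelforgeError, match=str(df.index[0])):
            pf.nsc_score(model, bad)

    def test_zero_delta_equals_standardized_nearest_centroid(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            df, labels = _random_instance(rng)
            model = pf.nsc_fit(df, labels, delta=0.0, priors="uniform")
            x = rng.normal(size=df.shape[0])
            dists = [
                (((x - model.centroids[:, ci]) / (model.s + model.s0)) ** 2).sum()
                for ci in range(len(model.classes))
            ]
            expected = model.classes[int(np.argmin(dists))]
            got = pf.nsc_score(model, pd.Series(x, index=df.index))[2].iloc[0]
            assert got == expected


class TestCvThreshold:
    def _separated(self, rng, p=6, n=24):
        x = rng.normal(size=(p, n)) * 0.1
        x[:, n // 2:] += 5.0
        cols = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(x, index=[f"f{j}" for j in range(p)], columns=cols)
        labels = pd.Series(["X"] * (n // 2) + ["Y"] * (n // 2), index=cols)
        return df, labels

    def test_grid_includes_endpoints(self):
        rng = np.random.default_rng(15)
        df, labels = self._separated(rng)
        model = pf.nsc_fit(df, labels)
        grid = threshold_grid(model, 30)
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(np.abs(model.d).max())

    def test_perfect_separation_zero_error_largest_delta(self):
        rng = np.random.default_rng(16)
        df, labels = self._separated(rng)
        delta_star, path = pf.nsc_cv_threshold(df, labels, n_folds=4, seed=2)
        zero = path[path["cv_error"] == 0.0]
        assert not zero.empty
        assert delta_star == pytest.approx(zero["delta"].max())

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(18)
        df, labels = _random_instance(rng, p=8, n=24)
        a = pf.nsc_cv_threshold(df, labels, n_folds=4, seed=7)
        b = pf.nsc_cv_threshold(df, labels, n_folds=4, seed=7)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])
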